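import numpy as np
import pandas as pd
import pytest

from crossfmt import (FeatureTable, SimulationConfig, find_markers,
                      generate_paired_study, generate_tree, normalize_relative,
                      otu_to_ko_table, write_bundle)
from crossfmt.pipeline import _load_bundle
from crossfmt.simulate import taxonomy_from_tree
from crossfmt.tables import UNCLASSIFIED


class TestGenerateTree:
    def test_two_leaves_single_cherry(self):
        tree = generate_tree(2, seed=0)
        assert sorted(t.name for t in tree.tips()) == ["OTU_1", "OTU_2"]
        assert len(tree.children) == 2

    def test_same_seed_identical_newick(self):
        a = str(generate_tree(20, seed=5))
        b = str(generate_tree(20, seed=5))
        assert a == b

    def test_bifurcating_internal_node_count(self):
        # a rooted bifurcating tree with n leaves has n - 1 internal nodes
        tree = generate_tree(50, seed=1)
        internals = [n for n in tree.traverse(include_self=True)
                     if not n.is_tip()]
        assert len(internals) == 49
        assert all(len(n.children) == 2 for n in internals)

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(1, seed=0)


class TestTaxonomyFromTree:
    def test_ranks_nest_consistently(self):
        tree = generate_tree(40, seed=3)
        taxonomy = taxonomy_from_tree(tree)
        frame = taxonomy.lineages
        assert len(frame) == 40
        # genus never spans families; family never spans phyla
        known = frame[frame["genus"] != UNCLASSIFIED]
        assert (known.groupby("genus")["family"].nunique() == 1).all()
        assert (frame.groupby("family")["phylum"].nunique() == 1).all()


class TestOtuToKo:
    def test_identity_gene_content_zero_noise(self, rng):
        values = rng.integers(1, 40, size=(4, 3)).astype(float)
        otu = FeatureTable(pd.DataFrame(values, index=list("abcd"),
                                        columns=["o1", "o2", "o3"]))
        gc = pd.DataFrame(np.eye(3), index=["o1", "o2", "o3"],
                          columns=["k1", "k2", "k3"])
        ko = otu_to_ko_table(otu, gc, noise_cv=0.0)
        np.testing.assert_allclose(ko.values(), normalize_relative(otu).values())
        assert ko.kind == "ko" and ko.normalization == "relative"

    def test_hand_two_by_three_product(self):
        otu = FeatureTable(pd.DataFrame([[1.0, 3.0]], index=["s"],
                                        columns=["o1", "o2"]))
        gc = pd.DataFrame([[1.0, 0.0, 2.0], [0.0, 4.0, 2.0]],
                          index=["o1", "o2"], columns=["k1", "k2", "k3"])
        # relative otu = (0.25, 0.75); product = (0.25, 3.0, 2.0); sum 5.25
        ko = otu_to_ko_table(otu, gc, noise_cv=0.0)
        np.testing.assert_allclose(ko.values()[0],
                                   np.array([0.25, 3.0, 2.0]) / 5.25)

    def test_doubling_private_otu_doubles_its_kos_premass(self):
        gc = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["o1", "o2"],
                          columns=["k1", "k2"])
        t1 = FeatureTable(pd.DataFrame([[1.0, 1.0]], index=["s"],
                                       columns=["o1", "o2"]))
        t2 = FeatureTable(pd.DataFrame([[2.0, 1.0]], index=["s"],
                                       columns=["o1", "o2"]))
        k1 = otu_to_ko_table(t1, gc, noise_cv=0.0).values()[0]
        k2 = otu_to_ko_table(t2, gc, noise_cv=0.0).values()[0]
        # ratio of k1-mass to k2-mass doubles
        assert (k2[0] / k2[1]) == pytest.approx(2 * k1[0] / k1[1])

    def test_negative_gene_content_rejected(self, rng):
        otu = FeatureTable(pd.DataFrame([[1.0, 1.0]], index=["s"],
                                        columns=["o1", "o2"]))
        gc = pd.DataFrame([[1.0], [-0.5]], index=["o1", "o2"], columns=["k1"])
        with pytest.raises(ValueError, match="nonnegative"):
            otu_to_ko_table(otu, gc)


class TestGeneratePairedStudy:
    def test_bit_reproducible_under_fixed_seed(self):
        config = SimulationConfig(n_otus=40, n_kos=60, samples_per_group=4,
                                  n_diff_otus=6, seed=9)
        b1 = generate_paired_study(config)
        b2 = generate_paired_study(config)
        pd.testing.assert_frame_equal(b1.donor_otu.data, b2.donor_otu.data)
        pd.testing.assert_frame_equal(b1.recipient_ko.data, b2.recipient_ko.data)
        assert str(b1.tree) == str(b2.tree)
        assert b1.truth.otu_signs == b2.truth.otu_signs

    def test_shapes_and_metadata(self, small_bundle):
        cfg = small_bundle.config
        assert small_bundle.donor_otu.shape == (2 * cfg.samples_per_group,
                                                cfg.n_otus)
        assert small_bundle.donor_ko.shape[1] == cfg.n_kos
        assert set(small_bundle.donor_metadata["group"]) == {"H", "M"}
        assert set(small_bundle.recipient_metadata["host"]) == {"mouse"}
        leaves = {t.name for t in small_bundle.tree.tips()}
        assert set(small_bundle.donor_otu.feature_ids) == leaves

    def test_truth_signs_valid(self, small_bundle):
        truth = small_bundle.truth
        assert set(truth.otu_signs.values()) <= {1, -1}
        assert len(truth.otu_signs) == small_bundle.config.n_diff_otus
        assert set(truth.otu_signs) <= set(small_bundle.donor_otu.feature_ids)
        # default concordant_fraction=1: recipient signs match donor signs
        assert truth.recipient_otu_signs == truth.otu_signs

    def test_planted_signs_split_across_phyla(self, small_bundle):
        tax = small_bundle.taxonomy
        up_phyla = {tax.taxon_at(o, "phylum")
                    for o, s in small_bundle.truth.otu_signs.items() if s > 0}
        down_phyla = {tax.taxon_at(o, "phylum")
                      for o, s in small_bundle.truth.otu_signs.items() if s < 0}
        assert up_phyla.isdisjoint(down_phyla)

    def test_amplification_one_equalizes_planted_effects(self):
        # with amplification=1 the estimated planted log2 effect is the same
        # in donor and recipient (up to sampling error)
        config = SimulationConfig(amplification=1.0, seed=11)
        bundle = generate_paired_study(config)
        donor_e = _mean_planted_effect(bundle.donor_otu, bundle.donor_metadata,
                                       bundle.truth.otu_signs)
        recip_e = _mean_planted_effect(bundle.recipient_otu,
                                       bundle.recipient_metadata,
                                       bundle.truth.otu_signs)
        assert recip_e == pytest.approx(donor_e, abs=0.4)
        assert donor_e == pytest.approx(config.log2_effect, abs=0.4)

    def test_null_config_plants_nothing_detectable(self):
        config = SimulationConfig(log2_effect=0.0, amplification=1.0, seed=13)
        bundle = generate_paired_study(config)
        markers = find_markers(bundle.donor_otu, bundle.donor_metadata,
                               profile="default")
        # BH at q<0.1 under a global null: rarely any discovery
        assert len(markers) <= 5

    def test_group_p_present_when_requested(self):
        config = SimulationConfig(n_otus=40, n_kos=60, samples_per_group=4,
                                  n_diff_otus=6, include_group_p=True, seed=3)
        bundle = generate_paired_study(config)
        assert set(bundle.recipient_metadata["group"]) == {"H", "M", "P"}
        assert bundle.recipient_otu.shape[0] == 12

    def test_bundle_round_trip_through_disk(self, tmp_path, small_bundle):
        write_bundle(small_bundle, tmp_path / "bundle")
        back = _load_bundle(tmp_path / "bundle")
        assert back.donor_otu == small_bundle.donor_otu
        assert back.truth.otu_signs == small_bundle.truth.otu_signs
        assert back.truth.amplification == small_bundle.truth.amplification
        assert {t.name for t in back.tree.tips()} == \
               {t.name for t in small_bundle.tree.tips()}


def _mean_planted_effect(table, metadata, signs):
    rel = normalize_relative(table).data
    h = rel.loc[metadata.index[metadata["group"] == "H"]]
    m = rel.loc[metadata.index[metadata["group"] == "M"]]
    effects = []
    for otu, sign in signs.items():
        ratio = (m[otu].mean() + 1e-9) / (h[otu].mean() + 1e-9)
        effects.append(sign * np.log2(ratio))
    return float(np.mean(effects))
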
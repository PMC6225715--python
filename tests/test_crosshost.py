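import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix

from crossfmt import (FeatureTable, amplification_factor, concordant_markers,
                      mean_between_group_distance, shared_features)
from crossfmt.crosshost import format_fold
from crossfmt.tables import TaxonomyMap


def meta(groups, host="cow"):
    ids = [f"{host}{i}" for i in range(len(groups))]
    return pd.DataFrame({"group": groups, "host": [host] * len(groups)},
                        index=pd.Index(ids, name="sample_id"))


def dm_from_blocks(block_hh, block_mm, block_hm, host="cow"):
    n_h, n_m = block_hh.shape[0], block_mm.shape[0]
    d = np.zeros((n_h + n_m, n_h + n_m))
    d[:n_h, :n_h] = block_hh
    d[n_h:, n_h:] = block_mm
    d[:n_h, n_h:] = block_hm
    d[n_h:, :n_h] = block_hm.T
    np.fill_diagonal(d, 0.0)
    ids = [f"{host}{i}" for i in range(n_h + n_m)]
    return DistanceMatrix(d, ids)


class TestMeanBetweenGroupDistance:
    def test_constant_distances(self):
        hm = np.full((2, 2), 0.42)
        dm = dm_from_blocks(np.zeros((2, 2)), np.zeros((2, 2)), hm)
        m = meta(["H", "H", "M", "M"])
        assert mean_between_group_distance(dm, m, "H", "M") == pytest.approx(0.42)

    def test_hand_block_mean(self):
        hm = np.array([[0.1, 0.2], [0.3, 0.4]])
        dm = dm_from_blocks(np.zeros((2, 2)), np.zeros((2, 2)), hm)
        m = meta(["H", "H", "M", "M"])
        assert mean_between_group_distance(dm, m, "H", "M") == pytest.approx(0.25)

    def test_same_group_rejected(self):
        dm = dm_from_blocks(np.zeros((2, 2)), np.zeros((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError, match="distinct"):
            mean_between_group_distance(dm, meta(["H", "H", "M", "M"]), "H", "H")

    def test_invariant_under_reordering_and_label_swap(self, rng):
        hm = rng.random((3, 2))
        within_h = rng.random((3, 3))
        within_m = rng.random((2, 2))
        dm = dm_from_blocks((within_h + within_h.T) / 2,
                            (within_m + within_m.T) / 2, hm)
        m = meta(["H", "H", "H", "M", "M"])
        forward = mean_between_group_distance(dm, m, "H", "M")
        backward = mean_between_group_distance(dm, m, "M", "H")
        assert forward == pytest.approx(backward)
        perm = [4, 2, 0, 3, 1]
        dm2 = DistanceMatrix(np.asarray(dm.data)[np.ix_(perm, perm)],
                             [dm.ids[i] for i in perm])
        assert mean_between_group_distance(dm2, m, "H", "M") == pytest.approx(forward)


class TestAmplificationFactor:
    def test_printed_otu_distances_give_three_fold(self):
        assert amplification_factor(0.104, 0.312) == pytest.approx(3.0)

    def test_printed_ko_distances_round_to_23_fold(self):
        fold = amplification_factor(0.017, 0.389)
        assert fold == pytest.approx(22.88, abs=0.005)
        assert format_fold(fold) == "23-fold"

    def test_identity(self):
        assert amplification_factor(0.2, 0.2) == pytest.approx(1.0)

    def test_reciprocal_product_is_one(self, rng):
        for _ in range(20):
            a, b = rng.random(2) + 0.01
            assert amplification_factor(a, b) * amplification_factor(b, a) \
                == pytest.approx(1.0)

    def test_nonpositive_donor_rejected(self):
        with pytest.raises(ValueError):
            amplification_factor(0.0, 0.3)


def two_host_tables(donor_values, recipient_values, features):
    donor = FeatureTable(pd.DataFrame(
        donor_values, index=["cowH", "cowH2", "cowM", "cowM2"], columns=features))
    recipient = FeatureTable(pd.DataFrame(
        recipient_values, index=["mH", "mH2", "mM", "mM2"], columns=features))
    dm = pd.DataFrame({"group": ["H", "H", "M", "M"], "host": ["cow"] * 4},
                      index=pd.Index(donor.sample_ids, name="sample_id"))
    rm = pd.DataFrame({"group": ["H", "H", "M", "M"], "host": ["mouse"] * 4},
                      index=pd.Index(recipient.sample_ids, name="sample_id"))
    return donor, dm, recipient, rm


class TestSharedFeatures:
    def test_recipient_subset_of_donor_gives_one(self):
        features = ["o1", "o2", "o3"]
        donor, dmeta, recipient, rmeta = two_host_tables(
            np.ones((4, 3)), [[1, 1, 0]] * 4, features)
        report = shared_features(donor, dmeta, recipient, rmeta, rank="otu")
        assert report.shared_fraction == {"H": 1.0, "M": 1.0}

    def test_disjoint_taxa_give_zero(self):
        features = ["o1", "o2"]
        donor, dmeta, recipient, rmeta = two_host_tables(
            [[1, 0]] * 4, [[0, 1]] * 4, features)
        report = shared_features(donor, dmeta, recipient, rmeta, rank="otu")
        assert report.shared_fraction == {"H": 0.0, "M": 0.0}

    def test_hand_case_seventy_percent_shared_abundance(self):
        features = ["shared", "novel"]
        donor, dmeta, recipient, rmeta = two_host_tables(
            [[1, 0]] * 4, [[7, 3]] * 4, features)
        report = shared_features(donor, dmeta, recipient, rmeta, rank="otu")
        assert report.shared_fraction["H"] == pytest.approx(0.7)

    def test_count_based_mode(self):
        features = ["a", "b", "c", "d"]
        donor, dmeta, recipient, rmeta = two_host_tables(
            [[1, 1, 0, 0]] * 4, [[5, 1, 1, 1]] * 4, features)
        report = shared_features(donor, dmeta, recipient, rmeta, rank="otu",
                                 weighted=False)
        assert report.shared_fraction["H"] == pytest.approx(0.5)

    def test_genus_rank_matching_via_taxonomy(self):
        features = ["o1", "o2"]
        taxonomy = TaxonomyMap(pd.DataFrame(
            {"phylum": ["P1", "P1"], "family": ["F1", "F1"],
             "genus": ["G1", "G1"]},
            index=pd.Index(features, name="otu_id")))
        # different OTU ids but same genus: fully shared at genus rank
        donor, dmeta, recipient, rmeta = two_host_tables(
            [[1, 0]] * 4, [[0, 1]] * 4, features)
        report = shared_features(donor, dmeta, recipient, rmeta,
                                 taxonomy=taxonomy, rank="genus")
        assert report.shared_fraction["H"] == pytest.approx(1.0)

    def test_unclassified_never_matches(self):
        features = ["o1", "o2"]
        taxonomy = TaxonomyMap(pd.DataFrame(
            {"phylum": ["P1", "P1"], "family": ["F1", "F1"],
             "genus": [None, None]},
            index=pd.Index(features, name="otu_id")))
        donor, dmeta, recipient, rmeta = two_host_tables(
            [[1, 0]] * 4, [[0, 1]] * 4, features)
        report = shared_features(donor, dmeta, recipient, rmeta,
                                 taxonomy=taxonomy, rank="genus")
        assert report.shared_fraction["H"] == pytest.approx(0.0)


def marker_frame(signs):
    return pd.DataFrame({"sign": list(signs.values()),
                         "p": [0.001] * len(signs)},
                        index=pd.Index(signs.keys(), name="feature_id"))


class TestConcordantMarkers:
    def test_identical_marker_sets_fully_concordant(self):
        donor = marker_frame({"K1": 1, "K2": -1, "K3": 1})
        out = concordant_markers(donor, donor.copy(), rank="otu")
        assert set(out["taxon"]) == {"K1", "K2", "K3"}

    def test_flipped_directions_give_empty(self):
        donor = marker_frame({"K1": 1, "K2": -1})
        recipient = marker_frame({"K1": -1, "K2": 1})
        out = concordant_markers(donor, recipient, rank="otu")
        assert len(out) == 0

    def test_partial_concordance(self):
        donor = marker_frame({"K1": 1, "K2": -1, "K3": 1})
        recipient = marker_frame({"K1": 1, "K2": 1, "K4": 1})
        out = concordant_markers(donor, recipient, rank="otu")
        assert set(out["taxon"]) == {"K1"}

    def test_genus_rank_concordance(self):
        taxonomy = TaxonomyMap(pd.DataFrame(
            {"phylum": ["P1", "P1"], "family": ["F1", "F1"],
             "genus": ["G1", "G1"]},
            index=pd.Index(["o1", "o2"], name="otu_id")))
        donor = marker_frame({"o1": 1})
        recipient = marker_frame({"o2": 1})  # different OTU, same genus
        out = concordant_markers(donor, recipient, taxonomy=taxonomy,
                                 rank="genus")
        assert set(out["taxon"]) == {"G1"}
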
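"""Generate a synthetic paired donor/recipient FMT study and inspect it.

The bundle contains donor (cow) and recipient (mouse) OTU count tables,
induced KO tables, a random phylogeny, a KO->pathway map, a taxonomy, and
the planted ground truth (which OTUs/pathways differ between the healthy
group H and the diseased group M, and by how much the recipient effect is
amplified).
"""

from crossfmt import SimulationConfig, generate_paired_study, write_bundle

config = SimulationConfig(seed=1)  # defaults: 12 samples/group, 150 OTUs,
                                   # log2 effect 1.5, amplification 3
bundle = generate_paired_study(config)

print(f"donor OTU table:     {bundle.donor_otu.shape} (samples x OTUs)")
print(f"donor KO table:      {bundle.donor_ko.shape}")
print(f"recipient OTU table: {bundle.recipient_otu.shape}")
print(f"planted differential OTUs: {len(bundle.truth.otu_signs)} "
      f"({sum(1 for s in bundle.truth.otu_signs.values() if s > 0)} up in M)")
print(f"planted pathways: {bundle.truth.pathway_signs}")

write_bundle(bundle, "scratch/example_bundle")
print("bundle written to scratch/example_bundle/ "
      "(tables TSV, tree newick, truth JSON)")
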
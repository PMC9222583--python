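"""Generate the synthetic study dataset.

Emulates the study design: 2 ecomorphs x 3 tissues x 3 pools, ~600
transcripts with planted ORFs, pooled allele counts with ~1% alternatively
fixed SNPs over a shared-variation background, NB expression counts with
planted tissue-specific and universal fold changes, and 37 landmark
configurations (19 wood, 18 rock) with a planted mean-shape displacement.
"""

from ecomorphdiv.synthdata import simulate_all

from _common import DATA, SIM

truth = simulate_all(SIM, DATA)

print(f"wrote {DATA}")
print(f"  transcripts          : {SIM.n_genes}")
print(f"  planted af-SNPs      : {len(truth.true_af_snps)}")
print(f"  planted DE (tissue)  : {len(truth.true_de)}")
print(f"  planted universal DE : {len(truth.true_universal_de)}")
print(f"  landmark specimens   : {len(truth.true_shape_classes)}")
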
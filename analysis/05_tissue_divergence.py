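"""Tissue-wise transcriptomic divergence.

Per tissue: proportions of expressed genes that are DE / highly DE
(universally DE genes excluded), the af-SNP frequency among genes with
non-universal expression, pairwise Fisher tests, the top-1%/5% composition
of the pooled significance ranking, and the highly-DE x af-SNP overlap.
"""

import pandas as pd

from ecomorphdiv import diffexpr, tissuediv as tdiv

from _common import RESULTS

de = pd.read_csv(RESULTS / "de.tsv", sep="\t")
fpkm = pd.read_csv(RESULTS / "fpkm.tsv", sep="\t")
eff = pd.read_csv(RESULTS / "snp_effects.tsv", sep="\t")

expressed = diffexpr.expressed_in_tissue(fpkm, how="either")
uni_de, uni_high = tdiv.universal_sets(de)
props, prop_tests = tdiv.tissue_de_proportions(de, expressed, uni_de, uni_high)
props.to_csv(RESULTS / "tissue_de_proportions.tsv", sep="\t", index=False,
             lineterminator="\n")
prop_tests.to_csv(RESULTS / "tissue_de_tests.tsv", sep="\t", index=False,
                  lineterminator="\n")

af = eff[eff["af_snp"]]
af_genes = set(af["contig"])
nonsyn = set(af.loc[af["effect"] == "non-synonymous", "contig"])
in_orf = set(af.loc[af["location"] == "coding", "contig"])
freqs, freq_tests = tdiv.tissue_afsnp_frequency(
    af_genes, expressed, af_nonsyn_genes=nonsyn, af_orf_genes=in_orf
)
freqs.to_csv(RESULTS / "tissue_afsnp_frequency.tsv", sep="\t", index=False,
             lineterminator="\n")

top = tdiv.top_quantile_composition(de)
top.to_csv(RESULTS / "top_quantile_composition.tsv", sep="\t", index=False,
           lineterminator="\n")
syn = set(af.loc[af["effect"] == "synonymous", "contig"])
overlap, overlap_tests = tdiv.de_afsnp_overlap(de, af_genes, nonsyn, syn)
overlap.to_csv(RESULTS / "de_afsnp_overlap.tsv", sep="\t", index=False,
               lineterminator="\n")

print(f"universal DE genes excluded: {len(uni_de)} "
      f"(highly DE: {len(uni_high)})")
print(props.to_string(index=False))
print("\naf-SNP frequency per tissue (non-universal expression):")
print(freqs.to_string(index=False))
print("\ntop-quantile composition:")
print(top.to_string(index=False))
print("\nhighly-DE x af-SNP overlap:")
print(overlap.to_string(index=False))
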
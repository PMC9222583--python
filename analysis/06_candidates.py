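"""Candidate genes for radula divergence.

Two filters: expression-based (highly DE between radulae, not DE between
mantles or feet) and SNP-based (>= 1 non-synonymous af-SNP, expressed in
the radula of both morphs).  Reports the per-candidate non-synonymous
af-SNP count distribution and density folds.
"""

import pandas as pd

from ecomorphdiv import candidates as cand

from _common import RESULTS

de = pd.read_csv(RESULTS / "de.tsv", sep="\t")
eff = pd.read_csv(RESULTS / "snp_effects.tsv", sep="\t")
fpkm = pd.read_csv(RESULTS / "fpkm.tsv", sep="\t")
dens = pd.read_csv(RESULTS / "af_snp_density.tsv", sep="\t", index_col=0)

expr_set = cand.expression_candidates(de)
af_flags = pd.Series(
    eff["af_snp"].to_numpy(dtype=bool),
    index=pd.MultiIndex.from_frame(eff[["contig", "position"]]),
)
snp_set = cand.snp_candidates(eff, af_flags, fpkm)
sets = cand.CandidateSet(expr_set, snp_set)
report = cand.candidate_report(sets, eff, af_flags, dens)

out = pd.DataFrame({"gene": sorted(expr_set | snp_set)}).assign(
    expression_based=lambda d: d["gene"].isin(expr_set),
    snp_based=lambda d: d["gene"].isin(snp_set),
)
out.to_csv(RESULTS / "candidates.tsv", sep="\t", index=False,
           lineterminator="\n")

print(f"expression-based candidates: {report['n_expression_candidates']}")
print(f"SNP-based candidates       : {report['n_snp_candidates']}")
print(f"intersection               : {report['n_intersection']}")
print(f"fraction with exactly one non-syn af-SNP: "
      f"{report['fraction_with_one_nonsyn_af_snp']:.2f} "
      f"(max {report['max_nonsyn_af_snps']})")
if "top_density_genes" in report:
    print(f"highest density fold: {report['top_density_genes'][0]} "
          f"({report['top_density_fold_vs_all'][0]:.1f}-fold vs all)")
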
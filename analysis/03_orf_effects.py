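"""Longest-ORF annotation and synonymous / non-synonymous classification of
the called SNPs, plus per-gene non-synonymous af-SNP density folds.

The density fold compares each gene's non-synonymous af-SNPs per kb of ORF
against all ORF-bearing transcripts and against af-SNP-bearing transcripts.
"""

import pandas as pd

from ecomorphdiv import orfcodon, popdiv
from ecomorphdiv.io_formats import parse_fasta

from _common import DATA, RESULTS

seqs = parse_fasta(DATA / "transcripts.fasta")
snp_df = pd.read_csv(RESULTS / "snps.tsv", sep="\t")
snps = [
    popdiv.SnpRecord(r.contig, int(r.position), r.major, r.minor, (), (),
                     float(r.maf), bool(r.af_snp))
    for r in snp_df.itertuples()
]

orfs, n_excluded = orfcodon.annotate_orfs(seqs)
effects = orfcodon.classify_all(snps, orfs, seqs)
eff_df = orfcodon.effects_table(effects)
eff_df["af_snp"] = snp_df["af_snp"].to_numpy()
eff_df.to_csv(RESULTS / "snp_effects.tsv", sep="\t", index=False,
              lineterminator="\n")

af_flags = {(r.contig, int(r.position)): bool(r.af_snp)
            for r in snp_df.itertuples()}
dens = orfcodon.af_snp_density(orfs, effects, af_flags)
dens.to_csv(RESULTS / "af_snp_density.tsv", sep="\t", lineterminator="\n")

coding = eff_df[eff_df["location"] == "coding"]
af_coding = coding[coding["af_snp"]]
top = dens.sort_values("fold_vs_all", ascending=False).head(3)
print(f"ORFs found             : {len(orfs)} ({n_excluded} transcripts without)")
print(f"coding SNPs            : {len(coding)} "
      f"({(coding['effect'] == 'synonymous').sum()} syn, "
      f"{(coding['effect'] == 'non-synonymous').sum()} non-syn)")
print(f"af-SNPs in ORFs        : {len(af_coding)} "
      f"({(af_coding['effect'] == 'non-synonymous').sum()} non-syn)")
print("top density folds vs all transcripts:")
for gene, row in top.iterrows():
    print(f"  {gene}: {row.fold_vs_all:.1f}-fold "
          f"({int(row.nonsyn_af_snps)} non-syn af-SNPs / {row.orf_kb:.2f} kb)")
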
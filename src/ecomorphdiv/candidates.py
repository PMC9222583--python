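"""Candidate-gene filters for radula-shape divergence.

Two sets: expression-based candidates (highly DE between the radulae,
FDR <= 1e-10 and |FC| >= 4, but not DE between mantles or feet, FDR >=
1e-5 and |FC| <= 4) and SNP-based candidates (at least one non-synonymous
af-SNP, expressed — mean FPKM >= 1 — in the radula of both morphs).  The
two sets were observed to be non-overlapping in the emulated study design;
any intersection is reported, not removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RADULA = "radula"
OTHER_TISSUES = ("mantle", "foot")


@dataclass
class CandidateSet:
    expression_based: set[str] = field(default_factory=set)
    snp_based: set[str] = field(default_factory=set)

    @property
    def intersection(self) -> set[str]:
        return self.expression_based & self.snp_based


def expression_candidates(
    de: pd.DataFrame,
    fdr_high: float = 1e-10,
    fdr_not_de: float = 1e-5,
    fc_min: float = 4.0,
) -> set[str]:
    """Genes highly DE in the radula and not DE in mantle or foot.

    Inclusion: radula FDR <= ``fdr_high`` and |FC| >= ``fc_min``; for each
    of mantle and foot: FDR >= ``fdr_not_de`` and |FC| <= ``fc_min``.  A
    gene untested in a tissue fails the radula criterion and passes the
    not-DE criterion; such genes are counted in a log line.
    """
    lfc_min = np.log2(fc_min)
    fdr = de.pivot(index="gene", columns="tissue", values="fdr")
    lfc = de.pivot(index="gene", columns="tissue", values="log2fc").abs()
    n_untested = int(fdr.isna().any(axis=1).sum())
    if n_untested:
        log.info("%d genes untested in at least one tissue", n_untested)
    if RADULA not in fdr.columns:
        return set()
    include = (fdr[RADULA] <= fdr_high) & (lfc[RADULA] >= lfc_min)
    include = include.fillna(False)
    for tissue in OTHER_TISSUES:
        if tissue not in fdr.columns:
            continue
        ok = (fdr[tissue] >= fdr_not_de) & (lfc[tissue] <= lfc_min)
        ok = ok.where(~fdr[tissue].isna(), True)  # untested passes not-DE gate
        include &= ok
    return set(include.index[include])


def snp_candidates(
    effects: pd.DataFrame,
    af_flags: pd.Series,
    fpkm_table: pd.DataFrame,
) -> set[str]:
    """Genes with >= 1 non-synonymous af-SNP, expressed in both radulae.

    ``effects`` is the per-SNP effect table (contig, position, effect);
    ``af_flags`` is indexed by (contig, position); expression requires the
    mean-FPKM >= 1 flag in the radula of each morph.
    """
    eff = effects.set_index(["contig", "position"])
    af_idx = af_flags[af_flags].index
    nonsyn_af_genes = {
        contig
        for contig, pos in af_idx
        if (contig, pos) in eff.index
        and eff.loc[(contig, pos), "effect"] == "non-synonymous"
    }
    radula = fpkm_table[fpkm_table["tissue"] == RADULA]
    expressed_both = set(
        radula.groupby("gene")["expressed"].all().pipe(lambda s: s.index[s])
    )
    return nonsyn_af_genes & expressed_both


def candidate_report(
    sets: CandidateSet,
    effects: pd.DataFrame,
    af_flags: pd.Series,
    densities: pd.DataFrame | None = None,
) -> dict:
    """Summary report: set sizes, the distribution of non-synonymous
    af-SNP counts over SNP-based candidates (fraction with exactly one and
    the maximum), and the density-fold ranking head."""
    eff = effects.copy()
    eff["af"] = [
        bool(af_flags.get((c, p), False))
        for c, p in zip(eff["contig"], eff["position"])
    ]
    nonsyn_af = eff[(eff["af"]) & (eff["effect"] == "non-synonymous")]
    per_gene = nonsyn_af.groupby("contig").size()
    per_gene = per_gene[per_gene.index.isin(sets.snp_based)]
    report = {
        "n_expression_candidates": len(sets.expression_based),
        "n_snp_candidates": len(sets.snp_based),
        "n_intersection": len(sets.intersection),
        "fraction_with_one_nonsyn_af_snp": (
            float((per_gene == 1).mean()) if len(per_gene) else float("nan")
        ),
        "max_nonsyn_af_snps": int(per_gene.max()) if len(per_gene) else 0,
    }
    if densities is not None and len(densities):
        top = densities.sort_values("fold_vs_all", ascending=False).head(10)
        report["top_density_genes"] = list(top.index)
        report["top_density_fold_vs_all"] = [float(x) for x in top["fold_vs_all"]]
    return report
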
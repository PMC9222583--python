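"""Tissue-wise transcriptomic divergence statistics.

Compares the three tissues on two axes of ecomorph divergence: the
proportion of expressed genes that are (highly) differentially expressed,
and the frequency of af-SNP-bearing genes among genes with non-universal
expression.  Genes (highly) DE in all three tissues — or expressed in all
three, for the SNP axis — are excluded as uninformative for
tissue-specific divergence.  Pairwise tissue contrasts use two-sided
Fisher's exact tests; the top-quantile composition ranks all gene x tissue
tests by p-value and reports each tissue's share.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TISSUES


def universal_sets(de: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Genes at tier >= DE (resp. highlyDE) in all three tissues."""
    tiers = de.pivot(index="gene", columns="tissue", values="tier")
    is_de = tiers.isin(["DE", "highlyDE"])
    is_high = tiers == "highlyDE"
    n_tissues = tiers.shape[1]
    universal_de = set(tiers.index[is_de.sum(axis=1) == n_tissues])
    universal_high = set(tiers.index[is_high.sum(axis=1) == n_tissues])
    return universal_de, universal_high


def _tissue_order(tissues) -> list[str]:
    """Canonical order (radula first: it is the percent-difference focal
    tissue), unknown labels after, alphabetically."""
    known = [t for t in TISSUES if t in tissues]
    return known + sorted(set(tissues) - set(TISSUES))


def _fisher(a_yes: int, a_no: int, b_yes: int, b_no: int) -> float:
    table = np.array([[a_yes, a_no], [b_yes, b_no]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def tissue_de_proportions(
    de: pd.DataFrame,
    expressed: pd.DataFrame,
    universal_de: set[str],
    universal_high: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue DE / highly-DE proportions with pairwise Fisher tests.

    Denominator per tissue: genes expressed in that tissue (either morph),
    minus the universal set of the corresponding tier.  ``expressed`` is
    the per (gene, tissue) either-morph flag table.  Percent-difference for
    a pair is (p_a - p_b) / p_b * 100 with the second tissue as baseline.
    """
    expr_by_tissue = {
        t: set(g.loc[g["expressed"], "gene"])
        for t, g in expressed.groupby("tissue")
    }
    de_genes = {
        t: set(g.loc[g["tier"].isin(["DE", "highlyDE"]), "gene"])
        for t, g in de.groupby("tissue")
    }
    high_genes = {
        t: set(g.loc[g["tier"] == "highlyDE", "gene"]) for t, g in de.groupby("tissue")
    }
    rows = []
    counts: dict[tuple[str, str], tuple[int, int]] = {}
    for tissue in _tissue_order(expr_by_tissue):
        for tier_name, genes, universal in (
            ("DE", de_genes, universal_de),
            ("highlyDE", high_genes, universal_high),
        ):
            denom_set = expr_by_tissue[tissue] - universal
            num_set = (genes.get(tissue, set()) & denom_set)
            denom, num = len(denom_set), len(num_set)
            if denom == 0:
                warnings.warn(f"no non-universal expressed genes in {tissue}; skipped")
                continue
            counts[(tissue, tier_name)] = (num, denom)
            rows.append((tissue, tier_name, num, denom, num / denom))
    props = pd.DataFrame(
        rows, columns=["tissue", "tier", "n", "denominator", "proportion"]
    )
    tests = []
    for tier_name in ("DE", "highlyDE"):
        present = [t for t in _tissue_order(expr_by_tissue)
                   if (t, tier_name) in counts]
        for ta, tb in combinations(present, 2):
            na, da = counts[(ta, tier_name)]
            nb, db = counts[(tb, tier_name)]
            p = _fisher(na, da - na, nb, db - nb)
            pct = (na / da - nb / db) / (nb / db) * 100 if nb else float("nan")
            tests.append((tier_name, ta, tb, pct, p))
    tests_df = pd.DataFrame(
        tests, columns=["tier", "tissue_a", "tissue_b", "percent_difference", "p"]
    )
    return props, tests_df


def tissue_afsnp_frequency(
    af_genes: set[str],
    expressed: pd.DataFrame,
    effects: pd.DataFrame | None = None,
    af_nonsyn_genes: set[str] | None = None,
    af_orf_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue af-SNP frequency among genes with non-universal expression.

    The denominator for a tissue is its expressed genes minus the
    universally expressed set (expressed in all three tissues).  Frequencies
    are reported overall, restricted to af-SNPs inside ORFs, and restricted
    to non-synonymous af-SNPs; pairwise two-sided Fisher tests compare
    tissues on the overall frequency.
    """
    expr_by_tissue = {
        t: set(g.loc[g["expressed"], "gene"]) for t, g in expressed.groupby("tissue")
    }
    tissues = _tissue_order(expr_by_tissue)
    universal_expr = (
        set.intersection(*expr_by_tissue.values()) if tissues else set()
    )
    af_orf_genes = af_orf_genes if af_orf_genes is not None else af_genes
    af_nonsyn_genes = af_nonsyn_genes if af_nonsyn_genes is not None else set()
    rows = []
    counts: dict[str, tuple[int, int]] = {}
    for tissue in tissues:
        denom_set = expr_by_tissue[tissue] - universal_expr
        denom = len(denom_set)
        if denom == 0:
            warnings.warn(f"all expressed genes universal in {tissue}")
            continue
        n_af = len(af_genes & denom_set)
        counts[tissue] = (n_af, denom)
        rows.append(
            (
                tissue, denom, n_af, n_af / denom,
                len(af_orf_genes & denom_set) / denom,
                len(af_nonsyn_genes & denom_set) / denom,
            )
        )
    freqs = pd.DataFrame(
        rows,
        columns=["tissue", "denominator", "n_af_genes", "frequency",
                 "frequency_orf", "frequency_nonsyn"],
    )
    tests = []
    for ta, tb in combinations(_tissue_order(counts), 2):
        na, da = counts[ta]
        nb, db = counts[tb]
        p = _fisher(na, da - na, nb, db - nb)
        pct = (na / da - nb / db) / (nb / db) * 100 if nb else float("nan")
        tests.append((ta, tb, pct, p))
    tests_df = pd.DataFrame(
        tests, columns=["tissue_a", "tissue_b", "percent_difference", "p"]
    )
    return freqs, tests_df


def top_quantile_composition(
    de: pd.DataFrame, fractions: tuple[float, ...] = (0.01, 0.05)
) -> pd.DataFrame:
    """Tissue shares among the top-fraction most significant tests.

    All (gene, tissue) tests are pooled and ranked by p ascending (ties by
    |log2FC| descending, then gene id); for each fraction the share of
    entries per tissue is reported.  Shares sum to 1.
    """
    ranked = de.assign(abs_lfc=de["log2fc"].abs()).sort_values(
        ["pvalue", "abs_lfc", "gene"], ascending=[True, False, True]
    )
    n = len(ranked)
    rows = []
    for frac in fractions:
        k = int(np.floor(n * frac))
        if k < 1:
            warnings.warn(f"fewer than {1/frac:.0f} entries; using top 1")
            k = 1
        top = ranked.head(k)
        shares = top["tissue"].value_counts(normalize=True)
        for tissue in de["tissue"].unique():
            rows.append((frac, tissue, int((top["tissue"] == tissue).sum()),
                         float(shares.get(tissue, 0.0))))
    return pd.DataFrame(rows, columns=["fraction", "tissue", "n", "share"])


def de_afsnp_overlap(
    de: pd.DataFrame,
    af_genes: set[str],
    af_nonsyn_genes: set[str] | None = None,
    af_syn_genes: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue overlap of highly DE genes with af-SNP-bearing genes.

    Reports, per tissue, how many highly DE genes carry at least one
    af-SNP (with synonymous / non-synonymous / noncoding-or-mixed splits),
    how many of those are exclusive to that tissue's highly DE set, and
    pairwise Fisher tests on the overlap proportion among highly DE genes.
    """
    af_nonsyn_genes = af_nonsyn_genes or set()
    af_syn_genes = af_syn_genes or set()
    high = {
        t: set(g.loc[g["tier"] == "highlyDE", "gene"]) for t, g in de.groupby("tissue")
    }
    rows = []
    counts: dict[str, tuple[int, int]] = {}
    for tissue, genes in high.items():
        overlap = genes & af_genes
        others = set().union(*(v for k, v in high.items() if k != tissue))
        exclusive = overlap - others
        counts[tissue] = (len(overlap), len(genes))
        rows.append(
            (
                tissue, len(genes), len(overlap),
                len(overlap & af_nonsyn_genes),
                len(overlap & af_syn_genes - af_nonsyn_genes),
                len(overlap - af_nonsyn_genes - af_syn_genes),
                len(exclusive),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["tissue", "n_highly_de", "n_overlap", "n_nonsyn", "n_syn_only",
                 "n_noncoding_only", "n_exclusive"],
    )
    tests = []
    for ta, tb in combinations(_tissue_order(counts), 2):
        na, ta_tot = counts[ta]
        nb, tb_tot = counts[tb]
        p = _fisher(na, ta_tot - na, nb, tb_tot - nb)
        tests.append((ta, tb, p))
    tests_df = pd.DataFrame(tests, columns=["tissue_a", "tissue_b", "p"])
    return table, tests_df
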
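"""Negative-binomial differential expression with tiered significance.

The DE caller is a self-contained conditional exact test on pooled count
data: counts are rescaled to a common library size, a common dispersion is
estimated by a trimmed method of moments, and each gene's rock-vs-wood
contrast is tested conditionally on the grand total under NB sampling.
Significance tiers follow the two-threshold scheme (DE: FDR <= 1e-2 and
linear fold change >= 4; highly DE: FDR <= 1e-10 and FC >= 4), with
Benjamini-Hochberg adjustment within each tissue contrast.

Also here: FPKM expression summaries with the >= 1 "expressed" gate, the
mapping-bias Fisher test (af-SNP-bearing x DE 2x2), and the allele-collapse
similarity check on oppositely regulated highly DE gene pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io_formats import MORPHS, SampleSheet

FDR_DE = 1e-2
FDR_HIGH = 1e-10
FC_MIN = 4.0
FDR_NOT_DE = 1e-5  # "not DE" gate used by the candidate filter
FPKM_EXPRESSED = 1.0


@dataclass
class DeModel:
    """Common-dispersion NB model: effective library sizes and phi-hat."""

    lib_sizes: pd.Series  # effective library size per sample
    dispersion: float = 0.0

    @property
    def common_scale(self) -> float:
        return float(np.exp(np.mean(np.log(self.lib_sizes))))


def normalize_libsizes(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios effective library sizes.

    Size factor per sample = median over genes (positive in every sample)
    of the ratio count / per-gene geometric mean; the effective size is the
    factor rescaled to count units by the geometric-mean total.  Falls back
    to raw totals when fewer than 50 genes are positive everywhere.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    positive = (counts > 0).all(axis=1)
    if positive.sum() < 50:
        return totals
    sub = counts.loc[positive].to_numpy(dtype=float)
    log_geomean = np.mean(np.log(sub), axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    geo_total = np.exp(np.mean(np.log(totals)))
    return pd.Series(factors * geo_total, index=counts.columns)


def _group_columns(sheet: SampleSheet) -> dict[tuple[str, str], list[str]]:
    groups: dict[tuple[str, str], list[str]] = {}
    for s, m, t in zip(sheet.samples, sheet.morph, sheet.tissue):
        groups.setdefault((m, t), []).append(s)
    return groups


def estimate_dispersion(counts: pd.DataFrame, sheet: SampleSheet,
                        lib_sizes: pd.Series) -> float:
    """Common dispersion by a trimmed method of moments.

    Counts are normalized to the common scale; within each (morph, tissue)
    replicate group, phi_g = max(0, (s^2 - m) / m^2), averaged over groups
    per gene; phi-hat is the 20%-per-tail trimmed mean over genes whose
    overall normalized mean is >= 5.  Averaging the within-group estimates
    before trimming keeps the n=3 skew bias small.
    """
    common = float(np.exp(np.mean(np.log(lib_sizes))))
    norm = counts / lib_sizes * common
    groups = [cols for cols in _group_columns(sheet).values() if len(cols) >= 2]
    if not groups:
        raise ValueError("need >= 2 replicates in at least one group")
    phis = []
    for cols in groups:
        sub = norm[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (s2 - m) / np.square(np.where(m > 0, m, 1.0)), 0.0)
        phis.append(np.maximum(0.0, phi_g))
    phi_gene = np.mean(phis, axis=0)
    overall = norm.to_numpy(dtype=float).mean(axis=1)
    keep = overall >= 5.0
    if not keep.any():
        raise ValueError("no gene with normalized mean >= 5")
    return float(stats.trim_mean(phi_gene[keep], 0.2))


def _log_nb_pmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log NB pmf with mean/dispersion parametrization (var = m + phi m^2)."""
    r = 1.0 / phi
    logp = np.log(r) - np.log(r + mean)  # log P(success)
    log1mp = np.log(mean) - np.log(r + mean)
    return gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * logp + k * log1mp


def exact_test(
    counts1: np.ndarray,
    counts2: np.ndarray,
    lib1: np.ndarray,
    lib2: np.ndarray,
    dispersion: float,
    common: float | None = None,
) -> tuple[float, float]:
    """Conditional NB exact test for one gene; returns (p, log2FC of 2 vs 1).

    Counts are rescaled to a common library size and rounded.  Conditional
    on the grand total T, the first group's sum under the null is compared
    with every split s + (T - s); the two-sided p doubles the smaller tail
    (splits as or more extreme than observed) and is capped at 1.  With
    dispersion ~0 the conditional law is the exact Binomial(T, n1/(n1+n2)).
    log2FC uses normalized group means with a 0.5 pseudo-count.
    """
    counts1 = np.asarray(counts1, dtype=float)
    counts2 = np.asarray(counts2, dtype=float)
    if common is None:
        common = float(np.exp(np.mean(np.log(np.concatenate([lib1, lib2])))))
    norm1 = counts1 / lib1 * common
    norm2 = counts2 / lib2 * common
    log2fc = float(np.log2((norm2.mean() + 0.5) / (norm1.mean() + 0.5)))

    s1 = int(round(norm1.sum()))
    s2 = int(round(norm2.sum()))
    total = s1 + s2
    if total == 0:
        return 1.0, 0.0
    n1, n2 = len(counts1), len(counts2)
    s = np.arange(total + 1)
    if dispersion < 1e-8:
        logp = stats.binom.logpmf(s, total, n1 / (n1 + n2))
    else:
        mu = total / (n1 + n2)
        # sum of n iid NB(mu, phi) is NB(n mu, phi / n)
        logp = _log_nb_pmf(s, n1 * mu, dispersion / n1) + _log_nb_pmf(
            s[::-1], n2 * mu, dispersion / n2
        )
        logp = logp - logsumexp(logp)
    left = logsumexp(logp[: s1 + 1])
    right = logsumexp(logp[s1:])
    p = 2.0 * np.exp(min(left, right))
    return float(min(1.0, p)), log2fc


def de_table(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    model: DeModel | None = None,
) -> pd.DataFrame:
    """Per-gene rock-vs-wood exact tests for every tissue contrast.

    Returns a tidy frame (gene, tissue, log2fc, pvalue) ready for
    :func:`classify_tiers`.
    """
    if model is None:
        libs = normalize_libsizes(counts)
        model = DeModel(libs, estimate_dispersion(counts, sheet, libs))
    groups = _group_columns(sheet)
    common = model.common_scale
    rows = []
    tissues = list(dict.fromkeys(sheet.tissue))
    for tissue in tissues:
        wood_cols = groups[("wood", tissue)]
        rock_cols = groups[("rock", tissue)]
        lib_w = model.lib_sizes[wood_cols].to_numpy(dtype=float)
        lib_r = model.lib_sizes[rock_cols].to_numpy(dtype=float)
        cw = counts[wood_cols].to_numpy()
        cr = counts[rock_cols].to_numpy()
        for gi, gene in enumerate(counts.index):
            p, lfc = exact_test(cw[gi], cr[gi], lib_w, lib_r,
                                model.dispersion, common)
            rows.append((gene, tissue, lfc, p))
    return pd.DataFrame(rows, columns=["gene", "tissue", "log2fc", "pvalue"])


def classify_tiers(
    de: pd.DataFrame,
    fdr_de: float = FDR_DE,
    fdr_high: float = FDR_HIGH,
    fc_min: float = FC_MIN,
) -> pd.DataFrame:
    """BH-adjust p-values within each tissue contrast and assign tiers.

    tier DE requires FDR <= ``fdr_de`` and linear |FC| >= ``fc_min``
    (|log2FC| >= log2 fc_min); tier highlyDE additionally FDR <=
    ``fdr_high``.  highlyDE is a subset of DE by construction.
    """
    out = de.copy()
    out["fdr"] = np.nan
    for tissue, idx in out.groupby("tissue").groups.items():
        pvals = out.loc[idx, "pvalue"].to_numpy()
        out.loc[idx, "fdr"] = multipletests(pvals, method="fdr_bh")[1]
    lfc_min = np.log2(fc_min)
    big_fc = np.abs(out["log2fc"]) >= lfc_min
    tier = np.where(
        (out["fdr"] <= fdr_high) & big_fc,
        "highlyDE",
        np.where((out["fdr"] <= fdr_de) & big_fc, "DE", "none"),
    )
    out["tier"] = tier
    return out


def fpkm_summary(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    sheet: SampleSheet,
    lib_sizes: pd.Series | None = None,
    threshold: float = FPKM_EXPRESSED,
) -> pd.DataFrame:
    """Mean FPKM and the expressed flag per (gene, tissue, morph).

    FPKM = count / (gene length in kb x effective library size in
    millions); a gene is expressed in a (tissue, morph) when its mean FPKM
    over that group's pools is >= ``threshold``.
    """
    if (gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if lib_sizes is None:
        lib_sizes = normalize_libsizes(counts)
    kb = gene_lengths.loc[counts.index].to_numpy(dtype=float) / 1000.0
    fpkm = counts / (lib_sizes / 1e6) / kb[:, None]
    rows = []
    for (morph, tissue), cols in _group_columns(sheet).items():
        mean_fpkm = fpkm[cols].mean(axis=1)
        for gene, val in mean_fpkm.items():
            rows.append((gene, tissue, morph, float(val), bool(val >= threshold)))
    return pd.DataFrame(
        rows, columns=["gene", "tissue", "morph", "mean_fpkm", "expressed"]
    )


def expressed_in_tissue(fpkm_table: pd.DataFrame, how: str = "either") -> pd.DataFrame:
    """Collapse the per-morph expressed flags to per (gene, tissue).

    ``how='either'``: expressed in the tissue in at least one morph;
    ``how='both'``: expressed in each morph.
    """
    agg = {"either": "any", "both": "all"}[how]
    return (
        fpkm_table.groupby(["gene", "tissue"])["expressed"].agg(agg).reset_index()
    )


def mapping_bias_test(
    de_flags: pd.Series, af_flags: pd.Series
) -> tuple[float, float, np.ndarray]:
    """Two-sided Fisher's exact test: af-SNP-bearing x DE on a common
    gene universe.  Returns (odds ratio, p, 2x2 table)."""
    common = de_flags.index.intersection(af_flags.index)
    de = de_flags.loc[common].astype(bool)
    af = af_flags.loc[common].astype(bool)
    table = np.array(
        [
            [int((af & de).sum()), int((af & ~de).sum())],
            [int((~af & de).sum()), int((~af & ~de).sum())],
        ]
    )
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        warnings.warn("degenerate margin in mapping-bias table; p set to 1")
        return float("nan"), 1.0, table
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def _shared_kmers(a: str, b: str, k: int = 11) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def allele_collapse_check(
    highly_de: pd.DataFrame,
    seqs: dict[str, str],
    identity_min: float = 0.95,
    coverage_min: float = 0.50,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag highly DE genes that look like collapsed alleles.

    For each tissue, every pair of highly DE genes with opposite regulation
    is locally aligned (match +1, mismatch -1, gap -2; k-mer prefilter
    k=11); a pair is flagged when identity exceeds ``identity_min`` over at
    least ``coverage_min`` of the shorter sequence.  Returns the flagged
    pairs and the per-tissue fraction of highly DE genes flagged.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-2,
    )
    pairs = []
    fractions: dict[str, float] = {}
    for tissue, grp in highly_de.groupby("tissue"):
        up = grp.loc[grp["log2fc"] > 0, "gene"].tolist()
        down = grp.loc[grp["log2fc"] < 0, "gene"].tolist()
        flagged_genes: set[str] = set()
        for ga in up:
            for gb in down:
                sa, sb = seqs[ga], seqs[gb]
                if not _shared_kmers(sa, sb):
                    continue
                short, long_ = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
                aln = aligner.align(short, long_)
                if len(aln) == 0:
                    continue
                best = aln[0]
                segs = best.aligned[0]
                if len(segs) == 0:
                    continue
                span = segs[-1][1] - segs[0][0]
                counts_ = best.counts()
                cols = counts_.identities + counts_.mismatches + counts_.gaps
                identity = counts_.identities / cols if cols else 0.0
                if identity > identity_min and span >= coverage_min * len(short):
                    pairs.append((tissue, ga, gb, identity, span / len(short)))
                    flagged_genes.update((ga, gb))
        n_high = grp["gene"].nunique()
        fractions[tissue] = len(flagged_genes) / n_high if n_high else 0.0
    return (
        pd.DataFrame(pairs, columns=["tissue", "gene_up", "gene_down",
                                     "identity", "coverage"]),
        fractions,
    )
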
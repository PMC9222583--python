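"""Pool-seq population divergence statistics.

Coverage standardization (multivariate-hypergeometric subsampling to a
uniform target depth), biallelic SNP calling with a global minor-allele
frequency gate, SNP-wise F_st in its heterozygosity form
(H_T - H_S) / H_T, the median pairwise F_st matrix over pools, the
combined-ecomorph F_st distribution (pools of a morph summed, e.g. 3 x 20x
-> 60x), and the alternatively-fixed-SNP (af-SNP) detector.

Estimator note: per comparison unit u with major-allele frequency p_u,
pi_u = 1 - p_u^2 - q_u^2; pi_within is the unweighted mean of the two
units' pi; pi_total uses the averaged frequency p_bar = (p_1 + p_2) / 2;
F_st = (pi_total - pi_within) / pi_total, defined 0 when pi_total = 0.
No finite-coverage bias correction is applied: the estimator then hits the
two endpoints exactly (0 for identical units, 1 for alternative fixation),
which the af-SNP criterion requires.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SyncRecord

# order of the four informative nucleotides in sync tuples
_ACGT_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}
_BASE_BY_IDX = {v: k for k, v in _ACGT_IDX.items()}
# deterministic tie-break order for allele demotion
_TIE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class SnpRecord:
    """A called biallelic SNP with per-pool major-allele frequencies."""

    contig: str
    position: int
    major: str
    minor: str
    pool_major_counts: tuple[int, ...]
    pool_minor_counts: tuple[int, ...]
    maf: float
    af_snp: bool = False

    @property
    def pool_freqs(self) -> np.ndarray:
        """Per-pool major-allele frequency over the two kept alleles."""
        maj = np.asarray(self.pool_major_counts, dtype=float)
        mino = np.asarray(self.pool_minor_counts, dtype=float)
        tot = maj + mino
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, maj / tot, np.nan)


@dataclass(frozen=True)
class FstRecord:
    """SNP-wise F_st with its heterozygosity components."""

    contig: str
    position: int
    unit: str
    pi_within: float
    pi_total: float
    fst: float


def _site_rng(seed: int, contig: str, position: int, pool: int) -> np.random.Generator:
    """Site-order-independent substream for one (contig, position, pool)."""
    key = (zlib.crc32(contig.encode()) & 0x7FFFFFFF, position, pool)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def coverage(record: SyncRecord) -> np.ndarray:
    """Per-pool informative coverage: A+T+C+G (N and del excluded)."""
    arr = np.asarray(record.counts, dtype=np.int64)
    return arr[:, :4].sum(axis=1)


def standardize_coverage(
    sites: list[SyncRecord], target: int, seed: int
) -> list[SyncRecord]:
    """Subsample every pool of every site to exactly ``target`` coverage.

    Subsampling is without replacement (multivariate hypergeometric over the
    pool's four nucleotide counts).  Sites at which any pool has coverage
    below the target are removed entirely.  N/del counts are zeroed, having
    been excluded from coverage.
    """
    if target < 1:
        raise ValueError("target coverage must be >= 1")
    out: list[SyncRecord] = []
    for rec in sites:
        arr = np.asarray(rec.counts, dtype=np.int64)[:, :4]
        cov = arr.sum(axis=1)
        if np.any(cov < target):
            continue
        new_pools = []
        for i, row in enumerate(arr):
            if cov[i] == target:
                sub = row
            else:
                rng = _site_rng(seed, rec.contig, rec.position, i)
                sub = rng.multivariate_hypergeometric(row, target)
            new_pools.append((int(sub[0]), int(sub[1]), int(sub[2]), int(sub[3]), 0, 0))
        out.append(SyncRecord(rec.contig, rec.position, rec.reference_base,
                              tuple(new_pools)))
    return out


def call_snps(sites: list[SyncRecord], maf_threshold: float = 0.10) -> list[SnpRecord]:
    """Call biallelic SNPs at a global minor-allele-frequency threshold.

    Alleles are ranked by their summed count over all pools (ties broken
    A < C < G < T); reads of third-ranked and lower alleles are discarded.
    A site is retained iff it is polymorphic and the combined minor-allele
    frequency is >= ``maf_threshold`` (boundary kept).
    """
    snps: list[SnpRecord] = []
    for rec in sites:
        arr = np.asarray(rec.counts, dtype=np.int64)[:, :4]  # A T C G per pool
        total = arr.sum(axis=0)
        bases = [_BASE_BY_IDX[i] for i in range(4)]
        order = sorted(range(4), key=lambda i: (-total[i], _TIE_ORDER[bases[i]]))
        maj_i, min_i = order[0], order[1]
        if total[min_i] == 0:
            continue  # monomorphic
        kept = total[maj_i] + total[min_i]
        maf = total[min_i] / kept
        if maf < maf_threshold:
            continue
        snps.append(
            SnpRecord(
                contig=rec.contig,
                position=rec.position,
                major=bases[maj_i],
                minor=bases[min_i],
                pool_major_counts=tuple(int(c) for c in arr[:, maj_i]),
                pool_minor_counts=tuple(int(c) for c in arr[:, min_i]),
                maf=float(maf),
            )
        )
    return snps


def fst_from_freqs(p1: float, p2: float) -> tuple[float, float, float]:
    """(pi_within, pi_total, fst) from two units' major-allele frequencies."""
    pi1 = 1.0 - p1 * p1 - (1.0 - p1) ** 2
    pi2 = 1.0 - p2 * p2 - (1.0 - p2) ** 2
    pi_within = 0.5 * (pi1 + pi2)
    pbar = 0.5 * (p1 + p2)
    pi_total = 1.0 - pbar * pbar - (1.0 - pbar) ** 2
    fst = 0.0 if pi_total == 0.0 else (pi_total - pi_within) / pi_total
    return pi_within, pi_total, fst


def pairwise_fst(snp: SnpRecord, unit1: int, unit2: int) -> FstRecord:
    """SNP-wise F_st between two pools of a called SNP."""
    freqs = snp.pool_freqs
    p1, p2 = float(freqs[unit1]), float(freqs[unit2])
    if np.isnan(p1) or np.isnan(p2):
        raise ValueError("unit with zero kept coverage at this SNP")
    pi_w, pi_t, fst = fst_from_freqs(p1, p2)
    return FstRecord(snp.contig, snp.position, f"pool{unit1}-pool{unit2}",
                     pi_w, pi_t, fst)


def _freq_matrix(snps: list[SnpRecord]) -> np.ndarray:
    return np.array([s.pool_freqs for s in snps])


def _fst_vectorized(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    pi1 = 2 * p1 * (1 - p1)
    pi2 = 2 * p2 * (1 - p2)
    pi_w = 0.5 * (pi1 + pi2)
    pbar = 0.5 * (p1 + p2)
    pi_t = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(pi_t > 0, (pi_t - pi_w) / np.where(pi_t > 0, pi_t, 1.0), 0.0)
    return fst


def median_fst_matrix(snps: list[SnpRecord], n_pools: int) -> pd.DataFrame:
    """Symmetric pool x pool matrix of median SNP-wise F_st (diagonal 0).

    A pair with no SNP covered in both pools gets NaN.
    """
    mat = np.zeros((n_pools, n_pools))
    if snps:
        freqs = _freq_matrix(snps)
    for i in range(n_pools):
        for j in range(i + 1, n_pools):
            if not snps:
                mat[i, j] = mat[j, i] = np.nan
                continue
            p1, p2 = freqs[:, i], freqs[:, j]
            ok = ~(np.isnan(p1) | np.isnan(p2))
            if not ok.any():
                mat[i, j] = mat[j, i] = np.nan
                continue
            med = float(np.median(_fst_vectorized(p1[ok], p2[ok])))
            mat[i, j] = mat[j, i] = med
    labels = [f"pool{i}" for i in range(n_pools)]
    return pd.DataFrame(mat, index=labels, columns=labels)


def morph_pool_indices(n_pools_per_morph: int) -> tuple[list[int], list[int]]:
    """Sync column convention: wood pools first, then rock pools."""
    wood = list(range(n_pools_per_morph))
    rock = list(range(n_pools_per_morph, 2 * n_pools_per_morph))
    return wood, rock


def combined_fst_distribution(
    snps: list[SnpRecord],
    wood_pools: list[int],
    rock_pools: list[int],
    maf_threshold: float = 0.10,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-SNP F_st between the two morphs with pools summed per morph.

    Summing e.g. three 20x pools gives a 60x unit per morph.  The MAF
    filter is re-applied on the combined (all pools) counts.  Returns the
    per-SNP table and a summary with the median and mean.
    """
    rows = []
    for snp in snps:
        maj = np.asarray(snp.pool_major_counts, dtype=float)
        mino = np.asarray(snp.pool_minor_counts, dtype=float)
        w_maj, w_min = maj[wood_pools].sum(), mino[wood_pools].sum()
        r_maj, r_min = maj[rock_pools].sum(), mino[rock_pools].sum()
        tot_min = w_min + r_min
        tot = w_maj + w_min + r_maj + r_min
        if tot == 0 or min(tot_min, tot - tot_min) / tot < maf_threshold:
            continue
        p_w = w_maj / (w_maj + w_min)
        p_r = r_maj / (r_maj + r_min)
        pi_w, pi_t, fst = fst_from_freqs(p_w, p_r)
        rows.append((snp.contig, snp.position, pi_w, pi_t, fst))
    table = pd.DataFrame(
        rows, columns=["contig", "position", "pi_within", "pi_total", "fst"]
    )
    summary = {
        "n_snps": float(len(table)),
        "median_fst": float(table["fst"].median()) if len(table) else float("nan"),
        "mean_fst": float(table["fst"].mean()) if len(table) else float("nan"),
    }
    return table, summary


def detect_af_snps(
    snps: list[SnpRecord],
    wood_pools: list[int],
    rock_pools: list[int],
) -> list[SnpRecord]:
    """Flag alternatively fixed SNPs.

    A SNP is alternatively fixed iff every pool is monomorphic and the two
    morphs carry different alleles — equivalently F_st = 0 for every
    within-morph pool pair and F_st = 1 for every across-morph pair.
    Returns the input records with the ``af_snp`` flag set.
    """
    out: list[SnpRecord] = []
    for snp in snps:
        maj = np.asarray(snp.pool_major_counts)
        mino = np.asarray(snp.pool_minor_counts)
        mono = (maj == 0) | (mino == 0)
        flag = False
        if mono.all():
            # which allele each pool is fixed for: True = major
            fixed_major = maj > 0
            w = fixed_major[wood_pools]
            r = fixed_major[rock_pools]
            if (w.all() or (~w).all()) and (r.all() or (~r).all()):
                flag = bool(w[0] != r[0])
        out.append(
            SnpRecord(
                snp.contig, snp.position, snp.major, snp.minor,
                snp.pool_major_counts, snp.pool_minor_counts, snp.maf, flag,
            )
        )
    return out


def af_snp_fst_criterion(
    snp: SnpRecord, wood_pools: list[int], rock_pools: list[int]
) -> bool:
    """The F_st form of the af-SNP definition (used as a cross-check).

    True iff fst = 0 for all within-morph pool pairs and fst = 1 for all
    across-morph pairs.
    """
    freqs = snp.pool_freqs
    for group in (wood_pools, rock_pools):
        for i, a in enumerate(group):
            for b_ in group[i + 1:]:
                if abs(fst_from_freqs(freqs[a], freqs[b_])[2]) > 1e-12:
                    return False
    for a in wood_pools:
        for b_ in rock_pools:
            if abs(fst_from_freqs(freqs[a], freqs[b_])[2] - 1.0) > 1e-12:
                return False
    return True


def snp_table(snps: list[SnpRecord]) -> pd.DataFrame:
    """Flatten SNP records to a tidy frame (one row per SNP)."""
    rows = []
    for s in snps:
        row = {
            "contig": s.contig,
            "position": s.position,
            "major": s.major,
            "minor": s.minor,
            "maf": s.maf,
            "af_snp": s.af_snp,
        }
        for i, p in enumerate(s.pool_freqs):
            row[f"p_pool{i}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
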
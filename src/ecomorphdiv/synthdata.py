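"""Synthetic-data generator with known ground truth for every pipeline stage.

Emulates the study design the pipeline targets: two ecomorphs (wood, rock)
x three tissues (radula, mantle, foot) x three pools per morph, with

* transcripts that each contain exactly one planted complete ORF,
* pooled per-site allele counts (sync format) with shared variation plus a
  planted subset of sites fixed for alternative alleles between morphs,
* negative-binomial fragment counts with planted tissue-specific and
  universal fold changes, and
* 2-D landmark configurations with a planted mean-shape displacement hidden
  under a random similarity transform.

Every generator is a pure function of a :class:`SimConfig`; the seed fixes
all outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    MORPHS,
    TISSUES,
    SampleSheet,
    SyncRecord,
    write_counts,
    write_fasta,
    write_sample_sheet,
    write_sync,
    write_tps,
)

BASES = np.array(["A", "C", "G", "T"])
STOP_CODONS = ("TAA", "TAG", "TGA")

# named substreams so each generator is reproducible in isolation
_STREAMS = {"transcripts": 1, "alleles": 2, "counts": 3, "landmarks": 4}


class ConfigError(ValueError):
    """Raised when a :class:`SimConfig` violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 3 pools per morph, three tissues,
    ~1% of SNPs alternatively fixed, 8-fold planted expression changes, and
    Poisson site depths around ``mean_coverage`` so the <target-coverage
    removal path is exercised.
    """

    n_genes: int = 500
    n_pools_per_morph: int = 3
    tissues: tuple[str, ...] = TISSUES
    mean_coverage: float = 30.0
    nb_dispersion: float = 0.1
    baseline_log_expression: tuple[float, float] = (5.0, 1.0)  # ln-scale mean, sd
    de_fraction_per_tissue: float | Mapping[str, float] = 0.05
    universal_de_fraction: float = 0.01
    planted_log2fc: float = 3.0
    snp_rate_per_kb: float = 10.0
    af_snp_fraction: float = 0.01
    shared_maf_beta: tuple[float, float] = (2.0, 2.0)
    morph_fst: float = 0.14  # Balding-Nichols divergence of shared sites
    orf_fraction: float = 0.6
    mean_transcript_len: int = 600
    tissue_restricted_fraction: float = 0.5
    landmark_n: int = 12
    n_specimens_per_morph: tuple[int, int] = (19, 18)  # wood, rock
    shape_effect: float = 0.08
    shape_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        def _fracs():
            yield self.universal_de_fraction
            yield self.af_snp_fraction
            yield self.orf_fraction
            yield self.tissue_restricted_fraction
            yield self.morph_fst
            if isinstance(self.de_fraction_per_tissue, Mapping):
                yield from self.de_fraction_per_tissue.values()
            else:
                yield self.de_fraction_per_tissue

        for f in _fracs():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"fraction {f} outside [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.n_pools_per_morph < 2:
            raise ConfigError("need >= 2 pools per morph")
        if len(self.tissues) != 3:
            raise ConfigError("exactly three tissue labels expected")
        if self.nb_dispersion < 0:
            raise ConfigError("negative NB dispersion")
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        # shortest transcripts are 70% of the mean; their ORF must reach 30 nt
        if self.orf_fraction * 0.7 * self.mean_transcript_len < 30:
            raise ConfigError("orf_fraction too small: planted ORF would be < 30 nt")
        if self.landmark_n < 3:
            raise ConfigError("landmark_n must be >= 3")

    def de_fraction(self, tissue: str) -> float:
        if isinstance(self.de_fraction_per_tissue, Mapping):
            return float(self.de_fraction_per_tissue.get(tissue, 0.0))
        return float(self.de_fraction_per_tissue)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    true_de: set[tuple[str, str, int]] = field(default_factory=set)
    true_universal_de: set[str] = field(default_factory=set)
    true_af_snps: set[tuple[str, int]] = field(default_factory=set)
    true_orfs: dict[str, tuple[int, int]] = field(default_factory=dict)
    true_shape_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_de": sorted(list(t) for t in self.true_de),
            "true_universal_de": sorted(self.true_universal_de),
            "true_af_snps": sorted(list(t) for t in self.true_af_snps),
            "true_orfs": {k: list(v) for k, v in sorted(self.true_orfs.items())},
            "true_shape_classes": dict(sorted(self.true_shape_classes.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_de={(g, t, int(s)) for g, t, s in d["true_de"]},
            true_universal_de=set(d["true_universal_de"]),
            true_af_snps={(c, int(p)) for c, p in d["true_af_snps"]},
            true_orfs={k: (v[0], v[1]) for k, v in d["true_orfs"].items()},
            true_shape_classes=dict(d["true_shape_classes"]),
        )


def _scan_longest_orf(seq: str) -> tuple[int, int] | None:
    """Simple forward-strand complete-ORF scan used to vet generated
    transcripts (leftmost-longest, 0-based half-open -> returns 1-based)."""
    best: tuple[int, int] | None = None
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                j = i + 3
                while j + 3 <= n:
                    if seq[j : j + 3] in STOP_CODONS:
                        length = j + 3 - i
                        if best is None or length > best[1] - best[0] + 1 or (
                            length == best[1] - best[0] + 1 and i + 1 < best[0]
                        ):
                            best = (i + 1, j + 3)
                        break
                    j += 3
            i += 3
    return best


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + a stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


def simulate_transcripts(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate transcripts, each containing exactly one planted ORF.

    The planted ORF (ATG ... stop, length a multiple of 3) covers roughly
    ``orf_fraction`` of the transcript; flanks are random sequence.  A
    candidate transcript is rejected and regenerated whenever a stray
    complete ORF as long as the planted one appears by chance, so the
    longest complete ORF is unambiguously the planted one.
    """
    rng = config.rng("transcripts")
    truth = SimTruth()
    seqs: dict[str, str] = {}
    for g in range(config.n_genes):
        name = f"gene{g + 1:05d}"
        length = int(rng.uniform(0.7, 1.3) * config.mean_transcript_len)
        n_codons = max(10, int(config.orf_fraction * length) // 3)
        orf_len = n_codons * 3
        for _attempt in range(200):
            orf = _random_orf(rng, n_codons)
            start0 = int(rng.integers(0, length - orf_len + 1))
            left = "".join(rng.choice(BASES, size=start0))
            right = "".join(rng.choice(BASES, size=length - orf_len - start0))
            seq = left + orf + right
            found = _scan_longest_orf(seq)
            if found == (start0 + 1, start0 + orf_len):
                break
        else:  # pragma: no cover - rejection virtually always succeeds
            raise RuntimeError(f"could not plant an unambiguous ORF in {name}")
        seqs[name] = seq
        truth.true_orfs[name] = (start0 + 1, start0 + orf_len)
    return seqs, truth


def simulate_pool_alleles(
    config: SimConfig, transcripts: dict[str, str]
) -> tuple[list[SyncRecord], SimTruth]:
    """Generate pooled allele counts in sync pool order wood1..wN, rock1..rN.

    SNP positions are drawn per transcript at ``snp_rate_per_kb``.  Shared
    sites draw one allele frequency per site from Beta(``shared_maf_beta``)
    used by every pool of both morphs; planted af-SNP sites fix all wood
    pools for one allele and all rock pools for the other.  An equal number
    of monomorphic filler sites is included.  Per-pool site depth is
    Poisson(``mean_coverage``).
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    rng = config.rng("alleles")
    n_pools = 2 * config.n_pools_per_morph
    a, b = config.shared_maf_beta
    records: list[SyncRecord] = []
    truth = SimTruth()
    base_index = {b_: i for i, b_ in enumerate("ATCG")}

    for name, seq in transcripts.items():
        n_snps = rng.poisson(len(seq) / 1000.0 * config.snp_rate_per_kb)
        n_snps = min(n_snps, len(seq))
        n_fill = min(int(n_snps), len(seq) - n_snps)
        pos_all = rng.choice(len(seq), size=n_snps + n_fill, replace=False) + 1
        snp_pos = np.sort(pos_all[:n_snps])
        fill_pos = np.sort(pos_all[n_snps:])
        site_list: list[tuple[int, bool]] = [(int(p), True) for p in snp_pos] + [
            (int(p), False) for p in fill_pos
        ]
        site_list.sort()
        for pos, is_snp in site_list:
            ref = seq[pos - 1]
            if ref == "N":
                continue
            depths = rng.poisson(config.mean_coverage, size=n_pools)
            counts = np.zeros((n_pools, 6), dtype=int)
            if not is_snp:
                counts[:, base_index[ref]] = depths
            else:
                alt = str(rng.choice([x for x in "ATCG" if x != ref]))
                if rng.random() < config.af_snp_fraction:
                    # alternative fixation: one morph all-ref, the other all-alt
                    wood_allele, rock_allele = (
                        (ref, alt) if rng.random() < 0.5 else (alt, ref)
                    )
                    for i in range(n_pools):
                        allele = (
                            wood_allele if i < config.n_pools_per_morph else rock_allele
                        )
                        counts[i, base_index[allele]] = depths[i]
                    truth.true_af_snps.add((name, pos))
                else:
                    p_ref = rng.beta(a, b)
                    if config.morph_fst > 0:
                        # Balding-Nichols: each morph's frequency drawn
                        # around the common one at divergence F
                        lam = (1.0 - config.morph_fst) / config.morph_fst
                        p_clip = min(max(p_ref, 0.01), 0.99)
                        p_morph = rng.beta(p_clip * lam, (1.0 - p_clip) * lam,
                                           size=2)
                    else:
                        p_morph = np.array([p_ref, p_ref])
                    pool_p = np.repeat(p_morph, config.n_pools_per_morph)
                    ref_counts = rng.binomial(depths, pool_p)
                    counts[:, base_index[ref]] = ref_counts
                    counts[:, base_index[alt]] = depths - ref_counts
            records.append(
                SyncRecord(name, pos, ref, tuple(tuple(row) for row in counts))
            )
    return records, truth


def make_sample_sheet(config: SimConfig) -> SampleSheet:
    samples, morphs, tissues, pools = [], [], [], []
    for morph in MORPHS:
        for tissue in config.tissues:
            for p in range(1, config.n_pools_per_morph + 1):
                samples.append(f"{morph}_{tissue}_p{p}")
                morphs.append(morph)
                tissues.append(tissue)
                pools.append(p)
    return SampleSheet(tuple(samples), tuple(morphs), tuple(tissues), tuple(pools))


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, SampleSheet, SimTruth]:
    """Generate the gene x sample fragment-count matrix.

    Counts are NB(mean, phi) with ln-mean = gene baseline + tissue effect
    (+ ``planted_log2fc`` * ln 2 on the rock morph for planted DE genes).
    Tissue-restricted genes are silenced in a random proper subset of
    tissues.  Universal-DE genes receive the shift in all three tissues.
    """
    rng = config.rng("counts")
    sheet = make_sample_sheet(config)
    truth = SimTruth()
    G = config.n_genes
    genes = [f"gene{g + 1:05d}" for g in range(G)]
    baseline = rng.normal(*config.baseline_log_expression, size=G)

    # tissue-restriction: which tissues a gene is expressed in
    expressed_in = np.ones((G, 3), dtype=bool)
    restricted = rng.random(G) < config.tissue_restricted_fraction
    for g in np.flatnonzero(restricted):
        n_on = int(rng.integers(1, 3))  # 1 or 2 tissues on
        on = rng.choice(3, size=n_on, replace=False)
        expressed_in[g] = False
        expressed_in[g, on] = True

    # plant universal DE among genes expressed everywhere
    all_on = np.flatnonzero(expressed_in.all(axis=1))
    n_univ = int(round(config.universal_de_fraction * G))
    univ = rng.choice(all_on, size=min(n_univ, all_on.size), replace=False)
    univ_dir = rng.choice([-1, 1], size=univ.size)
    for g, d in zip(univ, univ_dir):
        truth.true_universal_de.add(genes[g])

    # plant tissue-specific DE among genes expressed in that tissue
    de_shift = np.zeros((G, 3))
    for g, d in zip(univ, univ_dir):
        de_shift[g, :] = d
    for ti, tissue in enumerate(config.tissues):
        candidates = np.setdiff1d(np.flatnonzero(expressed_in[:, ti]), univ)
        n_de = int(round(config.de_fraction(tissue) * G))
        chosen = rng.choice(candidates, size=min(n_de, candidates.size), replace=False)
        dirs = rng.choice([-1, 1], size=chosen.size)
        for g, d in zip(chosen, dirs):
            de_shift[g, ti] = d
            truth.true_de.add((genes[g], tissue, int(d)))

    tissue_effect = rng.normal(0.0, 0.3, size=(G, 3))
    ln2fc = config.planted_log2fc * np.log(2.0)
    phi = config.nb_dispersion

    data = np.zeros((G, len(sheet)), dtype=np.int64)
    for si, (morph, tissue) in enumerate(zip(sheet.morph, sheet.tissue)):
        ti = config.tissues.index(tissue)
        ln_mean = baseline + tissue_effect[:, ti]
        ln_mean = np.where(expressed_in[:, ti], ln_mean, ln_mean - 8.0)
        if morph == "rock":
            ln_mean = ln_mean + de_shift[:, ti] * ln2fc
        mean = np.exp(ln_mean)
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
        else:
            lam = mean
        data[:, si] = rng.poisson(lam)
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"),
                          columns=list(sheet.samples))
    return counts, sheet, truth


def simulate_landmarks(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate 2-D landmark configurations for wood and rock specimens.

    Each specimen is a regular ``landmark_n``-gon; rock specimens have the
    first third of their landmarks displaced radially outward by
    ``shape_effect`` before isotropic Gaussian noise and a random rotation,
    translation, and positive scale (log-scale uniform on [-1, 1]) are
    applied.
    """
    rng = config.rng("landmarks")
    k = config.landmark_n
    theta = 2 * np.pi * np.arange(k) / k
    base = np.column_stack([np.cos(theta), np.sin(theta)])
    n_displaced = int(np.ceil(k / 3))
    truth = SimTruth()
    rows = []
    for morph, n_spec in zip(MORPHS, config.n_specimens_per_morph):
        for s in range(1, n_spec + 1):
            spec_id = f"{morph}{s:02d}"
            shape = base.copy()
            if morph == "rock":
                shape[:n_displaced] *= 1.0 + config.shape_effect
            shape = shape + rng.normal(0.0, config.shape_noise_sd, size=shape.shape)
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
            )
            scale = np.exp(rng.uniform(-1.0, 1.0))
            shift = rng.normal(0.0, 1.0, size=2)
            shape = scale * shape @ rot.T + shift
            truth.true_shape_classes[spec_id] = morph
            for j in range(k):
                rows.append((spec_id, j, shape[j, 0], shape[j, 1]))
    return pd.DataFrame(rows, columns=["specimen", "landmark", "x", "y"]), truth


def merge_truth(*parts: SimTruth) -> SimTruth:
    out = SimTruth()
    for p in parts:
        out.true_de |= p.true_de
        out.true_universal_de |= p.true_universal_de
        out.true_af_snps |= p.true_af_snps
        out.true_orfs.update(p.true_orfs)
        out.true_shape_classes.update(p.true_shape_classes)
    return out


def simulate_all(config: SimConfig, outdir: str | Path) -> SimTruth:
    """Run all four generators and write their outputs under ``outdir``.

    Files: transcripts.fasta, alleles.sync, counts.tsv, samples.csv,
    landmarks.tps, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seqs, t_orf = simulate_transcripts(config)
    sync, t_snp = simulate_pool_alleles(config, seqs)
    counts, sheet, t_de = simulate_counts(config)
    lm, t_shape = simulate_landmarks(config)
    truth = merge_truth(t_orf, t_snp, t_de, t_shape)
    write_fasta(seqs, outdir / "transcripts.fasta")
    write_sync(sync, outdir / "alleles.sync")
    write_counts(counts, outdir / "counts.tsv")
    write_sample_sheet(sheet, outdir / "samples.csv")
    write_tps(lm, outdir / "landmarks.tps")
    truth.to_json(outdir / "truth.json")
    return truth


def config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("tissues", "baseline_log_expression", "shared_maf_beta",
                "n_specimens_per_morph"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return SimConfig(**data)
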
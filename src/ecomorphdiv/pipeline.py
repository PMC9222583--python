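"""End-to-end orchestration over synthetic or on-disk inputs.

``run_all`` executes simulate -> fst -> orf -> de -> tissuediv ->
candidates -> morpho and writes every stage's tables plus a JSON manifest
recording the seed, thresholds, and per-stage summaries.  The manifest
stores relative paths only, so identical seeds give byte-identical
manifests regardless of the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, candidates as cand, diffexpr, morpho, orfcodon, popdiv
from . import tissuediv as tdiv
from .io_formats import (
    landmarks_to_array,
    parse_counts,
    parse_fasta,
    parse_sample_sheet,
    parse_sync,
    parse_tps,
)
from .synthdata import SimConfig, SimTruth, simulate_all

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage thresholds (defaults are the pipeline's canonical values:
    20x target coverage, 10% MAF, FDR tiers 1e-2 / 1e-10 at FC >= 4,
    not-DE gate FDR >= 1e-5 & FC <= 4, FPKM >= 1, PC variance gate 5%)."""

    target_coverage: int = 20
    maf: float = 0.10
    fdr_de: float = 1e-2
    fdr_high: float = 1e-10
    fc_min: float = 4.0
    fdr_not_de: float = 1e-5
    fpkm_min: float = 1.0
    min_var: float = 0.05
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.simulate and self.sim.seed != self.seed:
            self.sim = SimConfig(**{**asdict_config(self.sim), "seed": self.seed})


def asdict_config(sim: SimConfig) -> dict:
    d = asdict(sim)
    return d


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n", **kw)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; returns the manifest dict (also written to
    ``outdir/manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datadir = outdir / "data"
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "target_coverage": config.target_coverage,
            "maf": config.maf,
            "fdr_de": config.fdr_de,
            "fdr_high": config.fdr_high,
            "fc_min": config.fc_min,
            "fdr_not_de": config.fdr_not_de,
            "fpkm_min": config.fpkm_min,
            "min_var": config.min_var,
        },
        "stages": {},
    }

    # -- simulate ---------------------------------------------------------
    if config.simulate:
        truth = simulate_all(config.sim, datadir)
        manifest["stages"]["simulate"] = {
            "n_genes": config.sim.n_genes,
            "n_true_af_snps": len(truth.true_af_snps),
            "n_true_de": len(truth.true_de),
            "n_true_universal_de": len(truth.true_universal_de),
        }
    else:
        for name in ("transcripts.fasta", "alleles.sync", "counts.tsv",
                     "samples.csv", "landmarks.tps"):
            if not (datadir / name).exists():
                raise FileNotFoundError(f"missing input file: {datadir / name}")
        truth = None

    seqs = parse_fasta(datadir / "transcripts.fasta")
    sync = parse_sync(datadir / "alleles.sync")
    sheet = parse_sample_sheet(datadir / "samples.csv")
    counts = parse_counts(datadir / "counts.tsv", sheet)
    landmarks = parse_tps(datadir / "landmarks.tps")

    # -- fst --------------------------------------------------------------
    n_pools_per_morph = len({p for m, p in zip(sheet.morph, sheet.pool)
                             if m == "wood"})
    wood_pools, rock_pools = popdiv.morph_pool_indices(n_pools_per_morph)
    std = popdiv.standardize_coverage(sync, config.target_coverage, config.seed)
    snps = popdiv.call_snps(std, config.maf)
    snps = popdiv.detect_af_snps(snps, wood_pools, rock_pools)
    snp_df = popdiv.snp_table(snps)
    _write(snp_df, outdir / "snps.tsv", index=False)
    med = popdiv.median_fst_matrix(snps, 2 * n_pools_per_morph)
    _write(med, outdir / "median_fst_matrix.tsv")
    fst_tab, fst_summary = popdiv.combined_fst_distribution(
        snps, wood_pools, rock_pools, config.maf
    )
    _write(fst_tab, outdir / "combined_fst.tsv", index=False)
    af_set = {(s.contig, s.position) for s in snps if s.af_snp}
    within = [med.iloc[i, j] for g in (wood_pools, rock_pools)
              for i in g for j in g if i < j]
    across = [med.iloc[i, j] for i in wood_pools for j in rock_pools]
    # descriptive: the percentile at which the af-SNP class starts within
    # the combined distribution
    af_percentile = (
        100.0 * (1.0 - len(af_set) / len(fst_tab)) if len(fst_tab) else None
    )
    manifest["stages"]["fst"] = {
        "af_snp_percentile": (round(af_percentile, 2)
                              if af_percentile is not None else None),
        "n_sites_standardized": len(std),
        "n_snps": len(snps),
        "n_af_snps": len(af_set),
        "median_fst_combined": fst_summary["median_fst"],
        "mean_fst_combined": fst_summary["mean_fst"],
        "median_fst_within_pools": float(np.nanmedian(within)) if within else None,
        "median_fst_across_pools": float(np.nanmedian(across)) if across else None,
    }

    # -- orf --------------------------------------------------------------
    orfs, n_no_orf = orfcodon.annotate_orfs(seqs)
    effects = orfcodon.classify_all(snps, orfs, seqs)
    eff_df = orfcodon.effects_table(effects)
    _write(eff_df, outdir / "snp_effects.tsv", index=False)
    af_flags = pd.Series(
        {(s.contig, s.position): s.af_snp for s in snps}, dtype=bool
    )
    dens = orfcodon.af_snp_density(
        orfs, effects, {k: bool(v) for k, v in af_flags.items()}
    )
    _write(dens, outdir / "af_snp_density.tsv")
    manifest["stages"]["orf"] = {
        "n_orfs": len(orfs),
        "n_without_orf": n_no_orf,
        "n_coding_snps": int((eff_df["location"] == "coding").sum()),
        "n_nonsyn": int((eff_df["effect"] == "non-synonymous").sum()),
        "n_syn": int((eff_df["effect"] == "synonymous").sum()),
    }

    # -- de ---------------------------------------------------------------
    libs = diffexpr.normalize_libsizes(counts)
    phi = diffexpr.estimate_dispersion(counts, sheet, libs)
    model = diffexpr.DeModel(libs, phi)
    de = diffexpr.de_table(counts, sheet, model)
    de = diffexpr.classify_tiers(de, config.fdr_de, config.fdr_high, config.fc_min)
    _write(de, outdir / "de.tsv", index=False)
    lengths = pd.Series({g: len(s) for g, s in seqs.items()})
    lengths = lengths.reindex(counts.index).fillna(1000)
    fpkm_tab = diffexpr.fpkm_summary(counts, lengths, sheet, libs, config.fpkm_min)
    _write(fpkm_tab, outdir / "fpkm.tsv", index=False)
    de_any = de[de["tier"] != "none"].groupby("gene").size()
    de_flags = pd.Series(False, index=counts.index)
    de_flags[de_any.index] = True
    af_genes = {c for c, _ in af_set}
    af_gene_flags = pd.Series(
        [g in af_genes for g in counts.index], index=counts.index
    )
    odds, p_bias, _ = diffexpr.mapping_bias_test(de_flags, af_gene_flags)
    high = de[de["tier"] == "highlyDE"]
    collapse_pairs, collapse_frac = diffexpr.allele_collapse_check(high, seqs)
    manifest["stages"]["de"] = {
        "dispersion": round(phi, 6),
        "n_de": int((de["tier"] != "none").sum()),
        "n_highly_de": int((de["tier"] == "highlyDE").sum()),
        "per_tissue_highly_de": {
            t: int(((de["tissue"] == t) & (de["tier"] == "highlyDE")).sum())
            for t in dict.fromkeys(sheet.tissue)
        },
        "mapping_bias_p": round(float(p_bias), 6),
        "allele_collapse_fraction": {k: round(v, 6)
                                     for k, v in sorted(collapse_frac.items())},
    }

    # -- tissuediv --------------------------------------------------------
    expressed = diffexpr.expressed_in_tissue(fpkm_tab, how="either")
    uni_de, uni_high = tdiv.universal_sets(de)
    props, prop_tests = tdiv.tissue_de_proportions(de, expressed, uni_de, uni_high)
    _write(props, outdir / "tissue_de_proportions.tsv", index=False)
    _write(prop_tests, outdir / "tissue_de_tests.tsv", index=False)
    nonsyn_af_genes = {
        e.contig for e in effects
        if e.effect == "non-synonymous" and (e.contig, e.position) in af_set
    }
    orf_af_genes = {
        e.contig for e in effects
        if e.location == "coding" and (e.contig, e.position) in af_set
    }
    freqs, freq_tests = tdiv.tissue_afsnp_frequency(
        af_genes, expressed, af_nonsyn_genes=nonsyn_af_genes,
        af_orf_genes=orf_af_genes,
    )
    _write(freqs, outdir / "tissue_afsnp_frequency.tsv", index=False)
    top = tdiv.top_quantile_composition(de)
    _write(top, outdir / "top_quantile_composition.tsv", index=False)
    syn_af_genes = {
        e.contig for e in effects
        if e.effect == "synonymous" and (e.contig, e.position) in af_set
    }
    overlap, overlap_tests = tdiv.de_afsnp_overlap(
        de, af_genes, nonsyn_af_genes, syn_af_genes
    )
    _write(overlap, outdir / "de_afsnp_overlap.tsv", index=False)
    manifest["stages"]["tissuediv"] = {
        "n_universal_de": len(uni_de),
        "n_universal_highly_de": len(uni_high),
        "proportions": {
            f"{r.tissue}:{r.tier}": round(float(r.proportion), 6)
            for r in props.itertuples()
        },
        "top_quantile": {
            f"{r.fraction}:{r.tissue}": round(float(r.share), 6)
            for r in top.itertuples()
        },
    }

    # -- candidates -------------------------------------------------------
    expr_set = cand.expression_candidates(
        de, config.fdr_high, config.fdr_not_de, config.fc_min
    )
    snp_set = cand.snp_candidates(eff_df, af_flags, fpkm_tab)
    sets = cand.CandidateSet(expr_set, snp_set)
    report = cand.candidate_report(sets, eff_df, af_flags, dens)
    manifest["stages"]["candidates"] = {
        k: v for k, v in report.items() if not k.startswith("top_")
    }
    pd.DataFrame(
        {"gene": sorted(expr_set | snp_set)}
    ).assign(
        expression_based=lambda d: d["gene"].isin(expr_set),
        snp_based=lambda d: d["gene"].isin(snp_set),
    ).to_csv(outdir / "candidates.tsv", sep="\t", index=False, lineterminator="\n")

    # -- morpho -----------------------------------------------------------
    arr, specimens = landmarks_to_array(landmarks)
    gpa = morpho.procrustes_gpa(arr)
    pca = morpho.shape_pca(gpa)
    labels = np.array([s.rstrip("0123456789") for s in specimens])
    tests = morpho.pc_group_tests(pca, labels, config.min_var)
    _write(tests, outdir / "shape_pc_tests.tsv", index=False)
    # substrate x morph abundance; synthetic specimens sit on their own
    # morph's substrate
    wood_n = int((labels == "wood").sum())
    rock_n = int((labels == "rock").sum())
    chi2, p_chi = morpho.habitat_chi2(np.array([[wood_n, 0], [0, rock_n]]))
    tested = tests[tests["tested"]]
    manifest["stages"]["morpho"] = {
        "n_specimens": len(specimens),
        "gpa_iterations": gpa.n_iterations,
        "gpa_converged": gpa.converged,
        "pc1_variance_fraction": round(float(pca.variance_fraction[0]), 6),
        "n_pcs_tested": int(len(tested)),
        "min_tested_p": (round(float(tested["p"].min()), 10)
                         if len(tested) else None),
        "habitat_chi2": round(chi2, 6),
        "habitat_chi2_p": float(f"{p_chi:.6g}"),
    }

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
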
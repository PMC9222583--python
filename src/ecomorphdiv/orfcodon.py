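"""Longest-ORF annotation and synonymous / non-synonymous SNP classification.

ORFs are complete ATG...stop spans on the forward strand (libraries are
strand-specific), length a multiple of 3, at least ``min_len`` nucleotides;
the longest span wins, leftmost on ties.  Codon effects are classified by
substituting the major and minor allele into the codon at the SNP position
and comparing translations under the standard genetic code.  Per-gene
non-synonymous af-SNP densities (per kb of ORF) are reported as folds over
two backgrounds: all ORF-bearing transcripts and af-SNP-bearing transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .popdiv import SnpRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard genetic code, hardcoded so tests can cross-check against an
# independent translation library
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class OrfAnnotation:
    """A complete forward-strand ORF, 1-based inclusive coordinates."""

    transcript: str
    start: int
    end: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def length_codons(self) -> int:
        return self.length_nt // 3


@dataclass(frozen=True)
class SnpEffect:
    """Codon-effect classification of one SNP."""

    contig: str
    position: int
    location: str  # noncoding | coding
    effect: str  # synonymous | non-synonymous | not-applicable
    codon_index: int | None = None  # 0-based codon within the ORF
    major_codon: str | None = None
    minor_codon: str | None = None
    major_residue: str | None = None
    minor_residue: str | None = None


def find_longest_orf(
    transcript_id: str, seq: str, min_len: int = 30
) -> OrfAnnotation | None:
    """Longest complete ATG...stop ORF on the forward strand.

    Candidates containing N are skipped.  Ties go to the leftmost start.
    Returns None when no complete ORF of at least ``min_len`` nt exists.
    """
    seq = seq.upper()
    n = len(seq)
    best: tuple[int, int] | None = None  # 0-based [start, end)
    for i in range(0, n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= n:
            codon = seq[j : j + 3]
            if "N" in codon:
                break  # N inside the candidate: skip it
            if codon in STOP_CODONS and j > i:
                length = j + 3 - i
                if length >= min_len and (
                    best is None
                    or length > best[1] - best[0]
                    or (length == best[1] - best[0] and i < best[0])
                ):
                    best = (i, i + length)
                break
            j += 3
    if best is None:
        return None
    return OrfAnnotation(transcript_id, best[0] + 1, best[1])


def annotate_orfs(
    seqs: dict[str, str], min_len: int = 30
) -> tuple[dict[str, OrfAnnotation], int]:
    """Longest ORF per transcript; returns annotations and the number of
    transcripts excluded for lacking a complete ORF."""
    orfs: dict[str, OrfAnnotation] = {}
    n_excluded = 0
    for name, seq in seqs.items():
        ann = find_longest_orf(name, seq, min_len=min_len)
        if ann is None:
            n_excluded += 1
        else:
            orfs[name] = ann
    return orfs, n_excluded


def classify_snp_effect(
    snp: SnpRecord, orf: OrfAnnotation | None, seq: str
) -> SnpEffect:
    """Classify a SNP as noncoding / synonymous / non-synonymous.

    The codon at the SNP position is built twice — once carrying the major
    allele, once the minor — with the other two positions taken from the
    transcript sequence, and the translations compared under the standard
    code.  Codons containing N yield effect ``not-applicable``.
    """
    if not 1 <= snp.position <= len(seq):
        raise ValueError(f"SNP position {snp.position} outside transcript")
    if orf is None or not (orf.start <= snp.position <= orf.end):
        return SnpEffect(snp.contig, snp.position, "noncoding", "not-applicable")
    offset = snp.position - orf.start  # 0-based within ORF
    codon_index = offset // 3
    within = offset % 3
    cstart = orf.start - 1 + codon_index * 3  # 0-based codon start in seq
    codon = list(seq[cstart : cstart + 3].upper())
    major_codon = codon.copy()
    minor_codon = codon.copy()
    major_codon[within] = snp.major
    minor_codon[within] = snp.minor
    major_c, minor_c = "".join(major_codon), "".join(minor_codon)
    if "N" in major_c or "N" in minor_c:
        return SnpEffect(snp.contig, snp.position, "coding", "not-applicable",
                         codon_index, major_c, minor_c)
    aa1, aa2 = GENETIC_CODE[major_c], GENETIC_CODE[minor_c]
    effect = "synonymous" if aa1 == aa2 else "non-synonymous"
    return SnpEffect(snp.contig, snp.position, "coding", effect,
                     codon_index, major_c, minor_c, aa1, aa2)


def classify_all(
    snps: Iterable[SnpRecord],
    orfs: dict[str, OrfAnnotation],
    seqs: dict[str, str],
) -> list[SnpEffect]:
    return [
        classify_snp_effect(s, orfs.get(s.contig), seqs[s.contig]) for s in snps
    ]


def effects_table(effects: list[SnpEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [e.contig for e in effects],
            "position": [e.position for e in effects],
            "location": [e.location for e in effects],
            "effect": [e.effect for e in effects],
        }
    )


def af_snp_density(
    orfs: dict[str, OrfAnnotation],
    effects: list[SnpEffect],
    af_flags: dict[tuple[str, int], bool],
) -> pd.DataFrame:
    """Per-gene non-synonymous af-SNP density (per kb of ORF) with folds.

    Folds are against (a) the mean density over all ORF-bearing transcripts
    and (b) the mean over transcripts carrying at least one af-SNP.  Genes
    without an ORF are excluded.
    """
    nonsyn_af: dict[str, int] = {g: 0 for g in orfs}
    has_af: dict[str, bool] = {g: False for g in orfs}
    for e in effects:
        if e.contig not in orfs:
            continue
        if af_flags.get((e.contig, e.position), False):
            has_af[e.contig] = True
            if e.effect == "non-synonymous":
                nonsyn_af[e.contig] += 1
    genes = sorted(orfs)
    kb = np.array([orfs[g].length_nt / 1000.0 for g in genes])
    count = np.array([nonsyn_af[g] for g in genes], dtype=float)
    density = count / kb
    bg_all = float(density.mean()) if len(genes) else float("nan")
    af_mask = np.array([has_af[g] for g in genes])
    bg_af = float(density[af_mask].mean()) if af_mask.any() else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_all = np.where(bg_all > 0, density / bg_all, 0.0)
        fold_af = np.where(bg_af > 0, density / bg_af, 0.0)
    return pd.DataFrame(
        {
            "gene": genes,
            "orf_kb": kb,
            "nonsyn_af_snps": count.astype(int),
            "density_per_kb": density,
            "fold_vs_all": fold_all,
            "fold_vs_af_bearing": fold_af,
        }
    ).set_index("gene")
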
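"""Readers and writers for the plain-text formats the pipeline touches.

Four formats: FASTA transcripts, PoPoolation2-style ``sync`` allele counts,
tpsDIG-style TPS landmark files, and TSV count matrices with a CSV sample
sheet.  All writers emit LF line endings; sync and TSV are tab separated.
Sync positions are 1-based throughout; deletion and N counts are carried but
excluded from coverage by downstream consumers.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

NUCLEOTIDE_ORDER = ("A", "T", "C", "G", "N", "del")

MORPHS = ("wood", "rock")
TISSUES = ("radula", "mantle", "foot")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SyncRecord:
    """One site of a sync file: per-pool A:T:C:G:N:del count tuples."""

    contig: str
    position: int  # 1-based
    reference_base: str
    counts: tuple[tuple[int, int, int, int, int, int], ...]

    @property
    def n_pools(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per (morph, tissue, pool) combination."""

    samples: tuple[str, ...]
    morph: tuple[str, ...]
    tissue: tuple[str, ...]
    pool: tuple[int, ...]

    def __post_init__(self) -> None:
        keys = list(zip(self.morph, self.tissue, self.pool))
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (morph, tissue, pool) in sample sheet")
        for m in self.morph:
            if m not in MORPHS:
                raise FormatError(f"unknown morph {m!r}")
        for t in self.tissue:
            if t not in TISSUES:
                raise FormatError(f"unknown tissue {t!r}")

    def __len__(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "morph": self.morph,
                "tissue": self.tissue,
                "pool": self.pool,
            }
        )


def _parse_count_tuple(field: str, lineno: int) -> tuple[int, ...]:
    parts = field.split(":")
    if len(parts) != 6:
        raise FormatError(
            f"line {lineno}: malformed count tuple {field!r} (expected 6 fields)"
        )
    try:
        counts = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer count in {field!r}") from exc
    if any(c < 0 for c in counts):
        raise FormatError(f"line {lineno}: negative count in {field!r}")
    return counts


def parse_sync(path: str | Path) -> list[SyncRecord]:
    """Parse a sync file into an ordered list of :class:`SyncRecord`.

    The pool count is inferred from the first record and enforced on every
    subsequent line; a ragged line raises :class:`FormatError` naming the
    line number.
    """
    records: list[SyncRecord] = []
    n_pools: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"line {lineno}: expected >= 4 tab-separated columns")
            contig, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad position {pos_s!r}") from exc
            pools = tuple(_parse_count_tuple(f, lineno) for f in fields[3:])
            if n_pools is None:
                n_pools = len(pools)
            elif len(pools) != n_pools:
                raise FormatError(
                    f"line {lineno}: {len(pools)} pool columns, expected {n_pools}"
                )
            records.append(SyncRecord(contig, pos, ref, pools))
    return records


def write_sync(records: Sequence[SyncRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            pools = "\t".join(":".join(str(c) for c in p) for p in rec.counts)
            fh.write(f"{rec.contig}\t{rec.position}\t{rec.reference_base}\t{pools}\n")


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Identifiers are the first whitespace token of the header; sequences are
    upper-cased with U mapped to T.  Duplicate identifiers and empty
    sequences are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in out:
            raise FormatError(f"duplicate FASTA identifier {rec.id!r}")
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def parse_tps(path: str | Path) -> pd.DataFrame:
    """Parse a TPS landmark file.

    Returns a long-format frame with columns ``specimen, landmark, x, y``.
    Every specimen must carry the same landmark count.
    """
    rows: list[tuple[str, int, float, float]] = []
    k_expected: int | None = None
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise FormatError(f"expected LM= block at line {i + 1}, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise FormatError(f"bad landmark count in {line!r}") from exc
        if k_expected is None:
            k_expected = k
        elif k != k_expected:
            raise FormatError(
                f"landmark count {k} at line {i + 1} differs from {k_expected}"
            )
        coords: list[tuple[float, float]] = []
        i += 1
        for _ in range(k):
            if i >= len(lines):
                raise FormatError("truncated TPS block")
            parts = lines[i].split()
            if len(parts) != 2:
                raise FormatError(f"bad coordinate line {lines[i]!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise FormatError(f"non-numeric coordinate {lines[i]!r}") from exc
            i += 1
        spec_id = None
        while i < len(lines) and lines[i] and not lines[i].upper().startswith("LM="):
            key, _, val = lines[i].partition("=")
            if key.upper() == "ID":
                spec_id = val
            i += 1
        if spec_id is None:
            raise FormatError("TPS block missing ID= line")
        for j, (x, y) in enumerate(coords):
            rows.append((spec_id, j, x, y))
    return pd.DataFrame(rows, columns=["specimen", "landmark", "x", "y"])


def write_tps(landmarks: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format landmark frame (specimen, landmark, x, y) as TPS."""
    with open(path, "w", newline="\n") as fh:
        for spec_id, grp in landmarks.groupby("specimen", sort=False):
            grp = grp.sort_values("landmark")
            fh.write(f"LM={len(grp)}\n")
            for _, row in grp.iterrows():
                fh.write(f"{row.x:.6f} {row.y:.6f}\n")
            fh.write(f"ID={spec_id}\n")


def landmarks_to_array(landmarks: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Convert the long-format landmark frame to (n, k, 2) with specimen ids."""
    specimens = list(dict.fromkeys(landmarks["specimen"]))
    k = landmarks["landmark"].nunique()
    arr = np.empty((len(specimens), k, 2))
    for i, s in enumerate(specimens):
        grp = landmarks[landmarks["specimen"] == s].sort_values("landmark")
        arr[i] = grp[["x", "y"]].to_numpy()
    return arr, specimens


def parse_sample_sheet(path: str | Path) -> SampleSheet:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    if not rows:
        return SampleSheet((), (), (), ())
    return SampleSheet(
        samples=tuple(r["sample"] for r in rows),
        morph=tuple(r["morph"] for r in rows),
        tissue=tuple(r["tissue"] for r in rows),
        pool=tuple(int(r["pool"]) for r in rows),
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, index=False, lineterminator="\n")


def parse_counts(path: str | Path, sheet: SampleSheet) -> pd.DataFrame:
    """Read a gene x sample count TSV, reordering columns to sheet order.

    Counts must be non-negative integers; every sheet sample must appear in
    the header.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in sheet.samples if s not in df.columns]
    if missing:
        raise FormatError(f"samples in sheet missing from counts header: {missing}")
    unknown = [s for s in df.columns if s not in sheet.samples]
    if unknown:
        raise FormatError(f"samples in counts header not in sheet: {unknown}")
    df = df[list(sheet.samples)]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric entries in count matrix")
    if np.any(values < 0):
        raise FormatError("negative count in matrix")
    if not np.allclose(values, np.round(values)):
        bad = df.columns[np.argwhere(~np.isclose(values, np.round(values)))[0][1]]
        raise FormatError(f"non-integer count found (e.g. in sample {bad!r})")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", lineterminator="\n")
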
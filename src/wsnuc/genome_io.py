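"""Readers and writers for the formats the tool touches.

Sequences come in as FASTA; experimental nucleosome dyads as BED3 fragment
intervals (midpoints taken as dyads, optionally filtered to one fragment
length) or as two-column chrom/dyad TSV; score tracks go out as bedGraph or
fixed-step wiggle.  All coordinates are 0-based half-open internally; BED
and bedGraph are written the same way, wiggle 1-based per its standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scoring import FLANK, ScoreProfile

__all__ = [
    "DyadSet",
    "read_fasta",
    "write_fasta",
    "open_fasta_indexed",
    "read_dyads",
    "write_dyads_bed",
    "write_dyads_tsv",
    "filter_near_ends",
    "write_bedgraph",
    "read_bedgraph",
    "write_wig",
]

_DYAD_COLUMNS = ["chrom", "dyad", "label"]


@dataclass
class DyadSet:
    """Experimental or ground-truth nucleosome dyad coordinates.

    ``records`` has columns ``chrom`` (sequence name), ``dyad`` (0-based
    position of the central base pair) and ``label`` (free text).
    Duplicate dyads are legitimate (redundant MNase fragment sets) and are
    kept; ``n_duplicates`` exposes them for summary output.
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _DYAD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dyad table lacks columns {missing}")
        self.records = self.records[_DYAD_COLUMNS].reset_index(drop=True)

    @classmethod
    def from_positions(
        cls,
        positions: Iterable[tuple[str, int]] | Iterable[int],
        chrom: str | None = None,
        label: str = "",
        provenance: str = "",
    ) -> "DyadSet":
        """Build a DyadSet from (chrom, dyad) pairs, or bare positions on ``chrom``."""
        rows = []
        for p in positions:
            if isinstance(p, tuple):
                rows.append((p[0], int(p[1]), label))
            else:
                if chrom is None:
                    raise ValueError("bare positions require a chrom argument")
                rows.append((chrom, int(p), label))
        return cls(pd.DataFrame(rows, columns=_DYAD_COLUMNS), provenance=provenance)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, int, str]]:
        return iter(self.records.itertuples(index=False, name=None))

    @property
    def n_duplicates(self) -> int:
        return int(self.records.duplicated(subset=["chrom", "dyad"]).sum())

    def chroms(self) -> list[str]:
        return list(self.records["chrom"].unique())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into {name: sequence}.

    Names are the first whitespace-delimited token of each header.  Raises
    on an empty file or duplicate names.  Case is preserved (the scoring
    layer decides how to treat soft-masked bases).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta_indexed(path: str | Path):
    """Open a FASTA through a .fai index for random access to large genomes."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))


# ---------------------------------------------------------------------------
# Dyad tables
# ---------------------------------------------------------------------------

def read_dyads(
    path: str | Path,
    fmt: str = "auto",
    fragment_length: int | None = None,
    provenance: str = "",
) -> tuple[DyadSet, int]:
    """Read nucleosome dyads from BED3(+) fragment intervals or chrom/dyad TSV.

    BED rows give fragments as 0-based half-open intervals; the dyad is the
    fragment midpoint, ``start + (length - 1) // 2`` (the left of the two
    central bases for even lengths).  With ``fragment_length`` set, rows of
    any other length are dropped and counted — the standard filter that
    keeps only fragments wrapping a full nucleosome core.

    Returns ``(dyads, n_dropped)``.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "bed" if path.suffix.lower() in (".bed", ".bedgraph") else "tsv"
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"format must be 'bed' or 'tsv', got {fmt!r}")

    rows: list[tuple[str, int, str]] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if fmt == "bed":
                    if len(fields) < 3:
                        raise ValueError("BED needs >= 3 columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    if start < 0 or end <= start:
                        raise ValueError(f"bad interval [{start}, {end})")
                    label = fields[3] if len(fields) > 3 else ""
                    length = end - start
                    if fragment_length is not None and length != fragment_length:
                        n_dropped += 1
                        continue
                    dyad = start + (length - 1) // 2
                else:
                    if len(fields) < 2:
                        raise ValueError("TSV needs chrom and dyad columns")
                    chrom, dyad = fields[0], int(fields[1])
                    if dyad < 0:
                        raise ValueError(f"negative dyad {dyad}")
                    label = fields[2] if len(fields) > 2 else ""
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc}): {line!r}") from None
            rows.append((chrom, dyad, label))
    dyads = DyadSet(
        pd.DataFrame(rows, columns=_DYAD_COLUMNS),
        provenance=provenance or str(path),
    )
    return dyads, n_dropped


def write_dyads_bed(
    dyads: DyadSet, path: str | Path, fragment_length: int = 147
) -> None:
    """Write dyads as BED fragment intervals of ``fragment_length`` bp.

    The interval is placed so its midpoint recovers the dyad on re-reading:
    ``[dyad - (L-1)//2, dyad - (L-1)//2 + L)``.
    """
    half = (fragment_length - 1) // 2
    with open(path, "w") as fh:
        for chrom, dyad, label in dyads:
            start = dyad - half
            fh.write(f"{chrom}\t{start}\t{start + fragment_length}\t{label or '.'}\n")


def write_dyads_tsv(dyads: DyadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tdyad\tlabel\n")
        for chrom, dyad, label in dyads:
            fh.write(f"{chrom}\t{dyad}\t{label or '.'}\n")


def filter_near_ends(
    dyads: DyadSet,
    sequences: Mapping[str, str] | Mapping[str, int],
    flank: int = FLANK,
) -> tuple[DyadSet, int]:
    """Drop dyads closer than ``flank`` bp to either sequence end.

    A dyad at 0-based position ``d`` on a sequence of length ``L`` is kept
    iff ``flank <= d <= L - 1 - flank`` — exactly the positions where a full
    147-bp frame (and hence a score) exists.  ``sequences`` maps names to
    sequences or to integer lengths.  Returns ``(kept, n_removed)``.
    """
    lengths = {
        name: (value if isinstance(value, int) else len(value))
        for name, value in sequences.items()
    }
    missing = set(dyads.records["chrom"]) - set(lengths)
    if missing:
        raise KeyError(f"dyads reference sequences not provided: {sorted(missing)}")
    L = dyads.records["chrom"].map(lengths)
    keep = (dyads.records["dyad"] >= flank) & (dyads.records["dyad"] <= L - 1 - flank)
    kept = DyadSet(dyads.records[keep].reset_index(drop=True), provenance=dyads.provenance)
    return kept, int((~keep).sum())


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------

def write_bedgraph(
    profiles: ScoreProfile | Iterable[ScoreProfile], path: str | Path
) -> None:
    """Write score profiles as bedGraph (0-based half-open, one row per base).

    Undefined flank positions are omitted, not zero-filled.
    """
    if isinstance(profiles, ScoreProfile):
        profiles = [profiles]
    with open(path, "w") as fh:
        for p in profiles:
            for pos, score in zip(p.positions, p.scores):
                if isinstance(score, np.floating) and np.isnan(score):
                    continue
                fh.write(f"{p.sequence_name}\t{pos}\t{pos + 1}\t{_fmt(score)}\n")


def _fmt(x) -> str:
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else repr(xf)


def read_bedgraph(path: str | Path) -> dict[str, ScoreProfile]:
    """Read a single-base-resolution bedGraph into per-sequence profiles.

    Positions absent from the track become NaN (undefined), so externally
    produced tracks with gaps evaluate correctly.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns: {line!r}")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            for pos in range(start, end):
                per_chrom.setdefault(chrom, {})[pos] = value
    profiles: dict[str, ScoreProfile] = {}
    for chrom, values in per_chrom.items():
        lo, hi = min(values), max(values)
        scores = np.full(hi - lo + 1, np.nan)
        for pos, value in values.items():
            scores[pos - lo] = value
        profiles[chrom] = ScoreProfile(sequence_name=chrom, offset=lo, scores=scores)
    return profiles


def write_wig(
    profiles: ScoreProfile | Iterable[ScoreProfile], path: str | Path
) -> None:
    """Write profiles as fixed-step wiggle (1-based per the wig standard)."""
    if isinstance(profiles, ScoreProfile):
        profiles = [profiles]
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(f"fixedStep chrom={p.sequence_name} start={p.offset + 1} step=1\n")
            for score in p.scores:
                fh.write(f"{_fmt(score)}\n")
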
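"""Nucleosomal bending-site templates.

Nucleosomal DNA wraps the histone octamer in ~1.7 superhelical turns, bending
alternately into the minor and the major groove roughly every half helical
turn.  The scoring scheme in this package evaluates candidate nucleosome
frames against a fixed geometric *template*: an ordered set of 4-bp
DNA-bending sites, one per superhelical location (SHL), with half-integer
SHLs bending into the minor groove (14 sites, SHL ±0.5 … ±6.5) and nonzero
integer SHLs into the major groove (12 sites, SHL ±1 … ±6).

Two template lengths are supported, 147 bp and 146 bp, reflecting the two
stable lengths of nucleosome-core DNA; the 1-bp difference shifts the
midpoint by half a base and gives the scoring model its stretching
flexibility.

Site coordinates are constructed procedurally: the centre of the site at
superhelical location ``s`` is placed at ``D + s * period`` (``D`` the
template midpoint, 74 for 147 bp and 73.5 for 146 bp), the site occupies the
four positions starting at ``round(centre - 1.5)`` (round half up), and the
positive-SHL half is obtained by mirror symmetry about the midpoint.  The
default period of 10.45 bp/turn places the SHL -5.5 minor-groove site at
template positions 15-18 (1-based, inclusive), the anchor coordinate of the
published site table.  Users holding an exact site table can bypass the
construction entirely via :func:`load_template`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "MINOR",
    "MAJOR",
    "DEFAULT_PERIOD",
    "DEFAULT_ANCHOR_147",
    "SITE_LENGTH",
    "N_MINOR_SITES",
    "N_MAJOR_SITES",
    "TemplateError",
    "BendingSite",
    "NucleosomeTemplate",
    "build_template",
    "serialize_template",
    "parse_template",
    "save_template",
    "load_template",
]

MINOR = "minor"
MAJOR = "major"

#: bp per helical turn used to lay out site centres; 10.45 reproduces the
#: published anchor (SHL -5.5 at positions 15-18 of the 147-bp template).
DEFAULT_PERIOD = 10.45

#: (shl, 1-based start) of the one published site coordinate.
DEFAULT_ANCHOR_147 = (-5.5, 15)

SITE_LENGTH = 4
N_MINOR_SITES = 14
N_MAJOR_SITES = 12

# negative-half superhelical locations; the positive half is mirrored
_MINOR_SHLS = tuple(-(k + 0.5) for k in range(7))     # -0.5 .. -6.5
_MAJOR_SHLS = tuple(float(-k) for k in range(1, 7))   # -1 .. -6


class TemplateError(ValueError):
    """Raised when a template cannot be constructed or fails validation."""


def _is_half_integer(x: float) -> bool:
    return abs(x - math.floor(x) - 0.5) < 1e-9


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass(frozen=True)
class BendingSite:
    """One 4-bp minor- or major-groove bending site of a nucleosomal template.

    Coordinates are 1-based and inclusive, as positions along the template
    (position 1 = first base of the wrapped fragment).
    """

    shl: float
    groove: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.groove not in (MINOR, MAJOR):
            raise TemplateError(f"groove must be 'minor' or 'major', got {self.groove!r}")
        if self.end - self.start + 1 != SITE_LENGTH:
            raise TemplateError(
                f"bending sites are {SITE_LENGTH} bp; got [{self.start}, {self.end}]"
            )
        if self.groove == MINOR and not _is_half_integer(self.shl):
            raise TemplateError(f"minor-groove site requires half-integer SHL, got {self.shl}")
        if self.groove == MAJOR and (
            _is_half_integer(self.shl) or abs(self.shl) < 0.5 or self.shl != int(self.shl)
        ):
            raise TemplateError(f"major-groove site requires nonzero integer SHL, got {self.shl}")

    @property
    def step_slice(self) -> slice:
        """0-based slice of the 3 dinucleotide-step indices covered by the site.

        Step ``j`` (0-based) is the dinucleotide at template positions
        ``j+1, j+2`` (1-based); a site spanning 1-based positions
        ``start..end`` therefore covers steps ``start-1 .. end-2``.
        """
        return slice(self.start - 1, self.end - 1)


@dataclass(frozen=True)
class NucleosomeTemplate:
    """Ordered bending-site geometry of a 146- or 147-bp nucleosome core.

    ``frame_offset`` distinguishes how a 146-bp template is laid against a
    candidate dyad during scoring (0: window ``[n-73, n+72]``; 1: window
    ``[n-72, n+73]``); the site table itself is shared by both frames, so
    templates are normally built with ``frame_offset=0``.
    """

    length: int
    sites: tuple[BendingSite, ...]
    period: float
    frame_offset: int = 0

    def __post_init__(self) -> None:
        _validate(self)

    @property
    def minor_sites(self) -> tuple[BendingSite, ...]:
        return tuple(s for s in self.sites if s.groove == MINOR)

    @property
    def major_sites(self) -> tuple[BendingSite, ...]:
        return tuple(s for s in self.sites if s.groove == MAJOR)

    def site_at(self, shl: float) -> BendingSite:
        for s in self.sites:
            if abs(s.shl - shl) < 1e-9:
                return s
        raise KeyError(f"no site at SHL {shl}")


def _validate(t: NucleosomeTemplate) -> None:
    if t.length not in (146, 147):
        raise TemplateError(f"template length must be 146 or 147, got {t.length}")
    if t.frame_offset not in ((0,) if t.length == 147 else (0, 1)):
        raise TemplateError(f"invalid frame_offset {t.frame_offset} for length {t.length}")
    n_minor = sum(1 for s in t.sites if s.groove == MINOR)
    n_major = sum(1 for s in t.sites if s.groove == MAJOR)
    if n_minor != N_MINOR_SITES or n_major != N_MAJOR_SITES:
        raise TemplateError(
            f"expected {N_MINOR_SITES} minor + {N_MAJOR_SITES} major sites, "
            f"got {n_minor} + {n_major}"
        )
    prev_end = 0
    for s in t.sites:
        if s.start <= prev_end:
            raise TemplateError(f"sites overlap or are unsorted at [{s.start}, {s.end}]")
        if s.start < 1 or s.end > t.length:
            raise TemplateError(f"site [{s.start}, {s.end}] outside template [1, {t.length}]")
        prev_end = s.end
    # mirror symmetry about the template midpoint
    by_coords = {(s.start, s.end, s.groove) for s in t.sites}
    for s in t.sites:
        mirrored = (t.length + 1 - s.end, t.length + 1 - s.start, s.groove)
        if mirrored not in by_coords:
            raise TemplateError(
                f"site [{s.start}, {s.end}] ({s.groove}) lacks its mirror image"
            )


def build_template(
    length: int = 147,
    period: float = DEFAULT_PERIOD,
    anchor: tuple[float, int] | None = None,
    frame_offset: int = 0,
) -> NucleosomeTemplate:
    """Construct the bending-site template for a 146- or 147-bp nucleosome.

    Parameters
    ----------
    length
        Nucleosome-core DNA length, 146 or 147 bp.
    period
        Helical period in bp/turn used to lay out site centres; must lie in
        [10.0, 11.0].  The default (10.45) reproduces the published anchor
        coordinate for the 147-bp template.
    anchor
        Optional ``(shl, start)`` pair; construction fails if the site at
        that SHL does not begin at that 1-based position.  When omitted, the
        published anchor (SHL -5.5 at start 15) is enforced automatically
        for a 147-bp template built at the default period.
    frame_offset
        See :class:`NucleosomeTemplate`; only meaningful for 146-bp.
    """
    if length not in (146, 147):
        raise TemplateError(f"template length must be 146 or 147, got {length}")
    if not 10.0 <= period <= 11.0:
        raise TemplateError(f"period must lie in [10.0, 11.0] bp/turn, got {period}")
    if anchor is None and length == 147 and abs(period - DEFAULT_PERIOD) < 1e-12:
        anchor = DEFAULT_ANCHOR_147

    midpoint = (length + 1) / 2.0
    sites: list[BendingSite] = []
    for shl in sorted(_MINOR_SHLS + _MAJOR_SHLS):
        groove = MINOR if _is_half_integer(shl) else MAJOR
        centre = midpoint + shl * period
        start = _round_half_up(centre - 1.5)
        end = start + SITE_LENGTH - 1
        sites.append(BendingSite(shl=shl, groove=groove, start=start, end=end))
        # mirror image about the midpoint
        sites.append(
            BendingSite(
                shl=-shl,
                groove=groove,
                start=length + 1 - end,
                end=length + 1 - start,
            )
        )
    sites.sort(key=lambda s: s.start)

    template = NucleosomeTemplate(
        length=length, sites=tuple(sites), period=period, frame_offset=frame_offset
    )
    if anchor is not None:
        shl, want_start = anchor
        got = template.site_at(shl)
        if got.start != want_start:
            raise TemplateError(
                f"anchor violated: site at SHL {shl} starts at {got.start}, "
                f"expected {want_start} (period {period})"
            )
    return template


# ---------------------------------------------------------------------------
# TSV serialization — lets users substitute an exact published site table
# ---------------------------------------------------------------------------

_HEADER = "shl\tgroove\tstart\tend"


def serialize_template(t: NucleosomeTemplate) -> str:
    """Render a template as TSV, one bending site per row.

    Template length, period and frame offset travel in ``#``-prefixed
    comment lines so the text round-trips exactly through
    :func:`parse_template`.
    """
    lines = [
        f"# length={t.length}",
        f"# period={t.period!r}",
        f"# frame_offset={t.frame_offset}",
        _HEADER,
    ]
    for s in t.sites:
        shl = int(s.shl) if s.shl == int(s.shl) else s.shl
        lines.append(f"{shl}\t{s.groove}\t{s.start}\t{s.end}")
    return "\n".join(lines) + "\n"


def parse_template(text: str) -> NucleosomeTemplate:
    """Inverse of :func:`serialize_template`; validates all invariants."""
    meta: dict[str, str] = {}
    sites: list[BendingSite] = []
    header_seen = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            # any whitespace-delimited header naming the 4 columns is fine
            if line.split() != _HEADER.split("\t"):
                raise TemplateError(f"unexpected template header: {line!r}")
            header_seen = True
            continue
        fields = line.split()
        if len(fields) != 4:
            raise TemplateError(f"expected 4 fields per site row, got: {line!r}")
        shl_s, groove, start_s, end_s = fields
        sites.append(
            BendingSite(
                shl=float(shl_s), groove=groove, start=int(start_s), end=int(end_s)
            )
        )
    if "length" not in meta:
        raise TemplateError("template text lacks a '# length=' line")
    sites.sort(key=lambda s: s.start)
    return NucleosomeTemplate(
        length=int(meta["length"]),
        sites=tuple(sites),
        period=float(meta.get("period", DEFAULT_PERIOD)),
        frame_offset=int(meta.get("frame_offset", 0)),
    )


def save_template(t: NucleosomeTemplate, path: str | Path) -> None:
    Path(path).write_text(serialize_template(t))


def load_template(path: str | Path) -> NucleosomeTemplate:
    return parse_template(Path(path).read_text())
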
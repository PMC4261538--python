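"""WW/SS dinucleotide scoring of candidate nucleosome dyads.

The score rests on the sequence-dependent bending anisotropy of DNA:
AT-containing dinucleotide steps (AA, TT, AT, TA — "WW") bend preferentially
into the minor groove, GC-containing steps (GG, CC, GC, CG — "SS") into the
major groove.  A candidate 147-bp nucleosome frame with its dyad at position
``n`` is scored against the bending-site template by counting, at each 4-bp
site, the WW and SS steps among the site's three dinucleotides (C_WW, C_SS)
and summing

    S(n) = sum over minor sites (C_WW - C_SS) + sum over major sites (C_SS - C_WW)

so that WW at a minor-groove site and SS at a major-groove site are gains,
and the converse placements are penalties.  To allow for the 1-bp stretching
flexibility of nucleosome-core DNA, ``S(n)`` is the maximum of three frame
scores: the 147-bp template spanning ``[n-73, n+73]`` and the 146-bp
template at ``[n-73, n+72]`` and ``[n-72, n+73]``.  Linker DNA outside the
frame never enters the score.

Scores are exact integers in [-78, +78] (26 sites x 3 steps).  Positions
within 73 bp of a sequence end have no score.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .template import MAJOR, MINOR, BendingSite, NucleosomeTemplate, build_template

__all__ = [
    "FLANK",
    "StepClass",
    "SiteCounts",
    "ScoreProfile",
    "classify_step",
    "site_counts",
    "window_score",
    "combine_frames",
    "score_profile",
    "step_signs",
    "default_templates",
    "revcomp",
]

#: half-width of the widest (147-bp) frame; scores are undefined within
#: FLANK bp of either sequence end.
FLANK = 73

WW_STEPS = frozenset({"AA", "TT", "AT", "TA"})
SS_STEPS = frozenset({"GG", "CC", "GC", "CG"})

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn", "TGCAYRSWMKVHDBNtgcayrswmkvhdbn"
)


class StepClass(enum.Enum):
    """Bending class of a dinucleotide step."""

    WW = "WW"
    SS = "SS"
    OTHER = "OTHER"


def classify_step(dinucleotide: str) -> StepClass:
    """Classify a 2-mer as WW (AT-containing), SS (GC-containing) or OTHER.

    Total over arbitrary symbols: any step containing a non-ACGT character
    (N, IUPAC ambiguity codes, gaps) is OTHER.  Case-insensitive.
    """
    if len(dinucleotide) != 2:
        raise ValueError(f"a dinucleotide step has length 2, got {dinucleotide!r}")
    step = dinucleotide.upper()
    if step in WW_STEPS:
        return StepClass.WW
    if step in SS_STEPS:
        return StepClass.SS
    return StepClass.OTHER


@dataclass(frozen=True)
class SiteCounts:
    """Cumulative WW/SS step counts at one 4-bp bending site (3 steps)."""

    c_ww: int
    c_ss: int

    def __post_init__(self) -> None:
        if not (0 <= self.c_ww <= 3 and 0 <= self.c_ss <= 3 and self.c_ww + self.c_ss <= 3):
            raise ValueError(f"impossible site counts: c_ww={self.c_ww}, c_ss={self.c_ss}")


def site_counts(window: str, site: BendingSite) -> SiteCounts:
    """Count WW and SS steps among the three dinucleotides of ``site``.

    ``window`` is a template-length fragment; site coordinates are 1-based
    positions within it.
    """
    if site.end > len(window):
        raise ValueError(f"site [{site.start}, {site.end}] outside window of length {len(window)}")
    tet = window[site.start - 1 : site.end].upper()
    c_ww = c_ss = 0
    for i in range(3):
        step = tet[i : i + 2]
        if step in WW_STEPS:
            c_ww += 1
        elif step in SS_STEPS:
            c_ss += 1
    return SiteCounts(c_ww=c_ww, c_ss=c_ss)


def window_score(window: str, template: NucleosomeTemplate) -> int:
    """Score one template-length window: gains minus penalties over all sites."""
    if len(window) != template.length:
        raise ValueError(
            f"window length {len(window)} does not match template length {template.length}"
        )
    total = 0
    for site in template.sites:
        c = site_counts(window, site)
        if site.groove == MINOR:
            total += c.c_ww - c.c_ss
        else:
            total += c.c_ss - c.c_ww
    return total


@lru_cache(maxsize=None)
def default_templates() -> tuple[NucleosomeTemplate, NucleosomeTemplate]:
    """The default (147-bp, 146-bp) template pair."""
    return build_template(147), build_template(146)


def combine_frames(
    sequence: str,
    n: int,
    t147: NucleosomeTemplate | None = None,
    t146: NucleosomeTemplate | None = None,
) -> int:
    """Max-of-three frame score at candidate dyad ``n`` (0-based).

    Compares the 147-bp frame ``[n-73, n+73]`` with the two 146-bp frames
    ``[n-73, n+72]`` and ``[n-72, n+73]`` and returns the highest score.
    """
    if t147 is None or t146 is None:
        d147, d146 = default_templates()
        t147 = t147 or d147
        t146 = t146 or d146
    if n < FLANK or n > len(sequence) - 1 - FLANK:
        raise ValueError(
            f"dyad {n} closer than {FLANK} bp to a sequence end; score undefined"
        )
    s147 = window_score(sequence[n - 73 : n + 74], t147)
    s146a = window_score(sequence[n - 73 : n + 73], t146)
    s146b = window_score(sequence[n - 72 : n + 74], t146)
    return max(s147, s146a, s146b)


@dataclass
class ScoreProfile:
    """Per-position combined score S(n) along one sequence.

    ``scores[i]`` is the score at 0-based sequence position ``offset + i``;
    the first and last ``flank`` positions of the sequence carry no score.
    """

    sequence_name: str
    offset: int
    scores: np.ndarray
    flank: int = FLANK

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def positions(self) -> np.ndarray:
        """0-based sequence positions with defined scores."""
        return self.offset + np.arange(len(self.scores))

    def score_at(self, n: int) -> float | None:
        """Score at 0-based position ``n``, or None where undefined."""
        i = n - self.offset
        if i < 0 or i >= len(self.scores):
            return None
        v = self.scores[i]
        if isinstance(v, np.floating) and np.isnan(v):
            return None
        return v.item() if hasattr(v, "item") else v


def step_signs(sequence: str, lowercase: str = "keep") -> np.ndarray:
    """Vectorized step classification: +1 for WW, -1 for SS, 0 otherwise.

    ``lowercase='keep'`` treats soft-masked bases as their uppercase
    equivalent; ``lowercase='mask'`` treats them as N (steps touching them
    score 0).
    """
    if lowercase not in ("keep", "mask"):
        raise ValueError(f"lowercase policy must be 'keep' or 'mask', got {lowercase!r}")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    lower = (arr >= ord("a")) & (arr <= ord("z"))
    if lowercase == "mask":
        arr[lower] = ord("N")
    else:
        arr[lower] -= 32
    is_w = (arr == ord("A")) | (arr == ord("T"))
    is_s = (arr == ord("G")) | (arr == ord("C"))
    ww = is_w[:-1] & is_w[1:]
    ss = is_s[:-1] & is_s[1:]
    return ww.astype(np.int32) - ss.astype(np.int32)


def _template_kernel(template: NucleosomeTemplate) -> np.ndarray:
    """Signed step-weight vector of length ``template.length - 1``.

    Entry ``j`` weighs the dinucleotide step at template positions
    ``j+1, j+2`` (1-based): +1 within minor-groove sites, -1 within
    major-groove sites, 0 between sites.  The window score is then the dot
    product of this kernel with the window's step signs, because WW steps
    carry sign +1 and SS steps -1.
    """
    kernel = np.zeros(template.length - 1, dtype=np.int32)
    for site in template.sites:
        kernel[site.step_slice] = 1 if site.groove == MINOR else -1
    return kernel


def score_profile(
    sequence: str,
    sequence_name: str = "seq",
    t147: NucleosomeTemplate | None = None,
    t146: NucleosomeTemplate | None = None,
    lowercase: str = "keep",
) -> ScoreProfile:
    """Combined 147/146-bp score at every valid candidate dyad of a sequence.

    Implemented as three exact integer correlations of the step-sign track
    with the template kernels, followed by an elementwise max; identical to
    calling :func:`combine_frames` at every position, in a single pass.

    Raises ``ValueError`` for sequences shorter than 147 bp (no position has
    a defined score).
    """
    n_bases = len(sequence)
    if n_bases < 2 * FLANK + 1:
        raise ValueError(
            f"sequence {sequence_name!r} is {n_bases} bp; at least {2 * FLANK + 1} bp "
            "are required for a defined score"
        )
    if t147 is None or t146 is None:
        d147, d146 = default_templates()
        t147 = t147 or d147
        t146 = t146 or d146

    d = step_signs(sequence, lowercase=lowercase)
    k147 = _template_kernel(t147)
    k146 = _template_kernel(t146)
    s147 = np.correlate(d, k147, mode="valid")          # index i -> dyad i + 73
    s146 = np.correlate(d, k146, mode="valid")          # index i -> frame start i
    # 146-bp frame A starts at n-73 (index n-73), frame B at n-72 (index n-72)
    combined = np.maximum(np.maximum(s147, s146[:-1]), s146[1:])
    return ScoreProfile(
        sequence_name=sequence_name, offset=FLANK, scores=combined, flank=FLANK
    )


def revcomp(sequence: str) -> str:
    """Reverse complement (IUPAC-aware, case-preserving)."""
    return sequence.translate(_COMPLEMENT)[::-1]
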
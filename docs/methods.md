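# Methods

## Model

The package scores how well each candidate 146/147-bp window of a DNA
sequence matches the anisotropic bending pattern of nucleosomal DNA.  The
underlying physical picture: DNA wrapped on the histone octamer bends into
the minor groove at half-integer superhelical locations (SHL) and into the
major groove at integer SHLs, roughly every half helical turn; WW steps
(AA/TT/AT/TA) bend more readily into the minor groove, SS steps
(GG/CC/GC/CG) into the major groove, and runs of three-four consecutive
A·T pairs are especially favourable for the arginines that insert into the
minor groove — hence *cumulative* per-site counts rather than a per-step
independence assumption.

For a frame with dyad at position *n*, each of the 26 bending sites (4 bp,
3 dinucleotide steps) contributes its counts C_WW and C_SS, and

    S(n) = Σ_minor (C_WW − C_SS) + Σ_major (C_SS − C_WW)

with unit weights.  S(n) is an exact integer in [−78, +78]; no floating
point enters the kernel.  The combined score at *n* is the maximum of the
147-bp frame [n−73, n+73] and the two 146-bp frames [n−73, n+72] and
[n−72, n+73], which models the 1-bp stretching flexibility of core DNA.
Bases outside the frame (linker DNA) never affect S(n).  Any step
containing a non-ACGT symbol counts for neither class, so masked regions
score near zero rather than becoming undefined; lowercase (soft-masked)
bases are treated as their uppercase base by default, or as N with
`lowercase="mask"`.

## Template construction

The geometry is a table of 26 sites: 14 minor-groove sites at SHL
±0.5 … ±6.5 and 12 major-groove sites at SHL ±1 … ±6, each 4 bp.  Site
coordinates are generated procedurally: the centre of the site at SHL *s*
is D + *s*·period, with D the template midpoint (74 for 147 bp, 73.5 for
146 bp); the site starts at round(centre − 1.5) (round half up — chosen
over banker's rounding for determinism under floating-point representation)
and the positive-SHL half is produced by exact mirror symmetry about the
midpoint.  Rounding half up makes the construction reproducible; the
resulting layout is validated site-by-site (census 14+12, 4-bp lengths,
disjointness, in-bounds, exact mirror symmetry).

The **period** defaults to 10.45 bp/turn, inside the 10.0–11.0 physical
range accepted by `build_template`, and is chosen so the construction
reproduces the one externally fixed coordinate of the site table: the SHL
−5.5 minor-groove site occupies template positions 15–18 (1-based).  That
anchor is enforced automatically for the default 147-bp construction and
can be supplied explicitly for any other configuration.  Because the
procedural table is a reconstruction, the TSV template format
(`make-template` / `load_template`) lets a user substitute exact site
coordinates verbatim; everything downstream consumes the template object
and is agnostic to its origin.

The two 146-bp frames share one site table; they differ only in how the
window is laid against the candidate dyad, so the scoring layer places the
same 146-bp template at both offsets rather than keeping two tables.

## Scoring implementation

The profile kernel classifies every dinucleotide step of the sequence once
(+1 for WW, −1 for SS, 0 otherwise) and correlates this integer track with
a signed template kernel (+1 on minor-site steps, −1 on major-site steps),
yielding all three frame scores as exact integer correlations; the combined
profile is their elementwise maximum.  This is algebraically identical to
the per-window, per-site, per-step sum — the test suite checks equality
against a brute-force rescan at every position — and runs in
O(sequence × template) time with numpy.  Positions within 73 bp of either
sequence end carry no score and are omitted (not zero-filled) from output
tracks.

Strand symmetry is exact by construction: the WW and SS classes are closed
under reverse complement and the site layout is mirror-symmetric, so
`score_profile(revcomp(seq))` is the reversal of `score_profile(seq)`.

## Coordinates and I/O

Template positions are 1-based inclusive; all genome coordinates are
0-based half-open internally.  BED and bedGraph are read/written 0-based;
wiggle output is 1-based per its standard.  BED fragment intervals are
converted to dyads as the midpoint `start + (length−1)//2` (the left of the
two central bases for even lengths — a convention, configurable in the
sense that TSV input takes dyads verbatim); with fragment-length filtering
on (default 147 bp in the CLI), rows of any other length are dropped and
counted.  Dyads closer than 73 bp to a sequence end — where no full frame
exists — are excluded and counted, never silently dropped.

## Evaluation protocol

The per-nucleosome **prediction error** is the signed offset of the
highest-scoring position within ±5 bp of the experimental dyad; ±5 covers
half the ~10-bp spacing between rotational settings, so larger offsets
would alias onto the neighbouring helical phase.  Errors are summarized as
an 11-bin histogram with percentages summing to 100, plus the fractions
within 0, 1 and 2 bp.

**Tie-breaking.**  Integer scores plateau frequently (the max-of-three
combination makes equal neighbours common: in i.i.d. random sequence about
60% of ±5 windows contain a tied maximum), so the tie rule materially
shapes the error histogram.  The default rule picks among tied positions
deterministically but *uniformly*, keyed by CRC32 of the window contents:
runs are byte-reproducible, yet no offset is preferred, so with no signal
the error distribution is uniform on [−5, +5] — the calibration property
that makes the exact-recovery fraction interpretable against its 1/11
chance level.  A dyad-proximal rule (`tie_break="nearest"`: smallest
|error|, then −k before +k) is available for comparison but funnels every
tie to error 0, inflating apparent accuracy by roughly a factor of two
under the null; it should not be used when comparing models.

**Model comparison** uses a two-sample chi-squared test of homogeneity on
the 2×11 count table: categories empty in both samples are dropped, any
category with expected count below 1 is pooled into its neighbour nearer
error 0 (deterministic and argument-symmetric), and the degrees of freedom
are the remaining categories minus one.  `scipy.stats.chi2_contingency`
(without continuity correction) supplies the statistic.

**Dyad-aligned profiles** average the raw integer score over ±70 bp
(configurable) around every fully covered dyad and then symmetrize,
m′[k] = (m[k] + m[−k])/2, reflecting the two-fold symmetry of the
nucleosome; the symmetrization is exactly mirror-equal and idempotent.

## Synthetic data

The generator produces i.i.d. background with P(G)=P(C)=gc/2 and
P(A)=P(T)=(1−gc)/2 (defaults: gc = 0.5, the neutral composition at which
WW and SS steps are equally likely), then plants nucleosomes by redrawing
each base inside a bending site from the favoured class (uniform within
the class — W at minor sites, S at major sites) with probability
`strength`.  Planting uses only the 147-bp template, because an odd-length
window has an unambiguous central base to serve as ground truth.  At
strength 0 the sequence is returned unchanged; at strength 1 every minor
site is pure A/T and every major site pure G/C, so the dyad scores the
maximum +78.  Draws come from per-dyad counter-derived substreams of one
master seed (`default_rng([seed, i])`), so outputs are byte-identical for a
fixed seed and editing one dyad leaves the others untouched.

The bundled recovery experiment plants 200 dyads 200 bp apart (comfortably
beyond the 147-bp exclusion) on a ~40-kb genome and reports exact/1-bp/2-bp
recovery per strength over {0, 0.25, 0.5, 0.75, 1}; these sizes keep the
full experiment under a second while leaving per-bin binomial noise small
(SD ≈ 2 percentage points).  What the generator deliberately omits: MNase
cleavage bias, linker-length statistics, dinucleotide correlations beyond
the planted classes, and remodeling — so passing recovery tests
demonstrates the scoring and evaluation machinery is correct, not that the
model attains any particular accuracy on real chromatin.

## Known limitations

- The procedural site table reproduces the published census, symmetry and
  anchor, not necessarily every published coordinate; exact tables can be
  loaded from TSV.
- Only 146/147-bp templates are built; other core lengths would need their
  own site tables.
- The score targets rotational setting only: it has no translational
  (nucleosome-vs-linker) component, no occupancy model and no steric
  exclusion, so profile peaks say which face of the helix would contact the
  histones, not which positions are occupied in vivo.
- The error window of ±5 bp cannot distinguish a failure from an off-by-one
  helical turn (a ±10 bp error maps to the neighbouring window).
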
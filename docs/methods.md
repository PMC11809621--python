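# Methods

## Digestion model

RNase digestion is modelled as cleavage of the phosphodiester bond on the
3′ side of every recognised base: T1 cuts after G, U2 is configured
strictly purine-specific (after A and G).  The 3′-terminal base of the
construct is never a cut site.  Three digestion regimes are exposed:

- **Full digest** — every site cut.  Products partition the sequence; each
  internal product ends in a recognised base and contains no internal site.
- **Deterministic partial digest** — enumerates the theoretical fragment
  space: every contiguous run of 1..(m+1) full-digest products, annotated
  with its missed-cleavage count.  For n full-digest products and
  m ≥ n − 1 this is the complete window set of n(n+1)/2 fragments.
- **Stochastic partial digest** — each site fires independently with
  probability p under a seeded generator; fragments are the maximal uncut
  runs.  p → 1 converges to the full digest, p = 0 returns the intact
  sequence.  This models digestion *extent* (enzyme amount, incubation
  time), which cannot be simulated chemically; cut probability is
  site-independent, so sequence-context and secondary/tertiary-structure
  effects on accessibility are deliberately not modelled.

Internal products carry a 2′,3′-cyclic phosphate (the transesterification
product); the construct's 3′-terminal fragment keeps its hydroxyl.  The 5′
terminus is fixed at OH.

### Monoisotopic masses

Masses are built from IUPAC atomic monoisotopic masses hard-coded to six
decimals (H 1.007825, C 12.0, N 14.003074, O 15.994915, P 30.973762) and
the ribonucleoside formulas (A C10H13N5O4, C C9H13N3O5, G C10H13N5O5,
U C9H12N2O6).  An oligo of length n is the sum of its nucleoside masses
plus (n − 1)·(HPO3 − H2O) for the phosphodiester backbone; a linear
3′-phosphate adds HPO3 (79.966331 Da) and a cyclic phosphate that minus
H2O (18.010565 Da).  Modified bases enter through per-base Da offsets
(e.g. +CH2 = 14.015650 Da on U for N1-methylpseudouridine); no other
chemistry of modified nucleosides is modelled.

## Review filters

Identification tables are filtered by a pure conjunction of per-record
criteria, all individually switchable: confidence score ≥ 90 (0–100
scale), |Δppm| ≤ 20, non-unique sequence count ≤ 1, best ASR ≤ 2.0,
MS2-supported ID type, a 3′-terminal modification present, experimental
monoisotopic mass > 0, and no nonspecific/nonunique identification flags.
Because the conjunction is order-independent and idempotent, filter order
never matters.  Missing values (unparseable cells) fail any criterion that
inspects them — conservative rejection rather than silent acceptance.

Two confidence scales coexist in such exports: a 0–1 component-detection
confidence and the 0–100 review score.  Filtering operates on the 0–100
score; for coverage and display the score is normalised to [0, 1], with
the scale detected table-wide (any value > 1 marks a 0–100 table).
Whether published coverage figures derive from the fully filtered set or a
subset is not derivable from the outputs alone, so the filter set is
configuration, defaulting to all criteria enabled.  Mapping can optionally
(default on) be restricted to fragments whose sequence occurs exactly once
in the mRNA, since only unique fragments map unambiguously.

## Coverage

For an mRNA of length L, coverage of a digest is a pair of length-L
vectors: fragment count (how many mapped fragments contain position i) and
cumulative confidence (the sum of their confidences).  Percent coverage is
100 × (covered positions)/L, rounded to the nearest integer for display
with the raw float retained in machine output.  Two digests combine
position-wise into four categories — digest 1 only, digest 2 only, mutual,
none — and the combined cumulative confidence is the elementwise sum.
Combination is pairwise by design; n-way union coverage follows from
folding, but categories are only meaningful for a pair.  Positions are
1-based inclusive throughout; the implementation uses prefix sums of
endpoint deltas (exact for counts; uncovered positions are reset to
exactly 0 to cancel float round-off).  Poly(A)-tail positions count like
any other nucleotide.

## Image extraction

Sequence-map images are saturated colour bars on white.  The pipeline is:
Rec. 601 greyscale; crop to the bounding box of pixels strictly below the
white threshold (default 250/255); detect bar rows as maximal horizontal
pixel bands whose intensity falls below the bar threshold (default
240/255), auto-detected from the vertical intensity profile because the
exporting software's layout metrics are not published; within a band, each
maximal run of below-threshold columns is one bar; classify each bar's
colour (per-channel median over its ink pixels, so anti-aliased edges do
not vote) against the configured palette by nearest Euclidean RGB distance
within a tolerance (default 20), ties resolved toward the higher
confidence, unmatched bars excluded with a warning; convert pixel extents
to nucleotide coordinates by exact integer arithmetic,
start = ⌊x_start·L/W⌋ + 1, end = ⌈(x_end+1)·L/W⌉, clamped to [1, L].

The cropped content is assumed to span the full sequence — the only scale
input is the total sequence length.  The synthetic renderer guarantees
this with a 2-px grey ruler (intensity 245, between the two thresholds)
spanning the content width: it anchors the crop without being detected as
a bar.  Real exports whose plot area does not span the sequence would need
pre-cropping; axis/legend OCR is out of scope.  The true confidence
palette of the exporting software is configuration, not a guess: a 4-band
default (green 1.0, yellow 0.75, orange 0.5, red 0.25) ships for the
synthetic fixtures.

## Synthetic data

The fixture generator emulates the two real input kinds.  Fragment sets
draw uniform starts over [1, L] and uniform lengths in a window (default
3–30 nt, the size range that identifies well by MS/MS — shorter fragments
map non-uniquely, much longer ones fragment poorly), with confidences on
the discrete palette bands, because the exporting software colour-codes
bands rather than a continuum.  Defaults (300 nt, 40 fragments, 4 px/nt)
give maps of the density seen in practice.  Digestion-driven fixtures pass
in-silico digests through a length-window confidence model.  Images are
rendered without anti-aliasing so round trips are exact; a blur option
stress-tests tolerance.  The generator does not emulate chromatographic or
spectral effects, position-dependent identification bias, or correlated
misses along structured regions — a green round-trip test establishes that
extraction inverts rendering, not that real-instrument maps are error-free.

## Visualisation

Spiral geometry is not prescribed by the map style being reproduced, so an
Archimedean spiral r(θ) = r₀ + gθ/2π was chosen with arc-length-uniform
dot spacing (neighbouring dots equidistant along the curve), 5′ end
innermost, counterclockwise by default; angles are obtained by inverting a
dense trapezoid-integrated arc-length table, accurate to well under 1%
spacing error.  Dot size and opacity scale jointly and affinely with
cumulative confidence normalised by the per-figure maximum (the encoding
is relative, not absolute), with a floor so covered dots never vanish;
uncovered dots are grey at minimum size.  Category colours: blue digest 1,
yellow digest 2, red mutual, grey uncovered.  Linear maps pack fragments
first-fit by start with a one-nucleotide minimum gap — the exporting
software's own row assignment is unknown, so round-trip tests go through
the package's own renderer.  SVG is the canonical output (deterministic
text, byte-identical re-renders, machine-parseable primitives with
data-attributes); PNG is provided via matplotlib for convenience; every
figure gets a JSON sidecar with its computed percentages so downstream
checks never parse pixels.

## Numerical and degenerate-input conventions

- Coordinates 1-based inclusive; 0-based half-open only at array/pixel
  edges.
- Pixel→nucleotide mapping in exact integer arithmetic (a float
  formulation misplaces boundaries: 56/800·200 = 14.000000000000002).
- Crop threshold strict (`< threshold` is content); a pixel exactly at the
  white threshold is background.
- Colour-tie break: higher confidence wins (deterministic, errs
  optimistic on an exactly ambiguous colour).
- Empty identification tables parse to an empty list with a warning;
  fully white images and bar-free images raise errors naming the stage.
- Percent rounding: `round()` to nearest integer for display only.
- All stochastic components take explicit seeds; identical seed and
  parameters give byte-identical serialised output.

## Known limitations

- Site-independent cut probability; no structure-aware accessibility.
- No reproduction of the MS identification step itself (component
  detection, deconvolution, MS2 assignment) — identifications are inputs.
- Image extraction expects clean rasters (no JPEG artefacts, legends or
  axis furniture beyond an outer margin).
- Pairwise combination only; no statistical model of coverage or of
  overlap density.
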
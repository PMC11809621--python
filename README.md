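# oligomap

Sequence mapping of mRNA therapeutics from partial RNase digests analysed
by LC-MS/MS.

Long in-vitro-transcribed mRNAs (vaccine constructs, for example) are
characterised by digesting them with site-specific ribonucleases —
RNase T1 (cleaves 3′ of G) and RNase U2 (used here 3′ of A and G) — and
identifying the resulting oligoribonucleotides by mass spectrometry.
*Partial* digestion leaves some cut sites uncleaved, producing longer,
overlapping fragments with missed cleavages; the overlap both fills
coverage gaps and raises confidence where many fragments agree.  `oligomap`
provides the computational side of that workflow for analysts who have the
identification tables or the colour-coded sequence-map images exported by
oligonucleotide analysis software:

- **In-silico digestion** — full, deterministic-partial (every fragment
  with ≤ *m* missed cleavages) and stochastic-partial (each cut site fires
  independently with probability *p*) digests, with monoisotopic masses for
  3′-OH, 3′-phosphate and 2′,3′-cyclic-phosphate termini and
  fragment-uniqueness testing.
- **Review filtering** — configurable identification filters (confidence
  score ≥ 90, |Δppm| ≤ 20, best ASR ≤ 2.0, MS2-supported, unique,
  modification present, experimental monoisotopic mass > 0, no
  nonspecific/nonunique flags).
- **Coverage** — per-nucleotide cumulative confidence
  `C(i) = Σ_f conf(f) · 1[start_f ≤ i ≤ end_f]`, percent coverage
  `100 · |{i : count(i) > 0}| / L`, and the pairwise combination of two
  digests into four position categories (digest-1-only / digest-2-only /
  mutual / uncovered).
- **Image extraction** — recovers each fragment's start, end and confidence
  from sequence-map PNGs (greyscale conversion, margin cropping, bar
  detection from pixel-intensity runs, nearest-colour confidence
  classification, pixel→nucleotide conversion).
- **Visualisation** — linear maps (stacked fragment bars + colourmetric
  strip) and spiral plots (one dot per nucleotide; dot size and opacity
  encode cumulative confidence; blue/yellow/red/grey encode the combination
  categories) with the percentage coverage computed and displayed
  automatically.

## Worked example

```python
from oligomap import *
from oligomap.core import Fragment, FragmentSet

d1 = FragmentSet("t1", 10, [Fragment(1, 5, 0.9)])
d2 = FragmentSet("u2", 10, [Fragment(4, 8, 0.8)])
p1, p2 = build_profile(d1), build_profile(d2)
print("t1:", percent_coverage(p1))        # -> (50, 50.0)
print("u2:", percent_coverage(p2))        # -> (50, 50.0)
c = combine(p1, p2)
print("combined:", combined_percent(c))   # -> (80, 80.0)
print(c.cum_confidence_combined[3:5])     # -> [1.7 1.7]
```

Each digest alone covers 5 of 10 nucleotides (50%); together they cover
positions 1–8 (80%), and at the mutually covered positions 4–5 the
cumulative confidence is 0.9 + 0.8 = 1.7.

Digestion with mass annotation:

```python
for o in full_digest("AAGUCGA", RNASE_T1):
    print(o.sequence, o.start, o.end, f"{mono_mass(o.sequence, o.terminus_3p):.4f}")
# AAG 1 3 1003.1525
# UCG 4 6 956.1140
# A   7 7  267.0968
```

The internal products carry 2′,3′-cyclic phosphates (the direct
transesterification product); the 3′-terminal fragment keeps its hydroxyl.

The same functionality is exposed on the command line:

```sh
oligomap digest   --fasta mrna.fa --enzyme T1 --max-missed 2 --out oligos.csv
oligomap filter   --table ids.csv --fasta mrna.fa --out fragments.csv
oligomap extract  --image map.png --sequence-length 4284 --out fragments.csv
oligomap map      --input d1.png --input d2.png --sequence-length 4284 --outdir out/
oligomap fixtures --seed 7 --outdir fixtures/
```

`oligomap map` with two inputs writes a linear map, three spiral plots
(each digest and their combination), the per-position coverage CSV and a
JSON summary with the individual and combined percentages — with one input,
a linear map and a single spiral.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the whole pipeline end to end: it simulates complementary partial
RNase T1 and U2 digests of a seeded random 1200-nt construct, renders the
two sequence-map images, re-extracts the fragments from the images,
computes individual and combined coverage, renders all figures, checks the
stages against each other, and writes the results JSON to `--out`.
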
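# Methods

## Coordinate conventions

All coordinates inside the package are 0-based half-open, the BED
convention. GFF3/GTF input (1-based inclusive) is converted at the I/O
boundary (`start-1`, `end`) and converted back on write; interval length is
invariant under the round-trip. A single internal convention eliminates
whole classes of off-by-one errors. Out-of-bounds sequence lookups raise;
they are never silently truncated.

## Motif matching

A motif is a named IUPAC consensus compiled to per-position allowed-base
sets. Matching rules, chosen to be conservative and auditable:

- A genome base matches a position iff it is a concrete A/C/G/T in the
  allowed set. A genome **N matches nothing**, including motif N: a site
  that cannot be confirmed from sequence is never counted.
- Scanning covers both strands at every offset; **palindromic** motifs
  (consensus equal to its code-level reverse complement) are reported once
  per genomic span, on the plus strand. Both default consensi — AP-1
  `TGANTCA` and EcRE `RGGTCANTGACCY` — are palindromic, so no dedup
  ambiguity reaches the screen. For non-palindromic motifs, plus- and
  minus-strand matches at the same span are distinct hits.
- **Overlapping occurrences are all counted.** No exclusion or greedy
  masking rule is applied; counting all offsets is the simplest semantics
  to reason about and to reproduce.

The production scanner is vectorized (per-position boolean lookup tables
over a byte array); the test suite checks it for identity against a naive
per-offset, both-strand oracle on seeded random sequences.

The exact EcRE consensus used in the original screen is not on record;
`RGGTCANTGACCY`, the canonical hsp27-derived palindromic EcRE of the
literature, is the package default and both consensi are plain parameters,
so any alternative string can be supplied at every entry point.

## The region screen

A candidate region passes iff it contains at least `min_ap1` (default 4)
AP-1 motif occurrences **fully inside** the region and zero EcRE
occurrences. Occurrences straddling a region edge do not count: the region
is the unit of the screen. The screen is monotone in `min_ap1` and
idempotent on its passing subset; both properties are tested. The consensi
and threshold are echoed in the output header so a screen run is fully
reproducible from its report.

## Peak-overlap categories

Sites are colored by ChIP-seq peak overlap: green if an EcR peak overlaps
(≥1 shared base, no slop window), red if Jun and/or Kay (Fos) overlap but
EcR does not, blue otherwise. When a site overlaps both EcR and an AP-1
subunit, green wins — EcR recruitment is the screen's subject — and the
full factor list is retained on the record so the precedence choice loses
no information. Usp peaks are recorded in the factor list but never change
the category, matching the three-color scheme's definition. Adding peaks
can only promote a site (blue → red → green), never demote it.

## Gene context

- Region-to-gene assignment reports **all** genes within the window
  (default 10 kb, configurable and echoed in output): nested gene
  arrangements make single-winner assignment lossy. Distance is the gap
  between closest edges; overlapping genes get distance 0 with relation
  `contained_in_gene` or `overlaps_gene`. Abutting (gap 0, no shared base)
  intervals are classified `near_gene` with distance 0 — the edge
  arithmetic admits no other value.
- Gene size statistics use the **gene span**, not the exon union, because
  the comparison of interest concerns gene extent (large introns).
- Motif density is occurrences per 10 kb of span:
  `count * 10000 / span_length`.

## Image quantification

- **ROI fraction**: the ROI is a simple polygon in pixel-edge coordinates;
  a pixel belongs to it iff its center `(col+0.5, row+0.5)` lies inside
  (for simple polygons this coincides with even-odd fill), making areas
  reproducible across implementations. Signal is every pixel with
  intensity ≥ threshold; the value is `signal_px / roi_area_px`. The
  threshold is an explicit parameter to be held constant within a dataset;
  the direction "≥ threshold = signal" is fixed and documented here
  because thresholding conventions differ between tools.
- **Strip mean**: arithmetic mean gray value over a rectangle;
  `StripBatch` enforces one fixed selection size per comparison batch and
  errors on a differing rectangle instead of silently measuring.
- **Group comparison**: two-sided equal-variance Student's *t*-test with
  means ± s.e.m. (sd/√n). Zero pooled variance — possible on clean
  synthetic data — returns a flagged degenerate result (t = ±inf, p = 0,
  or t = 0, p = 1 for identical means) rather than crashing.
- **PLA classification**: a punctum is nuclear iff the pixel containing
  its centroid is inside the binary nuclear mask. Puncta are small
  relative to nuclei, so centroid membership is the simplest rule
  consistent with describing signals as nuclear or cytoplasmic;
  area-overlap rules would need an arbitrary fraction cutoff.

## Synthetic data

Every generator is a pure function of its spec, seed included. One global
seed expands to per-component child streams via numpy's
`SeedSequence(seed, spawn_key=(component,))`, giving reproducibility with
component independence.

- **Genomes**: i.i.d. bases at a configurable GC fraction (default 0.5,
  uniform) with motif realizations planted at stated coordinates
  (ambiguous positions drawn uniformly from their allowed sets). With
  `clean_background`, spurious occurrences of any registered motif are
  destroyed by mutating one constrained position per hit — never inside a
  planted site — and re-scanning to fixpoint, so planted counts are exact
  while base composition is perturbed only locally.
- **Region sets**: one region per prescribed `(ap1_count, ecre_count)`
  composition, sites placed in non-overlapping slots with seeded jitter.
  The screen's output on this data is the prescription itself. The
  fixture-scale summary uses 502 regions of 320 bp (gap 80 bp, ~200 kb
  chromosome) with 51 passing compositions spread across the set — sizes
  chosen so the full fixture screens in well under a second while
  exercising every composition class.
- **Peaks**: one peak per planned (site, factor) pair, the site span
  padded by 5 bp; expected categories follow from the plan by the
  precedence rule.
- **Gene sets**: gamma-distributed span lengths (CV 0.2 — dispersed but
  strictly positive) laid end to end; the size-ratio check draws 60
  candidate genes at mean 22 kb against 200 background genes at mean
  11 kb.
- **Images**: constant or Gaussian background, an exact number of planted
  signal pixels inside the ROI (background is clipped strictly below the
  threshold so the planted count stays exact even in noisy mode), strips
  filled at planted means (exact only in noiseless mode; the realized mean
  is recorded alongside), and PLA fixtures built from disk-shaped nuclear
  masks with prescribed nuclear/cytoplasmic partitions — e.g. 95 of 131
  puncta outside the mask gives 72.5% cytoplasmic, and 44 of 132 gives
  33.3%. When a ROI part is present, puncta are not rendered into the
  image so they cannot corrupt the planted pixel count.

### What the generators do not emulate

Real genome base composition and chromatin structure; ChIP-seq read-level
noise, peak-calling uncertainty, or stage/cell-type differences between
peak sets; optical blur, uneven illumination, z-projection artifacts, or
segmentation error in images; hand-selection variability of ROIs. Passing
tests therefore demonstrate the *correctness of the computations* on
inputs with known truth, not the biological validity of any particular
screen run on real data — real region sets, assemblies and peak files
remain user-supplied inputs whose provenance the package treats as opaque.

## Numerical and edge-case choices

- Empty screen input summarizes to `(0, 0, 0.0)` by convention.
- A motif longer than its sequence yields an empty hit list, not an error.
- BED lines failing validation are reported with their line number;
  missing BED names become deterministic `region_<i>` labels.
- FASTA ambiguity codes other than N are rejected by default; an explicit
  flag maps them to N (where they then match no motif, per the N rule).
- The t-test type-I calibration uses 1,000 null replicates of n = 10 per
  group; the background-density check uses 200 seeded 10-kb sequences,
  whose expected AP-1 count per sequence is `(10000−6)·4⁻⁶ ≈ 2.44`
  (six constrained positions, palindromic span dedup).

## Known limitations

- The screen does not attempt to reproduce any published region list; the
  fixture-scale 502/51 run demonstrates the bookkeeping at the published
  scale on synthetic regions only.
- Peak sets from different developmental stages are carried with a free-text
  `source_label` but no stage-comparability logic.
- Whether a palindromic site should ever be counted twice, and which EcRE
  string the original screen used, are configuration choices surfaced as
  parameters rather than resolved facts.
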
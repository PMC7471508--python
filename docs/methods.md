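# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention).  Printed
genome-browser coordinates are converted explicitly: gene annotations
(e.g. `chr2:145141942-145277958`) are 1-based inclusive, so the parser
shifts the start down by one and length is `end - start + 1`; round-number
map coordinates (region boundaries, loop anchors such as
`chr2:145305000-145310000`) are treated as half-open bin edges, so length
is `end - start`.  This makes the printed "20 kb" region and "295 kb"
loop spans exact rather than off-by-one.  *ZEB2* lies on the minus
strand, so its TSS-side coordinate is the larger printed gene coordinate;
the distance from the TSS to the distal enhancer region is computed from
that side.

## In-silico digestion

Recognition sites are matched IUPAC-expanded on the top strand only,
which is exact for the palindromic built-ins (ApoI `RAATTY`, cut offset
1; DpnII `GATC`, cut offset 0); non-palindromic patterns are rejected
rather than silently half-digested.  Lowercase (soft-masked) bases match
their uppercase equivalents — capture design ignores repeat masking.  `N`
in the sequence never matches, so runs of `N` lengthen fragments; a
warning is emitted when the `N` fraction exceeds 1 %.  Cuts landing
exactly on a region edge create no fragment boundary.  Fragment maps
always tile the region exactly (property-tested), and the scanner is
verified against both a naive position-by-position oracle and the
Biopython restriction engine.

## Contact matrix

Each mate of a pair is assigned to the fragment containing its 1-based 5'
mapped position.  This is deliberately simpler than the fragment-end
walking of full Hi-C pair tools; it is the rule most directly implied by
"annotate alignments with the restriction fragments in which they are
located" and is exactly reproducible.  Default filters: `mapq >= 30` on
both mates, drop same-fragment pairs (self-circles/undigested products,
uninformative), keep adjacent-fragment pairs (no established rule to
drop them for capture data; both settings are exercised in tests), count
but exclude trans and off-region pairs.  Every dropped pair is tallied
by the first reason that applies, and input = kept + Σ dropped always.

Binning assigns a fragment to the bin containing its midpoint and sums
counts — deterministic and integer-conserving, at the cost of a slight
edge blur for fragments straddling bin edges (~2.5 % of fragments at
500 bp fragments / 20 kb bins).  Aggregation acts on the upper-triangle
representation so that two distinct fragments falling in one bin
contribute one count to that bin's diagonal.  No balancing or
normalisation (ICE etc.) is applied; raw binned counts are reported.

Matrices are stored as upper-triangle triplet TSV plus a JSON sidecar
with the axis and full provenance (filters, tallies); read∘write is the
identity and inconsistencies between sidecar and triplets are errors.

## Insulation score and boundaries

The raw insulation value at bin *i* with window *w* (default 5 bins,
i.e. 100 kb at 20-kb resolution) is the mean count over the square
`(i-w, i] x (i, i+w]`; the first and last *w* bins have no full square
and are undefined.  Scores are `log2(value / mean over defined bins)`.
A raw value of 0 at a defined bin yields a score of −inf: this is a
legitimate, maximally-insulated boundary signal (a fully contact-free
gap), and the boundary caller handles it; finiteness holds whenever raw
values are positive.  If the mean itself is 0 the profile is entirely
undefined.  Boundaries are strict local minima with score ≤ −delta
(default 0.5, i.e. ≥ 1.4x depletion); a flat run of equal minimal
scores strictly below both neighbours is reported once at its leftmost
bin.  The insulation-square method was chosen over directionality-index
or arrowhead approaches because it has the fewest parameters and maps
directly onto the "sharpness of domain edges" intuition.

## Loop calling

Expected counts per separation *d* are plain means over all pixels at
that separation (zeros included).  Pixels with `|i-j| <= 1` are excluded
from everything — they are dominated by self- and re-ligation.  A pixel
is a loop candidate when (i) observed ≥ `min_count` (default 5),
(ii) observed/expected(d) ≥ `enrichment` (default 3), and (iii) observed
exceeds `enrichment` times the mean of its 8-neighbourhood.  Touching
candidates merge to the pixel of maximal enrichment.

At the simulated depth (10^5 pairs over a 100-bin map) the far-field
expectation is a few counts per pixel, so Poisson shot noise occasionally
produces pixels that clear all three thresholds; calls should therefore
be read by rank.  The planted loop (enrichment 8 over background) is the
top-ranked call in every tested seed with ~3x the enrichment of the
strongest noise call; an absolute false-positive guarantee would require
either greater depth or a significance model (deliberately out of scope).

## Enhancer candidates

Peaks with *any* overlap with the anchor are selected whole — a peak
straddling the anchor edge is evidence about the element, not about the
bin grid (clipping is available but off by default).  Selected peaks are
merged when separated by ≤ `merge_gap` (default 2 kb, the scale of the
published cluster separations), scored by length-weighted mean
conservation with uncovered bases counting 0, and named `Enh1..n` left
to right.  The conservation threshold defaults to 0 — conservation is
reported, not filtered on, since no published threshold exists.  Merging
is idempotent and naming is invariant under input permutation.

## Motif scanning

Counts convert to probabilities with a pseudocount of 0.8 split
proportionally to the background (uniform 0.25 by default), then to
log2 odds — the convention of standard JASPAR tooling.  The relative
score rescales a window's score between the per-column minimum and
maximum sums of the log-odds matrix, so 1.0 is the best attainable
match; "confidence > 90 %" is relative score ≥ 0.90.  Both strands are
scanned (minus strand = reverse complement of the window scored against
the profile, offset reported on the forward strand); windows containing
`N` are skipped; a fully degenerate profile (max = min) scores 1.0 by
convention.  Hits are ordered by (offset, strand `+` before `-`, motif
name).  The scanner is verified against a brute-force all-windows
scorer and against Biopython's PSSM engine.

The shipped profile file (`t2c/data/toy_motifs.pfm`) contains synthetic
toy profiles constructed for tests and simulation.  They are named after
the TF families they caricature (ETS1, FOXD2, HOXB2, SOX10, YY1) but are
not database profiles; real analyses should supply real PFMs.

## Synthetic data generator

The generator emulates the features of a capture experiment that the
pipeline's calls depend on, with full determinism under a seed:

* **Genome** — i.i.d. uniform bases with concrete ApoI-site realisations
  planted at exponential spacing.  Uniform sequence already contains one
  site per ~1024 bp (4 of 4096 hexamers match `RAATTY`), so the planting
  rate tops up the background rate to reach the target mean fragment
  size (default 500 bp, the observed scale in the AT-rich locus that
  motivated the package).  Background sites stay in the truth map, which
  equals the digest of the emitted sequence by construction.
* **Contacts** — bin-level weights
  `w(i,j) = (|i-j|+1)^(-alpha) * exp(tau*[same TAD]) * gamma_loop` for
  `|i-j| >= 2`, zero otherwise, normalised over the upper triangle;
  pairs are a single multinomial draw of `n_pairs` (default 10^5).
  Defaults: `alpha = 1.0` (the decay exponent typical of mammalian
  contact maps at the sub-Mb scale) and `tau = 1.0` (~2.7x within-TAD
  enrichment, mid-range for well-defined domains).  Read endpoints are
  placed uniformly in a uniformly-chosen fragment *whose midpoint lies
  in the drawn bin*, so re-running the contacts module on the emitted
  pairs reproduces the truth matrix exactly — the end-to-end identity
  the tests assert.  Short-range pixels carry zero probability,
  mirroring their exclusion by the callers.
* **Tracks** — one peak per planted enhancer; conservation 1.0 over
  enhancers and 0.1 elsewhere; the named profile's consensus written
  into the centre of each enhancer (the fragment map is digested after
  this edit, keeping it consistent with the emitted FASTA).

The default spec mimics the studied locus at reduced scale: a 2-Mb
region, 20-kb bins, TAD boundaries at bins 33 and 66 (three domains), a
loop spanning 25 bins (500 kb, the promoter-to-gene-desert scale) with
enrichment 8, and three enhancers of ~0.3–1 kb in the distal anchor.

What the generator does *not* model — and what passing tests therefore
do not show — includes sequencing error, PCR duplicates, capture
efficiency bias along the region, trans contacts, fragment-level (as
opposed to bin-level) contact structure, and realistic base composition
or conservation texture.  Recovery on this generator demonstrates the
correctness of the computational chain, not performance on real
libraries.

## Problem sizes and determinism

Tests and the acceptance script use the default 2-Mb/10^5-pair
simulation, with 20 seeds for boundary/loop recovery and a 1-Mb genome
for fragment-size statistics — sizes at which every statistical check is
stable while the whole suite runs in well under a minute of compute.
All random draws flow from `numpy.random.default_rng` seeded from a
single integer; reruns are byte-identical, file outputs included.
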
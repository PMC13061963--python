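# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, and what the synthetic-data generators do and do not
emulate.

## Read QC

Reads are cleaned in three steps: terminal adapter/barcode trimming,
concatemer flagging, then filtering.

**Adapter matching.** All matching (trimming, concatemer detection, flank
extraction) uses an exhaustive ungapped offset scan: every placement of the
adapter against the search region is scored by exact base identity over the
overlap, and a placement qualifies when identity ≥ `min_identity` (default
0.8) over ≥ `min_match_len` (default 12 nt) of overlap. `N` never counts as
a match. An ungapped scan was chosen over gapped local alignment because the
targets are short (≈ 20–30 nt), the acceptance band is loose (80%), and the
scan is exactly reproducible and trivially auditable; all three parameters
are exposed. Terminal trimming searches the first/last `end_window`
(default 150 nt) of the read and cuts at the hit's inner boundary, so it is
idempotent.

**Concatemer rule.** A read is a concatemer when an adapter hit lies inside
the read, outside both end windows; hits straddling a window boundary are
attributed by their midpoint. Consequence: an internal adapter closer than
`end_window` to a read end is not flagged — fragments shorter than the end
window joined at a read terminus are indistinguishable from terminal
adapter remnants under this rule. The synthetic recall/precision checks
therefore use pools whose fragments exceed the end window.

**Filters.** Length strictly greater than 65 nt (a 65-nt read is removed);
median per-base Phred ≥ 13 (a 13.0 read is kept; even-length medians are
the central-pair mean); no concatemer flag. Reads failing several rules are
removed once but counted under every rule in the report.

## Sequence statistics

**Transition matrix.** P(b→b′) = (count of adjacent ordered pairs b,b′) /
(count of b with a successor). Rows without support are NaN, never
zero-filled; consumers impute explicitly (clustering uses uniform 0.25).
Pool-level matrices are count-weighted — pair counts are pooled before row
normalization — because that is the only aggregation that reduces to the
single-read matrix on homogeneous pools; a read-averaged variant can be
built from per-read matrices if needed.

**Autocorrelation.** r(k) = |{i : sᵢ = sᵢ₊ₖ, both called}| / N with N the
full sequence length, for k = 0..max_lag. The fixed /N denominator (rather
than N−k) is deliberate: it encodes the finite length of the molecule, so
r decays toward 0 at large lags and profiles of different reads are
comparable at equal lag. r(0) = 1 for N-free sequences by the same formula.
An `N-k` denominator is available behind a flag. Exact matching only; `N`
bases never match anything.

## Tandem-repeat motifs

`max_tandem_copies` is a right-to-left dynamic program (copies starting at
i = 1 + copies at i+|m| when the motif matches at i), linear in sequence
length × motif length; ties in the maximal run resolve to the leftmost
start. Matching is exact: partial trailing copies and runs broken by one
substitution do not count. This makes classification stringent on noisy
reads — a deliberate convention; the error model of real reads would
otherwise leak into the repeat definition.

Copy thresholds by motif length: 7 consecutive copies for 1–3 nt, 6 for
4 nt, 4 for 6–8 nt; the 9–10 nt palindromic motifs (A⁴T⁴ at 8 nt is
covered; A⁵T⁵ at 10 nt) follow the long-motif rule of 4. Motif fraction
tables sample `min(600, available)` reads > 65 nt uniformly without
replacement (seeded) and classify each read independently; a read may carry
several motifs. Absent motifs report exactly 0.

Rotation handling: `GT` and `TG` denote the same repeat up to phase; with
`canonicalize_rotations` on, detection takes the maximum copy count over
all rotations (a maximal (TG)ₖ run differs from (GT)ₖ by at most one copy).
Default off, since the default panel already names one representative per
family.

**Genome scan.** Forward strand only (the scanned motif list enumerates
reverse-complement pairs explicitly), non-overlapping leftmost-greedy
counting of the doubled motif; an overlapping mode is flag-selectable. The
reported proportion is (n·m)/g with m = |motif| × copies.

## Clustering

Feature rows concatenate the composition vector (4), the flattened
transition matrix (16, NaN rows → 0.25), and r(1..24). Each column is
z-scored across reads; zero-variance columns stay 0. Distance/linkage are
Euclidean/Ward — unreported in the original analyses, chosen here for
determinism and robustness and config-exposed. The tree is cut to `n_top`
(default 7) groups; clusters are reported largest-first with deterministic
tie-breaking (lower original index). Labels: the panel motif passing in the
largest fraction of member reads, if that fraction is ≥ 0.5, else
"random"; ties break to the lexicographically smaller canonical rotation.
Pools are clustered separately below/above 250 nt after seeded subsampling
(default 500 reads per class).

## Two-phase kinetics

Curves are baseline-subtracted (mean of the first 3 points) and scaled so
max = 1. The two-phase model is a *continuous* hinge
y = c + a·t + d·max(t−b, 0): physical fluorescence is continuous, and the
joint fit removes one free parameter relative to disjoint regressions. For
fixed b the fit is linear least squares; b is located by exhaustive search
over interior grid points (≥ 3 points per side) and refined by bounded
scalar minimization between the neighbouring grid points. Deterministic;
noiseless recovery is exact to solver tolerance. The default fit window is
0–120 min, the regime in which both phases are linear; saturation is
handled separately. A fit is flagged low-confidence when the hinge improves
the residual sum of squares over a single line by < 5% (or the line already
fits to numerical precision) — the breakpoint is then unidentifiable.

**Stop time.** The centered moving-window least-squares slope (window
15 min) is compared against `slope_tol` (default 0.05) × fast rate; the
stop is the earliest time whose slope is below threshold, whose remainder
has mean slope below threshold, and after which no re-rise lasts ≥ 3
consecutive samples. The estimator is valid when the slope noise is below
the threshold: with 5-min sampling this means curve noise up to roughly
0.2–0.5% of the maximum. At higher noise the windowed slope cannot resolve
"stopped" against the 5% band and the function returns late times or None;
use longer windows or replicate-averaged curves there. Replicate averaging
is also how the headline rate ratio is computed in the acceptance script
(four replicates per experiment), mirroring how replicate fluorescence
assays are summarized; single-curve fits at 2% noise have a heavy-tailed
ratio (slow-rate in the denominator is estimated from ~6 points).

## AFM tracing

**Flattening.** Each scan row gets a cubic background subtraction. The
first pass uses an L1 (iteratively reweighted) fit, which resists a
contiguous ridge plateau crossing the row — an L2 cubic partially absorbs a
near-horizontal strand. A global foreground mask (flattened height >
median + 5 robust σ, dilated by 3 px so clean neighbouring rows reveal
strand pixels in corrupted rows) then drives a second per-row L2 fit on
background pixels only. A noiseless-image guard keeps the robust σ from
collapsing to rounding error. Rows whose majority is ridge remain
unrecoverable by any per-row method; the generator's layouts keep strand
coverage per row well below 50%.

**Segmentation.** Pixels above `threshold_nm`, 8-connected, after a
radius-1 morphological closing that bridges single-pixel dropouts without
merging separated molecules; components under `min_pixels` (default 20) are
discarded.

**Tracing.** The skeleton (one-pixel centerline) becomes a weighted pixel
graph: step 1 for rook moves, √2 for diagonal. Diagonal edges that shortcut
two rook edges are removed — they create spurious triangles at junctions —
so only true loops remain cycles; those are broken by deleting a cycle edge
at the highest-degree node (flagged `had_cycle`). Spurs shorter than
`spur_min_pixels` (default 5) are pruned. The *trunk* is the
maximum-weight endpoint-to-endpoint path (double Dijkstra sweep, exact on
trees); every sub-tree hanging off the trunk contributes a *branch*,
measured from its junction to its farthest endpoint, recursively, so
branches of branches are counted. Free path ends are extended along their
direction to the mask boundary, recovering the ~half strand-width the
skeleton loses at rounded caps (a no-op on one-pixel-wide masks).

**Lengths.** Physical lengths default to smoothed-path summation: the pixel
path is moving-average smoothed (window 7, endpoint-anchored) and Euclidean
step lengths summed. Raw chain-code summation overestimates digitized
straight lines by up to ~8% at shallow angles (staircase effect); smoothing
removes most of that bias while following genuine curvature. The raw 1/√2
step sum remains on the trace (`*_length_px`) and is what the path-level
invariants are stated in. Conversion: nm = px × `pixel_nm` (default 0.48),
nt = round(nm / 0.34).

The operator-guided junction selection of semi-automated AFM workflows is
replaced by automatic junction detection (skeleton nodes with ≥ 3
neighbours); ambiguous crossings may therefore resolve differently than a
human would resolve them.

## Synthetic data

The generators emulate the statistical structure the analyses assume, not
the instruments:

- **Read pools**: mixture components (tandem motif, poly-A, or uniform
  random) with weights; lengths from a log-normal mixture (default modes 80
  and 400 nt, σ = 0.35 — the bimodal shape of Taq pools at 65 °C; presets
  also provide an exponential-decay Vent-like model) or exponential decay;
  repeat reads start at a random phase of the motif; per-base Phred scores
  from a normal around a target median (default 13, clipped to [2, 41]);
  substitutions with probability 10^(−Q/10) per base unless a flat rate is
  given; indels (uniform positions, 50/50 insertion/deletion) applied after
  substitutions. Not modelled: homopolymer-length errors, strand bias,
  quality-position correlation, or any signal-level nanopore behaviour — so
  passing tests show the *analysis* logic is correct under a calibrated
  error budget, not that the pipeline is robust to every real nanopore
  artifact.
- **Artifacts**: a known ligation adapter (± barcode) on both termini;
  concatemers formed by joining a read with a random partner through an
  internal adapter copy. Ground-truth flags ride along in read metadata.
- **Kinetics curves**: analytic integral of a piecewise rate — slow to the
  breakpoint (default 30 min), fast (default 3.25×) to saturation onset
  (default 120 min, i.e. 1.5 h of linear fast phase), a half-cosine decay
  to zero at the stop (default 180 min), flat thereafter; 5-min sampling
  over 16 h; additive Gaussian noise as a fraction of the maximum. Using
  the analytic integral makes noiseless finite-difference slopes exact,
  which the model-identity tests rely on.
- **Height maps**: per-row cubic background (optionally scaled linearly
  with row index), 2-nm ridges of half-width 1 px along molecule polylines,
  Gaussian height noise; 0.48 nm pixels. The random layout generator places
  straight-trunk molecules one per grid cell (so masks never merge) and
  constrains branches to be shorter than both trunk arms — otherwise the
  maximum-path trunk definition legitimately routes through the branch and
  "trunk"/"branch" lose their ground-truth meaning.

One integer seed drives every generator through `numpy.random.SeedSequence`
sub-spawning: identical seeds give bit-identical pools, curves and images.

## Problem sizes

Default test and acceptance runs use pools of 2 000–3 000 reads, 600-read
motif samples, 50 kinetics seeds, and 50 AFM layouts of four molecules at
360×360 px — sizes at which the binomial/hypergeometric 3σ bounds used in
the recovery checks are tight enough to be informative while the full suite
stays desk-scale.

## Known limitations

- Concatemers whose fragments are shorter than the end window are
  undetectable under the midpoint rule (see QC above).
- Exact repeat matching undercounts motifs in high-error reads; there is no
  fuzzy matching by design.
- The stop-time estimator degrades above ~0.5% curve noise at 5-min
  sampling (see kinetics above).
- Genome scans are single-strand and exact-match; no reverse-complement
  folding, no mismatch tolerance.
- Cluster *fractions* depend on subsampling and the cut rule; only the
  labels and ground-truth agreement are treated as recoverable quantities.
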
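# Methods

## Problem setting

The input is a strand-specific, per-nucleotide read-count matrix: one row
per genomic position, one column per time point (d columns; the motivating
data have d = 24 samples covering ≈ 2.5 cycles of an oscillatory
transcriptome). Transcript boundaries are to be inferred from changes in
the *temporal pattern* along the genome. The only structure assumed on the
per-position measurements is a similarity function σ satisfying

* (s0) σ(u,u) ≥ 0, (s1) symmetry, (s2) self-maximality σ(u,u) ≥ σ(u,v).

Neither the triangle-type inequality (s3) nor identity of indiscernibles
(s4) is required or checked beyond construction-time validation of
(s0)–(s2) (matrices exhaustively; callables on sampled pairs).

## Exact segmentation (`simseg.exact`)

`solve_fixed_segments` and `solve_penalized` maximize the summed interval
scores via the standard change-point recursion, with interval scores σ_a
(average similarity to the interval) or σ_m (total similarity to the
interval medoid; medoid ties resolved to the smallest index). Average
scores are evaluated in O(1) from a 2-D prefix-sum of the similarity
matrix; medoid scores use per-column prefix sums (O(interval length) per
evaluation). The solvers are quadratic/cubic in n and serve as the exact
reference; genome-scale inputs go through the cluster DP.

Tie-breaking is fixed: the fixed-ℓ backtrace prefers the *later*
breakpoint; the penalized variant prefers *fewer* intervals among
co-optimal segment counts. `brute_force_segment` (n ≤ 16) enumerates all
2^(n−1) breakpoint sets and doubles as the test oracle, optionally
reporting the full co-optimal set.

**A note on subadditivity.** The requirement that splitting an interval
never lowers the score, f(i,k) ≤ f(i,u−1) + f(u,k), is *not* implied by
(s0)–(s2): with σ(u,u) = 1, σ(1,3) = 1 and σ(1,2) = σ(2,3) = −1 (a valid
similarity space), σ_a gives f(1,3) = 5/3 > f(1,2) + f(3,3) = 1. On
positive-semidefinite similarity matrices (every correlation-derived σ)
average-mode subadditivity is a theorem — writing the block sum as
‖Σ_u z_u‖² it reduces to ‖x+y‖²/(m+n) ≤ ‖x‖²/m + ‖y‖²/n — and the
property test asserts it there. Medoid scores can violate the inequality
even on such matrices. None of this affects the exactness of the DP, which
optimizes the stated objective regardless.

## DFT features (`simseg.timeseries`)

Each position's d-vector is mapped to Fourier components with a 1/d
normalization, so component 1 (DC) equals the temporal mean. Defaults
mirror the motivating application: components 1–7 (`dft.range = 1:7`)
retained; per-position amplitude normalization (`use.snr`) divides each
retained non-DC amplitude by the mean amplitude over *all* non-DC
components of that position, leaving phases untouched — this makes the
oscillatory features scale-invariant so that coverage level alone cannot
drive the clustering. The exact normalization formula is this package's
choice (the convention in the lineage literature is described only by
reference); the phase-preservation and scale-invariance contracts are what
downstream code relies on, and they are property-tested.

The DC component is kept as one real column: `dc.trafo = ash` stores
arcsinh(total counts over the cycle), compressing the dynamic range so
mean expression can separate close adjacent segments without dominating
the Pearson correlation; `raw` stores the plain temporal mean. A
`dc_weight` factor (default 1) scales its influence. An all-zero raw
series defines a non-expressed (nuisance) position: zero feature row,
`nuisance_flag = True`. Positions are processed independently — no
smoothing along the genome, no detrending, no library-size normalization
(inputs are assumed normalized).

## Clustering (`simseg.clustering`)

k-means (scikit-learn, Lloyd + k-means++, fixed `random_state`, `n_init`
= 10) runs on expressed positions only; labels are 1…K with 0 reserved for
nuisance. The published workflow uses R's Hartigan–Wong k-means;
algorithmic equivalence is deliberately not claimed — clustering
variability is treated as a robustness dimension to scan over, and
reproducibility under a seed is the contract. Cluster centers are plain
feature-space means. Two Pearson matrices follow: position × center
(`icor` basis) and center × center (`ccor` basis); zero-variance rows or
centers get correlation 0 by convention to keep scoring finite. Positions
correlating below θ (`nui.thresh`, default 0.6) with their own center are
re-assigned to the nuisance cluster; centers are *not* recomputed
afterwards. `sort_clusters_by_similarity` relabels clusters along a greedy
nearest-neighbour chain for display; all matrices are permuted
consistently, so downstream scores are invariant.

## Cluster-based DP (`simseg.clusterseg`)

Scoring functions per position i and cluster α: `ccls` (1 if the
position's label equals α, else a < 0, default −1), `icor`
(φ_ε(corr(x_i, x̄_α))), `ccor` (φ_ε(corr(x̄_{C_i}, x̄_α))). The transform
φ_ε(t) = sign(t)|t|^ε (ε ≥ 1) suppresses moderate correlations; it is
applied only to correlation-derived entries, never to the constants a
and ν.

Two nuisance parametrizations are implemented, selectable via
`nuisance_mode`:

* `compensate` (library default): s(i,k,0) = M, exactly offsetting the
  jump penalty so nuisance stretches are score-neutral. A consequence
  worth knowing: a lone all-covering nuisance segment then always scores
  exactly M, so for large M it can beat any weakly scoring real
  assignment — by the recursion itself, not a bug.
* `nu`: the nuisance column scores +ν for nuisance-labelled positions and
  −ν otherwise; under `ccor`, nuisance-labelled positions score −ν in
  every real column. ν > 1 actively enforces breaks at transitions into
  non-expressed or noisy regions, which is why the pipeline default uses
  this mode.

Jumps into the nuisance cluster cost M₀ (`Mn`, default = M). An optional
affine rescale of the score matrix into [0,1] (`scale01`) makes M
interpretable in segment-length units; with it, the number of intervals is
provably non-increasing in M (exchange argument over the penalty-linear
objective), which is asserted in the acceptance suite.

`segment` exploits the prefix identity s(i,k,α) = s(1,k,α) − s(1,i−1,α)
to maintain the inner maximum incrementally (top-two trick over the
predecessor clusters), giving O(nK) time; `segment_naive` evaluates the
recursion directly in O(n²K²) candidate enumerations and is the
correctness reference. Both share one tie policy — prefer the smaller
predecessor i (longer last segment), then the smaller cluster index — so
their outputs are identical, not merely equal in score. `chunk_and_segment`
cuts long inputs into overlapping chunks and stitches by the midpoint
rule: each chunk owns the half-open window up to the midpoints of its
overlaps, every breakpoint is owned exactly once, and segments far from
chunk borders reproduce the whole-input solution (the caller chooses the
overlap no smaller than the expected maximum segment length).

## Pre-segmentation (`simseg.preseg`)

Works on the presence signal n_i (number of time points with any signal),
hence depends only on the zero pattern. A wide centered moving average
(window `avg` = 1000 nt, truncated at chromosome ends) is thresholded at
`minrd` (default 8 of d = 24, i.e. 1/3); runs of at least `min_gap_len`
(1000 nt) below threshold are candidate gaps, and pre-segments are their
complements. Each boundary is then placed where a narrow (`favg` =
100 nt) moving average of n_i, *facing outward from the pre-segment*,
first reaches zero. The outward-facing window is a deliberate design
choice: it makes the final boundary coincide with the last position
carrying any signal whenever the adjacent zero run is longer than `favg`,
which yields the two invariants the heuristic is meant to guarantee —
every long all-zero run falls entirely into an inter-segment, and no
expressed position is ever lost to one. A centered window would leave
half a window of each zero run inside the pre-segment and could satisfy
neither. Pre-segments shorter than `minsg` (1000 nt) are fused with the
neighbour across the shorter inter-segment (ties to the left); nothing
extends or fuses across chromosome ends. Pre-segments and inter-segments
partition each chromosome exactly.

Note the detection arithmetic: with a 1000-nt centered window and the 1/3
threshold, an all-zero run is detected only if its below-threshold core is
itself ≥ `min_gap_len`, which for solidly expressed flanks requires the
zero run to exceed roughly 1.7 kb. The synthetic genome's inter-block gaps
are sized accordingly (2 kb).

## Synthetic data (`simseg.synthetic`)

The generator emulates a compact genome densely packed with oscillating
transcripts: expected coverage inside a transcript is
edge(p) · [baseline + amplitude (1 + cos(2π·cycles·t/d − phase))], with a
linear 0→1 ramp over `end_gradient_length` nt at both ends (coverage
gradients at transcript boundaries), same-strand overlaps summing,
reverse-strand transcripts covering only the reverse track, and exact
zeros outside all transcripts. Counts are Poisson (default), negative
binomial, or exact expectations (noise off). 2.5 cycles is deliberately
non-integer so the oscillation sits between DFT bins and spectral leakage
is exercised; phase-recovery tests use integer-cycle variants where the
bin argument equals −phase exactly.

Two seeded fixtures define the study conditions. `tiny`: 5-kb chromosome,
4 transcripts in two phase cohorts (π apart), one antisense overlap, one
600-nt gap. `desk`: 200-kb chromosome, 60 transcripts (56 forward in 7
blocks of 8, 4 antisense), lengths 1.8–3.2 kb, phases cycling through four
cohorts (adjacent transcripts always π/2 apart — temporal patterns, not
coverage gaps, must separate neighbours), within-block gaps 80–200 nt,
2-kb all-zero inter-block gaps, amplitudes 8–30, baselines 1.5–3,
Poisson noise. The layout is fixed; the seed drives the count noise.

What the fixtures do *not* emulate: mappability artefacts, library-size
drift between time points, replicate structure, spliced or fragmented
coverage within a transcript, and phase drift along a transcript. Passing
the desk-scale recovery test therefore demonstrates correctness and
internal consistency of the pipeline under its own model assumptions, not
performance on real sequencing data, where boundary gradients are noisier
and adjacent transcripts can share phase.

## Pipeline, determinism, evaluation

`run_pipeline` chains presegment → (per pre-segment) process → cluster →
segment → merge → evaluate. Clustering is per pre-segment by default
(`cluster.scope = preseg`; a whole-track mode exists, since either scope
is defensible), and each pre-segment derives its k-means seed stably from
(run seed, chromosome, strand, start) via CRC-32, so the merged output is
independent of processing order and reruns are byte-identical. Pre-segments
with fewer expressed positions than K are reported as skipped and the run
continues. Nuisance segments are omitted from BED output by default
(`include_nuisance` flips this). BED output is 0-based half-open with the
score column affinely scaled to [0,1000]; GFF3 is 1-based inclusive with
raw scores; bedGraph I/O is 0-based half-open, one file per time point per
strand.

Recovery of an annotation uses best-hit Jaccard per target (ties: larger
J, then smaller query start), J_tot = Σ intersections / Σ unions over
best-hit pairs (micro average; the macro mean of per-target J is reported
alongside, and the two are given separate names precisely because they
diverge except in degenerate cases), R = |Q|/|T| with R_short = fraction
≤ 0.8 and R_long = fraction ≤ 1.2 over hit targets, and the mean number
of hits per target. Overlaps are strand- and chromosome-matched; targets
without hits contribute J = 0 and no R.

## Problem sizes and defaults used in the shipped experiments

The shipped acceptance experiment runs the desk fixture (200 kb × 2
strands × 24 time points, 60 transcripts) with icor, ε = 3, ν = 3,
M = 100, M₀ = M, K = 10, θ = 0.6, dft.range 1:7, `use.snr` on,
`dc.trafo = ash` — the parameter regime (ε > 1, ν > 1, larger M) that the
motivating study found to recover annotated transcripts best. Exactness
checks run the brute-force oracles at n ≤ 12 (exact DP, 2^(n−1)
enumerations) and n ≤ 10, K ≤ 3 (cluster DP, segmentations × assignments),
with 300-point instances checking the O(nK) solver against the direct
recursion. These sizes were chosen so the full suite completes in well
under a minute of DP work while still exercising every scoring function,
both nuisance modes, and M₀ ≠ M.
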
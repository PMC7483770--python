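# Methods

## Model

A cohort of tumours is modelled as independent draws from a population
whose genomic signature is a discrete probability function Φ(r): for each
genomic region r, a subject is altered there (gain or loss of copy
number) with probability Φ(r), independently across regions and subjects
(a Bernoulli experiment per region). The analysis goal is the inverse
problem: given segmented profiles of N subjects, estimate Φ.

Region boundaries are not fixed a priori on real data. Instead they are
*induced* by the cohort: pooling every subject's segment starts and ends
on a chromosome and sweeping a counter (+1 per start, −1 per end) over
the sorted breakpoint sequence partitions the altered portion of the
chromosome into maximal intervals of constant subject count — the common
regions of alteration. Within one common region, every subject's
alteration status is constant by construction, so the estimate

    Φ̂(r) = n_occurrences(r) / N_subjects

is an exact integer ratio; no floating-point path touches the counts.
Each Φ̂(r) carries a proportion confidence interval treated per region
(no joint band).

### Assumptions and caveats

- Common regions are treated as independent; spatial correlation along
  the chromosome is ignored.
- The cohort is treated as homogeneous; the signal amplitude (log2 ratio)
  is used only for calling, not weighted afterwards.
- Per-subject segments must be disjoint before the sweep, otherwise one
  subject would be double-counted; `merge_subject_segments` unions
  overlapping or book-ended same-subject intervals first.
- Differential regions between two groups are declared where the two
  confidence bands are disjoint. Non-overlap of two 95% intervals is a
  conservative descriptive screen, not a 5%-level test, and no
  multiple-testing correction is applied. This is a deliberate caveat of
  the procedure, not a defect to be patched silently.

## Coordinates and tie rules

Internally every interval is 0-based half-open `[start, end)`; SEG input
(1-based inclusive) is converted on read. At equal breakpoint positions,
ends are processed before starts, so book-ended segments share a boundary
without overlapping and remain separate regions. Segments exactly at a
calling threshold are called altered (closed comparisons ≥/≤). Zero-
coverage gaps between altered blocks are not emitted as regions; when an
estimate must live on a fixed grid (simulation scoring), absent grid
cells get Φ̂ = 0.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_probes` | 10 | drop segments supported by fewer array probes |
| `gain_threshold` | +0.2 | log2 ratio at/above which a segment is a gain |
| `loss_threshold` | −0.2 | log2 ratio at/below which a segment is a loss |
| `mode` | SEPARATE | gains/losses partitioned independently, or COMBINED |
| `confidence_level` | 0.95 | two-sided level of the per-region band |
| `ci_method` | wilson | also `wald`, `clopper-pearson` |

The calling thresholds are conventional SNP-array cut-offs chosen by this
package, not derived from any reference dataset; results on real data
depend on them and they should be set per platform. Wilson score is the
default interval because it is well-behaved at Φ̂ = 0 and 1, which occur
routinely (regions altered in nobody or everybody).

Group comparison distance: the choice of summary was open; this package
uses the region-length-weighted mean absolute difference
Σ_r |Φ̂_a−Φ̂_b|·len(r) / Σ_r len(r), because common regions have very
unequal sizes and an unweighted mean would let many tiny regions dominate.
For comparability, two groups are always profiled on one *pooled*
partition (boundaries from both groups' segments), each against its own
cohort size.

## Simulator

`sample_cohort` draws a subjects × regions binary matrix from a generator
function over fixed-size regions (default 1,000 bp); `matrix_to_segments`
expands each altered cell into one segment, keeping adjacent altered
regions as separate book-ended segments so that every grid boundary
survives as a breakpoint. Consequently the partition recovers the exact
grid and the incidence matrix reproduces the simulated matrix on
non-empty columns — an exact closure property tested for every seed.
Randomness uses one child stream per subject spawned from the root seed,
so cohorts are reproducible regardless of iteration order.

What the simulator does **not** emulate: variable region sizes, probe-
level noise and aliasing artefacts, germline CNVs, tumour purity/ploidy
effects, or correlated alterations. Passing simulation tests therefore
demonstrates the correctness of the partition/estimation machinery, not
robustness to real-data noise; on real cohorts the calling thresholds and
upstream segmentation quality dominate.

## Error metrics and convergence

With known truth Φ and pipeline estimate Φ̂ at cohort size n:

- ε = Σ_r (Φ(r)−Φ̂(r))² / n. Since Var(Φ̂(r)) = Φ(1−Φ)/n, its
  expectation is Σ_r Φ(1−Φ)/n², giving the 1/n² decay the convergence
  study measures (the summation over replicates is done explicitly by
  `convergence_study`, which reports mean ± SD over replicates).
- ε_p = Σ_{r: Φ(r)>0} (Φ−Φ̂)²/Φ. Regions with Φ(r)=0 are excluded:
  the estimator returns Φ̂=0 there almost always, and a spurious
  alteration would otherwise produce an infinite term. Such regions are
  counted separately (`n_unsupported`) instead. n·ε_p has expectation
  Σ_r (1−Φ(r)), consistent with its approximate χ² behaviour.

The built-in convergence study ships four generator functions over ten
1,000-bp regions — a unimodal signature, a bimodal one, a flat plateau
and a monotone ramp — chosen by this package to span qualitatively
different profiles. Default problem sizes in the test suite (30
replicates at n ∈ {100, 400, 1000}; 100 random generators at n ≤ 50 for
the closure property) were chosen as the smallest sizes at which the
Monte-Carlo assertions are stable.

## Numerical and degenerate-input choices

- Unbalanced breakpoint sequences (counter going negative) raise an error
  naming the offending position rather than clamping.
- An empty filtered cohort is a valid empty result, not an error.
- CI bounds are clipped to [0,1] and nudged to bracket Φ̂ exactly at the
  boundaries.
- Stratified subsampling uses largest-remainder rounding of class quotas
  (ties broken by class label) so per-class draws sum exactly to n, and a
  fixed seed reproduces the draw.

## Known limitations

- No significance model against a genomic background (this is a
  frequency-profile method, not a driver-peak caller).
- Region boundaries depend on the sample: adding a subject can split
  regions, which complicates cross-cohort comparison of boundaries
  (profiles themselves change little). Spline smoothing of profiles for
  cross-cohort comparison is out of scope.
- Sex chromosomes are excluded at calling time.
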
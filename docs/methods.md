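# Methods

## MIC at a locus

For each locus the association between the paired blood and cancer CN
vectors (one value per patient, n = 63 in the study design) is the maximal
information coefficient: the maximum over two-way grids of the grid mutual
information normalized by `log2 min(nx, ny)`, with the grid-size budget
`nx * ny < B(n)` and `B(n) = n^0.6`. The budget is compared strictly and
un-floored; since `63^0.6 = 12.01`, the admissible shapes at n = 63 include
the product-12 grids (2x6, 6x2, 3x4, 4x3) for a total of 12 shapes. All
mutual information is computed in bits from empirical cell frequencies,
with `0 log 0 := 0`.

The maximization over cut placements is solved in three regimes:

* **n ≤ 20** — exhaustive: every placement of `nx-1` and `ny-1` cuts
  between distinct consecutive order statistics is enumerated.
* **2x2 grids at n ≤ 200** — exhaustive over all single-cut pairs, O(n²)
  with cumulative rank counts.
* **otherwise** — one axis receives an equifrequency partition (ideal
  boundaries snapped to admissible cut positions); the other axis' cuts are
  then optimized *exactly* by dynamic programming, which is possible
  because with one margin fixed the grid MI is additive over the free
  axis' segments. Both orientations are evaluated and the larger taken.

Cuts are placed only between distinct sorted values, so tied values are
never split and the statistic is a function of the ranks alone — this makes
MIC exactly symmetric in its arguments and exactly invariant under strictly
increasing transformations (both asserted in tests). The heuristic search
space is a subset of the exhaustive one, so the scalable estimate can only
under-shoot; an independent enumeration oracle (`mic_exhaustive_oracle`,
value-space binning, direct three-entropy evaluation) pins the exhaustive
mode to 1e-12 on small samples. Argmax ties between grid shapes resolve to
the lexicographically smaller shape; degenerate (constant) loci score 0
rather than erroring, because zero association is the correct limit for
flat CN segments.

Profiles over whole chromosomes run in a numba-compiled batch loop that
mirrors the reference implementation decision-for-decision; the test suite
asserts bitwise equality between the two paths.

## Feature selection

A locus is selected when its MIC *strictly* exceeds the threshold γ
(`MIC > 0.65` and `MIC > 0.52` are the two fixed configurations). The
learned threshold is formalized as the largest value on a grid
(default 0.00–0.99, step 0.01) such that every chromosome retains at least
`min_loci` (default 2) selected loci; the result carries a maximality
certificate (feasible at γ, infeasible at γ + step). Selection is
anti-monotone in γ by construction. A chromosome with an empty selection
under a fixed threshold is reported as an unclustered 0/0/0 block rather
than aborting the run.

## Clustering

Kernel K-means never materializes the feature map: squared distance to a
cluster center is `M_ii - 2 mean_{j∈k} M_ij + mean_{j,l∈k} M_jl`, and the
stopping rule compares successive implicit centers through the same
expansion (`max_k ||mu_k,t - mu_k,t-1||² < ε`, default ε = 1e-6), with an
additional stop when assignments are unchanged. Defaults: Gaussian RBF
kernel with median-heuristic bandwidth (the median nonzero pairwise
distance), 10 restarts from random balanced partitions, max 300 iterations,
mandatory integer seed, distance ties to the lower cluster index, empty
clusters repaired by moving in the worst-fitting point. The recorded
objective sequence is non-increasing; if a repair would increase it the
previous state is kept. With a linear kernel the update coincides
algebraically with Lloyd's K-means, which the tests exploit as an oracle
(objectives within 1e-8 under shared initialization). Lloyd's K-means and
Bezdek fuzzy c-means (fuzzifier 2.0, membership-change stopping, hard
labels by maximal membership, coincident-center singularity resolved to
full membership) are the baselines.

## Evaluation

True rate is two-cluster accuracy under the better of the two
cluster-to-label mappings, hence ≥ 0.5 for any assignment. NMI uses
geometric-mean normalization by default (selectable: arithmetic/min/max —
the variants differ on unbalanced partitions and the original report does
not say which was used); a zero-entropy partition scores 0. PD and APD are
reported as `(TR_RFS - TR_EFS)`, scaled to percent, so that positive
values mean the reduced set clusters better — this follows the stated
interpretation and the signs of all published values, although the
displayed formulas have the opposite orientation. APD additionally divides
by `TR_EFS`.

## Synthetic cohorts

Real per-locus CN matrices for this design are not public, so the
generator emulates their structure: background loci are independent
`N(baseline, noise_sd²)` in both tissues (baseline 2.0, noise_sd 0.15 CN);
a fraction `shared_fraction` (default 1%) of loci, grouped into contiguous
segments of `segment_length` (default 25) loci, carry a per-patient,
per-segment latent germline aberration that enters *both* tissues. At
those loci the marginal spread is `aberration_sd` (default 0.3) and the
tumor-blood correlation is `dependence_strength²` (rho default 0.9, i.e.
corr ≈ 0.8); the tumor sample additionally receives a somatic shift of
`tumor_shift` (delta, default 0.15 CN) whose gain/deletion sign is drawn
once per segment and shared across patients, the way recurrent arm-level
aberrations appear in real tumor cohorts. A per-patient random sign was
considered and rejected: it turns the tumor group into a multi-modal shell
that no two-cluster method can map onto tumor-vs-blood, which contradicts
the recovery behavior the analysis is designed to exhibit. All values are
clipped to [1, 3], matching the bounded CN score range, and every draw
descends from the config seed.

The defaults put the entire-feature-set clustering near chance
(TR ≈ 0.5–0.6) while the reduced set improves — the regime of the real
cohort — and the learned threshold on null cohorts lands near 0.52.
What the generator does **not** model: SNP-array noise (GC waves,
attenuation), allele-specific CN, tumor purity/ploidy, inter-locus
correlation beyond segment structure, and any real linkage between loci
and genomic coordinates (locus identity is ordinal). Passing tests
therefore certify the statistical machinery, not performance on real
arrays.

## Problem sizes used in tests

The recovery checks run on a study-shaped suite scaled to 3 chromosomes of
5000/4400/3800 loci (each large enough to carry ≥ 2 planted segments at
the default shared fraction), 63 patients, 5 seeds; the strong-signal
condition uses delta = 1.0, rho = 0.95 and evaluates the reduced set at the
MIC > 0.52 configuration, the null condition uses the learned threshold.
The full 22-chromosome suite at study sizes (2,520–22,215 loci,
256,554 total) is available via `study_shaped_suite` and
`analysis/01_simulate_cohorts.py --full`.

## Known limitations

* The equifrequency/DP search is exact per orientation but not over all
  grids; outside the exhaustive regimes MIC can be slightly conservative
  (never anti-conservative).
* The learned-threshold rule is deliberately maximal, so it strands the
  weakest chromosome at exactly `min_loci` loci; on synthetic cohorts the
  fixed 0.52 threshold recovers the planted loci much more completely
  (Jaccard ≈ 0.95 vs ≈ 0.3–0.7).
* True rate is defined only for the two-group problem; K > 2 is rejected.
* MIC here is used as a raw score with fixed thresholds; no permutation
  null or multiple-testing control is attempted (by design of the original
  analysis).
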
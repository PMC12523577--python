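# Methods

## Model and procedure

The package builds prognostic staging systems for factor-coded censored
survival cohorts. The unit of analysis is the *combination*: the set of
patients sharing one tuple of factor levels (e.g. `T2bcN0M0P3G2`). A fitted
system is a partition of the training combinations into groups numbered by
survival (group 1 best), plus the artifacts needed to audit it: the
dendrogram, the C-index-vs-groups curve, per-group Kaplan–Meier curves and
the training concordance.

The pipeline makes no proportional-hazards or parametric survival
assumption. Its only substantive assumptions are that (i) survival within a
combination is exchangeable, (ii) the Gehan–Wilcoxon effect size is a
meaningful pairwise distance between combination-level survival
distributions, and (iii) censoring is uninformative.

### Cohort preparation

Records with unknown survival time, unknown event status or an unknown
level in any requested factor are excluded, never imputed. Multi-reason
records are counted once under the first failing reason in the fixed order
time → event → factor, so the exclusion report is reproducible and
conserves counts (kept + excluded = input). Combinations with fewer than
`min_combo_size` patients (default 25) are dropped with a patient count;
the threshold is configurable since any reasonable cutoff serves the same
purpose — enough patients per combination for a stable survival sample.
Event semantics follow cause-specific survival: `event=1` means death from
the disease under study; deaths from other causes must arrive pre-coded as
censored. Combinations are ordered by level rank in scheme factor order;
that fixed order anchors every downstream tie-break.

### Gehan–Wilcoxon effect size (initial dissimilarity)

For observation s in the pooled pair of cohorts, the U-score is
U_s = #{t : s definitively outlives t} − #{t : s definitively dies before
t}, where "s definitively outlives t" iff time_s > time_t and t is an
event, or the times tie with s censored and t an event. Two events at the
same time are not definitively ordered (Gehan's original scoring). U-scores
are computed by a sorted sweep in O(m log m) — at registry scale there are
~n²/2 cohort pairs to score — with an O(m²) pair-enumeration oracle kept in
the test suite.

With W = Σ U over the first cohort and the permutation variance
Var(W) = n_a n_b ΣU² / (N(N−1)), the effect size is r = |z|/√N with
z = W/√Var(W). The √N normalization is the standard
effect-size-from-test-statistic convention; it is isolated in
`gehan_effect_size` so an alternative denominator (e.g. √(n_a n_b)) could
be swapped in one place. A degenerate pool (Var = 0, e.g. everything
censored) gets effect size 0 by convention, so structurally identical
cohorts cluster together rather than erroring. The effect size is invariant
under common time rescaling and symmetric in its arguments.

### PAM ensemble (learned dissimilarity)

"PAM" is the classical Kaufman–Rousseeuw two-phase algorithm: BUILD greedily
adds the medoid with the largest cost reduction; SWAP repeatedly applies the
single best strictly-improving medoid/non-medoid exchange until none exists
(capped at `max_swap_iters`, default 200 — never reached in practice at
desk scale). Both phases and the nearest-medoid assignment break ties by
lowest index, which makes the whole ensemble seed-free. k = 1 and k = n are
forced partitions and are filled in without running PAM. The learned
dissimilarity with uniform weights over the full k-range is the fraction of
the n partitions separating a pair; it is bounded in [1/n, (n−1)/n]
off-diagonal because k = 1 never separates and k = n always does.

The swap acceptance uses a strict-improvement threshold of 1e-12 to keep
the loop finite under floating-point ties; the swap-optimality contract in
the tests uses the same tolerance.

### Minimax linkage and the cut

Agglomeration merges, at every step, the active cluster pair whose union
has the smallest minimax radius r(G) = min_x max_y d(x,y); the merge height
is that radius and the attaining center is stored as the cluster's
prototype (a real combination summarizing the cluster). Pair ties break by
the lexicographically smallest (left, right) node-id pair in
cluster-creation order; prototype ties by lowest leaf index. Because
minimax heights need not be monotone, the g-group partition is defined by
undoing the last g−1 merges (merge-order cut) rather than by a height
threshold — this always yields exactly g groups. Cuts at successive g are
nested by construction. Newick export derives branch lengths as
parent-minus-child heights; with non-monotone heights a branch length can
be negative, which readers such as Bio.Phylo accept.

### Group ordering, C-index curve and knee

Groups are renumbered by decreasing pooled restricted mean survival time
(RMST) at `horizon` (default 60 months — the conventional 5-year summary
window); ties by Kaplan–Meier survival at the horizon, then smallest
original label. The group index then serves as the ordinal risk in
Harrell's C over all pooled patients: comparable pairs are
(time_i < time_j, i an event) or tied times with i an event and j censored;
tied risks count 0.5. With group 1 = best survival, C > 0.5 is the expected
direction.

The C-index curve is computed for g in `g_range` (default 2 … n). The
number of groups n\* is the curve's knee: the interior point with maximum
perpendicular distance to the chord joining the first and last points, ties
to the smallest g, computed on raw (g, C) coordinates. The knee is a
heuristic for a visually chosen elbow; `n_groups` overrides it with a fixed
count, and on nearly-flat curves the chord criterion can legitimately land
a point or two past the bend.

### Evaluation and serialization

Held-out patients are staged by exact combination lookup; combinations
unseen in training are strictly "unassigned" and counted (no
nearest-combination fallback — deliberately deferred, since extrapolating
assignments needs a separate validation argument). Evaluation reports
Harrell's C with a percentile-bootstrap confidence interval over
patient-level resamples (default B = 200, seeded; replicates with no
comparable pair are dropped with a logged count), per-group Kaplan–Meier
curves, and a log-rank test for every adjacent group pair with the
observed/expected hazard ratio (O_hi/E_hi)/(O_lo/E_lo) as a direction
check — O/E avoids fitting a hazards model. Adjacent tests use α = 0.05
per pair with no multiplicity adjustment, matching how such systems are
conventionally reported. Evaluating the training table reproduces the
training C-index exactly.

A fitted system serializes to versioned JSON (sorted keys, fixed
separators, shortest-round-trip floats), so identical input, configuration
and seed give byte-identical files; import reproduces assignment behavior
and stored statistics exactly. The dissimilarity matrices and raw
per-combination samples are not serialized — they are audit artifacts of
the fitting session, re-derivable from the input.

The five- and seven-variable systems are one code path parameterized by the
factor list; the AJCC TNM 9th-Version substage mapping (nine substages
I … IVB over the coarse grid of Grade Group, T, N, M and PSA category)
provides the baseline risk score. One cell of the printed staging table —
Grade Group 1, T2bc, N0, M0, PSA < 10 — is not covered by any printed row;
lenient mode (the default) assigns IIA consistent with the official
8th-Edition rule, strict mode refuses the cell.

## Synthetic cohorts

The generator emulates the *structure* of a registry extract: factor-coded
patients, per-combination survival samples, a training and a validation
replicate drawn from the same truth and distinguished by diagnosis year
(2010–2014 vs 2015). Combinations are the first q·c tuples of the factor
grid in lexicographic scheme order, assigned to the q latent strata in
contiguous blocks, so the planted truth is human-readable. Event times are
Weibull with S(t) = exp(−(λt)^shape) and stratum rate λ (shape 1 =
exponential, the default); censoring is the minimum of an administrative
horizon and an independent exponential loss-to-follow-up draw.

Reference conditions (the defaults): q = 3 strata, hazards
(0.002, 0.01, 0.05) per month — adjacent hazard ratios of 5, the kind of
separation a real staging system exhibits between distant stages — 10
combinations per stratum, 100 patients per combination per replicate, a
120-month horizon, and loss-to-follow-up rate 0.002 per month (~21%
attrition by 120 months, plausible registry loss). Under these conditions
the per-stratum event fraction has the closed form
λ/(λ+c)·(1 − e^−(λ+c)H), which the tests check against the empirical
fraction.

What the generator does **not** emulate: real factor-level marginals (the
level-to-stratum assignment is arbitrary, so the synthetic AJCC baseline is
uninformative by design), discrete-month times and their heavy ties,
informative censoring, or registry scale (3,000 patients per replicate vs
hundreds of thousands). Passing tests therefore demonstrate that the
machinery recovers planted survival structure and generalizes across
replicates — not that any particular real-data C-index is reproduced.

## Numerical and testing choices

* All tolerances on exact combinatorial quantities (U-scores, pair counts,
  PAM costs, merge heights) are 0 or 1e-10–1e-12; stochastic contracts
  (recovery in ≥ 9/10 seeds, bootstrap coverage 95% ± 3%) state their seed
  counts explicitly and run derandomized.
* Independent oracles in `tests/_oracles.py` (pure-Python pair enumeration,
  exhaustive medoid search, from-scratch minimax recomputation) validate
  each fast implementation; Kaplan–Meier goes through lifelines, and the
  log-rank and concordance implementations are additionally cross-checked
  against lifelines where conventions coincide.
* Problem sizes in the test suite and acceptance script are desk-scale
  (n ≤ 30 combinations, ≤ 3,000 patients per replicate, ≤ 10 seeds per
  contract), chosen so the full pipeline including the PAM ensemble over
  every k runs in seconds while exercising every code path at the reference
  generator conditions.

## Known limitations

* Assignment is exact lookup; validation combinations absent from training
  are unassigned rather than mapped to a neighbor.
* The knee criterion can select a group count slightly past the visual
  elbow on flat curves; fix `n_groups` when the count is known.
* PAM BUILD+SWAP is a local search; it is swap-optimal but not guaranteed
  globally optimal for every k (the ensemble averages over all k, which
  damps individual-k suboptimality).
* The minimax radius is recomputed per candidate pair per step (cached per
  pair); the implementation targets hundreds of combinations, not tens of
  thousands.
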
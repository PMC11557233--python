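# Methods

`rddmsim` simulates the maintenance of CHH methylation by RNA-directed
DNA methylation (RdDM) over successive cell cycles, and scores whether a
simulated condition maintains the starting methylation distribution.
This note records the model, its parameters, and the design decisions
behind the implementation.

## Model

**State.** 1000 unique RdDM loci (configurable), each carrying a CHH
methylation fraction `m ∈ (0, 1]` and, optionally, an RdDM-independent
CG methylation fraction on [0, 0.20]. Loci are parametrically identical;
all persistent differences between them live in their methylation.

**Cell cycle.** Each generation opens with DNA synthesis: every locus's
methylation halves (CHH and CG), and the AGO:siRNA complex pool from the
previous cycle is dissolved (see *Pool policy*). siRNA production then
follows the configured schedule, AGO:siRNA complexes search for their
targets through the rest of the cycle, matched binding converts dwell
time into methylation gain, and the generation closes pre-replication.
The recorded per-generation vectors are therefore end-of-cycle states,
directly comparable with the assigned starting vector, which is likewise
a pre-replication state.

**siRNA production.** At each production event a locus emits siRNAs
according to one of four rules evaluated at its current methylation `m`
(plus CG when CG-coupled):

* linear: `round(m · L)` with production level `L` (50–700 in sweeps);
* saturated linear: `round(min(m, s) · L)` with saturation point `s`
  (0.05 / 0.10 / 0.15 / 0.25 / 0.50);
* Hill: `round(A·x^h / (K^h + x^h))` on methylation percent `x = 100 m`
  (defaults A = 10, h = 5, K = 5);
* sigmoid: `round(A·x / (K + x))` (defaults A = 11.1, K = 6).

Rounding is half-away-from-zero, so 10% methylation at level 100 yields
exactly 10 siRNAs. The Hill and sigmoid coefficient defaults follow the
printed forms of those relationships; all coefficients are configurable
because the source expressions are typographically ambiguous.

**Schedules.** `bursty` places a single production event immediately
after replication. `steady` spreads `steady_events` (default 6) events
evenly through the cycle, each producing `1/steady_events` of the
momentary production. Because methylation is updated continuously,
steady production responds within the cycle to methylation already
gained — a positive feedback absent from bursty production. (A variant
in which each steady event emits the full production is available via
`steady_full_production`; it floods the occupancy cap and compresses
the distribution rather than driving the characteristic steady-mode
hypermethylation, so it is not the default.)

**AGO loading.** AGO is slightly limiting: 0.8 AGO per siRNA produced.
The default `proportional` loading gives each locus
`0.8 × (its unrounded production)` complexes, stochastically rounded to
an integer (expectation exactly proportional, no quantisation bias) and
capped by the integer siRNA count. The alternative `competitive` mode
implements literal pooled competition — `floor(0.8 · pool)` complexes
drawn uniformly without replacement across all siRNAs. Pooled
competition injects hypergeometric noise of CV ≈ `0.5/√k` into every
locus's complex count each generation (k = its siRNA count), which by
itself is enough to disperse the methylation distribution over ten
generations; proportional loading is the reading consistent with AGO
limitation having no influence beyond its interplay with the overall
production level.

**Pool policy.** Under the default `recycle` policy complexes do not
persist past DNA synthesis: the pool is rebuilt by the post-replication
burst, with AGO recycled through replication. Under `carryover` the
pool is halved at replication (uniformly at random), survivors count
against the next burst's AGO budget, and only the shortfall is newly
loaded. Carryover adds `Binomial(k, 1/2)` per-locus noise per
generation and is retained for comparison; it is not the default
because that noise term alone dominates the per-locus gain variance.

**Target search.** Complexes search RNA or DNA molecules by facilitated
diffusion on 1-D lattices of `molecule_length` (50) positions, with one
move per `step_interval` (1 s on RNA, 0.3 s on DNA — the ~3× faster DNA
on-rate). A free complex lands on an RdDM-locus molecule with
probability `p_on_target` (0.5 RNA, 0.1 DNA; the remainder of the
molecule population is off-target) — and an on-target landing is the
complex's own cognate locus with probability `p_self_target` (default
1: the siRNA sequence guides the complex to complementary targets).
On a non-matching molecule the complex scans: per step it dissociates
with `p_exit_scan` (0.02 per 1-s step on RNA, 0.009 per 0.3-s step on
DNA — the measured off-rates of imperfect, less-than-seed-plus-
supplementary contacts), else jumps to a fresh landing with `p_jump`
(0.10), else slides one position left or right (50/50); sliding off
either lattice end is an exit. Landing on the cognate locus the complex
binds if the locus holds fewer than `max_occupancy` (10) complexes,
drawing an exponential dwell with rate `k_off_match`; a full locus
scores an *occupancy rejection*. `k_off_match` — the off-rate of full
cognate pairing — has no direct measurement and is set internally
(0.5 s⁻¹ RNA, 0.75 s⁻¹ DNA, preserving the 2:3 RNA:DNA ratio of the
weak-contact rates and the shorter dwell at DNA targets). With these
values a searching complex spends roughly a tenth of its time bound,
the median locus logs thousands of short reinforcement events per
cycle, and the occupancy cap engages only for the most productive loci
— which is what makes the self-inhibition diagnostics visible without
destabilising the bulk of the distribution.

**Dwell → methylation.** The summed bound time of all matching
complexes at a locus (its *dwell*) is converted continuously into
methylation: each step's dwell increment adds
`0.01 · dwell / dwell_per_percent` to the locus's fraction, clipped at
1.

**Calibration (burn-in).** `dwell_per_percent` is estimated once, in
generation 1, under the assumption that the dwell a locus realises is
exactly sufficient to regain its replication loss — i.e. the median
locus (8% pre-replication, 4% post-replication) doubles its
post-replication methylation. During the burn-in, methylation is frozen
while dwell accumulates; the exchange rate is then the
regression-through-origin ratio

    dwell_per_percent = Σ dwell / (100 · Σ min(m_post, s)),

taken over loci unaffected by occupancy rejections (occupancy-limited
loci realise less dwell than their production predicts and would bias
the ratio), and the burn-in's gains are applied retrospectively from
its own dwell log. This estimator is unbiased under the model's
dwell-proportional-to-production structure and has ~1–2% sampling
error; a literal "mean dwell of median-band loci" estimator carries ~5%
error per run, which compounds into a visible scale drift over nine
further generations. The reference dwell (expected burn-in dwell of a
median locus) satisfies `reference = dwell_per_percent ×
target_gain_pp` exactly, so a locus receiving it gains exactly the
target (4 percentage points for the 8% median case). With production
off entirely (level 0) reinforcement is disabled and methylation decays
geometrically; a run that produces siRNAs but accumulates no dwell
aborts with a calibration error.

**Stability assessment.** After the final generation, the end-of-cycle
distribution is compared with the first generation's end-of-cycle
distribution by a two-sample Kolmogorov–Smirnov test; a replicate is
*stable* when p > 0.01. The p-value uses the asymptotic Kolmogorov
series with the Stephens small-sample correction at the effective
sample size — the formula used by the statistical environments this
stability rule originates from (an exact small-sample mode is
available). Comparing against generation 1 rather than the assigned
vector means both samples are states produced by the dynamics; the
assigned quantile-matched vector has a density kink at the 8% anchor
(34.4% of its mass lies in [0.08, 0.10] by construction) whose one-time
smoothing in the first cycle is a property of the synthetic starting
distribution, not of maintenance. The assigned-vector baseline remains
available (`baseline="initial"`). Conditions are scored by the count of
stable replicates out of (typically) seven.

## Initial distribution

Two samplers generate starting CHH fractions:

* `formula` — the truncated-exponential inverse transform
  `m = −log(1 − (1 − e^(−μ))·U)/μ`, `U = 1 − 0.9·Unif(0,1)`; `μ` can
  be calibrated to a target median by bracketed root search (median
  8% → μ ≈ 9.98). The family spans right-skewed to near-uniform
  shapes, but no single `μ` attains the three printed quantiles of the
  low-methylation regime jointly.
* `quantile_matched` (default) — piecewise log-linear survival
  interpolation through (support_min = 0.005, p = 0) and the anchors
  (0.08, 0.500), (0.10, 0.844), (0.15, 0.948); beyond the last anchor a
  truncated exponential tail continues the last inter-anchor decay rate
  and reaches F(1) = 1 exactly (a log-linear segment cannot, since
  log 0 diverges). Each anchor probability is reproduced exactly by the
  inverse CDF.

The generator emulates the *shape* of a low-methylation euchromatic
locus population — median 8%, 84.4% below 10%, 94.8% below 15% — not
any real methylome: there is no per-cytosine structure within a locus,
no locus-to-locus sequence homology, and no biological covariates.
Passing stability tests therefore demonstrate maintenance of a
realistic marginal distribution under the model's kinetics, nothing
about genomic context.

## Numerical and implementation notes

* The per-step search loop is compiled with numba; scanning events are
  sampled from a single uniform with nested thresholds (exit, else
  jump, else slide direction), distributionally identical to sequential
  Bernoulli draws. Within a step the order is: dwell credit and
  releases, then searching in complex-index order (a complex freed this
  step searches from the next step; a jump lands within the same step);
  binds respect the occupancy cap in processing order.
* All randomness flows from one `numpy` Generator per simulation,
  seeded per replicate (`base_seed + 1000·condition + replicate`); the
  compiled kernel is seeded from that stream per call. Identical seeds
  give bit-identical trajectories, and sweep results are independent of
  condition execution order.
* Dwell times are real-valued; bound time is credited in step-sized
  increments capped by the remaining dwell, so total credited dwell
  equals the drawn dwell (truncated at cycle end).
* Default `cycle_duration` is 3600 s. The calibration normalises the
  dwell-to-methylation exchange to the realised search statistics, so
  mean maintenance is invariant to the cycle length; per-locus
  *dispersion* is not — reinforcement noise scales as 1/√(events per
  cycle) — so longer cycles are strictly more stable and results at
  3600 s are conservative relative to a 24 h cycle. Test and
  diagnostic runs use 600–1000 loci and 900–3600 s cycles; the
  stability checks at published conditions use the full 1000 loci,
  10 generations and 7 replicates.

## Known limitations

* Loci are exchangeable, so no locus has its own stable fixed point:
  per-locus maintenance is neutral (expected gain equals expected
  loss), and distribution shape is preserved only for as long as
  accumulated per-locus noise remains below the KS detection threshold.
  Stability over 10 generations at n = 1000 is exactly what is scored,
  and is the regime where production levels ≥ ~300 with saturation
  ≥ 15% succeed.
* The cognate-guidance probability and the matched off-rate are
  internally set model parameters, not measured constants; their
  defaults were chosen once, from the bound-fraction and occupancy
  reasoning above, and all qualitative conclusions (bursty > steady,
  linear > Hill/sigmoid, saturation ≥ 15%, RNA ≈ DNA with higher DNA
  production requirements, self-inhibition at high production) are
  robust to moderate changes.
* CG methylation, when enabled, is a static uniform [0, 20%] draw that
  only halves and doubles; coupling production to CHH+CG intentionally
  reproduces the unrealistic distribution collapse of that scenario.
* No sublocus sites, no siRNA sequence space, no homologous loci, no
  intercellular siRNA movement, and no survival of bound complexes
  through replication.
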
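# Methods

`brainmass` implements a personalized whole-brain modeling workflow: coupled
excitatory/inhibitory (E/I) neural-mass dynamics on a structural connectome,
per-region inhibition tuned to a firing-rate target, a hemodynamic forward
model to BOLD, a global-coupling fit against functional connectivity, and the
downstream graph-theoretic and statistical analyses. This note documents the
model, the numerical choices, the synthetic-data generator, and what the
package's tests do and do not establish.

## Dynamic mean-field model

Each region `i` hosts an excitatory (NMDA) and an inhibitory (GABA)
population described by synaptic gating variables `S_E, S_I ∈ [0, 1]`:

```
I_E,i = W_E·I_0 + w+·J_NMDA·S_E,i + G·J_NMDA·Σ_j C_ij·S_E,j − J_i·S_I,i
I_I,i = W_I·I_0 + J_NMDA·S_E,i − S_I,i
r_E   = φ_E(I_E),  r_I = φ_I(I_I),   φ(I) = (aI − b) / (1 − exp(−d(aI − b)))
dS_E/dt = −S_E/τ_E + (1 − S_E)·γ·r_E + σ·η(t)
dS_I/dt = −S_I/τ_I + r_I + σ·η(t)
```

`C` is the subject's normalized structural connectome (weights in [0, 1]),
`G` the only globally fitted parameter, and `J_i` (nA) the local
inhibitory-to-excitatory weight set by feedback inhibition control (FIC).
Constants are the standard published values of this model family
(`a_E = 310 nC⁻¹, b_E = 125 Hz, d_E = 0.16 s; a_I = 615, b_I = 177,
d_I = 0.087; τ_E = 100 ms, τ_I = 10 ms, γ = 0.641, J_NMDA = 0.15 nA,
w+ = 1.4, W_E = 1, W_I = 0.7, I_0 = 0.382 nA, σ = 0.01 nA`). They are
documented defaults, not fitted quantities; all are configurable on
`RwwParameters`.

Integration is Euler–Maruyama in millisecond units with additive noise
`σ·√dt·N(0,1)` on both gating equations and hard clamping of the gating to
[0, 1]. The default step is `dt = 0.1 ms`; the package's own studies use
`dt = 1 ms`, which changes stationary mean rates by < 5 % (checked against a
half-step refinement) at a tenth of the cost. No conduction delays are
modeled — coupling is instantaneous, and tract lengths are carried only for
I/O completeness. Trajectories are bit-reproducible given the integer seed.

## Feedback inhibition control

FIC raises each `J_i` until the excitatory population's time-averaged firing
rate sits at the target of 3 Hz — the intrinsic rate of an isolated
population — with tolerance 0.25 Hz. The controller evaluates mean rates on
a frozen-noise window (same seed every iteration, so the loop is
deterministic) and applies a proportional update
`J_i ← max(J_min, J_i + m_i·η·(r̄_i − target))` with `η = 0.005 nA/Hz`,
`J_min = 0.1 nA`, and a per-region adaptive multiplier `m_i` (×1.3 while the
error sign persists, halved on a flip, steps capped at 0.2 nA). Two
safeguards address collective effects near the critical coupling, where all
regions move together:

- **Backtracking** — if a proposed update increases the window RMS rate
  error, the global step is shrunk (×0.25, up to four times).
- **Stall detection** — if the RMS error fails to improve by 2 % for eight
  consecutive iterations, tuning aborts with a non-convergence error rather
  than burning the iteration budget.

The plain proportional rule alone stalls near the fixed point (the rate
becomes insensitive to `J`; measured error decay was ~1 %/iteration), which
motivated the adaptive gain.

The **tuning window is 30 s** after a 2-s burn-in. This length is set by
estimator noise: a 10-s window estimates stationary rates to only ~0.1 Hz,
so `J` tuned to 0.25 Hz on such a window misses that tolerance on an
independent run for ~15 % of regions; 30 s brings independent-run agreement
to ≥ 95 % of regions. Screening sweeps use shorter windows (8–10 s) where
only the rough magnitude of `J` matters.

**Criticality.** The rate clamp is only well-posed below a
connectome-dependent critical coupling: beyond it the network's
window-averaged rates fluctuate more than any tolerance, and no `J` vector
satisfies the clamp. For the default synthetic connectomes (mean in-strength
≈ 1.3) this boundary sits near `G ≈ 1.4–1.9`, varying with the realization.
`g_sweep` records such grid points as NaN and skips them;
`tune_fic_feasible` walks `G` up with warm-started `J` and returns the
largest simulable coupling, which the cohort generator uses to cap each
subject's generative coupling. Cold starts at moderate `G` use the same
continuation internally (0.25-wide stages from `G = 0.5`), since jumping
straight into a strongly coupled regime from `J = 1` can land in the
collectively unstable basin.

## Hemodynamics

The Balloon–Windkessel cascade converts the excitatory gating `S_E` (the
drive convention of this model family; switchable to rates) into BOLD:
vasodilatory signal, inflow, venous volume, and deoxyhemoglobin, with the
standard constants `κ = 0.65 s⁻¹, γ_f = 0.41 s⁻¹, τ_h = 0.98 s, α = 0.32,
ρ = 0.34, V_0 = 0.02, k1 = 7ρ, k2 = 2, k3 = 2ρ − 0.2`. Integration is
deterministic RK4 at the neural recording step (1 ms); the resting state is
an exact fixed point, so zero drive yields exactly zero BOLD (verified to
machine precision, and a pulse response agrees with an adaptive reference
solver to < 1 %). States are initialized at the steady state of the initial
drive value: starting from the zero-drive rest point instead would superpose
a large onset transient — identical across regions — on every BOLD series,
which spuriously correlates even fully decoupled regions (z ≈ 0.6 at G = 0
in a 107-s run). BOLD is sampled every TR (floor(duration/TR) volumes), and
FC is the Fisher-z Pearson correlation of the regional series, with
correlations clipped at ±(1 − 1e−7) so degenerate toy inputs stay finite.

## Coupling fit

`g_sweep` scans `G` (default grid 0.01 to 3 in steps of 0.015; the package's
desk-scale studies use 0.05–1.85 in steps of 0.15, covering the simulable
regime), re-tunes FIC at every point (warm-starting `J` from the previous
point), simulates BOLD with the empirical duration and TR, and scores the
link-wise Pearson correlation between simulated and target FC upper
triangles (both Fisher-z). `G*` is the argmax; ties resolve to the smallest
`G`. Per-point seeds derive deterministically from (base seed, point index).
Only `G` is fitted to FC — the sole target of `J_i` is the firing rate.

**Identifiability.** The link-wise Pearson criterion identifies `G` well
only near the critical coupling. Deep in the subcritical regime the
simulated FC pattern is nearly `G`-independent — raising `G` mostly rescales
its amplitude, which *increases* the correlation with any structured target —
so the fit curve rises monotonically and the argmax overshoots toward
criticality (measured: only 5/10 recoveries within two grid steps when
`G_true` is drawn uniformly over the subcritical range). Near the critical
point the FC structure changes sharply with `G` and the curve peaks. The
recovery study therefore places `G_true` at each connectome's *operating
point* — two grid steps below the largest simulable coupling, emulating
where fitted optima concentrate — and recovers it within two grid steps in
≥ 8/10 replicates (92-s runs, 68 regions).

## Synthetic cohort

The generator emulates the study design of a brain-tumor modeling cohort
(controls / meningioma-like / glioma-like, default counts 11/14/11):

- **Connectomes** — planted-partition graphs (4 modules, within:between edge
  odds 4:1) at density 0.30 over 68 regions; weights lognormal(μ = −2,
  σ = 1) scaled by √(size_i·size_j) so strength tracks region size, then
  max-normalized into [0, 1]. Region sizes are lognormal(log 1500, 0.4)
  voxels. Tract lengths come from a random 3-D embedding and are unused by
  the dynamics.
- **Lesions** — a focal node set (1 + Poisson(1) nodes from one module) with
  incident edge weights multiplied by a per-patient severity factor
  (U(0.4, 1.0) meningioma-like, U(0.1, 0.8) glioma-like) and region sizes
  inflated by U(1.1, 2.5). The wide severity spread mirrors the
  two-orders-of-magnitude range of real lesion volumes and is what makes
  tumor-region summaries more *variable*, not just lower.
- **Couplings** — each subject's generative `G_true` is drawn U(0.6, 1.6)
  and capped at the connectome's feasible coupling. The upper end of this
  range corresponds to the strongly structured, near-critical operating
  regime where fitted models of real subjects sit.
- **Covariates** — age, sex, motivation (1/MOT latency), emotional distress,
  lesion volume (0 for controls), handedness, TR flag (≈ 11/36 subjects at
  2.1 s, the rest 2.4 s), head motion, and a DWI intensity-normalization
  factor, from plain parametric laws. They exist to exercise the
  residualization machinery, not to encode real effect sizes.

What the generator does **not** emulate: the hub-concentrated, spatially
embedded weight organization of real tractography (see Limitations),
measurement noise on BOLD, subject-level hemodynamic variability, and any
true association between covariates and dynamics.

## Statistics

Because the `J_i` distribution is skewed, per-subject summaries are medians:
whole-brain, tumor-node, and non-tumor-node (for controls the non-tumor
median *is* the whole-brain median). Region size confounds `J` (larger
regions carry more connections, hence need more inhibition), so analyses of
`J` first regress size out; the regression can pool all regions in one fit
(default) or fit within subject (`subject_ids=`), which additionally removes
subject-level scale offsets such as different fitted couplings — the
lesion-contrast study uses the within-subject form for exactly that reason.
Outcomes are residualized on covariate main effects and expressed as
z-scores against the control-group residual mean/SD. Group comparisons use
one-way ANOVA (with Tukey post-hoc) or Kruskal–Wallis, gated by a per-group
Shapiro–Wilk check at α = 0.05 in `auto` mode, plus Levene's test for
variance equality; associations are OLS with classical
η² = SS_predictor/SS_total (the extra sum of squares over the
covariate-only model). Tests are two-sided at α = 0.05 with no
multiple-testing correction. The ANOVA's empirical type-I rate is verified
against the nominal level on 500 null simulations.

## Graph metrics

Weighted metrics on the thresholded, normalized connectome (the matrix that
enters the model): global efficiency (mean inverse shortest-path length with
1/weight edge lengths, Dijkstra, cross-checked against a Floyd–Warshall
oracle), modularity via best-of-100 seeded Louvain runs (γ = 1) with a
partition-stability score (mean co-classification agreement of each node's
best-partition module mates across runs, in percent), and the weighted
participation coefficient `P_i = 1 − Σ_m (k_im/k_i)²` on the same
decomposition. A candidate panel (strength, degree, density, betweenness,
clustering, …) feeds the de-correlation step: greedily drop metrics until
all pairwise |r| < 0.80, then report the first two principal-component
loadings of the retained set.

## Numerical conventions and degenerate inputs

Correlation clipping at ±(1 − 1e−7) bounds |z| by ~8.4; constant BOLD series
raise a degenerate-series error naming the region; thresholding that
disconnects the network raises rather than returning a fragmented substrate;
the connectivity check is reachability on the binary graph of nonzero
weights; zero-variance FC vectors are rejected by the fit criterion;
isolated nodes get participation 0; a node alone in its module counts as
fully stable; all sweep/cohort seeds are derived below 2³¹ from a single
base seed.

## Study problem sizes

The package's system studies run at sizes chosen for a single CPU: FIC
verification at 68 regions with a fresh 60-s run; TR-swap at 5 subjects with
~390-s full runs at the assigned operating coupling; coupling recovery at 10
replicates of 68 regions with 92-s runs; the lesion contrast at 10 cohorts
of 34 regions with 8-s tuning windows. `dt = 1 ms` throughout.

## Known limitations

- Synthetic connectomes are statistically exchangeable block models; they
  lack the hub-dominated, spatially organized weight concentration of real
  tractography. Their simulated FC therefore carries a much weaker
  deterministic structure (Fisher-z spread ~0.1–0.2, vs the ~0.4–0.5 implied
  by the near-unity run-to-run reproducibility of fitted empirical models),
  so FC correlations between two independent full-length runs at the
  operating coupling average only ~0.45 (range ~0.34–0.64 across subjects).
  The TR-swap study reports
  whatever the pipeline actually produces; closing this gap would require a
  generator with realistic hub/weight concentration, at the cost of pushing
  the critical coupling below the G = 1 clamp condition the firing-rate
  study exercises.
- Above the critical coupling the rate clamp is infeasible by construction;
  sweeps skip those points, so fit curves are truncated where a real-data
  study might still report (poorly clamped) fits.
- The lesion model rescales incident weights multiplicatively; it does not
  grow tumors, displace geometry, or alter the hemodynamics of affected
  tissue.
- Covariates are independent of the dynamics, so covariate-adjusted
  associations in synthetic cohorts test machinery, not biology.
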
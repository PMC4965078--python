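# Methods

## The model

A gene's promoter toggles between a transcriptionally silent and an active
state:

    OFF --k_on--> ON,   ON --k_off--> OFF,
    ON --T--> ON + mRNA,   mRNA --d_m--> 0,
    mRNA --L--> mRNA + protein,   protein --d_p--> 0.

All rates are per mRNA lifetime (`d_m = 1` by convention): the data this
package emulates — per-cell mRNA counts and calibrated fluorescence — carry
no absolute clock, only rate ratios, so absolute time units would be
spurious precision.

In the bursting regime (`k_off >> k_on`, `k_off >~ d_m`) the promoter fires
short transcriptional bursts of geometric mean size `b = T/k_off` at rate
`k_on` (the burst frequency). Two stationary moment results organize
everything downstream:

* mRNA: `<m> = T k_on / (d_m (k_on + k_off))` and
  `Fano = 1 + T k_off / ((k_on + k_off)(k_on + k_off + d_m))`, which tends
  to `1 + b` in the bursting limit. `CV² × <m>` *is* the Fano factor, so
  the count-based burst-size readout is the Fano factor of the counts.
* protein: `CV² = C (1 + b) / <p>` with `C = L/(d_m + d_p)` — a hyperbola
  in the noise-versus-mean plane. Holding `b` fixed and varying `k_on`
  slides a clone along the curve; changing `b` moves it across curves.
  This form drops the Poisson shot-noise terms and is accurate when
  translation amplifies bursts (`C >> 1`) and the promoter is bursty.

Burst sizes from fluorescence use the calibration
`B = CV² × <MESF> / 5000 − 1`; 5,000 MESF per burst unit and the −1 offset
are fixed constants of that calibration, taken as given. Because Eq.-2
count burst sizes equal `Fano ≈ 1 + b` while the kinetic burst size is
`b = T/k_off`, estimates carry both the raw value `B` and
`b_geom = max(B − 1, 0)`; the two conventions are never silently mixed.

## Simulation and oracles

`simulate_ssa` is an exact Gillespie realization (pure Python, for
inspection); `sample_steady_state` draws independent per-cell end states
after a burn-in of 10× the slowest relaxation timescale
(`1/d_m`, `1/d_p` when protein is simulated, `1/(k_on+k_off)`), with the
inner loop compiled by numba. Per-cell streams come from
`numpy.random.SeedSequence(seed)`, so cell *i*'s draw is independent of how
many cells are requested — runs are reproducible and prefix-stable.

Two independent oracles check the sampler:

* `stationary_distribution` solves the truncated chemical master equation
  on `(promoter state) × (mRNA 0..N)` with scipy's sparse solver. The
  truncation starts at `mean + 10 √variance` (closed form) and doubles
  until the mass in the top states is below tolerance.
* `sample_mrna_exact` draws from the exact stationary law, a Poisson
  mixture over beta-distributed promoter activity:
  `m ~ Poisson((T/d_m) q)`, `q ~ Beta(k_on/d_m, k_off/d_m)`.

SSA, CME and Poisson-beta are cross-checked against each other and against
the closed-form moments in the test suite; the empirical
total-variation check is calibrated against the null distribution of the
TV statistic computed from the oracle itself (a perfect sampler's
empirical TV is not zero).

## The synthetic clone panel

Each clone stands in for a distinct genomic integration site. Defaults:
30 clones; burst size log-uniform on 2–12 and burst frequency log-uniform
on 0.05–2 per mRNA lifetime; 150 cells per clone for count tables (the
emulated experiments image >100 cells per condition); 50,000 flow events
per clone of which ~3,000 survive gating. Rates follow
`k_off = 20 d_m max(1, b/2)`, `T = b k_off`, `k_on = f d_m`, which keeps
every clone in the bursting regime across the size range (a log warning
fires if `k_off ≤ 10 k_on`).

Burst size and frequency are paired comonotonically by default
(`correlate_size_with_mean=True`): dim clones burst small, bright clones
burst big, as the empirical panels do. This is what makes extreme
manifolds fitted to the dimmest and brightest clones bracket the panel;
set it False for independent draws.

Count tables are drawn from the exact Poisson-beta stationary law by
default (`mrna_sampler="ssa"` switches to burn-in SSA; the two agree by
construction and by test). Flow fluorescence is built from the analytic
protein moments: per-event protein is gamma-distributed with the exact
mean `<m> L/d_p` and the hyperbola CV²; fluorescence is
`protein × mesf_per_protein × E + background`, with `E` a unit-mean
log-normal extrinsic factor (CV 0.3 by default) shared with the scatter
channels (times channel noise, CV 0.05), and the background additive
Gaussian (200 ± 50 MESF) clipped at zero. A gamma law is used rather than
per-event protein SSA because a default experiment needs ~3×10⁶ protein
events per run; the gamma family is the stationary shape of bursty protein
expression and is moment-matched exactly to the model being emulated.

Protein-stage defaults are `d_p = 0.05 d_m` and `L = 5250`: fluorescent
reporters are roughly twenty-fold more stable than their transcript, and
`C = L/(d_m+d_p) = 5000` makes one burst unit equal the 5,000-MESF
calibration at `mesf_per_protein = 1`, so fluorescence burst sizes recover
`b` by construction.

The TNFα-like perturbation multiplies every clone's `k_on` by
`freq_fold_change` (default 5); clones whose baseline mean exceeds
`size_threshold_mean` (default 10 mRNA) also multiply `T` by
`size_fold_change` (default 2) — the expression-level threshold above
which burst size, not frequency, responds.

What the generator does *not* emulate: imaging/spot-calling noise in the
counts, cell-cycle gene dosage, reporter maturation delay, multi-state
promoters, or any mechanistic coupling between integration site and
kinetics. Passing tests therefore demonstrate that the estimators and the
manifold analysis behave correctly on data whose ground truth is the
telegraph model itself — not that real panels obey the model.

## Noise statistics and gating

Variance is always the unbiased (n−1) estimator; populations of a few
hundred cells make the estimator choice visible. `CV² = var/mean²`,
`Fano = var/mean`; populations with fewer than two cells or zero mean are
rejected rather than silently propagated.

Sub-gating keeps the `target_n` events (default 3,000 of 50,000) nearest
the mode of the log-scatter density, located on a 64×64 histogram. The
distance is Mahalanobis with a **diagonal** covariance (per-channel
scales): the full sample covariance is dominated by the shared extrinsic
factor, so a full-covariance metric stretches the gate ellipse along
exactly the direction the gate exists to clamp — measured on the default
panel it leaves ~20× more residual extrinsic variance and biases bright
clones' CV² upward by ~13%. Ties are broken by input order, making the
gate deterministic.

Autofluorescence correction subtracts the background mean *and* variance
(the background's width dominates dim clones' CV²); a negative corrected
variance is floored at 1e-12 and flagged. The correction applies after
gating, since the background is per-event and survives the scatter gate;
both orders are available through the API.

## Manifold analysis

Extreme manifolds pass exactly through the dimmest and the brightest
clone's (mean, CV²) point — a one-parameter hyperbola through one point is
the minimal reading of "fit to the dimmest/brightest clone". The log-log
noise-mean slope uses ordinary least squares on (log mean, log CV²);
points on one exact manifold give slope −1 to machine precision.

Perturbation scoring on matched clone panels reports:

* `contraction_fraction` — clones whose mean rose while CV² fell;
* `containment_fraction` — share of points (both conditions) with burst
  size inside `[B_min(1−tol), B_max(1+tol)]`, `tol = 0.15`. The band has
  finite width because the constant-B curves are the bursting-limit
  idealization: at finite `k_off` a pure `k_on` fold-change of 5–10 drifts
  the Fano factor by up to ~12%, and moment estimates at a few thousand
  cells fluctuate comparably;
* exclusion counts — points beyond the extremes by more than a 1.5×
  margin, operationalizing the empty upper-right / lower-left regions of
  the noise-mean plane;
* a modulation class per clone: `frequency` if `|ΔB|/B ≤ 0.25`, `size` if
  larger with the mean rising, `mixed` otherwise. The 0.25 threshold (and
  the band width and margin) are configurable; defaults are reported in
  every result.

## Numerical choices and problem sizes

CME truncation caps at 10⁵ states and errors rather than looping; manifold
assignment rounds half-up and clamps to the 0–12 grid with a flag; CSV
floats are written with 9 significant digits for reproducible diffs. The
test suite and `scripts/acceptance.py` run panels of 30 clones at 1,000 or
3,000 cells per clone for count statistics, 50,000 events per clone for
gating, 10,000 SSA cells per grid point for oracle comparisons, and 600
protein-stage SSA cells per parameter set — sizes at which every check
completes in seconds while the Monte-Carlo error sits well inside each
check's tolerance (the one exception, the 10%/27-of-30 recovery check, is
analyzed below).

## Known limitations

* Near-silent clones (`f ≈ 0.05`, mean 0.1–0.6 mRNA) have zero-inflated,
  heavy-tailed count distributions; the Fano/Eq.-2 burst-size estimator's
  sampling SD is ~9% even at 3,000 cells. A fixed 10% recovery band then
  excludes ≈3–4 of 30 clones on a typical panel — an estimator-noise
  floor, not a bias; the recovery test documents this regime honestly
  rather than hiding it.
* Moment-based inference only: no likelihood fits of `(k_on, k_off, T)`
  from count histograms.
* The MESF-unit burst size recovers `b` only when the fluorescence scale
  matches the 5,000-MESF calibration (`mesf_per_protein × C = 5000`);
  mis-scaled inputs shift every burst size, which the scale-dependence
  test documents.
* FCS binary files are out of scope; flow data move as CSV.
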
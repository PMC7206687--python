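# Methods

## The model

Untreated tumor volume follows the Gompertz law

    V(t) = V0 · exp((α/β) · (1 − e^(−βt)))

with intrinsic growth rate α (day⁻¹) and deceleration factor β (day⁻¹);
the plateau is V0·exp(α/β). Electrochemical therapy (EChT) — low-level
direct current i (mA) delivered through needle electrode arrays — is
modelled by replacing α with a time-dependent modified rate

    α*(t) = [a₁(1 − e^(−γt)) + a₂] α,   a₁ = r(2 − r),  a₂ = 1 − r,  r = i/i₀,

where i₀ (mA) is the polarization current the tumor induces against the
applied field and γ (day⁻¹) is the first-order decay rate of the net
treatment effect after the current is switched off. α*(t) is substituted
pointwise into the closed form above (the modified Gompertz equation, MGE);
we deliberately do not re-derive a time-varying-rate ODE, because the
closed form with the substituted rate is the fitting function as used in
this literature. For i = 0 the MGE reduces algebraically to the Gompertz
law; the asymptotic volume V0·exp((1 + r − r²)α/β) crosses V0 at
r = (1+√5)/2 ≈ 1.618, above which the model predicts net regression.
Exposure time and electrode-array geometry (C-I collinear needles, C-II /
C-III electrode pairs) never appear explicitly: their influence is carried
by i₀ and γ, so the package keeps geometry only as a metadata tag.

Derived quantities: the closed-form doubling time
−(1/β)·ln(1 − β·ln2/α) (infinite when α ≤ β·ln2, i.e. the plateau never
reaches 2V0), and the Steel relation DT = T_c·ln2/[(1−φ)·ln(1+GF)] linking
doubling time to cell-cycle time, cell-loss factor and growth fraction.

## Two-stage fitting protocol

Each animal is fitted individually, in two windows re-zeroed to t = 0:

* **TGK₁** (days 18–31): unperturbed Gompertz, free (α, β), V0 fixed to
  the observed day-18 volume.
* **TGK₂** (days 31–49): MGE with (α, β) frozen to the same animal's
  TGK₁ estimates and the applied current given; free (i₀, γ), V0 fixed to
  the observed day-31 volume.

Control animals additionally get a full-range (18–49) Gompertz fit.
V0 is fixed rather than fitted so that every stage satisfies V(0) = V0
exactly, the window's stated initial condition.

Numerics. Both stages minimise the volume-residual sum of squares with
Levenberg–Marquardt on log-transformed parameters (positivity without hard
constraints; estimates are afterwards projected onto α, β ∈ (10⁻⁶, 5],
i₀ ∈ (10⁻³, 100], γ ∈ (10⁻³, 200], boxes beyond which the cost is flat on
a twice-weekly schedule). Analytic Jacobians are used throughout. After LM
converges we polish with undamped Gauss–Newton steps to the stationary
point of the normal equations: the (α, β) cost valley is so flat that
cost-based stopping alone leaves the estimate anywhere within ~10⁻¹⁰ of
the optimum, which matters for leave-one-out statistics (below). Five
jittered restarts are attempted if a solve fails; a near-constant series is
flagged degenerate (α̂ = 0) instead of fitted.

Initial values: α₀ from the log-volume slope of the first three points,
β₀ = 0.02, γ₀ = 10 day⁻¹; i₀ is initialised by a one-dimensional profile
fit with γ frozen at γ₀, starting from i/1.3 (the centre of observed
ratios). The profiling step matters: (i₀, γ) sit on an identifiability
ridge — γ → ∞ at ratio r and γ → 0 at ratio 1 − (1 + r − r²) produce the
same constant effective rate — and a naive joint start can slide to the
wrong branch even on noiseless data. Profiling selects the branch on which
the treatment effect saturates (the interpretation under which the i₀
tables of this assay are read); the near-flatness of γ then shows up
honestly as a large standard error. Parameter standard errors are
e_θ = √diag(s²(JᵀJ)⁻¹) with s² = SSE/(n₁−k) and J the natural-parameter
Jacobian at the optimum; the covariance uses a pseudo-inverse so weakly
identified directions report wide, not broken, errors.

## Fit assessment

Per fitted window with n₁ points and k = 2 free parameters: SSE,
SE = √(SSE/(n₁−k)), r² with total sum of squares about the mean,
r_a² = [(n₁−1)r² − k + 1]/(n₁−k) (a fit is called satisfactory above
0.98), RMSE and Dmax of the residuals. PRESS refits the stage with one
point deleted and scores the prediction at the deleted point; the default
("printed") form sums the first n₁−1 deletions and divides by n₁−k, with a
`standard` mode giving the conventional unnormalised full sum. When the
origin point is deleted, V0 stays anchored at its observed value — V0 is
the window's initial condition, not a fitted datum. MPRESS(m) fits the
first m points (m = 3 reported by default) and scores the forecast of the
remaining n₁−m. Leave-one-out and first-m refits use deterministic
cold starts: noisy windows can hold adjacent shallow optima, and a
statistic that depends on where a warm start happened to settle is not
reproducible at the 10⁻¹⁰ level our oracle tests require (warm starts
remain available as an option). Treated-vs-control group curves on a
common daily grid of M days are compared with Dmax = max|Fᵢ − Gᵢ| and
RMSE = √(Σ(Fᵢ−Gᵢ)²/M).

Interpolation onto the daily grid uses monotone shape-preserving
piecewise-cubic Hermite polynomials (PCHIP, Fritsch–Carlson derivatives):
the interpolant passes through every observation, cannot overshoot between
monotone neighbours and therefore cannot produce negative volumes. A 1-day
grid matches the day⁻¹ units of all rates. No extrapolation, and animals
that die mid-study contribute to group means only on days they were
observed.

## Synthetic cohorts

The study's raw data are confidential, so a generator reproduces the
design: 8 arms (2 controls, 6 treated at 2/6/10 mA for 10/20 min with
geometries C-I/C-II/C-III) × 2 genders × 10 mice = 160 animals; treatment
at day 31 when tumors are near 0.5 cm³; twice-weekly caliper measurements
on days {18, 21, 25, 28, 31, 32, 35, 38, 42, 45, 49} (n₁ = 11; the day-32
point is the first post-treatment check and gives the γ transient
measurable support); follow-up to day 49.

Per animal, (α, β) are drawn from truncated normals around gender-specific
means (females 0.490, males 0.422 day⁻¹; β around 0.045 day⁻¹), and for
treated arms (i₀, γ) around the arm-specific scales of the assay
(i₀ ≈ 1.4–7.1 mA, γ ≈ 4.5–50 day⁻¹). The true curve is anchored at the
first measurement day — the drawn α is the growth rate at the window
origin the fits estimate — with V0 back-solved so the true day-31 volume
hits a lognormal target around 0.5 cm³. Controls follow one continuous
Gompertz curve; treated animals switch at day 31 to the MGE re-anchored
there with the time clock re-zeroed, which is exactly the model family the
two-stage protocol fits, so noiseless cohorts are an end-to-end
parameter-recovery oracle. Latency (truncated normal per arm, ~11–15 days,
floored at 5 and capped at 17) is recorded as palpability metadata.

Observation model: observed volume = true volume × unit-mean lognormal
factor with CV 5%. The 5% default is back-computed from the assay's
reported control-window SE/RMSE (≈0.02–0.06 cm³ at volumes up to ~2 cm³,
i.e. a multiplicative scatter of roughly 2–7%). Caliper diameters (major a,
minor b, mm) are back-solved from each noisy volume through V = πab²/6
with a uniform aspect ratio a/b ∈ [1, 2], so recorded diameters and
volumes are exactly consistent. Fates: two constant death hazards —
0.00902 day⁻¹ before treatment (≈24.4% cumulative by day 31) and
0.00804 day⁻¹ afterwards (≈13.5% over days 31–49) — plus deterministic
ethics censoring at the first scheduled observation ≥ 2 cm³ (the crossing
observation is recorded, none later).

What the generator does not emulate: irregular tumor borders above
1.5 cm³ (the assay reports inflated scatter there), physiological
ulceration and fibrosis, metastasis biology behind the death hazards,
body-weight trajectories, and deep treatment regressions — with the
arm-level γ values (≥ 4.5 day⁻¹) the MGE transient decays within a day, so
synthetic treated tumors show slowed growth rather than the 30–77%
regressions the assay reports; this is a property of the model at those
parameters, and no test or reported number pins synthetic regression
percentages to the assay's. Passing tests therefore demonstrate correctness
of the fitting/diagnostic machinery under the study's design and noise
scale, not biological fidelity of every endpoint.

## Eligibility and reporting

Mirroring the study's bookkeeping: observations at or above the 2 cm³
ethics limit are excluded from fitting; each stage needs ≥ 4 remaining
points including the window origin; stage 2 requires a converged stage 1
and positive current (controls are never stage-2 fitted). An optional cap
subsamples eligible animals to a fixed number per group–gender arm (the
study fitted 5 per gender). Group summaries report mean ± SEM
(sd/√N), with the group current ratio aggregated either as i divided by
the mean i₀ (the table convention, default) or as the mean of individual
ratios — the two differ and both are available.

Endpoints per animal: regression percent 100·|V_min − V0|/V0 from the
interpolated post-treatment curve (magnitude when the tumor shrinks, 0
otherwise, signed raw value retained; V_min from the interpolated curve by
default to damp single-measurement noise, with a raw-point mode);
doubling time as the first day the (interpolated) curve reaches 2V0,
linearly refined between grid days, with an infinite sentinel when never
reached; response class with configurable thresholds — CR below a
0.01 cm³ detection limit, PR at ≥ 50% regression, PD at final volume
≥ 2V0 without ≥ 25% regression, SD otherwise (the assay cites but does not
define its criteria; these are standard preclinical conventions). Per
group: overall effectiveness 100·(PR+CR)/N and growth delay as the ratio
of treated to control mean doubling times (C-I arms against the C-I
control, others against the C-II control). The assay's printed growth
delays are not reproducible from its own printed doubling-time means via
the stated ratio — the stated formula is what we implement, and nothing is
asserted against those cells. Its attrition chain is likewise internally
inconsistent (160 − 39 = 121 alive at treatment, yet 19/141 and 122/160
are printed); the accounting helper accepts explicit denominators so the
printed percentages can be reproduced as printed.

## Problem sizes and determinism

All randomness flows through one seeded `numpy` generator; identical seeds
give byte-identical cohort CSVs and report bundles. The shipped test suite
simulates full 160-animal cohorts (hundreds of replicates for the
mortality calibration), runs 200-replicate recovery studies at 5% noise
and checks PRESS/MPRESS against brute-force refit loops on 50 series;
`scripts/acceptance.py` repeats those computations from scratch at three
cohort replicates for the fit-quality regime. These sizes keep a full run
in tens of seconds on one CPU while leaving Monte-Carlo error well inside
every asserted margin.

## Known limitations

γ is structurally unidentifiable above a few day⁻¹ on a twice-weekly
schedule (only the day-32 point sees the transient); estimates are
reported with their honest wide errors and capped at 200 day⁻¹. The
per-point lognormal noise is independent across days, while real caliper
series show serially correlated irregularity. Survival analysis and
between-group hypothesis testing are out of scope.
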
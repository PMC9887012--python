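# Methods

`reefshield` models the chain from coral reef ecology to coastal wave
hazard: coral assemblage structure → hydraulic roughness → nearshore wave
transformation → run-up statistics. This note records the models, the
parameters that matter, the synthetic-data assumptions, the numerical
choices, and the limits of what the test suite demonstrates.

## Reef construction and structural complexity

A reef cross-section is represented as a substrate strip (default 160 m
along-slope × 1 m across, following the fore-reef transect from 20 m depth
to the crest) populated colony by colony. For each taxon a mesh is drawn
from a shape bank, resized by resampling the survey's (width, length,
height) distribution, rotated uniformly in [−π/2, π/2], and placed
uniformly at random with its footprint inside the strip, until the taxon's
**summed planar area** first reaches its target cover. We use summed-area
stopping (each colony's own rasterized footprint counts, overlaps and all)
rather than union-of-footprints counting: the survey cover that drives the
procedure is itself a sum of colony planar areas, and the stated stopping
rule (add colonies until the summed planar area matches cover) only
closes under that convention. Cover targets are validated to sum to
≤ 1, so no >100% artefact can arise; at high densities the union of
footprints falls slightly below nominal cover, which mimics real colony
crowding.

The composite surface is a rasterized height field — pointwise maximum of
substrate and colony surfaces at 1 cm cells — and structural complexity is
its **rumple index**: 3D surface area (two triangles per cell) divided by
planar area. Rumple of a flat plane is exactly 1, of a 45° plane √2, and
of a hemispherical colony mesh 2, which anchor the implementation against
closed forms.

Colony shape families are parametric height-field proxies, not
photogrammetry: a ridged, steep-rimmed plate for tabular *Acropora*, a
strongly corrugated dome standing in for branching *Pocillopora*, and a
smooth lobed hemispheroid for massive *Porites*. Per-colony rumple with
the default parameters is ≈3.4 / ≈4.3 / ≈2.4 respectively, giving the
documented ordering Pocillopora > Acropora > Porites at comparable
dimensions. Absolute assemblage SC depends directly on this choice (and on
the raster cell): with the default families a healthy 45–50%-cover
Pocillopora-dominated year yields median SC ≈ 1.8–1.9 and the collapsed 3%
year ≈ 1.08. Real photogrammetric colonies carry much finer structure
(observed reef-scale SC up to ≈ 3.9); conclusions below are therefore
about orderings and scalings of SC, never its absolute value.

## Structural complexity → Nikuradse roughness

Reef sections take k_n = 0.01 × SC^2.98 (m), the empirical reef power law;
crest and back-reef sections scale the fore-reef value by configurable α
ratios (default 1.0 — the field ratios are site data we do not possess);
the sandy section takes the grain-size convention k_n = 2.5 d50 (default
d50 = 63 μm → 1.575 × 10⁻⁴ m). One k_n(x) profile is built per SC draw, and
a state's representative profile is the pointwise median of its replicate
profiles.

The inversion of paired pressure records proceeds per 15-min burst:
pressure → surface elevation by the linear transfer function
cosh(kh)/cosh(k(h+z)) applied per FFT bin up to a 0.4 Hz cutoff;
sea–swell (0.04–0.4 Hz) energy flux F = ρg Σ S(f) C_g(f) df at each
sensor; the flux loss per metre is attributed to friction,
D = (2/3π) ρ f_w u_b³, with u_b the representative near-bed orbital
velocity amplitude (√2 × rms, averaged between sensors); and the Jonsson
friction-factor relation f_w = exp[5.213 (k_n/a₀)^0.194 − 5.977] is
inverted for k_n with a₀ = u_b/ω_peak. The synthetic pressure-record
generator implements exactly this forward model (JONSWAP sea at the
seaward sensor, flux decayed by the same law, additive Gaussian noise at a
configurable SNR), so generator and inversion close the loop: k_n is
recovered within 5% over 0.05–0.6 m at SNR 20. Bursts with non-positive
inferred dissipation, or friction factors outside the invertible range,
yield flagged estimates at the bounds (k_n floor 10⁻⁴ m).

## Wave model

The solver integrates depth-averaged continuity plus an enhanced-
Boussinesq momentum equation of the Madsen–Sørensen family with B = 1/15
(Padé [2,2] dispersion, accurate to kh ≈ π):

    ζ_t + P_x = 0
    P_t + (P²/h + R_r)_x + g h ζ_x
        = (B + ⅓) d² P_xxt + ⅓ d d_x P_xt + B g d³ ζ_xxx
          + 2 B g d² d_x ζ_xx + E_br + E_sw − τ_b/ρ

with P = hU. The momentum equation printed in the source material for this
model family is typographically garbled; we implement the standard
higher-order form above rather than guessing the corrupted terms, keeping
the published closure terms (roller M_u, swash eddy viscosity, τ_b).

**Numerics.** Uniform grid (1 m for reef transects); AB3 predictor / AM4
corrector in time with dt = 0.2 dx/√(g d_max); the dispersive P_xxt terms
are grouped into q = P − (B+⅓)d²P_xx − ⅓ d d_x P_x and recovered by a
tridiagonal solve with time-constant coefficients. Continuity uses
face-flux form with mirror ghosts at the walls, conserving mass to machine
precision in a closed basin (the trapezoid volume measure is the conserved
quantity). Dispersion is tapered off below 0.4 m still depth (the swash is
treated as nonlinear shallow water, standard for this model family).
Measured dispersion error is < 0.5% up to kh = π at 60 points per
wavelength; a solitary wave seeded from the weakly-nonlinear sech² profile
sheds ≈5% amplitude while adjusting to the model's own solitary form and
thereafter drifts < 2% over 50 effective wavelengths; non-breaking
solitary-wave run-up on a 1:19.85 plane beach is within ~4% of the
analytic 2.831 √(cotβ) (H/d)^1.25 law.

**Breaking.** Detection combines a front-slope criterion (initiation 20°,
hysteresis at 10°) with a surface-rise-rate criterion ζ_t > γ √(gh)
(γ = 0.20 fresh, 0.08 near already-breaking cells): at metre-scale grids
the rise-rate form is the robust trigger because discrete fronts are
smoothed below the nominal breaking slope. Inside breaking regions the
geometric roller thickness δ (area above the 10° tangent from the local
crest, capped at h/2) contributes the excess momentum flux
R_r = δ(c² − u₀²), c = 1.3 √(gh), applied only on converging front faces
(U_x < 0) where the term is provably dissipative; dissipation is completed
by a turbulent-mixing eddy viscosity ν = 1.2 h ζ_t in flagged cells plus a
local 3-point filter, all bounded by the explicit-diffusion stability
limit ν ≤ dx²/(4 dt). With this closure the surf zone saturates
(Hs/h of order one at the shore) and a plane-beach R_2% lands within tens
of percent of the Stockdon parameterization.

**Swash and run-up.** The swash zone is the region of still depth below
R/4 (R first estimated from the Stockdon formula), *confined to the beach
neighbourhood*: for energetic seas the bare depth rule would swallow the
reef crest and flat and disable the breaking model exactly where the bores
are. In the swash the roller is replaced by the eddy-viscosity term
E = B_b [ν_e P_x]_x with ν_e = (3.5h)² |U_x|. Wetting/drying uses a 1 mm
threshold with the dry-bed condition; the waterline for R(t) is the
landward end of the contiguous wet run from the beach toe at a 2 cm depth
threshold (a run-up-wire convention — thin films stranded by previous
swash events drain slowly on an impermeable beach and must not count),
interpolated against the next bed level. Bed friction
τ_b = ½ ρ f_w U|U| is applied as a decay rate on P capped at the explicit
stability limit (the quadratic law is stiff in centimetre-deep water); a₀
for f_w is updated every 100 steps from a running local Hs estimate.

**Boundaries.** Waves enter through an internal source function (component
amplitude calibrated by the radiation relation S = 2 a c per component,
JONSWAP γ = 3.3, 80 components, tanh ramp over 4 T_p) with a 40 m sponge
at the offshore boundary. The sponge damps ζ toward zero but damps P
toward its running mean, so it absorbs the oscillatory motion while
passing the mean return current — damping P to zero blocks the return flow
against the wave-driven (Stokes) transport and steadily floods the domain.
The landward-most nodes act as an overwash sink: water carried past the
top of the beach leaves the domain and is tallied, rather than stacking
against the end wall.

**R_2%.** Individual run-up maxima are peaks of R(t) separated by at least
T_p/2; R_2% is their 98th percentile with the linear-interpolation
convention; fewer than 50 maxima raises a low-confidence flag.

**Validated envelope.** The configuration is exercised with offshore Hs up
to ≈5 m (≈ the 97.5th percentile of the default climate) over the default
reef. The rare largest synthetic seas (Hs ≈ 8 m, T_p ≈ 21 s at the
percentile-100 condition of a 30-year climate) overtop the entire beach;
such runs complete stably via the overwash sink but their R_2% saturates
at the beach crest and no longer discriminates reef states. Ensemble
machinery tolerates this by construction (failures and saturation are
logged per run); quantitative state comparisons are made within the
envelope.

## Wave climate and ensemble

The synthetic weekly climate uses a Weibull Hs marginal (shape 1.8, scale
set for a 1.5 m mode), a lognormal T_p marginal (median 12 s), and a
Gaussian copula (default ρ = 0.5, Kendall τ = ⅓) — the real hindcast's
marginal and dependence strength are not published, so these are
config-exposed defaults, not assertions. Conditions are Hs percentiles
(0.1:0.1:100 at full scale, 1000 conditions) with T_p the conditional
median of the fitted copula (fitted by ML on rank pseudo-observations;
dependence reported as ρ and τ). The ensemble runs one simulation per
(state, condition); per-run seeds derive from the condition only, so every
state sees identical forcing (paired comparisons) and state relabelling
permutes rows without changing values.

## Extreme-value analysis

R_2% exceedances over a threshold (default: weighted 90th percentile) are
fitted with a generalized Pareto distribution by weighted maximum
likelihood, each condition carrying its annual occurrence rate under the
assumption of 52 independent weekly events per year (a desk-scale
annualization choice; the deposited study data would support an empirical
one). The shape is constrained to ξ ∈ [−0.95, 1] — at ξ ≤ −1 the ML
problem is degenerate. Return levels use the closed form
R(T) = u + σ/ξ [(λT)^ξ − 1]; frequency amplification between states is
T/T′ with T′ from closed-form inversion of the degraded-state curve,
flagged as a lower bound when the healthy level sits below the degraded
threshold. Small desk-scale ensembles produce strongly negative ξ
(bounded-tail) fits; amplification factors extrapolated to long return
periods are then order-of-magnitude statements, not precise multipliers.

## Bayesian run-up model

RU ~ N(μ, σ) with μ = (α+σ_ζ) Hs + (β+σ_ζ) SC + (γ+σ_ζ) SC·Hs (no
intercept), priors α, β, γ ~ N(0,1) and σ, σ_ζ ~ Gamma(shape 2, rate 0.1).
The shared slope-dispersion term σ_ζ is implemented literally as printed:
the same draw is added to all three slopes. This makes (α, β, γ, σ_ζ)
only *jointly* identified through the effective slopes a = α+σ_ζ, etc.; we
deliberately do not reinterpret it as a hierarchical random effect. The
sampler works on the identified scale (a, b, c, log σ, log σ_ζ) where the
posterior is well conditioned, and maps back. It is an adaptive
random-walk Metropolis (four chains vectorised in lock-step; proposal
covariance adapted during warm-up from the chain history, frozen
afterwards; initial scales from the least-squares covariance) — a
gradient-based sampler is not among the package's dependencies and this
posterior is 5-dimensional and cheap. Defaults: 4 chains × 5000 draws,
1000 warm-up, 16,000 retained; fits are gated on split-R̂ < 1.05
(arviz). Because the structural parameters are not point-identified,
recovery is checked by simulation-based calibration: across datasets whose
parameters are drawn from the priors, 90% posterior intervals cover the
truths at the nominal rate (pooled over α, β, γ, σ); for data generated
with σ_ζ = 0 the *effective* slopes are recovered to the third decimal.
Predictions (posterior mean and interval of μ on an Hs × SC grid) use the
identified slopes; residual run-up subtracts each Hs level's minimum
prediction so the per-level minimum is exactly zero.

## Desk-scale problem sizes

The default "desk" profile uses a 20 m × 0.5 m strip at 1 cm cells with 20
replicates per year, a 10-year climate, a reduced reef flat (40 m + 30 m
sand), 2 reef states × 30 percentile conditions, and shortened
simulations; the "full" profile restores the study-scale counts
(100 replicates × 10 years, 1000 conditions, 10 states). The acceptance
tests compare reef states on percentile grids within the validated
envelope, with run lengths chosen so each run collects at least 50 swash
maxima for the ordering check. The pipeline's counting contracts
(1000 SC profiles, 1000 conditions, 10 × 1000 ensemble rows, 16,000
posterior draws) are exercised directly, with a surrogate solver standing
in for the 10,000-run sweep whose plumbing — not physics — is under test.

## Known limitations

* Colony shapes are smooth height-field proxies; assemblage SC magnitudes
  sit well below photogrammetric reef values, so SC-dependent results are
  comparative, not absolute.
* The 1D transect cannot drain laterally; lagoon filling and seiching are
  stronger than on a real reef with passes, inflating infragravity run-up
  variability.
* The roller + eddy-viscosity breaking closure is calibrated for
  robustness at 1 m resolution, not against surf-zone laboratory data;
  absolute R_2% values inherit that uncertainty.
* GPD tail extrapolation from tens of conditions is indicative only.
* The synthetic climate's marginals and dependence are plausible defaults;
  no claim is made that they match any particular hindcast.
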
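# Methods

`loewe` implements a non-linear isobolographic analysis of two-drug
combinations for behavioral pharmacology, together with a synthetic data
generator that emulates the kind of study the analysis was designed for: a
mouse chronic-constriction-injury (CCI) neuropathic-pain experiment in
which two cannabinoids (THC and CBD) are given intrathecally, alone and as
a 1:1 fixed-ratio mixture, and allodynia is read out behaviorally.

## Normalization to %MPE

Raw assay values are mapped to percent of maximum possible effect:

| assay            | formula                               | cut-off |
|------------------|---------------------------------------|---------|
| mechanical PWT   | 100·(post − pre)/(cutoff − pre)       | 6.84 g  |
| acetone, rotarod | 100·(pre − post)/pre                  | —       |
| bar              | 100·(post − pre)/cutoff               | 120 s   |

Open-field crossings are analyzed raw. Negative scores (worsening) are
retained by default; `clip=True` floors them at 0. Duplicate measurements
within a timepoint are averaged on the raw scale before normalization;
the 1 h and 2 h post-drug scores are then averaged per animal (this
timepoint reduction is a package choice, configurable via
`average_timepoints=False`). A pre-drug threshold at or above the cut-off,
or a zero pre-drug count, makes the normalization undefined and raises
rather than coercing.

## Hill dose-response model

Effects follow the three-parameter sigmoid

E(d) = E_max / (1 + 10^{p·(log10 ED50 − log10 d)}),

with the lower asymptote fixed at 0 %MPE. Fitting is nonlinear least
squares (`scipy.optimize.curve_fit`) on individual animals' %MPE values,
not dose-group means, so residual degrees of freedom and standard errors
are well defined at n = 6 per group. The ED50 is optimized as log10 ED50
for stability and reported on the linear scale (covariance transformed
with the Jacobian ln 10 · ED50). Initialization: E_max at the maximum
observed effect, ED50 at the dose whose group mean is nearest half of it,
slope 1; overridable. Bounds keep the optimizer in the pharmacologically
meaningful region (E_max ≤ 120 %MPE, ED50 ∈ [0.1, 1000] nmol, slope ∈
(0.1, 10]). At least four distinct doses are required; flat data or a
rank-deficient Jacobian raise `UnidentifiableFitError` instead of
returning defaults.

## Dose-equivalence additive surface

For drugs with unequal maxima (drug A the lower-maximum drug, parameters
E_A, C_A, q; drug B the higher, E_B, C_B, p), the predicted-additive
effect of a dose pair (a, b) converts a into its equi-effective dose of
drug B and applies drug B's curve:

k(a) = (E_B/E_A)·(1 + C_A^q/a^q) − 1,
b_eq(a) = C_B / k(a)^{1/p},
E(a, b) = E_B·(b + b_eq)^p / (C_B^p + (b + b_eq)^p).

b_eq solves the equi-effect condition hill_B(b_eq) = hill_A(a) exactly,
which gives the model its Loewe property: a sham combination of a drug
with itself reproduces the drug's own curve at any mixing ratio. Some
write-ups print the maxima ratio in k the other way around, as E_A/E_B;
that orientation violates the equi-effect condition, makes k negative at
large a, and fails to reproduce the predicted combination potencies, so
the E_B/E_A form is the default and the other is available only as
`printed_k=True` for comparison. The composite denominator is the
standard C_B^p + (b + b_eq)^p, the only form that reduces to drug B's
Hill curve at a = 0.

The predicted-additive ED50 of a fixed-ratio ray (a = f_A·D, b = f_B·D)
is the total dose D where E(a, b) = E_B/2 — half the composite curve's
maximum — found by bracketed Brent root-finding (relative tolerance
1e-10, bracket expanded geometrically). For a 1:1-by-weight THC:CBD ray
the weight and molar ratios coincide because the two drugs are structural
isomers; the design records the basis anyway.

### Role assignment

Drug B must be the higher-maximum drug. `make_surface` assigns roles from
the fitted maxima (ties broken by potency). The surface is *not*
symmetric under role exchange when the slopes differ, and the assignment
is therefore consequential: when the true maxima are close (here 85 vs
79 %MPE) sampling noise flips the fitted ordering in a non-trivial
fraction of replicate experiments, and the predicted ED50 jumps
discontinuously with the flip — variability that the delta-method SE,
a local linearization, cannot see. Simulations in the test suite show
that per-replicate data-driven assignment inflates the synergy test's
type-I error roughly threefold at these parameter values, while fixing
the convention from prior knowledge of which drug has the higher maximum
(`RunConfig(role_assignment="fixed")`) restores nominal calibration.
A one-shot analysis of a single study is unaffected by this distinction;
it matters only for resampling studies of the procedure. This is a known
limitation of the dose-equivalence model near equal maxima.

### Delta-method uncertainty

The SE of the predicted ED50 propagates the six fitted parameters
(E_A, C_A, q, E_B, C_B, p) through the implicit ED50 function:
se² = g·Σ·gᵀ, with g the central-difference gradient (relative step
1e-5; results are stable to step choice at the 1e-4 level) and Σ the
block-diagonal covariance of the two single-drug fits — block-diagonal
because each drug is tested in its own animal cohort. A Monte-Carlo check
(resampling parameters from Σ) agrees with the delta SE to within ~10%
at realistic parameter values.

## Isoboles

The non-linear additivity isobole at effect level L (%MPE) is
b(a) = D_B(L) − b_eq(a), floored at 0, where D_B(L) is the dose of drug B
alone producing L (inverse Hill). The a = 0 intercept is D_B(L) — the
single-drug ED50 when L = E_B/2. Because b_eq saturates at the B-dose
equivalent of drug A's maximum, isoboles at levels above E_A have a
strictly positive b-asymptote at every dose of A: they never meet the
a-axis, unlike the classical linear isobole
b = ED50_B·(1 − a/ED50_A), which assumes equal 100% maxima and unit
slopes and always spans intercept to intercept. Levels are absolute %MPE
(family default 20, 30, 40, 50); the default a-grid spans 1.25× the
drug-A ED50, the plotting region around the axis intercepts.
`classify_point` reads a dose pair against an isobole: below =
supra-additive, on = additive, above = sub-additive; queries outside the
computed grid raise rather than extrapolate.

## Synergy test

Experimental (fitted combination) and predicted-additive ED50s are
compared with an unpaired t-test, t = |pred − exp|/√(se²_exp + se²_pred),
two-sided. The residual dof convention is open in such analyses; all
three implemented options are labeled in the report: Welch–Satterthwaite
from the two estimates' dof (default), the smaller dof (conservative),
or a z approximation. At the study's design (≥ 6 dose groups × 6 animals,
3 parameters per fit) every convention yields the same significance
calls; the acetone comparison's p < 0.001 specifically requires dof ≥ 9,
satisfied by any of them. The verdict is directional: synergistic only
when the experimental ED50 is significantly smaller than predicted,
antagonistic when larger, otherwise additive. α defaults to 0.05; no
multiplicity correction is applied across assays.

## Synthetic data generator

The generator emulates the study's structure, not its animals: n = 6 per
group; vehicle, each drug alone at 1–178 nmol (half-log ladder 1, 3.2,
10, 32, 100, 178), and a 1:1 ray at total doses 1.5–153 nmol; von Frey
thresholds bounded by the 0.2 and 6.84 g filaments; acetone counts;
rotarod ≤ 300 s; bar ≤ 120 s. Each animal gets a pre-surgery baseline
and an allodynic post-CCI pre-drug baseline (PWT 3.5 → 0.6 g, acetone
0.5 → 6 counts). The latent drug effect comes from ground-truth Hill
curves (defaults: THC 85/14/2.6 and CBD 79/20/1.5 %MPE/nmol for
mechanical PWT; 52/21/1.7 and 27/11/2.2 for acetone); combination groups
evaluate the additive surface at dose/`interaction_shift`, so shift < 1
embeds true synergy (experimental ED50 = shift × additive prediction)
and 1.0 embeds exact additivity. Gaussian noise (default SD 10 %MPE,
chosen so fitted SEs are comparable in magnitude to fits reported for
such experiments; the true residual variance is not published and this
is an assumption) is added on the %MPE scale and back-transformed to raw
units with clipping to the assay bounds; acetone counts are rounded
(a Poisson mode exists for robustness checks). Side-effect assays carry
zero latent effect by default, with a hook to inject one.

What the generator does **not** emulate: the up-down filament testing
sequence (thresholds are emitted directly), pharmacokinetic time courses
beyond two interchangeable post-drug timepoints, between-animal
heterogeneity in drug sensitivity (noise is purely residual), or
antagonist pharmacology. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the assumed
noise model, not that real behavioral data meet those assumptions —
in particular, count quantization makes low-baseline acetone scores
coarse (one count ≈ 17 %MPE at a 6-count baseline), which visibly
distorts acetone Hill slopes even in noise-free closed loops.

## Numerical choices and degenerate inputs

- ED50 root-finds use Brent with expanding brackets; an unreachable
  half-maximum on a ray raises (inconsistent surface).
- k(a) overflow at vanishing a returns +∞ (zero B-equivalent), keeping
  additive_effect continuous at the axes; a = b = 0 returns 0 by
  convention.
- Equal maxima (E_B = E_A) are admitted — k stays positive for finite a —
  so sham combinations are exact, not approximate.
- A forced role convention with fitted E_A slightly above E_B
  (`check_roles=False`) is admitted; the surface then has a finite domain
  and evaluation beyond it (k ≤ 0) raises.
- Problem sizes in the simulation-based tests: 20 replicates for fit
  recovery, 10⁴ draws for the Monte-Carlo SE check, 200 replicates for
  type-I calibration — sizes at which the binomial noise of the measured
  rates is well inside the asserted margins.

## Known limitations

- The delta-method SE is first-order; it understates uncertainty near
  the role-assignment boundary (see above) and for strongly skewed ED50
  sampling distributions.
- Confidence bands around isoboles are not computed.
- Only Loewe-type dose equivalence is implemented; no Bliss independence
  or response-surface alternatives.
- The predicted-additive SE reconstructed from summary tables (SEs
  without cross-parameter covariances) omits the within-fit correlation
  terms and can differ from one computed from full fit covariances.
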
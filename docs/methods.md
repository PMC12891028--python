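# Methods

`thickfil` models how phosphorylation of the myosin regulatory light chain
(RLC) is laid out along the cardiac thick filament and how that spatial
pattern changes contraction. This note records the models, the default
parameters and why they have the values they do, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Filament geometry

A half thick filament is a 1D stack of myosin crowns at 14.33 nm spacing
beyond an 80 nm bare-zone half width, divided M-line → tip into P-, C- and
D-zones. The rodent default is 49 crowns (4 P, 27 C, 18 D) × 3 dimers,
i.e. 294 myosin molecules per filament. These numbers were chosen so that
two anatomical facts hold simultaneously: the C-zone carries 27/49 ≈ 55 %
of the heads, and the mirrored A-band doublet spans
2 × (80 + 49 × 14.33) nm ≈ 1.56 µm, inside the 1.52–1.58 µm range measured
for ventricular A-bands. Each dimer contributes one *blocked* and one
*free* head (the two structurally distinct heads of the folded
interacting-heads motif), addressed independently by the simulator.

## Two-population phosphorylation kinetics

Per population, phosphorylation follows mass-action kinase/phosphatase
kinetics with closed-form exponential solutions and hyperbolic steady
states; no saturable (Michaelis–Menten) kinase term is modeled because the
observables being reproduced are phenomenological exponential/hyperbolic
fits. Defaults: fast class = P+C-zone heads (fraction 31/49), slow class =
D-zone heads; rate constants k_P = 10 and 1 µM⁻¹ min⁻¹ (fast/slow) with
k_D = 1 µM⁻¹ min⁻¹ for both. Consequences, which are the observables:

* at 0.1 µM phosphatase the steady-state dose–response is biphasic with
  EC50s of 0.01 and 0.1 µM kinase;
* at the default kinase dose (0.02 µM, no phosphatase — the kinetic assay
  adds no phosphatase) the two observed rates are 0.2 and 0.02 min⁻¹, an
  order of magnitude apart, giving a biexponential time course.

The amplitudes of the two phases and the absolute rate values are package
fixtures; only the EC50s and the ~10:1 rate separation are anchored to
measurements. A cap `p_max` (0.95 by default, 0.65 for BDM-like
conditions) limits attainable phosphorylation without any mechanistic
state coupling.

The biphasic fit minimizes *relative* residuals with the baseline fixed at
zero and EC50s parameterized on a log scale from a grid of start pairs.
Relative weighting matches densitometric data whose error scales with
signal; with unweighted fitting and a free baseline the large-EC50 site is
substantially biased at 5 % multiplicative noise. The
biexponential/monoexponential comparison uses an extra-sum-of-squares
F-test, with a machine-precision floor so noiseless monophasic data report
"no second phase" instead of a degenerate p-value.

## Zonal profiles and FWHM

Fluorescence profiles are rendered as sums of Gaussians (PSF σ = 60 nm,
FWHM ≈ 141 nm; pixel 32.5 nm; both package choices, the imaging system's
PSF not being specified) centred on the crowns of both mirrored half
filaments, weighted by head count × phosphorylation occupancy. FWHM is
measured like the experimental profiles: background (mean of the outer
10 % of pixels) is subtracted, and the outermost linear-interpolated
crossings of half the peak are reported, so a doublet with a central dip
is measured across its full width.

Occupancy models:

* **sequential** — C-zone crowns fill uniformly to saturation, then
  D-zone crowns fill outward from the C/D boundary, then P-zone crowns.
  This is the strict reading of "C-zone motors are phosphorylated to
  completion before D-zone motors start", with spillover adjacent to the
  C-zone.
* **kinetic** — both populations fill uniformly at the occupancies the
  two-population time course predicts when the global level is reached.

A mass-conservation consequence worth stating: with the C-zone holding
55 % of heads, a global level of 0.6 leaves only 5 % of total head mass
for the D-zone — about 2.4 crowns (~35 nm) of spillover. The rendered
FWHM at level 0.6 is therefore ≈ 1.13 µm, only slightly above the
C-zone-confined 1.06 µm, and this is insensitive to the PSF width because
a blurred step edge crosses half-maximum at the edge. Measured widths
near 1.25 µm at that level imply a broader, graded spillover than any
occupancy model that saturates the C-zone first can produce; the package
reports the model's honest value rather than emulating the measurement.

## Mechanosensing sarcomere model

Desk-scale half-sarcomere: one thick filament (every head tracked) and two
thin filaments of 26 regulatory units × 7 actins; rigid filaments, no
cross-bridge strain distribution, a single attached (force-generating,
FG) state with constant force per head. Head cycle OFF ⇌ ON ⇌ FG with

* OFF→ON: `k1_0 (1 + g·k_force·F_sense)` — thick-filament mechanosensing;
  `g = phi_P` for phosphorylated heads targeted by the placement model
  (A: C-zone blocked heads; B: all blocked heads; C: C-zone both heads),
  otherwise 1. Phosphorylation multiplies the force-dependent term only,
  so it does nothing at zero load — matching the observation that relaxed
  orientation is barely affected while loaded activation is accelerated.
* ON→OFF: `k2`; ON→FG: `k3 × (thin unit active) × overlap`; FG→ON: `k4`.

`F_sense` is the whole-filament active force plus a linear titin-like
passive force `passive_gain × max(0, SL − 1.8 µm)`, which supplies the
length dependence of activation. Thin-filament units activate with rate
`a_kon·[Ca]·(1 + a_coop·n_active_neighbors)` and deactivate at `a_koff`,
except that a unit holding an attached head cannot deactivate (tropomyosin
cannot re-block actin over a bound cross-bridge). That attachment→
activation coupling is what gives the model its cooperativity beyond the
nearest-neighbor term and lets placement variants feed back into the
force–pCa shape.

Default rates (s⁻¹ unless noted): `k1_0 = 1`, `k2 = 100`, `k3 = 80`,
`k4 = 12`, `f_head = 8 pN`, `a_koff = 100`, `a_coop = 5`,
`k_force = 0.005 pN⁻¹`, `phi_P = 3`; `a_kon` (≈5.7 µM⁻¹ s⁻¹) and
`passive_gain` (≈210 pN µm⁻¹) are calibration outputs, not inputs. The
`k1_0/k2` ratio sets the depth of the OFF reserve. It is deliberately deep
(~2–3 % of heads ON at low load): the expressible phosphorylation-induced
pCa50 shift, and in particular its growth with sarcomere length, depends
on a large recruitable OFF pool remaining at the long-length operating
point. Shallow-reserve parameterizations reproduce the short-length shift
but saturate at long length, inverting the observed length dependence.
One caveat of the deep reserve: force redevelopment after a restretch is
recruitment-limited, so absolute ktr values (~3–5 s⁻¹) sit below tissue
values (~13–16 s⁻¹); only the *direction* of the phosphorylation effect on
ktr is asserted, and that direction is protocol-dependent in this reduced
model (it holds for short slack periods and long sarcomere length, the
trabecula-like condition used in the checks).

Engines:

* **Monte-Carlo** — per-head tau-leaping at dt = 0.5 ms with exact
  exponential per-step probabilities (proportional branching for
  competing exits); an error is raised if any single-step rate·dt exceeds
  0.1. Thin units flip with exact exponential probabilities with neighbor
  counts frozen over the step. Seeds are mandatory.
* **mean-field** — zone/role/phosphorylation-aggregated ODEs (LSODA) with
  the same rate laws, a self-consistent force, and the unit-hold effect
  approximated by `P(unit holds ≥1 FG head) = 1 − (1 − fg)^h` with `h`
  the mean heads per unit. For steady states a damped fixed-point
  iteration on (force, activation), started from the relaxed state,
  replaces time integration; it converges to the same attractor as the
  ODEs started relaxed (bistable upper branches, where they exist, are
  not selected). Mean-field and Monte-Carlo steady forces agree within a
  few percent at saturating Ca²⁺ on the one-filament system; mean-field
  ignores fluctuation–nonlinearity coupling, which is the residual gap.

Slack–restretch: mechanical unloading is idealized — during the slack
phase sensed and reported force are zero, attachment is suspended and
detachment is accelerated ×10; after the restretch normal kinetics resume
and ktr is the single-exponential rate of force recovery. The slack-only
protocol resumes attachment at the shortened length (passive force zero
below slack length).

## Calibration and fitting

The experimental force–pCa data enter as Hill curves through the published
operating points: pCa50 5.56 → 5.64 on phosphorylation at SL 1.9 µm, and
5.64 → 5.76 at SL 2.3 µm; Hill coefficient 4 everywhere except the
long-length phosphorylated curve (2.8, encoding its reduced
cooperativity — a fixture, not a published coefficient). Observation σ =
0.03 normalized force.

Stage 1 pins the unphosphorylated model: (a_kon, passive_gain) are
root-found so the model's pCa50 equals 5.56/5.64 at the two lengths
(tolerance 0.005 pCa). This calibration is *profiled over k_force* (log
interpolation across a calibrated grid), so the sampler can vary the
mechanosensing gain without un-pinning the baseline; above
k_force ≈ 0.008 pN⁻¹ the feedback makes the curve switch-like and no
calibration exists, which bounds the prior. Stage 2 samples
{phi_P, k_force} with the affine-invariant ensemble sampler (Gaussian
likelihood over all four curves, log-uniform priors, phi_P ∈ [1, 30],
k_force ∈ [0.001, 0.008] pN⁻¹). Chains are exactly reproducible given
seed, walker count and step count. Headline runs use 16 walkers × 120–150
steps (burn-in 50–60); the posterior is a well-behaved two-parameter
surface for which this is ample.

Model discrimination re-evaluates the MAP parameter vector under placement
variants B and C: both overshoot the phosphorylated curves (B triples the
number of responding heads, C doubles them within the C-zone) and inflate
the summed squared residual several-fold relative to A.

## Orientation analysis

⟨P2⟩ = (3cos²θ−1)/2 of a probe axis relative to the filament axis;
maximum-entropy (β, γ) densities have the exponential form
exp(Σ λ_{j2}P2(θ_j) + λ_{j4}P4(θ_j)) with multipliers solved so achieved
order parameters match measurements within 1e-4. The basis is truncated
at rank 4 because single-photon polarized fluorescence determines only
⟨P2⟩ and ⟨P4⟩ per probe. Because P2 and P4 are even in cosθ, the solved
density is automatically symmetric under (β, γ) → (180°−β, γ+180°), the
degeneracy of the measurement. Integrals use Gauss–Legendre quadrature in
cos β × a uniform periodic γ grid (64 × 180 nodes), which is spectrally
accurate; the displayed 2° × 2° map is a separate tabulation. Peak
finding merges local maxima with a pole-aware metric (γ distance scaled
by sin β) and pairs each peak with its degeneracy partner.

Euler angles from structures: β is the angle between the least-squares
E-helix axis (SVD of Cα coordinates) and a user-supplied filament axis; γ
is the azimuth of the E→G inter-helix vector about the E-helix, zero when
that vector lies in the (E-helix, filament-axis) plane. Residue spans are
configuration inputs. The structural test uses synthetic ideal-helix
coordinates written and re-read through the structure-file layer; a
comparison against a deposited cardiac IHM model is possible with the
same API but requires the coordinates locally.

⟨P2⟩ transients are fitted phase-wise: a single exponential on
[release, restretch) (Ph1, heads detaching and partially re-forming the
OFF state) and on [restretch, end] (Ph2, heads leaving the OFF state).
Phases with amplitude below a noise floor (default 0.002) are flagged
absent rather than fitted.

## Synthetic data: what passing tests show

Generators emit exactly the tabular schemas the analysis stages consume,
plus JSON ground truth; everything is deterministic per seed. They
emulate the *statistical structure* of each assay — Hill-shaped force–pCa
points with Gaussian noise, biexponential time courses, Poisson-noise
doublet profiles, two-phase ⟨P2⟩ traces with event markers — but not
instrument systematics: no photobleaching, no sarcomere misregistration
or averaging across myofibrils, no channel cross-talk, no densitometric
saturation. Parameter-recovery results therefore demonstrate estimator
correctness at the stated noise levels, not robustness to those
systematics. Tissue-scale magnitudes (absolute ⟨P2⟩ levels, Ph1 rates,
basal in-vivo phosphorylation) appear only as generator parameters;
claims about them are directional inequalities on synthetic data, never
value reproductions.

## Known limitations

* Rigid filaments, one attached state, no strain dependence: absolute
  forces and ktr magnitudes are not tissue-calibrated; shifts, ratios and
  directions are.
* The mean-field unit-hold closure is a moment approximation; it is
  validated against the Monte-Carlo engine only at high activation.
* The sequential occupancy model is a limiting case; graded
  kinase-accessibility profiles along the filament are not modeled.
* Whether the thick filament senses node-local or whole-filament force is
  unresolved; whole-filament force is used.
* P-zone heads are grouped with the C-zone for phosphorylation kinetics
  but fill last in the sequential spatial model; the data constrain
  neither choice directly, and both are flagged where they matter.
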
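# Methods

This note documents the model implemented by `mgm`, its assumptions, the
numerical choices made where the design was open, and what the synthetic
test campaign does and does not demonstrate.

## Model summary and assumptions

The model treats the frequency-mean lineal energy y_F (keV/μm) of a beam
component as a sufficient statistic for the DNA damage a single track
induces in a cell nucleus. This rests on the *short-track condition*: the
particle loses approximately the same energy per unit length across the
microdosimetric site, so the energy imparted by one event is y_F times the
chord length. The condition fails for very low-energy particles (roughly
sub-MeV protons and ~1-MeV alphas), and the y_F-parameterized functions are
calibrated for y_F ∈ [2, 200] keV/μm; outside this range every evaluation
logs a warning but still returns a value, since the functional forms remain
finite and monotone.

Per-track yields:

| quantity | form | interpretation |
|---|---|---|
| direct SB/BD/DS | k·y_F | energy deposition in DNA scales with y_F |
| indirect SB/BD/DS | N_max(1 − e^(−a·y_F)) | radical recombination saturates ROS-mediated damage |
| DSB-containing sites | c₁y_F + c₂y_F² | ionization clustering makes DSBs super-linear in y_F |

Totals are direct + indirect by construction. The linear-quadratic DSB-site
law is fitted through the origin (no intercept): zero lineal energy means no
tracks and no damage. An intercept can be emulated by adding a constant
column externally, but is deliberately not a fitting option.

Complexity C (strand breaks + base damages in a DSB-containing 10-bp site,
minimum 2) follows a Gamma density whose shape a(y_F) and rate b(y_F) are
quadratic polynomials in y_F. The quadratics are fitted on the linear y_F
abscissa by default; a log10(y_F) mode is provided (`abscissa="log10"`)
because damage trends are commonly displayed on a logarithmic y_F axis, and
the mode is recorded in the parameter object so serialized calibrations are
unambiguous.

Because C is an integer score but the fitted law is continuous, generated
complexities are discretized: a Gamma draw X becomes max(2, round(X)). All
expectations that must match the generator (notably the mean lethality in
the closed-form survival) are therefore taken under the discretized mass
function P(2) = F(2.5), P(k) = F(k+0.5) − F(k−0.5), truncated where the
upper tail mass falls below 1e−12 (the residual is absorbed into the last
bin so masses sum to one exactly).

## Geometry and dose–track conversion

Sites and nuclei are liquid-water spheres (density 1000 kg/m³,
configurable). The mean chord length of a sphere under μ-randomness is
Cauchy's l̄ = 2d/3, and the y_F↔z_F conversion is

z_F [Gy] = y_F [keV/μm] · l̄ [μm] · (1.602176634·10⁻¹⁶ J/keV) / m [kg].

The mean number of tracks delivering dose D is ν = D / z_F(nucleus). Track
chords enter uniformly over the nucleus's projected disk, parallel to one
axis by default (external beam); an isotropic mode exists for internal-
emitter geometries. Energy bookkeeping (Σ y_F·chord / mass) recovers the
nominal dose in expectation and is property-tested.

## Damage generation

Per spectral component, the component weight is read as a *dose fraction*
(not a fluence fraction — the alternative is a one-line change and the
choice is recorded here because mixed-beam realizations depend on it). Track
counts are Poisson(ν), DSB-site counts per track are Poisson(c₁y_F+c₂y_F²),
site positions are uniform along the chord, complexities are discretized
Gamma draws. Tracks are independent: cross-track damage accumulation is not
applied during generation (valid for moderate doses); the record-level
`accumulate_tracks` operation merges overlapping 10-bp windows (transitive
closure per chromosome, lesion counts summed, DSB flag re-derived) for
analyses that need it.

For SDD export a complexity C is decomposed into a minimal lesion pattern:
one strand break on each strand (the DSB) plus C−2 surplus lesions split
50:50 between extra strand breaks (alternating strands) and base damages;
the split ratio is configurable. Scoring the exported record always returns
C; no unique inverse exists, and this one is the least-structured choice.

## Survival and RBE

Each DSB-containing site is lethal with probability
p(C) = 1/(1+e^(−d(C−C_half))); a cell survives if no site is lethal. The
generator's site count is *compound* Poisson (Poisson tracks carrying
Poisson site numbers), so the exact closed-form survival follows from the
probability generating functions applied at both levels:

S(D) = exp( Σ_components ν_i(D) · (e^(−m_i·E[p(C_i)]) − 1) ),

with m_i the mean DSB-site count per track. For small m·E[p] this reduces to
the familiar exp(−μ·E[p]) with μ = νm the expected total site count, but at
high lethality per track the compound form predicts higher survival because
lethal sites arrive clustered on tracks rather than independently. This
derivation is the package's own; it is validated against the Monte Carlo
route (per-site Bernoulli lethality, 4-binomial-SE agreement) in the test
suite.

LQ parameters come from non-negative least squares of −ln S on (D, D²); the
exact unconstrained solution is used whenever it is feasible, the bounded
solver only when a coefficient would go negative. RBE at a survival level
inverts the fitted LQ analytically (quadratic formula) rather than
interpolating the dose grid. The α-ratio low-dose limit is labelled
`RBE_min` in outputs for continuity with common usage in the high-LET
literature, although for high-LET test radiations this limit is
conventionally the *maximum* RBE; the label is cosmetic, the quantity is
α_test/α_reference.

## Calibration

- Saturation curves: `scipy.optimize.curve_fit` with positivity bounds,
  initialized at N_max = 1.2·max(N), a = 1/median(y_F), tolerances 1e−10,
  ≤10⁴ evaluations. A fit whose saturation is already complete at the
  smallest y_F (a·min(y_F) > 5) is flagged: a is then only bounded below by
  the data.
- Linear and linear-quadratic laws: (weighted) least squares through the
  origin, c₁, c₂ ≥ 0 with active constraints reported.
- Gamma per quality: continuous maximum likelihood (`scipy.stats.gamma.fit`
  with location fixed at 0) by default, or least squares of the density
  against the unit-bin normalized histogram (`histogram-ls`), which mirrors
  how such fits are usually displayed. R² is reported on the
  normalized-histogram scale in both modes so they are comparable.
- Trends: two independent quadratic least-squares fits of (a, b) vs y_F,
  with positivity of both curves verified on a 512-point grid over the
  validity range.

`calibrate()` defaults to *relative* (inverse-variance with σ ∝ value)
weighting of the yield fits. Per-track yields have dispersion that scales
with their mean, and unweighted fitting lets the large high-y_F residuals
drown the low-y_F points that identify a_sat and c₁; with relative
weighting, all coefficients are recovered to within ~10% under 5%
multiplicative noise at 15 qualities (simulated over 200 random campaigns,
97.5% of which meet 10% on every coefficient simultaneously). The individual
`fit_*` functions stay unweighted unless variances are passed.

### Identifiability caveat for the Gamma parameters

When the complexity mean a/b is small (≲4), the discretization
(round + clamp at 2) folds a large probability mass into C = 2 and the
*continuous* (a, b) are no longer identifiable from integer scores: a
continuous-likelihood fit to discretized low-mean draws returns a shape
inflated by up to ~2×, with the mean roughly preserved. Calibrations from
per-quality (a, b) tables are unaffected; calibrations from raw integer
scores should be read as fitting the *discretized* law, and the package's
record-level validation therefore compares distributions with the RMSE of
histogram bin masses rather than parameter values.

## Synthetic test campaign

`mgm.synthetic` emulates a damage-simulation campaign at 15 log-spaced
qualities spanning 2–200 keV/μm. Its default parameter set is synthetic —
plausible in order of magnitude (tens of strand breaks per track, complexity
means 2.5–5 across the range) but not any published calibration, and every
serialized fixture is labelled as such. Two paths exist:

- the *yield-table* path emits exact expected per-quality yields (optionally
  perturbed by unit-mean multiplicative lognormal noise of chosen σ), which
  is what the parameter-recovery tests calibrate against: noiseless recovery
  is to machine precision, 5%-noise recovery is within 10%;
- the *record-level* path emits per-track Poisson counts, discretized Gamma
  complexities and SDD files, exercising parsing, scoring, bootstrap and
  the RMSE-based distributional checks.

What passing these tests shows: the estimators invert the generative model
correctly at realistic noise levels, and the generator/analytic pair is
self-consistent. What they do not show: that real track-structure data
follow these functional forms, that the synthetic coefficients resemble any
real calibration, or that the sigmoid repair model is biologically adequate
(it is an illustrative device; its known artifacts — e.g. repair-deficient
curves crossing proficient ones at high complexity — come with it).

Problem sizes used by the default suite were chosen to keep statistical
assertions comfortably powered: 10⁶ draws for the Gamma-fit fidelity check,
10⁴ repetitions per dose for the Monte-Carlo-vs-analytic survival oracle,
2·10⁵ chords for the mean-chord oracle, 400–600 tracks per quality for the
record-level pipeline checks.

## Known limitations

- Only protons and alpha-like qualities are in the calibrated range;
  heavier ions and full photon spectra are out of scope (a photon spectrum
  mixes qualities and loses the single-Gamma complexity shape — mixtures
  must be represented as multi-component beams).
- No lesion-level repair kinetics, chromosome-aberration pairing, cell-cycle
  or chromatin-compaction effects; per-track time stamps are carried so a
  downstream repair model can implement protracted irradiation, but no
  decay/washout kinetics are modeled.
- The SDD dialect implements the minimal field set this model consumes
  (header key–value block, 7-field data lines with lesion counts, DSB flag
  and direct/indirect cause); other SDD fields survive a round trip as
  opaque header text but are not interpreted.
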
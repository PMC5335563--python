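# Methods

This note records the models implemented in flavoquant, the default
parameters and where they come from, the design choices made where the
problem was genuinely open, and what the synthetic-data validation does
and does not demonstrate.

## Tight-binding titration model

The observable is total fluorescence of a cuvette containing flavin
(FAD, FMN or riboflavin) being titrated with apoenzyme. Three species
contribute linearly: free flavin, the quenched apoenzyme–flavin
complex, and the titrant itself (whose small signal accounts for
residual holoenzyme carried in the apoprotein preparation — it grows
linearly with added titrant and is absorbed into the single factor
`f_apo` rather than modelled as a separate binding species):

    F(ft, at) = f_flavin (ft − c) + f_complex c + f_apo (at − c)

The complex concentration `c` is the smaller root of

    c² − (ft + at + K_D) c + ft·at = 0,

the tight-binding (Morrison) solution, required because K_D (~20 nM) is
an order of magnitude below the flavin concentration, so ligand
depletion is severe. The root is evaluated in the cancellation-free
form `c = 2·ft·at / (s + √(s² − 4·ft·at))` with `s = ft + at + K_D`;
the larger root always exceeds `min(ft, at)` and is discarded by
construction. A property test checks the root against an independent
bisection solver of the mass-action equilibrium to 1e-9 relative over
10⁴ random parameter triples.

**Dilution correction.** Totals at addition *i* are computed exactly:
`V_i = v0 + i·ΔV`, `ft = ft0·v0/V_i`, `at = at_stock·i·ΔV/V_i`. Under
the default schedule (1.3 mL start, fifty 5 µL additions of 5 µM
titrant) the cumulative dilution reaches 250/1550 ≈ 16%, far too large
to ignore. Defaults: `v0 = 1300 µL`, `flavin_stock = 200 nM`,
`titrant_conc = 5000 nM`, `aliquot_volume = 5 µL`, `n_additions = 50`.

**Fitting.** Bounded (positive) trust-region least squares over
(K_D, f_flavin, f_complex, f_apo); unweighted by default (no error model
accompanies typical single-read data), with an optional per-point
weight vector. Initialisation: `f_flavin` from the pre-addition point
`F₀/ft₀`; `f_complex` from the endpoint plateau; `K_D` at one tenth of
the starting flavin concentration. Standard errors are Gauss–Newton
curvature estimates, `cov = (JᵀJ)⁻¹·RSS/(n−p)`. A fit whose 95% Wald
interval on K_D spans more than two orders of magnitude is flagged as
unidentifiable — the expected outcome for a very weak binder such as
riboflavin under this protocol, where the titrant never approaches K_D.

The 30-second emission recording per point is represented in the
simulator by averaging `n_readings` noisy draws per point; the fitter
always consumes one value per point.

## FMN/FAD composition

Free FMN is ~9× brighter than free FAD (adenine stacking quenches FAD),
which makes the emission of a released cofactor pool an accurate
composition probe. With equimolar pure references F_FMN and F_FAD and
the sample reading F_fin:

    f_FMN = (F_fin − F_FAD) / (F_FMN − F_FAD),   f_FAD = 1 − f_FMN

Fractions outside [0, 1] are **reported unclamped with a warning**
rather than silently truncated: an out-of-range value is diagnostic of
a bad reference or a third fluorophore, and hiding it would destroy
that signal. First-order error propagation from replicate scatter gives
the fraction uncertainty, which shrinks as the brightness contrast
|F_FMN − F_FAD| grows.

The full-spectrum variant fits the mixture spectrum as the convex
combination `f·S_FMN(λ) + (1−f)·S_FAD(λ)` with the single fraction `f`
free (closed-form least squares). The sum-to-one constraint was chosen
over unconstrained non-negative least squares deliberately: it reduces
*exactly* to the two-point solve on a one-wavelength grid, remains
well-posed there (two free non-negative coefficients would be
underdetermined at a single wavelength), and preserves the
report-unclamped policy, which clipping at zero would silently violate.

**MRM route.** Each species is quantified by its quantifier transition
(FAD 786.15→348.10 m/z, positive mode; FMN 455.00→97.00 m/z, negative
mode) against an ordinary least-squares calibration line with free
intercept (through-origin available via a flag). Back-calculated
concentrations below zero are floored at zero with a warning; the mole
fraction is `c_FMN/(c_FMN + c_FAD)`. The second transition per species
(FAD→136.10, FMN→78.90) is treated as a qualifier: an identity gate on
the qualifier/quantifier area ratio, default ±30% relative. Peak
detection and integration from raw chromatograms are out of scope —
inputs are integrated peak areas.

## Enzyme kinetics

Initial rates from the proline:DCPIP assay are fitted to
`v = Vmax·S/(K_M + S)` by nonlinear least squares only; linearised
estimators (Lineweaver–Burk, direct linear plot) are excluded because
they distort the error structure. `kcat = Vmax/[E]` (with an optional
per-minute → per-second conversion), `kcat/K_M` in s⁻¹M⁻¹ from K_M in
mM, and `kcat_app = SA·M_subunit/60000` converts specific activity
(U mg⁻¹, 1 U = 1 µmol min⁻¹) via the subunit molar mass. Defaults:
ε(DCPIP, 600 nm) = 21 000 M⁻¹cm⁻¹ (standard literature value for
pH ~7.4; configurable), subunit mass 74 401 Da (the MBP-tagged fusion;
configurable). A fitted K_M outside the measured substrate range
triggers an identifiability warning. Note the specific-activity
conversion yields the turnover *at the assay substrate concentration*;
at 100 mM proline with K_M ≈ 68 mM this is ~60% of the Vmax turnover,
and the two conventions agree only through the Michaelis factor
S/(K_M+S).

## Thermal unfolding

The two-domain fusion unfolds non-cooperatively, so the CD melt is
modelled as two logistic transitions over a shared flat baseline:

    y(T) = b + a₁/(1 + e^{(Tm1−T)/w1}) + a₂/(1 + e^{(Tm2−T)/w2})

This is the simplest "double sigmoidal" form consistent with a two-step
melt; sloped native/denatured baselines are not fitted by default
(the only reproducible claims are the midpoints, which are insensitive
to baseline slope at these signal-to-noise levels). Midpoint ordering
is built into the parameterisation (`Tm2 = Tm1 + Δ`, `Δ > 0`), and the
`Tm2` standard error combines the `Tm1` and `Δ` variances with their
covariance. When one amplitude collapses or the midpoints coincide the
fit falls back to a single logistic with a warning. The default
simulation grid is 20–95 °C in 0.5 °C steps, matching a 0.5 °C min⁻¹
scan read every 0.5 °C. Thermodynamic analysis (ΔH, van 't Hoff,
scan-rate corrections) is out of scope.

## Mass and cell arithmetic

Peptide masses use the IUPAC *average* residue-mass table (+18.0153 Da
for a free peptide) — the convention in which predicted denatured
protein masses such as 74 401 Da are quoted; a monoisotopic table is
available behind a flag. Truncation masses subtract the residue-mass
sum of the removed peptide (the leaving peptide takes the water).
Hexagonal cell volume is `a²c·√3/2`; the Matthews coefficient is
`V_cell/(Z·M)` with Z the number of protein molecules per unit cell;
solvent content uses the classical approximation
`100·(1 − 1.23/V_m)` (protein partial specific volume 0.74 cm³/g).

## Synthetic data: what it shows and what it does not

Every generator is the exact forward model of its fitter plus seeded
Gaussian noise (additive, or proportional for photon-flux-like
fluorescence data; the choice of Gaussian noise is a modelling default,
not a measured instrument property). Consequences:

- **Zero-noise round trips are exact** and are asserted for every
  generator/fitter pair; identical seeds give byte-identical outputs.
- Parameter-recovery runs (100 seeds at 1% noise for titrations, 2%
  for melts) establish that the estimators are unbiased and precise
  *under the assumed model*. They do not probe instrument drift,
  inner-filter effects, photobleaching, scatter, chromatographic
  interference or model misspecification — a fit to real data can be
  worse in ways these tests cannot reveal.
- Synthetic emission spectra use a single Gaussian peak (centre 525 nm,
  width 30 nm) for both species, differing only in brightness (FMN 1,
  FAD 1/9). Real FMN/FAD spectra differ slightly in shape; since every
  downstream computation uses only relative intensities on a common
  grid, the simplification is harmless for validation purposes but
  means the spectral route is not tested against shape differences.

Problem sizes in the recovery studies (100 replicates of a 51-point
titration or 151-point melt) were chosen as the smallest runs whose
median estimates are stable to well within the assertion tolerances.

## Numerical choices

- Morrison root via the numerically stable quotient form (no
  subtractive cancellation at `at ≫ ft` or `K_D → 0`).
- All optimisations use bounded trust-region least squares; the
  kinetics fit tightens `xtol/ftol/gtol` to 1e-14 so that noiseless
  round trips recover parameters to ≤1e-6 relative.
- Interior-point standard errors can be unavailable for singular
  Jacobians; they are then reported as infinite rather than fabricated.
- Concentrations are carried in nM for titrations and mM for substrate
  (the natural scales of each assay); unit-tagged conversion helpers
  (`to_molar`) cover I/O.

## Known limitations

- Single-curve fitting only; no global multi-curve analysis.
- The titration model treats residual holoenzyme as a linear background
  (`f_apo`), valid when the residual flavin is a small fraction of the
  titrant; a large holo contamination would need an explicit species.
- MRM quantification assumes linear response over the calibrated range
  and no ion suppression.
- The melt model's flat shared baseline under- or over-estimates
  amplitudes (not midpoints) when real baselines slope strongly.
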
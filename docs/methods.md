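# Methods

`ludose` implements the cycle-1 dosimetry and blood-pharmacokinetics
workflow used for Lu-177 radioligand therapy (Lu-177-PSMA-617): from raw
gamma-counter counts and three-energy-window planar ROI counts to
non-compartmental PK parameters, time-integrated activity coefficients
(TIACs), MIRD organ absorbed doses, ICRP 103 effective dose, and the
cumulative dose extrapolated to six treatment cycles.  Because the raw
clinical data behind such studies are not public, the package ships a
synthetic virtual-patient generator that reproduces the protocol's sampling
schedules and the published organ-kinetics magnitudes, so every stage is
testable end to end.

## Physical model

All decay corrections use a Lu-177 physical half-life of exactly 161.6 h
(the value used in the source analyses), not a more precise literature
value: reproducing the published arithmetic takes precedence over the last
decimal of the nuclide datasheet.  Only single-nuclide exponential decay is
modelled; the metastable branch and daughters are ignored.

Half-life algebra follows the standard decomposition
`1/t_eff = 1/t_bio + 1/t_phys`.  Effective half-lives are defined on
as-measured (physically decaying) activity; biological half-lives on
decay-corrected data.  A fitted phase at or slower than physical decay has
no resolvable biological clearance; it is reported with `t_bio = None` and
a flag rather than an error, because real planar fits do brush against this
boundary.

## Blood pharmacokinetics

The gamma-counter calibration is a blank-subtracted ordinary least squares
of cpm on Bq over a standard series (defaults span ~0.1-700 kBq/mL in
triplicate).  LLOQ is the lowest standard whose back-calculated accuracy
and precision are within +/-20%; ULOQ the highest within +/-15%.
Quantification flags are assigned on the concentration *as counted*
(before the dilution factor is applied), mirroring how counter readouts are
screened against the validated range.

NCA follows the usual IV conventions: observed Cmax/Tmax, linear
trapezoidal AUC on actual times, `AUC_inf = AUC_last + C_last/lambda_z`,
`CL = dose/AUC_inf`, `Vz = CL/lambda_z`, MRT from AUMC/AUC with the
analytic tail terms, `Vss = CL * MRT`.  The terminal window is chosen by
best adjusted r^2 over all contiguous terminal windows of >= 3 points after
Tmax, requiring adjusted r^2 >= 0.80, preferring windows spanning at least
two fitted half-lives, and breaking ties toward more points.  This mirrors
the common commercial-software default; the threshold and rule are
config-overridable.  NCA runs on decay-corrected concentrations, so its
terminal half-life is biological; the corresponding effective half-life is
derived through the half-life algebra above.

Mass concentration (ng/mL) is derived from %IA/mL via the administered
peptide mass (default 110 ug), so both unit systems appear in outputs.

## Planar quantification

Scatter correction is the triple-energy-window (TEW) estimator with the
Lu-177 windows: main 208 keV / 15% width (31.2 keV), lower 170 keV / 15%
(25.5 keV), upper 240 keV / 10% (24.0 keV):

    C_SC = C_main - 1/2 * (W_main/W_low * C_low + W_main/W_upper * C_upper)

Negative results are clamped to zero and flagged - over-subtraction at low
counts is expected behaviour of TEW and must not silently corrupt fits.

Quantification is single-view and self-calibrating: the camera sensitivity
factor is fixed by requiring that the scatter-corrected total-body plus
urine-container count rate at the first scan equal the administered
activity decayed to that time.  Organ activities are the scatter-corrected,
background-subtracted rates times this factor.  Any global rescaling of
detector sensitivity therefore cancels exactly out of %IA.  A conjugate
anterior/posterior geometric-mean mode with attenuation maps would be the
natural extension point but is out of scope: the workflow consumes ROI
counts, not images.  Background is removed as a per-pixel count-rate
density from a dedicated background ROI, scaled by each ROI's pixel area.

The co-imaged sealed reference source (50-100 MBq) provides camera QC: a
log-linear fit of its scatter-corrected counts must recover the physical
half-life within 5% (configurable).

Both the as-measured %IA series (used for t_eff fits) and the
decay-corrected series (tracer view, used for t_bio) are reported.

## TAC fitting and TIACs

Organ TACs are fitted with sums of 1-3 exponentials by multi-start
nonlinear least squares (log-parameterised amplitudes and rates for
positivity; starts from curve peeling plus rate-jittered variants;
tolerances 1e-14).  The pipeline assigns phase counts per region from the
reported model forms - bi-exponential kidneys, salivary glands, thyroid and
total body, mono-exponential bowel, tri-phasic blood-derived red marrow -
because an automatic criterion cannot discriminate models on 4-point
imaging TACs, where a bi-exponential already has zero residual degrees of
freedom.  Automatic selection (corrected AIC with an exact-fit parsimony
short-circuit) remains available for richer data.  With a missing imaging
time point, phase counts are reduced so fits keep non-negative degrees of
freedom (3-point TACs are fitted mono-exponentially).

`AUC_inf = sum(A_i/lambda_i)` in closed form; TIAC = AUC_inf divided by the
administered activity.  A fit on as-measured activity can never legitimately
exceed the physical ceiling `t_phys/ln2 = 233.1 h`; violations are flagged.

Source regions not imaged directly:

* **Red marrow** - from blood via
  `A_RM = AC_blood * RMBLR * m_RM / rho_blood` with RMBLR = 1 and
  rho_blood = 1.06 g/mL as fixed model constants, and a red-marrow mass of
  1170 g (adult male reference; the mass is not stated in the source
  analyses and is config-exposed).  The blood schedule has 9 points, enough
  for the tri-phasic fit.
* **Urinary bladder contents** - a periodic voiding model: the bladder
  accumulates the physically decaying urinary inflow between voids and
  empties every 3.5 h (default; unstated in the source and a common
  dosimetry default).  The content integral is evaluated void-by-void in
  closed form; tests check it against independent ODE integration.  The
  urinary excreted fraction defaults to `1 - gut_fraction`, since the
  bi-exponential whole-body retention eventually clears completely and
  urine collection in the protocol only covers the first 2 h.
* **Gut** - the full ICRP 100 alimentary-tract model is replaced by a
  documented 3-segment catenary chain (right colon, left colon,
  rectosigmoid) with first-order transit (default mean 12 h per segment)
  plus radioactive decay, solved in closed form.  When a bowel ROI was
  quantified, the segment TIACs are rescaled so their sum equals the imaged
  bowel TIAC, keeping dosimetry consistent with imaging.
* **Remainder** - total body minus all source regions; a negative
  remainder raises (inconsistent inputs) instead of clamping.

## Dosimetry

Absorbed doses follow the MIRD schema, `D(t) = sum_s TIAC(s) * S(t<-s)`,
against an explicit S-value matrix supplied as CSV.  Proprietary phantom
tables are not bundled; instead `toy_phantom_smatrix()` constructs a
documented synthetic geometry: each region absorbs the full non-penetrating
energy per decay locally (`S_self = E_np * kappa / m`, with E_np = 0.1473
MeV and kappa = 576.72 mGy*g per MeV per MBq*h), photons are treated as
uniformly mixed over the body with a single absorbed fraction (0.3), and
the bladder wall receives half the contents' surface electron dose.  Any
user-supplied matrix in the same schema drops in unchanged.

The lacrimal glands use the unit-density sphere model with 0.7 g per gland
and activity split equally between the two glands; sphere S-values are
interpolated log-log (power functions) through a knot table that defaults
to pure `E_np/m` scaling - the photon self-dose term is negligible for
sub-10 g spheres but can be supplied.

Effective dose is the ICRP 103 tissue-weighted sum (weights hard-coded as a
versioned resource summing exactly to 1), with the 13-tissue remainder rule
applied as an arithmetic mean and the remainder-region dose acting as the
fallback for tissues the workflow does not resolve individually (stomach,
breast, gonads, oesophagus, skin, bone surface, brain).  For Lu-177's
beta/gamma emissions the radiation weighting factor is 1, so mGy and mSv
are numerically equal.  Six-cycle cumulative doses multiply the cycle-1
normalized dose by 44,400 MBq and are reported raw and rounded to 2
significant figures (half-up), the convention of the published report
tables.

## Synthetic cohort: what it emulates and what it does not

The generator encodes ground truth as sums of exponentials: organ
amplitudes are solved at generation time from the published 2-h uptakes
(e.g. kidneys 3.7 %IA, liver 4.2 %IA), phase effective half-lives (kidneys
7.0/43 h, thyroid 5.7/62 h, total body 7.5/73 h) and, where published,
the TIAC (kidneys 1.8, liver 1.2 MBq*h/MBq).  The bowel is mono-exponential
(t_eff 52 h) because no bi-exponential with plausible half-lives satisfies
both 2.6 %IA at 2 h and a TIAC of 2.0.  The total-body fast/slow split
(0.775/0.225) reproduces a whole-body TIAC near 32 MBq*h/MBq.  Blood is
tri-phasic (t_bio 0.32/5.0/52.6 h) and scaled so the red marrow holds 13
%IA at the end of infusion, which lands Cmax near 11-13 ng/mL for a 110 ug
peptide dose.  The administered activity is drawn uniformly within
7400 MBq +/- 10%.  Cohort realism comes from seeded lognormal inter-patient
jitter with spreads taken from the published SD/mean ratios.

Counting noise is Poisson in every simulated channel.  Scatter uses a
per-window leak model constructed so the TEW estimate is unbiased: the
flanking windows carry `(W_low/W_main)` and `(W_upper/W_main)` times the
true main-window scatter, hence noiseless simulation inverts exactly.  This
is deliberate - the TEW equation is the estimator under test, so the
simulator must embed a ground truth that estimator can recover.  What the
simulator does *not* emulate: attenuation, collimator response and partial
volume effects, organ overlap in projection (the inflated thyroid doses
seen clinically from overlying bone lesions), patient motion, and real
scatter spectra whose TEW estimate is biased.  Passing recovery tests
therefore validates the estimation chain, not planar quantification physics.

Acquisition durations and count levels are not published; defaults
(10 cps/MBq, 300 s) give 1e5-1e6 main-window counts for major organs at
the first scan, i.e. sub-percent relative counting noise, and are
config-exposed.

## Verification strategy and problem sizes

Closed forms are tested against independent oracles: numerical quadrature
for `AUC_inf`, ODE integration (`scipy.solve_ivp`) for the voiding-bladder
and catenary-gut models, direct formula evaluation for TEW and the
red-marrow equation, and hand arithmetic for the NCA trapezoids.  End-to-end
recovery uses the noiseless simulator (every organ t_eff within 1%, TIAC
within 2%) and 50 Poisson-noise seeds (terminal t_eff and TIAC within 10%
for at least 95% of organ x seed pairs).  The default verification sizes -
nine-participant cohorts, 50 noise seeds, 100-seed calibration and QC
simulations - run the whole suite in well under a minute and were chosen as
comfortably sufficient for the tolerances tested.

## Known limitations

* Single-view planar calibration ignores attenuation and depth; absolute
  activities inherit whatever bias the supplied counts carry.
* The toy S-matrix is a stand-in geometry; absolute doses from it are
  illustrative until a phantom-derived matrix is supplied.
* The gut model is a 3-segment simplification of the ICRP 100 transit
  model; segment boundaries are nominal.
* Cohort summary statistics assume lognormal-like spread (geometric mean /
  geometric CV%), which fails loudly on non-positive values by design.
* Urinary excretion measured from collections is only used through 2 h;
  later excretion is inferred from whole-body retention.
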
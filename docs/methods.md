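# Methods

## Model structure

Each model variant is a network of well-mixed compartments carrying free
ATP and ADP. Exchange between two connected compartments is linear in the
concentration difference, with one lumped permeability coefficient per
connection (nmol·min⁻¹·mg protein⁻¹·mM⁻¹). This deliberately collapses all
spatial detail — including the known phenomenological character of the C4
coupling — into three or four coefficients. All reactions interconvert ATP
and ADP 1:1:

| reaction | compartment | rate law |
|---|---|---|
| ATP synthase | IMS | `V_syn·ADP/(ADP + Km_syn_adp·(1 + ATP/Ki_syn_atp))` |
| ATPase 1 (2) | cytosol (cytosol or C4) | `V·ATP/(ATP + Km_atp·(1 + ADP/Km_adp))` |
| endogenous PK 1 (2) | cytosol (C4) | `V·ADP/(ADP + Km_pk_adp)`, × PEP switch |
| exogenous PK | solution | `V_pkexo·ADP/(ADP + Km_pkexo_adp)`, × PEP switch |

PEP and pyruvate are not state variables: PEP acts as a saturating on/off
switch per protocol, and the coupled LDH reporter is assumed fast and
unrestricted, so the summed PK flux is read out directly. The ADP product
inhibition of the ATPases is competitive with the fitted `Km_adp`.
Variant 2s omits the second cytosolic ATPase entirely: two co-located
ATPases sharing one affinity pair are mathematically a single reaction, and
the free-parameter counts (6, 8, 11, 11, 13, 11, 13 for 1, 2s, 2, 3s, 3,
4s, 4) only close without it. C4 attaches to the cytosol in models 3/3s
and to the solution in models 4/4s; with the large fitted solution–cytosol
permeabilities the two anchorings are nearly equipotential, and neither
family is nested in the other.

## Steady states and boundary conditions

A steady state zeroes the net production of each nucleotide in every
compartment. Titration points are treated as independent steady states
with the solution clamped at the titrant (quasi-steady approximation for a
large chamber); in the spectrophotometric ATPase assay only solution ATP is
clamped while solution ADP balances cell efflux against the exogenous PK;
the PK-competition assay conserves the total adenine nucleotide loaded
into the closed chamber (2 mM). Because every reaction conserves ATP+ADP,
one closed-chamber balance equation is redundant and is replaced by the
conservation constraint.

The solver is a damped Newton iteration on the ≤ 8 unknown concentrations
with an analytic Jacobian: initial guess equal to the clamped solution
values (or an even nucleotide split in the closed chamber), step-halving
on residual increase, nonnegativity clipping. Convergence requires the
max-norm balance residual below 10⁻⁹ relative to the largest flux, with a
floating-point floor of `16·eps × (largest exchange throughput C·c)` that
only matters for near-infinite exchange coefficients. Non-convergence
raises an error carrying the last residual; during fitting such points
enter the objective as a large fixed penalty residual.

## Fitting

The objective pools all six assays: `rss = Σ((y_model − y)/w)²`, `w` the
per-point sd (else the assay's max |y|). The published residual scale is
not reproducible without the original per-point weighting, so published
RSS values are treated as inputs to the statistics, never as fit targets.
Optimization runs in log10 parameter space (Km bounds 0.05–10 mM; rates
and exchange coefficients bounded above at 10⁷/10⁶ with a 10⁻³ floor
standing in for zero) using bounded trust-region least squares, restarted
from one data-driven guess (curve plateaus seed the maximal rates) plus
seeded latin-hypercube draws (default 20 starts). Identical seeds give
identical fits; parameters ending on a bound are flagged, mirroring the
0.05/10 clamps visible in published confidence intervals.

## Model comparison

Least-squares information criteria: `AIC = n·ln(rss/n) + 2k`,
`AICc = AIC + 2k(k+1)/(n−k−1)`, `BIC = n·ln(rss/n) + k·ln(n)`. The AIC,
AICc and F-test columns of the published statistics table reproduce from
the printed residuals with n = 29 and the k vector above (to the precision
allowed by the 2-decimal printed residuals); the printed BIC column does
not follow from this BIC form (nor from the full-likelihood variant) and
is therefore computed but excluded from any numerical reconstruction
claims. Nested pairs are compared by the extra-sum-of-squares F-test; a
richer fit that is no better reports p = 1.

Confidence intervals follow the frozen-parameter scan: one parameter is
displaced from its optimum, all others fixed at their fitted values, until
the F-test (df1 = 1, df2 = n − k) against the optimal fit reaches α. Ends
are located by geometric bracketing and bisection to three significant
digits and clamp at the fitting bounds (flagged). A re-optimizing profile
mode (`reoptimize=True`) is available but off by default, since the
frozen-parameter scan is the documented procedure; it is conservative (it
can only narrow intervals relative to re-optimization — the reported
intervals are lower bounds on the profile-likelihood ones).

## Fixed auxiliary constants and their calibration

The lumped ATP-synthase affinities, the respiration stoichiometry and the
effective exogenous-PK capacity are not identifiable from the packaged
point estimates and are treated as calibration constants of the
reconstruction, configurable on `ParameterSet`:

- `atp_per_o2 = 4.13` — the ratio of the preset maximal synthase rate
  (380 nmol ATP·min⁻¹·mg⁻¹) to the measured maximal ADP-stimulated
  respiration (92 nmol O₂·min⁻¹·mg⁻¹).
- `Km_syn_adp = 0.02 mM`, `Ki_syn_atp = 0.059 mM` — a low intrinsic ADP
  affinity with competitive ATP product inhibition. Both regimes the data
  constrain demand this form: at 2 mM ATP the effective saturation term
  must be ≈ 0.8 mM to reproduce the PK-competition respiration rates,
  while during ADP titrations (low ATP) it must be several-fold smaller so
  that respiration approaches its maximum by 10 mM ADP. A pure
  Michaelis–Menten law in ADP cannot satisfy both.
- `V_pkexo = 465 nmol·min⁻¹·mg⁻¹`, `Km_pkexo_adp = 0.3 mM` — the
  effective competition strength of the added PK, expressed per mg cell
  protein. The nominal activity (20 U/ml at a typical chamber loading)
  would pin solution ADP at essentially zero, which is quantitatively
  inconsistent with the published model solutions for the PK-competition
  stage under any synthase law; assay units at working temperature/pH
  overstate effective activity, so the capacity is calibrated instead.
  Only the ratio V/Km matters in the relevant low-ADP regime.

`Ki_syn_atp` and `V_pkexo` were calibrated once — by least squares on the
published model solutions for the PK-competition stages of variants
2s/2/3s/3/4s — and frozen; they are not adjusted per fit. With these
constants those five variants reproduce their published PK-competition
rates within ±7%, and the C4 flux share at 2 mM ATP evaluates to 39.4%
(4s) / 38.5% (3s), matching the published "about 40%".

Known irreproducible cells: variant 4's published PK-competition
respiration (6.86) and variant 1's (13.44) are not reproduced (4.75 and
18.8 here). Both values require effective synthase saturation far from
what the other five variants demand, implying the original (unpublished)
rate law is not a single competitive-MM form; no global setting of the
auxiliary constants reconciles them without degrading every other variant.

## Synthetic data

The generator emulates the pooled study layout: titration schedules
0.025–2 mM (7 points, ADP assays) and 0.05–2 mM (6 points, ATP assays),
two PK-competition rates and one basal reading — 29 points. Per condition
it draws 7 replicates of `y·(1 + cv·ε)`, ε standard normal truncated at
±3, with cv = 0.22 (the dispersion of the published summary statistics),
and stores the replicate mean and sample sd (floored at 0.1 assay units).
It emulates means and dispersion only: no instrument drift, chamber oxygen
depletion, cell clumping, per-assay noise heterogeneity, or correlated
errors within a titration. Passing recovery/selection tests therefore
demonstrates the estimator and the statistics under the assumed noise
model, not robustness to those real-data artifacts.

## Numerical choices and problem sizes

Default titration schedules and chamber composition are configurable;
basal respiration defaults to 0 for fitting (the basal reading then
anchors nothing) and is supplied by the caller for acceptor-control-style
summaries. Acceptance-style end-to-end checks use 20 synthetic datasets
with 2 optimizer starts per fit and 100+ random parameter draws for the
solver-vs-bisection oracle comparison; noise-free recovery uses 4–6
starts. These sizes were chosen to exercise every code path at desk
scale.

## Limitations

- The exact rate laws and fixed synthase constants of the original
  analysis live in its companion modelling work; the forms here are
  declared reconstructions, calibrated as described above.
- Exchange-coefficient units (per mg protein per mM) are assumed.
- Published point estimates cannot be exactly regenerated because the
  underlying experimental curves are available only as plots; published
  residuals/criteria are reproduced instead, and parameter recovery is
  demonstrated on synthetic data.
- Sodium, potassium, calcium, creatine kinase and time-resolved chamber
  dynamics are out of scope; inhibitor conditions enter only as parameter
  sets.
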
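# Methods

## Cosinor rhythmometry

The core statistic is the classical single-cosinor fit at fixed 24 h
period. The cosine is linearized to `y = M + β·cos(ωt) + γ·sin(ωt)` and
solved by OLS, which handles unequal replication per time point naturally;
observations are never averaged within a time point first, because that
would discard residual degrees of freedom on an already small design.
Amplitude and acrophase follow from the linear coefficients
(`A = √(β²+γ²)`, `φ = atan2(γ,β)/ω mod 24`), with the sign convention that
φ is the clock time of the fitted maximum in hours after lights-on — the
convention used when peak times are reported against the light/dark cycle —
not the negative-radian phase some rhythmometry texts use.

Rhythm detection is the zero-amplitude F-test (full cosinor vs
intercept-only, F(2, n−3)). With the default design (6 time points × 4–5
replicates, 25 observations) the test has 22 residual df. The suite
verifies its type-I error is within [0.04, 0.06] on 5 000 null series with
multiplicative log-normal noise of CV 0.2 — the mild skew of that noise
does not measurably distort the calibration at this df.

Degenerate inputs: an exactly constant series returns A = 0, F = 0, p = 1;
an exact (noiseless) cosine drives RSS below machine tolerance and is
flagged `degenerate` with p = 0 — confidence limits are not meaningful
there and are reported NaN. Confidence limits for M are exact t-intervals;
for A and φ the delta method is the default, with the joint-ellipse
construction for φ (numerically traced over the (β,γ) 95% region) behind a
flag. When the ellipse covers the origin the acrophase is unbounded and
the interval is NaN.

Acrophase display: a study sampling ZT10–ZT30 reports peaks inside its
sampling window, so phases below the window start are shown one period
later (φ = 0.7 displays as ZT24.7). The fit itself always stores φ in
[0, 24).

Times are reduced modulo 24 before fitting; since the period is fixed at
24 h this is exact, and it lets metadata carry monotone clock times across
the dark→light transition (ZT26, ZT30).

## Rhythm screen

Every feature is fitted independently and called rhythmic at raw p < 0.05.
No multiple-testing correction is applied by default — the screen is a
descriptive census, and the downstream candidate filter (top quartile +
precursor support) is the effective error control; a Benjamini–Hochberg
option can be applied by the caller on the returned p column. Quartile
bands use empirical quantiles of per-feature mean expression over all
samples (mean, not total, so unequal replication cannot bias the bands);
boundary ties fall to the lower band, making "above the upper quartile"
strictly greater than Q3. All-zero features are flagged unfittable rather
than fitted.

The D/L ratio divides the mean over samples collected in the dark phase
(ZT mod 24 ∈ [12, 24)) by the mean over light-phase samples; assignment is
by phase of collection. The abundance–ratio regression fits
log(D/L) ~ log(mean expression); a zero-variance response is reported as a
flagged degenerate null rather than an error.

## Strand/precursor atlas

A family is one mature miRNA with up to two arms (5p/3p) and one or more
precursor hairpins/loci. Families are classified on the cross of
{both arms, one arm} × {single locus, multiple loci}, counting only arms
with any nonzero expression; percentages are integer-rounded over families
with at least one expressed arm, and both counts and computed percentages
are always reported together. Mature↔precursor correlation is assessed
only for single-locus families (multi-locus mature series mix several
hairpins' contributions) by an OLS slope test per arm at p < 0.05 on
untransformed relative units; a log1p option exists. The guide strand is
operationalized as the arm with the greater mean expression, with an
explicit annotation override and exact ties reported undetermined —
abundance is the standard operational proxy when annotation-based guide
calls are unavailable.

## Candidate selection and set algebra

A mature miRNA is a candidate when it is rhythmic, above the upper
expression quartile, and at least one linked precursor is rhythmic with
mean expression above the precursor median. For multi-precursor miRNAs
the "any precursor" reading is implemented (the all-precursors variant
would silently drop every multi-copy family whose copies are expressed at
different levels); this is an assumption and is recorded on the evidence
trail. Target genes are unioned per cluster from a validated-interaction
table filtered to a configurable strong-evidence label set (default
`{Functional MTI}`); identifiers can be translated through a user-supplied
two-column map (e.g. rat→human) before lookup, and candidates with no
entry contribute an empty set but are logged. Venn regions are exact set
algebra for 2–3 sets; dark-phase specificity uses the collapsed sets
D = D1 ∪ D2 vs L = L1 ∪ L2. Pathways are retained per cluster when at
least `min_genes` (default 3) of the cluster's genes map to them.

## Cohort statistics

Tumor vs adjacent tissue is compared with the unpaired equal-variance
t-test by default, matching the convention the screen pairs with; because
the samples are in fact paired per patient, `paired=True` and Welch
options exist and the unpaired default is a documented caveat, not an
oversight. Median stratification puts values equal to the median in the
low group. Survival uses the product-limit estimator and the standard
two-group log-rank test (simultaneous risk-set convention for ties), time
origin at surgery; both are delegated to `lifelines`, with an independent
brute-force risk-set enumeration serving as the oracle in the tests.
Five-year follow-up is represented as administrative censoring at 60
months.

The age–expression regression is reported both ways the question can be
posed (tumor expression vs age, or the adjacent/tumor ratio vs age):
`fit_line` is response-agnostic and callers choose the column.

## Synthetic data

The expression generator emulates a colon time course: six time points at
4 h spacing (ZT10–ZT30) with 4 replicates per point and 5 at ZT30 — the
unequal replication is kept on purpose to exercise unbalanced-design
handling. Rhythmic profiles are `mesor·(1 + A_rel·cos(2π(t−φ)/24))` with
multiplicative log-normal noise of CV 0.2 (mean exactly 1). The log-normal
choice reflects that the pipeline consumes normalized relative units, not
raw counts; a count-dispersion mode is out of scope. The per-feature
dispersion of real small-RNA data is not known here, so CV 0.2 is a stated
assumption. Defaults: 10% of families truly rhythmic; acrophases drawn
from cluster weights (0.45, 0.35, 0.20, 0) over D1/D2/L1/L2 — the zero L2
weight mirrors the observed absence of peaks in the late light phase and
is fully configurable; mesors log-normal (μ=3, σ=1.5 on the natural-log
scale) to span the quartile range; relative amplitudes uniform on
[0.3, 0.6]; strand-class fractions 0.54/0.34/0.09/0.03; guide arm a fair
coin with guide:passenger abundance ratio 5; precursor coupled to the
guide arm's noiseless profile with probability 0.89; 3% orphan families
(zero mature arms, expressed precursor).

Coupling is through the *noiseless* temporal profile, so arrhythmic
families (flat profiles) show no mature↔precursor correlation beyond
chance — shared rhythm, not shared measurement noise, is what the atlas
detects. Recovery properties of the coupling are therefore tested at
`frac_rhythmic = 1`.

What the generator does not emulate: count-level sampling noise,
between-animal random effects, batch effects, and correlated noise across
features — passing tests bound estimator behaviour under the stated noise
model, not under every artefact of real sequencing data.

Deterministic census fixtures complement the stochastic generator: the
family-class fixture realises exact class counts, and the
correlation-class fixture builds correlating arms as exact linear
functions of the precursor and non-correlating arms from seeded noise
residualized against the precursor. The residualization pins the in-sample
regression slope at exactly zero; truly independent noise would flip ~5%
of arms per draw and make a fixture with prescribed class counts
irreproducible.

The cohort generator draws ages uniformly, builds the tumor-expression
response `slope·age + intercept` with Gaussian noise whose SD is set
analytically as `σ = |slope|·SD_age·√(1/R² − 1)` so the population
correlation magnitude equals the requested R (a zero slope takes unit
noise, since the correlation is then zero regardless), shifts
adjacent-tissue expression +15 r.u. on average, and assigns exponential
survival by median-split group (monthly hazards 0.03 low / 0.01 high —
low expression fares worse) with censoring at 60 months.

## Problem sizes

The test suite and the acceptance script use 200 replicates for acrophase
recovery, 500 for cohort-slope recovery, 5 000 series for type-I-error
calibration, and 5 000 families for census-convergence checks; these sizes
put Monte-Carlo error comfortably below the tolerances being asserted
while keeping a full run in tens of seconds.

## Known limitations

* Fixed-period fitting only; free-period or multi-component models are
  out of scope, as are rank-based rhythm detectors.
* The F-test assumes homoscedastic Gaussian residuals; heavy-tailed noise
  will inflate its error rate beyond what the log-normal calibration
  check covers.
* The guide-strand call is abundance-based and can disagree with
  annotation-derived calls for near-balanced duplexes.
* Pathway selection is pure set logic; no over-representation statistic
  is computed.
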
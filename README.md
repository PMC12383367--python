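# mirhythm

Rhythm analysis of miRNA expression over the light/dark cycle.

Many microRNAs in peripheral tissues such as the colon oscillate with a
~24 h period, and the phase of that oscillation decides *when* a miRNA's
target genes are repressed. `mirhythm` implements the full analysis chain
for a bulk small-RNA time course sampled against Zeitgeber time (ZT, hours
after lights-on): rhythm detection for every mature and precursor miRNA,
stratification by expression level, grouping by peak time, a census of the
5p/3p-arm and precursor structure of each miRNA family, selection of
high-confidence rhythmic candidates, set algebra over their validated
target genes and pathways, and survival statistics for a tumor cohort
stratified by miRNA expression. A synthetic-data generator with known
ground truth makes every stage testable end to end.

## The model

Each feature is fitted with a **single cosinor** of fixed 24 h period by
ordinary least squares:

```
y(t) = M + β·cos(ωt) + γ·sin(ωt),   ω = 2π/24
     = M + A·cos(ω(t − φ))
```

* **M** — mesor, the rhythm-adjusted mean;
* **A = √(β² + γ²)** — amplitude, half the peak–trough difference (also
  reported relative to the mesor, A/M);
* **φ = atan2(γ, β)/ω mod 24** — acrophase, the peak time in hours after
  lights-on.

Rhythmicity is decided by the **zero-amplitude test**, the F statistic
`F = ((RSS₀ − RSS)/2)/(RSS/(n − 3))` against F(2, n−3), at p < 0.05.
Rhythmic features are clustered by acrophase into D1 (ZT12–18), D2
(ZT18–24), L1 (ZT0–6) and L2 (ZT6–12); candidates for target analysis must
be rhythmic, above the upper expression quartile, and supported by a
rhythmic precursor above the precursor median. Mature↔precursor coupling is
assessed per arm by a regression slope test; survival is compared with the
Kaplan–Meier product-limit estimator and the two-group log-rank test.

## Worked example

```python
>>> import numpy as np
>>> from mirhythm import fit_cosinor, assign_cluster, simulate_rhythmic_series
>>> t, y = simulate_rhythmic_series(acrophase=15.6, rel_amplitude=0.5,
...                                 noise_cv=0.2, rng=np.random.default_rng(1))
>>> fit = fit_cosinor(t, y)
>>> round(fit.acrophase_hours, 2), f"{fit.p_zero_amplitude:.1e}"
(15.45, '1.6e-12')
>>> assign_cluster(fit.acrophase_hours)
'D1'
```

The series was generated with its peak planted in the middle of the dark
phase (ZT15.6) on the unequal time-course design (ZT10–ZT30 every 4 h, 4
replicates per point, 5 at ZT30); the fit recovers the peak at ZT15.45
(0.15 h off, within the noise), rejects the flat model at p ≈ 1.6·10⁻¹²,
and the acrophase falls in the first half of the dark phase (cluster D1).

The same workflow runs from the shell:

```sh
mirhythm simulate --outdir data --seed 3
mirhythm screen --mature data/mature.tsv --pre data/pre.tsv \
                --meta data/meta.tsv --out screened
mirhythm atlas  --mature data/mature.tsv --pre data/pre.tsv \
                --annot data/annotation.tsv --meta data/meta.tsv --out atlas
```

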
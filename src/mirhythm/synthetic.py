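"""Synthetic expression and cohort generators with known ground truth.

The expression generator emulates a rat colon time-series design: sampling
every 4 h across one light/dark cycle (ZT10, 14, 18, 22, 26, 30) with 4
animals per time point and 5 at the last, mature miRNAs organised into
families carrying a 5p and/or 3p arm transcribed from one or several loci,
and precursor hairpins whose temporal profile may be coupled to the guide
arm.  Rhythmic features follow

    x(t) = mesor * (1 + A_rel * cos(2*pi*(t - acrophase)/24)) * eps,

with multiplicative log-normal noise ``eps`` of configured coefficient of
variation (mean exactly 1).  A log-normal noise model is used rather than a
count model because the pipeline consumes normalized relative units, not raw
reads.

The cohort generator emulates a colorectal-cancer patient series: paired
tumor/adjacent expression, an age-linear expression response with noise
calibrated analytically so the population correlation magnitude hits a
requested R, and exponential survival with administrative censoring at 60
months (5-year follow-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cosinor import DesignError
from .io import ExpressionMatrix, validate_annotation, validate_metadata

__all__ = [
    "SimulationConfig",
    "simulate_expression",
    "simulate_cohort",
    "simulate_rhythmic_series",
    "build_census_fixture",
    "build_correlation_fixture",
    "cohort_noise_sd",
]

#: acrophase bins (hours after lights-on) for the four peak-time clusters
CLUSTER_BINS = {"D1": (12.0, 18.0), "D2": (18.0, 24.0), "L1": (0.0, 6.0), "L2": (6.0, 12.0)}

_STRAND_CLASSES = (
    "dual_single_locus",
    "single_single_locus",
    "dual_multi_locus",
    "single_multi_locus",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the expression simulator.

    Defaults reproduce the emulated study's conditions: six time points at
    4 h spacing with unequal replication (n=5 at ZT30), ~10% truly rhythmic
    features, no peaks in the second half of the light phase (the L2 weight
    is zero), mature-class fractions matching the observed strand/locus
    census (54/34/9/3%), and multiplicative noise with CV 0.2 — the assumed
    per-feature dispersion of the normalized data.
    """

    n_families: int = 200
    frac_rhythmic: float = 0.10
    cluster_weights: tuple[float, float, float, float] = (0.45, 0.35, 0.20, 0.0)
    mesor_log_mu: float = 3.0
    mesor_log_sigma: float = 1.5
    rel_amplitude_range: tuple[float, float] = (0.3, 0.6)
    noise_cv: float = 0.2
    timepoints: tuple[float, ...] = (10.0, 14.0, 18.0, 22.0, 26.0, 30.0)
    replicates: tuple[int, ...] = (4, 4, 4, 4, 4, 5)
    frac_dual_strand: float = 0.54
    frac_single_strand: float = 0.34
    frac_dual_multigene: float = 0.09
    frac_single_multigene: float = 0.03
    guide_passenger_ratio: float = 5.0
    p_pre_couples_guide: float = 0.89
    frac_orphan_pre: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.frac_rhythmic,
            self.p_pre_couples_guide,
            self.frac_orphan_pre,
            *self.cluster_weights,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        strand = (
            self.frac_dual_strand,
            self.frac_single_strand,
            self.frac_dual_multigene,
            self.frac_single_multigene,
        )
        if any(not 0 <= p <= 1 for p in strand):
            raise ValueError("strand fractions must lie in [0, 1]")
        if abs(sum(strand) - 1.0) > 1e-9:
            raise ValueError(f"strand fractions must sum to 1, got {sum(strand)}")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        lo, hi = self.rel_amplitude_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("rel_amplitude_range must be within (0, 1]")
        if len(self.timepoints) != len(self.replicates):
            raise ValueError("timepoints and replicates lengths differ")
        if self.frac_rhythmic > 0 and len(set(self.timepoints)) < 4:
            raise DesignError(
                "rhythmic simulation needs >= 4 distinct time points for the "
                "cosinor to retain residual df"
            )

    @property
    def strand_fractions(self) -> tuple[float, float, float, float]:
        return (
            self.frac_dual_strand,
            self.frac_single_strand,
            self.frac_dual_multigene,
            self.frac_single_multigene,
        )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    # log-normal factor with E = 1 and SD/E = cv
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def _profile(mesor: float, rel_amp: float, acrophase: float, t: np.ndarray) -> np.ndarray:
    return mesor * (1.0 + rel_amp * np.cos(2 * math.pi * (t - acrophase) / 24.0))


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (mature, pre, annotation, metadata, truth) for one design.

    Per family: a strand/locus class is drawn from the configured fractions;
    the guide arm is a fair coin between 5p and 3p; the passenger arm (dual
    families) is the guide scaled down by ``guide_passenger_ratio``.  With
    probability ``p_pre_couples_guide`` each precursor shares the guide
    arm's noiseless temporal profile (rescaled to its own mesor); otherwise
    it is tonic at its own mesor.  Orphan families carry exactly-zero mature
    arms with an expressed precursor.  Identical configs (including seed)
    give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    t = np.repeat(
        np.asarray(config.timepoints, dtype=float),
        np.asarray(config.replicates, dtype=int),
    )
    sample_ids = []
    for zt, nrep in zip(config.timepoints, config.replicates):
        sample_ids.extend(f"ZT{zt:g}_r{i + 1}" for i in range(nrep))
    meta = validate_metadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "zt_hours": t,
                "replicate": [int(s.rsplit("r", 1)[1]) for s in sample_ids],
                "group": "timecourse",
            }
        )
    )

    cluster_names = tuple(CLUSTER_BINS)
    cw = np.asarray(config.cluster_weights, dtype=float)
    cw = cw / cw.sum()

    mature_rows: dict[str, np.ndarray] = {}
    pre_rows: dict[str, np.ndarray] = {}
    ann_records = []
    truth_records = []

    for i in range(config.n_families):
        fam = f"fam{i:04d}"
        strand_class = rng.choice(_STRAND_CLASSES, p=config.strand_fractions)
        dual = strand_class.startswith("dual")
        multi = strand_class.endswith("multi_locus")
        n_loci = int(rng.integers(2, 4)) if multi else 1
        guide = "5p" if rng.random() < 0.5 else "3p"
        arms = ("5p", "3p") if dual else (guide,)
        orphan = rng.random() < config.frac_orphan_pre

        rhythmic = (not orphan) and rng.random() < config.frac_rhythmic
        if rhythmic:
            cluster = rng.choice(cluster_names, p=cw)
            lo, hi = CLUSTER_BINS[cluster]
            acro = float(rng.uniform(lo, hi))
            a_lo, a_hi = config.rel_amplitude_range
            rel_amp = float(rng.uniform(a_lo, a_hi))
        else:
            acro, rel_amp = 0.0, 0.0

        guide_mesor = float(rng.lognormal(config.mesor_log_mu, config.mesor_log_sigma))
        precursors = [f"pre-{fam}-{j + 1}" for j in range(n_loci)]
        loci = [f"locus-{fam}-{j + 1}" for j in range(n_loci)]

        for arm in arms:
            mid = f"{fam}-{arm}"
            mesor = guide_mesor if arm == guide else guide_mesor / config.guide_passenger_ratio
            if orphan:
                series = np.zeros_like(t)
            else:
                series = _profile(mesor, rel_amp, acro, t) * _lognormal_noise(
                    rng, config.noise_cv, t.size
                )
            mature_rows[mid] = series
            for pre_id, locus in zip(precursors, loci):
                ann_records.append(
                    {"mature_id": mid, "arm": arm, "precursor_id": pre_id, "locus_id": locus}
                )
            truth_records.append(
                {
                    "feature_id": mid,
                    "family_id": fam,
                    "arm": arm,
                    "true_mesor": 0.0 if orphan else mesor,
                    "true_rel_amplitude": rel_amp if rhythmic else 0.0,
                    "true_acrophase": acro if rhythmic else math.nan,
                    "rhythmic": rhythmic,
                    "strand_class": strand_class,
                    "guide_arm": guide,
                    "orphan": orphan,
                }
            )

        for pre_id in precursors:
            pre_mesor = float(
                rng.lognormal(config.mesor_log_mu - 1.0, config.mesor_log_sigma)
            )
            coupled = (not orphan) and rng.random() < config.p_pre_couples_guide
            if coupled:
                noiseless = _profile(pre_mesor, rel_amp, acro, t)
            else:
                noiseless = np.full_like(t, pre_mesor)
            pre_rows[pre_id] = noiseless * _lognormal_noise(rng, config.noise_cv, t.size)
            truth_records.append(
                {
                    "feature_id": pre_id,
                    "family_id": fam,
                    "arm": "pre",
                    "true_mesor": pre_mesor,
                    "true_rel_amplitude": rel_amp if (coupled and rhythmic) else 0.0,
                    "true_acrophase": acro if (coupled and rhythmic) else math.nan,
                    "rhythmic": bool(coupled and rhythmic),
                    "strand_class": strand_class,
                    "guide_arm": guide,
                    "orphan": orphan,
                    "pre_coupled": coupled,
                }
            )

    mature = ExpressionMatrix(
        pd.DataFrame(mature_rows, index=sample_ids).T.set_axis(sample_ids, axis=1)
    )
    pre = ExpressionMatrix(
        pd.DataFrame(pre_rows, index=sample_ids).T.set_axis(sample_ids, axis=1)
    )
    annotation = validate_annotation(pd.DataFrame(ann_records))
    truth = pd.DataFrame(truth_records)
    if "pre_coupled" not in truth.columns:
        truth["pre_coupled"] = False
    truth["pre_coupled"] = truth["pre_coupled"].map(lambda v: bool(v) if v == v else False)
    return mature, pre, annotation, meta, truth


def simulate_rhythmic_series(
    acrophase: float,
    rel_amplitude: float = 0.5,
    noise_cv: float = 0.2,
    mesor: float = 100.0,
    timepoints=(10.0, 14.0, 18.0, 22.0, 26.0, 30.0),
    replicates=(4, 4, 4, 4, 4, 5),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One rhythmic series at the study design; returns (times, values).

    The noiseless profile is ``mesor*(1 + rel_amplitude*cos(2*pi*(t -
    acrophase)/24))`` sampled at each (timepoint, replicate), multiplied by
    log-normal noise of the given CV.
    """
    if rng is None:
        rng = np.random.default_rng()
    t = np.repeat(np.asarray(timepoints, dtype=float), np.asarray(replicates, int))
    y = _profile(mesor, rel_amplitude, acrophase, t) * _lognormal_noise(
        rng, noise_cv, t.size
    )
    return t, y


def build_census_fixture(
    class_counts: dict[str, int] | None = None, seed: int = 0
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Annotation + mature matrix realising given strand/locus class counts.

    ``class_counts`` maps each of the four mature classes to the number of
    families to construct (default: the emulated study's census,
    199/126/35/11).  Every constructed arm gets positive expression over a
    minimal 4-sample design, so ``classify_families`` recovers the counts
    exactly.
    """
    if class_counts is None:
        class_counts = {
            "dual_single_locus": 199,
            "single_single_locus": 126,
            "dual_multi_locus": 35,
            "single_multi_locus": 11,
        }
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1}" for i in range(4)]
    ann_records, rows = [], {}
    idx = 0
    for cls, n in class_counts.items():
        dual = cls.startswith("dual")
        multi = cls.endswith("multi_locus")
        for _ in range(n):
            fam = f"fix{idx:04d}"
            idx += 1
            n_loci = 2 if multi else 1
            arms = ("5p", "3p") if dual else (("5p",) if rng.random() < 0.5 else ("3p",))
            for arm in arms:
                mid = f"{fam}-{arm}"
                rows[mid] = rng.uniform(1.0, 100.0, size=4)
                for j in range(n_loci):
                    ann_records.append(
                        {
                            "mature_id": mid,
                            "arm": arm,
                            "precursor_id": f"pre-{fam}-{j + 1}",
                            "locus_id": f"locus-{fam}-{j + 1}",
                        }
                    )
    annotation = validate_annotation(pd.DataFrame(ann_records))
    mature = ExpressionMatrix(pd.DataFrame(rows, index=samples).T)
    return annotation, mature


def _orthogonal_noise(rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
    """Positive noise series with exactly zero in-sample regression slope on x.

    Seeded noise is residualized against x (and the intercept), which pins
    the sample regression slope at zero; with truly independent noise a
    ~5% false-positive rate per arm would otherwise blur a constructed
    correlation-class fixture.
    """
    n = rng.lognormal(3.0, 0.5, size=x.size)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, n, rcond=None)
    resid = n - design @ coef
    return resid - resid.min() + 1.0


def build_correlation_fixture(
    class_counts: dict[str, int] | None = None,
    seed: int = 0,
    timepoints=(10.0, 14.0, 18.0, 22.0, 26.0, 30.0),
    replicates=(4, 4, 4, 4, 4, 5),
) -> tuple[pd.DataFrame, ExpressionMatrix, ExpressionMatrix]:
    """Single-locus dual-arm families with constructed correlation classes.

    ``class_counts`` maps {both, 5p_only, 3p_only, neither} to family counts
    (default: the emulated study's 26/77/74/22).  Correlating arms are exact
    linear functions of the precursor; non-correlating arms use seeded noise
    made exactly orthogonal to the precursor in-sample, so the classifier
    reproduces the construction deterministically at any alpha.
    """
    if class_counts is None:
        class_counts = {"both": 26, "5p_only": 77, "3p_only": 74, "neither": 22}
    rng = np.random.default_rng(seed)
    t = np.repeat(np.asarray(timepoints, dtype=float), np.asarray(replicates, int))
    samples = []
    for zt, nrep in zip(timepoints, replicates):
        samples.extend(f"ZT{zt:g}_r{i + 1}" for i in range(nrep))
    ann_records, mature_rows, pre_rows = [], {}, {}
    idx = 0
    for cls, n in class_counts.items():
        for _ in range(n):
            fam = f"corr{idx:04d}"
            idx += 1
            pre_id = f"pre-{fam}-1"
            x = rng.lognormal(3.0, 0.6, size=t.size)
            pre_rows[pre_id] = x
            for arm in ("5p", "3p"):
                correlating = cls == "both" or cls == f"{arm}_only"
                if correlating:
                    series = rng.uniform(0.5, 3.0) * x
                else:
                    series = _orthogonal_noise(rng, x)
                mid = f"{fam}-{arm}"
                mature_rows[mid] = series
                ann_records.append(
                    {
                        "mature_id": mid,
                        "arm": arm,
                        "precursor_id": pre_id,
                        "locus_id": f"locus-{fam}-1",
                    }
                )
    annotation = validate_annotation(pd.DataFrame(ann_records))
    mature = ExpressionMatrix(pd.DataFrame(mature_rows, index=samples).T)
    pre = ExpressionMatrix(pd.DataFrame(pre_rows, index=samples).T)
    return annotation, mature, pre


def cohort_noise_sd(slope: float, age_low: float, age_high: float, target_r: float) -> float:
    """Noise SD giving population |corr(age, response)| = target_r.

    With ages uniform on [age_low, age_high] (SD = range/sqrt(12)) and
    response = slope*age + noise,  R^2 = s^2 V / (s^2 V + sigma^2), so
    sigma = |slope| * SD_age * sqrt(1/R^2 - 1).
    """
    sd_age = (age_high - age_low) / math.sqrt(12.0)
    if sd_age == 0:
        raise ValueError("zero age variance: target correlation is infeasible")
    if not 0 < target_r < 1:
        raise ValueError("target_R must lie strictly inside (0, 1)")
    return abs(slope) * sd_age * math.sqrt(1.0 / (target_r * target_r) - 1.0)


def simulate_cohort(
    n_patients: int = 47,
    age_range: tuple[float, float] = (37.0, 86.0),
    slope: float = -1.163,
    intercept: float = 72.265,
    target_R: float = 0.301,
    survival_hazard_by_group: dict[str, float] | None = None,
    seed: int = 0,
    adjacent_shift: float = 15.0,
    censor_months: float = 60.0,
) -> pd.DataFrame:
    """Generate a patient cohort with an age-linear tumor-expression response.

    Ages are uniform over ``age_range``; tumor expression follows
    ``slope*age + intercept`` plus Gaussian noise whose SD is set
    analytically so the population correlation magnitude equals
    ``target_R``.  Adjacent-tissue expression sits ``adjacent_shift`` r.u.
    above the tumor value on average (expression is lower in tumor).
    Patients are split at the median tumor expression into ``low``/``high``
    groups; survival is exponential with the group's monthly hazard and
    administratively censored at ``censor_months``.
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    if survival_hazard_by_group is None:
        survival_hazard_by_group = {"low": 0.030, "high": 0.010}
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    # slope 0 makes the population correlation 0 for any noise level; unit
    # noise is used since no SD can then be derived from target_R
    sigma = 1.0 if slope == 0 else cohort_noise_sd(slope, lo, hi, target_R)
    ages = rng.uniform(lo, hi, size=n_patients)
    expr_tumor = slope * ages + intercept + rng.normal(0.0, sigma, size=n_patients)
    expr_adjacent = expr_tumor + adjacent_shift + rng.normal(
        0.0, sigma / 2.0, size=n_patients
    )
    cry1_tumor = 50.0 - 0.4 * expr_tumor + rng.normal(0.0, sigma / 2.0, size=n_patients)

    median = float(np.median(expr_tumor))
    group = np.where(expr_tumor <= median, "low", "high")
    hazards = np.array([survival_hazard_by_group[g] for g in group])
    raw_times = rng.exponential(1.0 / hazards)
    survival = np.minimum(raw_times, censor_months)
    event = np.where(raw_times <= censor_months, "death", "censored")

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n_patients)],
            "age": ages,
            "expr_tumor": expr_tumor,
            "expr_adjacent": expr_adjacent,
            "cry1_tumor": cry1_tumor,
            "group": group,
            "survival_months": survival,
            "event": event,
        }
    )
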
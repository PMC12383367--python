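"""Genome-wide rhythm screen: cosinor per feature, quartile stratification,
acrophase clusters, dark/light ratios and the abundance-ratio regression.

Features are binned by the quartiles of their mean expression over all
samples ("above the upper quartile" means strictly greater than Q3; boundary
ties fall to the lower band).  The acrophase clusters partition the 24 h
cycle into half-phases of the light/dark cycle: D1 = ZT12-18, D2 = ZT18-24,
L1 = ZT0-6, L2 = ZT6-12.  The D/L ratio is the mean over dark-phase samples
(collection ZT mod 24 in [12, 24)) divided by the mean over light-phase
samples.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import CosinorFit, DesignError, fit_cosinor
from .io import ExpressionMatrix

__all__ = [
    "assign_cluster",
    "dl_ratio",
    "screen",
    "quartile_summary",
    "abundance_ratio_regression",
    "heatmap_normalize",
    "QUARTILE_BANDS",
]

QUARTILE_BANDS = ("0-25", "25-50", "50-75", "75-100")


def assign_cluster(phi: float) -> str:
    """Acrophase -> cluster label over half-open bins partitioning [0, 24)."""
    if not 0 <= phi < 24:
        raise ValueError(f"acrophase must be in [0, 24), got {phi}")
    if 12 <= phi < 18:
        return "D1"
    if 18 <= phi < 24:
        return "D2"
    if phi < 6:
        return "L1"
    return "L2"


def dl_ratio(values, zt_hours) -> float:
    """Mean dark-phase over mean light-phase expression for one feature.

    Samples are assigned by collection phase: ZT mod 24 in [12, 24) is dark.
    Returns NaN when the light-phase mean is zero (undefined ratio).
    """
    v = np.asarray(values, dtype=float)
    zt = np.mod(np.asarray(zt_hours, dtype=float), 24.0)
    dark = (zt >= 12.0) & (zt < 24.0)
    if not dark.any() or dark.all():
        raise ValueError("need at least one sample in each of the D and L phases")
    light_mean = v[~dark].mean()
    if light_mean == 0:
        return math.nan
    return float(v[dark].mean() / light_mean)


def _quartile_band(mean_expr: np.ndarray) -> list[str]:
    q1, q2, q3 = np.quantile(mean_expr, [0.25, 0.50, 0.75])
    bands = []
    for m in mean_expr:
        if m <= q1:
            bands.append("0-25")
        elif m <= q2:
            bands.append("25-50")
        elif m <= q3:
            bands.append("50-75")
        else:
            bands.append("75-100")
    return bands


def screen(matrix: ExpressionMatrix, meta: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Cosinor-screen every feature of *matrix* against the design in *meta*.

    Returns one row per feature with the fit parameters, the rhythmic
    verdict at ``p < alpha``, the acrophase cluster (``none`` for
    arrhythmic features), the expression quartile band and the D/L ratio.
    All-zero features are flagged unfittable and excluded from the verdict.
    Rows are sorted by mean expression descending within quartile band.
    """
    zt = meta.set_index("sample_id").loc[matrix.sample_ids, "zt_hours"].to_numpy(float)
    if np.unique(np.round(np.mod(zt, 24.0), 9)).size < 3:
        raise DesignError("screen needs >= 3 distinct ZT phases")
    records = []
    for fid in matrix.feature_ids:
        y = matrix.feature(fid)
        mean_expr = float(y.mean())
        rec = {
            "feature_id": fid,
            "mean_expr": mean_expr,
            "unfittable": False,
            "mesor": math.nan,
            "amplitude": math.nan,
            "relative_amplitude": math.nan,
            "acrophase": math.nan,
            "p": math.nan,
            "rhythmic": False,
            "cluster": "none",
            "dl_ratio": math.nan,
        }
        if np.all(y == 0):
            rec["unfittable"] = True
        else:
            fit = fit_cosinor(np.mod(zt, 24.0), y)
            rec.update(
                mesor=fit.mesor,
                amplitude=fit.amplitude,
                relative_amplitude=fit.relative_amplitude,
                acrophase=fit.acrophase_hours,
                p=fit.p_zero_amplitude,
                rhythmic=fit.p_zero_amplitude < alpha,
            )
            if rec["rhythmic"]:
                rec["cluster"] = assign_cluster(fit.acrophase_hours)
            rec["dl_ratio"] = dl_ratio(y, zt)
        records.append(rec)
    rows = pd.DataFrame(records)
    rows["quartile_band"] = _quartile_band(rows["mean_expr"].to_numpy())
    band_order = {b: i for i, b in enumerate(QUARTILE_BANDS[::-1])}
    rows = rows.sort_values(
        ["quartile_band", "mean_expr"],
        ascending=[True, False],
        key=lambda s: s.map(band_order) if s.name == "quartile_band" else s,
    ).reset_index(drop=True)
    return rows


def quartile_summary(rows: pd.DataFrame, total_features: int | None = None) -> pd.DataFrame:
    """Count of rhythmic features per quartile band, plus percent of all
    detected features (the convention of the rhythm-screen summary tables)."""
    if total_features is None:
        total_features = len(rows)
    out = []
    for band in QUARTILE_BANDS[::-1]:
        n_rhythmic = int(((rows["quartile_band"] == band) & rows["rhythmic"]).sum())
        out.append(
            {
                "quartile_band": band,
                "n_rhythmic": n_rhythmic,
                "pct_of_all_features": 100.0 * n_rhythmic / total_features,
            }
        )
    return pd.DataFrame(out)


def abundance_ratio_regression(rows: pd.DataFrame) -> dict:
    """OLS of log(D/L ratio) on log(mean expression) across screen rows.

    Mirrors the tonic-expression analysis: a negative slope means the most
    abundant features tend to be expressed tonically (ratio near 1) while
    low-abundance features swing more.  Requires >= 3 rows with a defined,
    positive ratio and positive mean expression.
    """
    ok = rows[
        rows["dl_ratio"].notna()
        & (rows["dl_ratio"] > 0)
        & (rows["mean_expr"] > 0)
    ]
    if len(ok) < 3:
        raise ValueError(f"need >= 3 usable rows, got {len(ok)}")
    x = np.log(ok["mean_expr"].to_numpy(float))
    y = np.log(ok["dl_ratio"].to_numpy(float))
    if np.allclose(y, y[0]):
        return {"slope": 0.0, "r": 0.0, "p": math.nan, "n": len(ok), "degenerate": True}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "n": len(ok),
        "degenerate": False,
    }


def heatmap_normalize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-feature min-max scaling to [0, 1] — display convention only,
    never used in any statistic."""
    df = matrix.data.astype(float)
    lo = df.min(axis=1)
    span = df.max(axis=1) - lo
    span = span.replace(0, np.nan)
    return df.sub(lo, axis=0).div(span, axis=0).fillna(0.0)
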
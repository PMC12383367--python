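"""Single-cosinor rhythmometry with a fixed period.

The model is the classical linearized single cosinor

    y(t) = M + beta * cos(omega * t) + gamma * sin(omega * t),    omega = 2*pi/period

fitted by ordinary least squares.  The rhythm parameters follow from the
linear coefficients: amplitude ``A = sqrt(beta**2 + gamma**2)`` (half the
peak-trough difference), mesor ``M`` (rhythm-adjusted mean), and acrophase
``phi = atan2(gamma, beta) / omega  (mod period)`` so the fitted curve equals
``M + A*cos(omega*(t - phi))`` and peaks at ``t = phi`` hours after lights-on.

Rhythmicity is declared by the zero-amplitude test: the F statistic
comparing the full cosinor against the intercept-only model,

    F = ((RSS_reduced - RSS_full) / 2) / (RSS_full / (n - 3)),

referred to F(2, n-3).  Unequal replication across time points is handled
naturally by OLS; observations are never averaged within a time point first,
which would discard residual degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DesignError",
    "CosinorFit",
    "fit_cosinor",
    "acrophase_display",
    "circular_mean_hours",
]

#: residual sums of squares below this are treated as an exact (noiseless) fit
_RSS_TOL = 1e-12


class DesignError(ValueError):
    """The sampling design cannot support a cosinor fit."""


@dataclass(frozen=True)
class CosinorFit:
    """Result of a single-cosinor fit at fixed period.

    ``mesor`` and ``amplitude`` are in the data's expression units;
    ``acrophase_hours`` is in [0, period) hours after lights-on.
    ``degenerate`` flags an exact fit (residuals at machine tolerance),
    where the F test and the confidence limits are not meaningful.
    """

    mesor: float
    amplitude: float
    relative_amplitude: float
    acrophase_hours: float
    beta: float
    gamma: float
    n: int
    rss_full: float
    rss_reduced: float
    f_statistic: float
    p_zero_amplitude: float
    ci_mesor: tuple[float, float]
    ci_amplitude: tuple[float, float]
    ci_acrophase: tuple[float, float]
    period: float = 24.0
    degenerate: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        omega = 2 * math.pi / self.period
        return self.mesor + self.amplitude * np.cos(
            omega * (np.asarray(t, dtype=float) - self.acrophase_hours)
        )


def _acrophase_ci_ellipse(
    beta: float, gamma: float, cov_bg: np.ndarray, dfree: int, omega: float
) -> tuple[float, float]:
    """Acrophase limits from the joint 95% confidence ellipse of (beta, gamma).

    The ellipse {(b, g) : (b-beta, g-gamma)' C^-1 (b-beta, g-gamma) <= 2 F}
    is traced numerically; if it contains the origin the acrophase is
    unbounded and (nan, nan) is returned.
    """
    f_crit = stats.f.ppf(0.95, 2, dfree)
    try:
        cinv = np.linalg.inv(cov_bg)
    except np.linalg.LinAlgError:
        return (math.nan, math.nan)
    center = np.array([beta, gamma])
    if center @ cinv @ center <= 2 * f_crit:
        return (math.nan, math.nan)
    # boundary: center + sqrt(2 F) * L u, with C = L L'
    chol = np.linalg.cholesky(cov_bg)
    theta = np.linspace(0, 2 * math.pi, 3600, endpoint=False)
    pts = center[:, None] + math.sqrt(2 * f_crit) * (
        chol @ np.vstack([np.cos(theta), np.sin(theta)])
    )
    phis = np.arctan2(pts[1], pts[0]) / omega
    # widest contiguous arc around the point estimate, on the circle
    phi_hat = math.atan2(gamma, beta) / omega
    period = 2 * math.pi / omega
    delta = (phis - phi_hat + period / 2) % period - period / 2
    return (phi_hat + delta.min()) % period, (phi_hat + delta.max()) % period


def fit_cosinor(
    times,
    values,
    period: float = 24.0,
    acrophase_ci_method: str = "delta",
) -> CosinorFit:
    """Fit a single cosinor of fixed *period* (hours) by OLS.

    Parameters
    ----------
    times, values
        Sampling times in hours and the matching observations.  At least 4
        observations spanning >= 3 distinct phases (times modulo the period)
        are required for the zero-amplitude test to have residual df.
    period
        Fixed period in hours; 24 throughout this pipeline.
    acrophase_ci_method
        ``"delta"`` (default) for the delta-method interval, ``"ellipse"``
        for limits from the joint confidence region of the linear
        coefficients.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and of equal length")
    n = t.size
    if n < 4:
        raise DesignError(f"cosinor needs >= 4 observations, got {n}")
    if not np.isfinite(y).all() or not np.isfinite(t).all():
        raise ValueError("non-finite value in cosinor input")
    phases = np.round(np.mod(t, period), 9)
    if np.unique(phases).size < 3:
        raise DesignError(
            "times collapse to fewer than 3 distinct phases modulo the period"
        )

    omega = 2 * math.pi / period
    design = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise DesignError("rank-deficient cosinor design")
    mesor, beta, gamma = (float(c) for c in coef)
    resid = y - design @ coef
    rss_full = float(resid @ resid)
    rss_reduced = float(np.sum((y - y.mean()) ** 2))

    amplitude = math.hypot(beta, gamma)
    acrophase = (math.atan2(gamma, beta) / omega) % period
    rel_amplitude = amplitude / mesor if mesor != 0 else math.inf

    dfree = n - 3
    scale = max(1.0, float(np.mean(y * y)))
    degenerate = rss_full <= _RSS_TOL * scale
    if degenerate:
        if rss_reduced - rss_full <= _RSS_TOL * scale:
            f_stat, p = 0.0, 1.0  # exactly constant series
        else:
            f_stat, p = math.inf, 0.0  # exact cosine, residuals at tolerance
        nanci = (math.nan, math.nan)
        return CosinorFit(
            mesor, amplitude, rel_amplitude, acrophase, beta, gamma, n,
            rss_full, rss_reduced, f_stat, p, nanci, nanci, nanci,
            period=period, degenerate=True,
        )

    f_stat = ((rss_reduced - rss_full) / 2.0) / (rss_full / dfree)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, 2, dfree))

    sigma2 = rss_full / dfree
    cov = sigma2 * np.linalg.inv(design.T @ design)
    tcrit = stats.t.ppf(0.975, dfree)
    se_mesor = math.sqrt(cov[0, 0])
    ci_mesor = (mesor - tcrit * se_mesor, mesor + tcrit * se_mesor)

    if amplitude > 0:
        grad_a = np.array([beta, gamma]) / amplitude
        se_amp = math.sqrt(grad_a @ cov[1:, 1:] @ grad_a)
        ci_amp = (amplitude - tcrit * se_amp, amplitude + tcrit * se_amp)
        grad_phi = np.array([-gamma, beta]) / (amplitude**2 * omega)
        se_phi = math.sqrt(grad_phi @ cov[1:, 1:] @ grad_phi)
        if acrophase_ci_method == "ellipse":
            ci_phi = _acrophase_ci_ellipse(beta, gamma, cov[1:, 1:], dfree, omega)
        else:
            ci_phi = (acrophase - tcrit * se_phi, acrophase + tcrit * se_phi)
    else:
        ci_amp = (math.nan, math.nan)
        ci_phi = (math.nan, math.nan)

    return CosinorFit(
        mesor, amplitude, rel_amplitude, acrophase, beta, gamma, n,
        rss_full, rss_reduced, f_stat, p, ci_mesor, ci_amp, ci_phi,
        period=period,
    )


def acrophase_display(phi: float, window_start: float = 10.0) -> float:
    """Map an acrophase in [0, 24) into the sampling window convention.

    A study sampling ZT10..ZT30 reports peaks inside that window, so a phase
    earlier than lights-on + ``window_start`` is shown one period later
    (e.g. phi = 0.7 displays as ZT24.7).  Result lies in
    [window_start, window_start + 24).
    """
    if not 0 <= phi < 24:
        raise ValueError(f"acrophase must be in [0, 24), got {phi}")
    return phi if phi >= window_start else phi + 24.0


def circular_mean_hours(phis, period: float = 24.0) -> float:
    """Circular mean of phase values in hours, returned in [0, period)."""
    ang = 2 * math.pi * np.asarray(phis, dtype=float) / period
    mean_ang = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
    out = (mean_ang * period / (2 * math.pi)) % period
    return 0.0 if out >= period else out  # guard the fmod rounding edge
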
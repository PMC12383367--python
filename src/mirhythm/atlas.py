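"""Strand/precursor census of mature miRNA families.

A *family* is one mature miRNA: up to two arms (5p/3p) cleaved from one or
several precursor hairpins, each encoded at one or several genomic loci.
The census classifies every family by which arms are expressed and how many
loci encode it, relates each arm's expression to its precursor by linear
regression, assigns the guide strand by relative abundance, and tabulates
where correlating arms sit in the expression-quartile distribution.

Correlation between a mature arm and its precursor is only assessed for
families encoded at a single locus (the mature series would otherwise mix
several hairpins' contributions), by an OLS slope test at ``p < alpha`` on
untransformed relative units; a log-scale option is available.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .screen import QUARTILE_BANDS, _quartile_band

__all__ = [
    "family_table",
    "classify_families",
    "classify_precursors",
    "correlate_mature_pre",
    "correlation_census",
    "assign_guide",
    "correlating_share_by_quartile",
    "MATURE_CLASSES",
    "CORR_CLASSES",
]

MATURE_CLASSES = (
    "dual_single_locus",
    "single_single_locus",
    "dual_multi_locus",
    "single_multi_locus",
)
CORR_CLASSES = ("both", "5p_only", "3p_only", "neither", "not_applicable")


def _family_id(mature_id: str) -> str:
    for suffix in ("-5p", "-3p"):
        if mature_id.endswith(suffix):
            return mature_id[: -len(suffix)]
    return mature_id


def family_table(annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse the annotation to one row per family: arms, precursors, loci."""
    ann = annotation.copy()
    ann["family_id"] = ann["mature_id"].map(_family_id)
    rows = []
    for fam, grp in ann.groupby("family_id", sort=True):
        arm_of = dict(zip(grp["mature_id"], grp["arm"]))
        mature_ids = tuple(sorted(arm_of))
        rows.append(
            {
                "family_id": fam,
                "arms": tuple(sorted(set(arm_of.values()))),
                "mature_ids": mature_ids,
                "mature_arms": tuple(arm_of[m] for m in mature_ids),
                "precursor_ids": tuple(sorted(grp["precursor_id"].unique())),
                "n_loci": int(grp["locus_id"].nunique()),
            }
        )
    return pd.DataFrame(rows)


def _expressed(matrix: ExpressionMatrix, feature_id: str) -> bool:
    return feature_id in matrix.data.index and bool(
        (matrix.feature(feature_id) > 0).any()
    )


def classify_families(
    annotation: pd.DataFrame, mature: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Classify each family by expressed arms x locus multiplicity.

    Returns ``(families, counts, unannotated)``: the per-family table with a
    ``mature_class`` column, a count/percentage summary over the four
    classes (denominator = families with at least one expressed arm,
    percentages rounded to nearest integer), and matrix features missing
    from the annotation.
    """
    annotated_ids = set(annotation["mature_id"])
    unannotated = [f for f in mature.feature_ids if f not in annotated_ids]

    fams = family_table(annotation)
    classes, expressed_arms = [], []
    for _, row in fams.iterrows():
        arms = tuple(
            sorted(
                {
                    arm
                    for mid, arm in zip(row["mature_ids"], row["mature_arms"])
                    if _expressed(mature, mid)
                }
            )
        )
        expressed_arms.append(arms)
        if not arms:
            classes.append("unexpressed")
            continue
        dual = len(arms) == 2
        multi = row["n_loci"] > 1
        if dual:
            classes.append("dual_multi_locus" if multi else "dual_single_locus")
        else:
            classes.append("single_multi_locus" if multi else "single_single_locus")
    fams["expressed_arms"] = expressed_arms
    fams["mature_class"] = classes

    expressed = fams[fams["mature_class"] != "unexpressed"]
    denom = len(expressed)
    counts = []
    for cls in MATURE_CLASSES:
        n = int((expressed["mature_class"] == cls).sum())
        counts.append(
            {
                "mature_class": cls,
                "count": n,
                "percent": round(100.0 * n / denom) if denom else 0,
            }
        )
    return fams, pd.DataFrame(counts), unannotated


def classify_precursors(
    annotation: pd.DataFrame, mature: ExpressionMatrix, pre: ExpressionMatrix
) -> pd.DataFrame:
    """Sort precursors into single-locus/multi-locus-with-mature vs orphan.

    A precursor is an orphan when no mature arm of its family shows nonzero
    expression.  Returns counts and computed percentages alongside the raw
    classification.
    """
    ann = annotation.copy()
    ann["family_id"] = ann["mature_id"].map(_family_id)
    rows = []
    for pre_id, grp in ann.groupby("precursor_id", sort=True):
        mature_ids = grp["mature_id"].unique()
        has_mature = any(_expressed(mature, m) for m in mature_ids)
        n_loci = int(grp["locus_id"].nunique())
        if not has_mature:
            cls = "orphan"
        elif n_loci > 1:
            cls = "multi_locus_with_mature"
        else:
            cls = "single_locus_with_mature"
        rows.append({"precursor_id": pre_id, "class": cls, "n_loci": n_loci})
    return pd.DataFrame(rows)


def _regress(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Slope-test regression of y on x; zero-variance input -> flagged null."""
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 0.0, 1.0, True
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.pvalue), False


def correlate_mature_pre(
    family_row,
    mature: ExpressionMatrix,
    pre: ExpressionMatrix,
    alpha: float = 0.05,
    log_scale: bool = False,
) -> dict:
    """Correlation class of one single-locus dual-arm family vs its precursor.

    Each arm's expression is regressed on the precursor's across all
    samples; the arm "correlates" when the slope test gives ``p < alpha``.
    ``log_scale`` regresses log1p-transformed values instead.
    """
    if family_row["n_loci"] != 1:
        return {"corr_class": "not_applicable"}
    pre_id = family_row["precursor_ids"][0]
    x = pre.feature(pre_id)
    if log_scale:
        x = np.log1p(x)
    verdicts, detail = {}, {}
    for mid, arm in zip(family_row["mature_ids"], family_row["mature_arms"]):
        y = mature.feature(mid)
        if log_scale:
            y = np.log1p(y)
        r, p, flagged = _regress(x, y)
        verdicts[arm] = (p < alpha) and not flagged
        detail[f"r_{arm}"], detail[f"p_{arm}"] = r, p
    if set(verdicts) != {"5p", "3p"}:
        return {"corr_class": "not_applicable", **detail}
    if verdicts["5p"] and verdicts["3p"]:
        cls = "both"
    elif verdicts["5p"]:
        cls = "5p_only"
    elif verdicts["3p"]:
        cls = "3p_only"
    else:
        cls = "neither"
    return {"corr_class": cls, **detail}


def correlation_census(
    annotation: pd.DataFrame,
    mature: ExpressionMatrix,
    pre: ExpressionMatrix,
    alpha: float = 0.05,
    log_scale: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation classes for every single-locus dual-arm family.

    Returns the per-family table and a summary with class counts, computed
    integer percentages, and the share of families with >= 1 correlating arm.
    """
    fams, _, _ = classify_families(annotation, mature)
    eligible = fams[fams["mature_class"] == "dual_single_locus"]
    records = []
    for _, row in eligible.iterrows():
        res = correlate_mature_pre(row, mature, pre, alpha=alpha, log_scale=log_scale)
        records.append({"family_id": row["family_id"], **res})
    table = pd.DataFrame(records)
    n = len(table)
    summary_rows = []
    for cls in ("both", "5p_only", "3p_only", "neither"):
        c = int((table["corr_class"] == cls).sum()) if n else 0
        summary_rows.append(
            {"corr_class": cls, "count": c, "percent": round(100.0 * c / n) if n else 0}
        )
    any_arm = int(table["corr_class"].isin(["both", "5p_only", "3p_only"]).sum()) if n else 0
    summary_rows.append(
        {
            "corr_class": "any_arm",
            "count": any_arm,
            "percent": round(100.0 * any_arm / n) if n else 0,
        }
    )
    return table, pd.DataFrame(summary_rows)


def assign_guide(
    family_row, mature: ExpressionMatrix, annotation_override: str | None = None
) -> str:
    """Guide arm = arm with the greater mean expression; override wins.

    Exact ties are reported ``undetermined``.
    """
    if annotation_override is not None:
        return annotation_override
    means = {}
    for mid, arm in zip(family_row["mature_ids"], family_row["mature_arms"]):
        if mid in mature.data.index:
            means[arm] = float(mature.feature(mid).mean())
    if len(means) < 2:
        return next(iter(means), "undetermined")
    if means["5p"] == means["3p"]:
        return "undetermined"
    return "5p" if means["5p"] > means["3p"] else "3p"


def correlating_share_by_quartile(
    families: pd.DataFrame,
    corr_table: pd.DataFrame,
    mature: ExpressionMatrix,
) -> pd.DataFrame:
    """Counts of correlating families per arm per expression quartile.

    For each arm, the quartile is taken over that arm's mean expression
    across all families carrying the arm; the count in each band is the
    number of families whose arm correlates with its precursor.
    """
    if len(families) < 4:
        raise ValueError("need >= 4 families for a quartile distribution")
    merged = families.merge(corr_table, on="family_id", how="left")
    out = []
    for arm in ("5p", "3p"):
        ids, means, correlates = [], [], []
        for _, row in merged.iterrows():
            mid = next(
                (
                    m
                    for m, a in zip(row["mature_ids"], row["mature_arms"])
                    if a == arm
                ),
                None,
            )
            if mid is None or mid not in mature.data.index:
                continue
            ids.append(row["family_id"])
            means.append(float(mature.feature(mid).mean()))
            cls = row.get("corr_class")
            correlates.append(cls in ("both", f"{arm}_only"))
        if not ids:
            continue
        bands = _quartile_band(np.asarray(means))
        for band in QUARTILE_BANDS:
            n_corr = sum(c for c, b in zip(correlates, bands) if b == band)
            out.append({"arm": arm, "quartile_band": band, "n_correlating": int(n_corr)})
    return pd.DataFrame(out)
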
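"""Read-level and reader-level performance metrics.

Sign conventions (documented prominently, used everywhere downstream):

* treatment effect on error metrics = mean(unassisted) - mean(assisted),
  so positive means AI assistance *improved* (reduced) error;
* treatment effect on AUROC = assisted - unassisted, so positive again
  means improvement.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from hetfx.data_model import StudyBundle

logger = logging.getLogger(__name__)

READ_METRICS = ("abs_error", "signed_error")


class UndefinedMetricError(ValueError):
    """AUROC (or a sensitivity/specificity component) is undefined
    because only one truth class is present."""


def absolute_error(predicted_prob, truth_prob):
    """|predicted - truth| on the 0-100 scale."""
    p = np.asarray(predicted_prob, dtype=float)
    t = np.asarray(truth_prob, dtype=float)
    if np.any((p < 0) | (p > 100)) or np.any((t < 0) | (t > 100)):
        raise ValueError("probabilities must lie in [0, 100]")
    out = np.abs(p - t)
    return float(out) if out.ndim == 0 else out


def signed_error(predicted_prob, truth_prob):
    """predicted - truth; negative values mean underestimation."""
    p = np.asarray(predicted_prob, dtype=float)
    t = np.asarray(truth_prob, dtype=float)
    if np.any((p < 0) | (p > 100)) or np.any((t < 0) | (t > 100)):
        raise ValueError("probabilities must lie in [0, 100]")
    out = p - t
    return float(out) if out.ndim == 0 else out


def auroc(scores, labels) -> float:
    """Empirical AUROC: Mann-Whitney pair probability with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: need both classes")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sensitivity_specificity(predicted_probs, truth_labels, threshold: float = 50.0):
    """(sensitivity, specificity) at the reader-side ``threshold``.

    The positive call is ``predicted >= threshold``. An undefined
    component (no positives / no negatives in truth) is returned as NaN.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(truth_labels, dtype=int)
    calls = p >= threshold
    pos, neg = y == 1, y == 0
    sens = float(calls[pos].mean()) if pos.any() else float("nan")
    spec = float((~calls[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


@dataclasses.dataclass(frozen=True)
class ReaderSummary:
    """Per-reader mean of a metric with its standard error."""

    radiologist_id: str
    scope: str  # a pathology label or "all"
    condition: str  # "unassisted", "assisted" or "effect"
    value: float
    se: float
    n: int
    flagged: bool = False  # se == 0 from degenerate inputs, or n == 1


def _per_read_values(merged: pd.DataFrame, metric: str, reader_threshold: float = 50.0) -> pd.DataFrame:
    """Attach a per-read ``value`` column for a read-level metric.

    ``sens``/``spec`` restrict the rows to the relevant truth class and
    use the 0/1 correctness of the thresholded call, so their reader
    means are the usual sensitivity/specificity proportions.
    """
    if metric in READ_METRICS:
        return merged.assign(value=merged[metric])
    if metric == "sens":
        sub = merged[merged["truth_label"] == 1]
        return sub.assign(value=(sub["predicted_prob"] >= reader_threshold).astype(float))
    if metric == "spec":
        sub = merged[merged["truth_label"] == 0]
        return sub.assign(value=(sub["predicted_prob"] < reader_threshold).astype(float))
    raise ValueError(f"unknown read-level metric {metric!r}")


def _mean_se(values: np.ndarray) -> tuple[float, float, int, bool]:
    n = values.size
    mean = float(values.mean())
    if n < 2:
        return mean, 0.0, n, True
    se = float(values.std(ddof=1) / np.sqrt(n))
    return mean, se, n, se == 0.0


def reader_summaries(
    bundle: StudyBundle,
    metric: str = "abs_error",
    pathology_scope: str = "all",
    reader_threshold: float = 50.0,
) -> pd.DataFrame:
    """Per-reader condition means, standard errors and treatment effects.

    Returns a frame with one row per (reader, condition) where condition
    is ``unassisted``, ``assisted`` or ``effect``. The effect row is
    mean(unassisted) - mean(assisted); its standard error uses the
    independent-samples combination for non-repeated readers and the
    paired per-case difference for repeated readers (clinical-history
    conditions pooled). Readers lacking reads in either condition are
    excluded with a log entry.
    """
    merged = bundle.merged(pathology_scope)
    table = _per_read_values(merged, metric, reader_threshold)
    agg = (
        table.groupby(["radiologist_id", "assisted"])["value"]
        .agg(["mean", "std", "count"])
        .unstack("assisted")
    )
    complete = agg.notna().all(axis=1) if len(agg) else pd.Series(dtype=bool)
    excluded = [str(r) for r in agg.index[~complete]] if len(agg) else []
    agg = agg[complete] if len(agg) else agg
    if excluded:
        logger.info(
            "reader_summaries(%s, %s): excluded %d readers missing a condition",
            metric,
            pathology_scope,
            len(excluded),
        )
    pieces = []
    for cond, code in (("unassisted", 0), ("assisted", 1)):
        if not len(agg):
            continue
        n = agg[("count", code)].to_numpy(dtype=float)
        sd = agg[("std", code)].to_numpy(dtype=float)
        se = np.where(n >= 2, np.nan_to_num(sd) / np.sqrt(np.maximum(n, 1)), 0.0)
        pieces.append(
            pd.DataFrame(
                {
                    "radiologist_id": agg.index.astype(str),
                    "scope": pathology_scope,
                    "condition": cond,
                    "value": agg[("mean", code)].to_numpy(dtype=float),
                    "se": se,
                    "n": n.astype(int),
                    "flagged": (se == 0.0),
                }
            )
        )
    # effect rows: paired per-case differences for the repeated design,
    # independent-samples combination for the non-repeated design
    design_of = table.groupby("radiologist_id")["design"].first()
    if len(agg):
        is_rep = design_of.reindex(agg.index).eq("repeated")
        mean_u = agg[("mean", 0)]
        mean_a = agg[("mean", 1)]
        se_u = pieces[0].set_index(pieces[0]["radiologist_id"])["se"]
        se_a = pieces[1].set_index(pieces[1]["radiologist_id"])["se"]
        eff_value = (mean_u - mean_a).copy()
        eff_se = pd.Series(
            np.sqrt(se_u.to_numpy() ** 2 + se_a.to_numpy() ** 2), index=agg.index
        )
        eff_n = (agg[("count", 0)] + agg[("count", 1)]).astype(int)
        rep_readers = agg.index[is_rep]
        if len(rep_readers):
            rep = table[table["radiologist_id"].isin(rep_readers)]
            per_case = (
                rep.groupby(["radiologist_id", "case_id", "pathology", "assisted"])["value"]
                .mean()
                .unstack("assisted")
            )
            diff = (per_case[0] - per_case[1]).dropna()
            stats_rep = diff.groupby(level="radiologist_id").agg(["mean", "std", "count"])
            eff_value.loc[stats_rep.index] = stats_rep["mean"]
            n_rep = stats_rep["count"].to_numpy(dtype=float)
            eff_se.loc[stats_rep.index] = np.where(
                n_rep >= 2, np.nan_to_num(stats_rep["std"]) / np.sqrt(np.maximum(n_rep, 1)), 0.0
            )
            eff_n.loc[stats_rep.index] = stats_rep["count"].astype(int)
        pieces.append(
            pd.DataFrame(
                {
                    "radiologist_id": agg.index.astype(str),
                    "scope": pathology_scope,
                    "condition": "effect",
                    "value": eff_value.to_numpy(dtype=float),
                    "se": eff_se.to_numpy(dtype=float),
                    "n": eff_n.to_numpy(),
                    "flagged": (eff_se.to_numpy() == 0.0),
                }
            )
        )
    frame = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["radiologist_id", "scope", "condition", "value", "se", "n", "flagged"])
    )
    frame.attrs["excluded_readers"] = excluded
    return frame


def reader_auroc_summaries(
    bundle: StudyBundle,
    pathology_scope: str = "all",
    n_boot: int = 200,
    seed: int = 0,
    per_pathology_average: bool = False,
) -> pd.DataFrame:
    """Per-reader AUROC per condition with a seeded case-level bootstrap SE.

    By default reads are pooled across the scope's pathologies into one
    AUROC per reader and condition; ``per_pathology_average`` averages
    per-pathology AUROCs instead (readers without both classes in a
    pathology skip that pathology). The effect row is assisted minus
    unassisted (improvement convention for AUROC).
    """
    merged = bundle.merged(pathology_scope)
    rng = np.random.default_rng(seed)
    rows = []
    excluded = []

    def _auroc_of(frame: pd.DataFrame) -> float:
        if per_pathology_average:
            vals = []
            for _, sub in frame.groupby("pathology"):
                try:
                    vals.append(auroc(sub["predicted_prob"], sub["truth_label"]))
                except UndefinedMetricError:
                    continue
            if not vals:
                raise UndefinedMetricError("no pathology with both classes")
            return float(np.mean(vals))
        return auroc(frame["predicted_prob"], frame["truth_label"])

    for reader, grp in merged.groupby("radiologist_id", sort=True):
        out = {}
        try:
            for cond, sub in (("unassisted", grp[grp["assisted"] == 0]), ("assisted", grp[grp["assisted"] == 1])):
                point = _auroc_of(sub)
                cases = sub["case_id"].unique()
                boots = []
                for _ in range(n_boot):
                    pick = rng.choice(cases, size=cases.size, replace=True)
                    resampled = sub.set_index("case_id").loc[pick].reset_index()
                    try:
                        boots.append(_auroc_of(resampled))
                    except UndefinedMetricError:
                        continue
                se = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0
                out[cond] = (point, se, len(sub))
        except UndefinedMetricError:
            excluded.append(str(reader))
            continue
        for cond in ("unassisted", "assisted"):
            point, se, n = out[cond]
            rows.append(ReaderSummary(str(reader), pathology_scope, cond, point, se, n, se == 0.0))
        effect = out["assisted"][0] - out["unassisted"][0]
        se = float(np.sqrt(out["assisted"][1] ** 2 + out["unassisted"][1] ** 2))
        rows.append(
            ReaderSummary(
                str(reader), pathology_scope, "effect", effect, se,
                out["assisted"][2] + out["unassisted"][2], se == 0.0,
            )
        )
    frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    frame.attrs["excluded_readers"] = excluded
    return frame


def error_table(bundle: StudyBundle, pathology_scope: str = "all", metric: str = "abs_error") -> pd.DataFrame:
    """Long regression table: one row per read with its error metric.

    Columns: radiologist_id, case_id, pathology, design, assisted, error.
    """
    merged = bundle.merged(pathology_scope)
    return merged[["radiologist_id", "case_id", "pathology", "design", "assisted"]].assign(
        error=merged[metric].to_numpy(dtype=float)
    )
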
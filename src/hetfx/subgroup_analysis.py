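"""Subgroup construction and AI-error bin analyses.

Subgroup splitters: the oracle median split on shrunk per-reader
treatment effects, median splits on single survey characteristics, and
the cross-fitted combined-characteristics model (train on one random
half of readers, score and split the other half, swap, repeat).

Bin analyses assign every read to a bin by its case's AI error
(absolute or signed) and estimate per-bin treatment effects with the
subgroup-specific regression.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from hetfx import regression_core
from hetfx.data_model import StudyBundle
from hetfx.metrics import error_table
from hetfx.regression_core import TestResult

logger = logging.getLogger(__name__)

#: Absolute-error bin edges: [0,20), [20,40), [40,60), [60,80), [80,100].
ABS_ERROR_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
#: Signed-error bins: ten width-20 bins spanning [-100, 100].
SIGNED_ERROR_EDGES = tuple(float(e) for e in range(-100, 101, 20))

LOW, HIGH = "low", "high"


class DegenerateSplitError(ValueError):
    """A split produced an empty group (e.g. all values identical)."""


@dataclasses.dataclass
class SubgroupAssignment:
    groups: pd.Series  # radiologist_id -> group label
    splitter: str
    details: dict = dataclasses.field(default_factory=dict)

    @property
    def group_sizes(self) -> dict:
        return self.groups.value_counts().to_dict()

    def to_dict(self) -> dict:
        return {
            "splitter": self.splitter,
            "group_sizes": {str(k): int(v) for k, v in self.group_sizes.items()},
            "groups": {str(k): str(v) for k, v in self.groups.items()},
            "details": self.details,
        }


@dataclasses.dataclass
class BinnedEffectTable:
    edges: tuple
    labels: list[str]
    table: pd.DataFrame  # bin, te, se, ci_low, ci_high, n
    joint_test: TestResult
    dropped_bins: list[str]

    def to_dict(self) -> dict:
        return {
            "edges": list(self.edges),
            "labels": list(self.labels),
            "table": self.table.to_dict(orient="list"),
            "joint_test": self.joint_test.to_dict(),
            "dropped_bins": list(self.dropped_bins),
        }


def median_split(values: pd.Series, tie_rule: str = "le") -> SubgroupAssignment:
    """Binary split at the median: low group gets values <= median.

    ``tie_rule="lt"`` puts exact-median values into the high group
    instead. All-identical values produce an empty group -> error.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("need at least two readers")
    med = float(np.median(values.to_numpy()))
    if tie_rule == "le":
        low = values <= med
    elif tie_rule == "lt":
        low = values < med
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    groups = pd.Series(np.where(low, LOW, HIGH), index=values.index, name="group")
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise DegenerateSplitError(
            f"median split degenerate at median {med}: one group is empty"
        )
    return SubgroupAssignment(
        groups=groups,
        splitter=f"median({med:.6g}, tie_rule={tie_rule})",
        details={"median": med, "tie_rule": tie_rule},
    )


def oracle_split(shrinkage) -> SubgroupAssignment:
    """Median split on empirical-Bayes-shrunk per-reader treatment effects."""
    assignment = median_split(shrinkage.posterior_means)
    assignment.splitter = "oracle:" + assignment.splitter
    return assignment


def combined_characteristics_split(
    profiles: pd.DataFrame,
    reader_tes: pd.Series,
    seed: int = 0,
    threshold: float | None = None,
) -> SubgroupAssignment:
    """Cross-fitted combined-characteristics split.

    Readers with profiles are randomly halved (seeded). A linear model of
    the mean treatment effect on an intercept plus three binary
    characteristics -- experience <= median years, thoracic subspecialty,
    AI-tool experience -- is fit on one half; its predictions score the
    other half, which is split at the grand median treatment effect
    (``threshold``; defaults to the median of ``reader_tes`` over all
    included readers). Halves are then swapped so every reader is
    assigned. Fitted coefficients from both folds are kept in
    ``details``. A characteristic constant within a training half is
    dropped from that fold's model with a warning.
    """
    prof = profiles.dropna(subset=["years_experience", "thoracic_subspecialty", "ai_experience"])
    prof = prof[prof["radiologist_id"].isin(reader_tes.index)].reset_index(drop=True)
    if len(prof) < 4:
        raise ValueError("need at least four readers with profiles")
    med_years = float(prof["years_experience"].median())
    feats = pd.DataFrame(
        {
            "exp_le_median": (prof["years_experience"] <= med_years).to_numpy(dtype=float),
            "thoracic": prof["thoracic_subspecialty"].to_numpy(dtype=float),
            "ai_experience": prof["ai_experience"].to_numpy(dtype=float),
        },
        index=prof["radiologist_id"].to_numpy(),
    )
    te = reader_tes.loc[feats.index]
    if threshold is None:
        threshold = float(te.median())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(feats))
    half_a = feats.index[order[: len(feats) // 2]]
    half_b = feats.index[order[len(feats) // 2 :]]

    def _fit(train_idx) -> tuple[np.ndarray, list[str]]:
        Xcols, used = [np.ones(len(train_idx))], ["intercept"]
        for col in feats.columns:
            v = feats.loc[train_idx, col].to_numpy()
            if np.unique(v).size < 2:
                logger.warning("combined split: %s constant in training half; dropped", col)
                continue
            Xcols.append(v)
            used.append(col)
        X = np.column_stack(Xcols)
        coefs, *_ = np.linalg.lstsq(X, te.loc[train_idx].to_numpy(), rcond=None)
        return coefs, used

    def _score(test_idx, coefs, used) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(test_idx))] + [feats.loc[test_idx, c].to_numpy() for c in used[1:]]
        )
        return X @ coefs

    groups = pd.Series(index=feats.index, dtype=object)
    folds = []
    for train_idx, test_idx in ((half_a, half_b), (half_b, half_a)):
        coefs, used = _fit(train_idx)
        scores = _score(test_idx, coefs, used)
        groups.loc[test_idx] = np.where(scores <= threshold, LOW, HIGH)
        folds.append({"columns": used, "coefficients": [float(c) for c in coefs]})
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise DegenerateSplitError("combined characteristics split produced one empty group")
    return SubgroupAssignment(
        groups=groups.rename("group"),
        splitter="combined_characteristics",
        details={
            "threshold": threshold,
            "median_years": med_years,
            "seed": seed,
            "folds": folds,
        },
    )


def subgroup_effect_report(
    assignment: SubgroupAssignment,
    bundle_or_table,
    pathology_scope: str = "all",
    shrunk_tes: pd.Series | None = None,
    df_correction: bool = False,
) -> dict:
    """Per-group treatment effects plus heterogeneity tests for one scope.

    Runs the subgroup-specific regression with two-way clustering and the
    Wald joint-equality test; when ``shrunk_tes`` is supplied (the oracle
    split) an unpaired t-test between the groups' shrunk effects is added.
    Reads from readers outside the assignment are dropped.
    """
    table = (
        error_table(bundle_or_table, pathology_scope)
        if isinstance(bundle_or_table, StudyBundle)
        else bundle_or_table
    )
    table = table[table["radiologist_id"].isin(assignment.groups.index)].copy()
    table["subgroup"] = assignment.groups.reindex(table["radiologist_id"]).to_numpy()
    fit = regression_core.subgroup_te_model(table, df_correction=df_correction)
    te_names = [f"treatment:subgroup[{lvl}]" for lvl in fit.extra["levels"]]
    joint = regression_core.wald_joint_equality(fit, te_names)
    report = {
        "scope": pathology_scope,
        "splitter": assignment.splitter,
        "subgroup_tes": fit.extra["subgroup_tes"],
        "joint_test": joint.to_dict(),
        "n_obs": fit.n_obs,
        "n_clusters": fit.n_clusters,
    }
    if shrunk_tes is not None:
        by_group = {
            g: shrunk_tes.reindex(assignment.groups.index[assignment.groups == g]).dropna()
            for g in assignment.groups.unique()
        }
        if set(by_group) == {LOW, HIGH}:
            t = regression_core.unpaired_t_test(by_group[LOW], by_group[HIGH])
            report["shrunk_group_means"] = {g: float(v.mean()) for g, v in by_group.items()}
            report["shrunk_group_difference"] = float(
                by_group[LOW].mean() - by_group[HIGH].mean()
            )
            report["t_test"] = t.to_dict()
    return report


def assign_bins(values: np.ndarray, edges) -> np.ndarray:
    """Left-closed bins with a closed last edge; values outside -> error."""
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    values = np.asarray(values, dtype=float)
    if np.any((values < edges[0]) | (values > edges[-1])):
        raise ValueError("value outside the bin edge span")
    idx = np.digitize(values, edges, right=False) - 1
    idx[values == edges[-1]] = len(edges) - 2
    return idx


def bin_labels(edges) -> list[str]:
    edges = list(edges)
    out = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 2)]
    out.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    return out


def ai_error_bin_analysis(
    bundle: StudyBundle,
    edges=None,
    error_kind: str = "absolute",
    pathology_scope: str = "all",
    df_correction: bool = False,
) -> BinnedEffectTable:
    """Treatment effects by AI-error bin, with a joint equality test.

    Every read is assigned a bin by its case's AI error for that
    pathology; the subgroup-specific regression treats bins as
    subgroups. Bins without reads (or missing a condition) are dropped
    with a note.
    """
    if error_kind == "absolute":
        edges = tuple(edges) if edges is not None else ABS_ERROR_EDGES
        col = "ai_abs_error"
    elif error_kind == "signed":
        edges = tuple(edges) if edges is not None else SIGNED_ERROR_EDGES
        col = "ai_signed_error"
    else:
        raise ValueError(f"unknown error_kind {error_kind!r}")
    merged = bundle.merged(pathology_scope)
    labels = bin_labels(edges)
    idx = assign_bins(merged[col].to_numpy(dtype=float), edges)
    table = merged[["radiologist_id", "case_id", "assisted"]].copy()
    table["error"] = merged["abs_error"].to_numpy(dtype=float)
    table["subgroup"] = pd.Categorical.from_codes(idx, labels)
    cells = pd.crosstab(table["subgroup"], table["assisted"])
    keep = [
        lbl
        for lbl in labels
        if lbl in cells.index and (cells.loc[lbl] > 0).all() and cells.shape[1] == 2
    ]
    dropped = [lbl for lbl in labels if lbl not in keep]
    if dropped:
        logger.info("ai_error_bin_analysis(%s): dropped empty bins %s", error_kind, dropped)
    if len(keep) < 1:
        raise ValueError("no usable bins")
    table = table[table["subgroup"].isin(keep)].copy()
    table["subgroup"] = pd.Categorical(table["subgroup"], categories=keep)
    fit = regression_core.subgroup_te_model(table, df_correction=df_correction)
    te_names = [f"treatment:subgroup[{lvl}]" for lvl in keep]
    if len(keep) >= 2:
        joint = regression_core.wald_joint_equality(fit, te_names)
    else:
        joint = TestResult(0.0, "chi2(0)", 1.0, "single bin: nothing to compare", degenerate=True)
    rows = [
        {
            "bin": lvl,
            "te": fit.extra["subgroup_tes"][lvl]["te"],
            "se": fit.extra["subgroup_tes"][lvl]["se"],
            "ci_low": fit.extra["subgroup_tes"][lvl]["ci_low"],
            "ci_high": fit.extra["subgroup_tes"][lvl]["ci_high"],
            "n": fit.extra["subgroup_tes"][lvl]["n"],
        }
        for lvl in keep
    ]
    return BinnedEffectTable(
        edges=edges,
        labels=keep,
        table=pd.DataFrame(rows),
        joint_test=joint,
        dropped_bins=dropped,
    )


def bin_auroc_table(
    bundle: StudyBundle,
    edges=None,
    pathology_scope: str = "all",
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Per-bin pooled AUROC treatment effects with the binned F-test.

    AUROC per condition is computed over all reads in a bin; standard
    errors come from a seeded case-level bootstrap; a bin whose reads
    lack both truth classes in either condition aborts the analysis
    (AUROC undefined), mirroring the metric's aggregate nature.
    """
    from hetfx.metrics import UndefinedMetricError, auroc

    edges = tuple(edges) if edges is not None else ABS_ERROR_EDGES
    merged = bundle.merged(pathology_scope)
    idx = assign_bins(merged["ai_abs_error"].to_numpy(dtype=float), edges)
    labels = bin_labels(edges)
    merged = merged.assign(bin=pd.Categorical.from_codes(idx, labels))
    rng = np.random.default_rng(seed)
    rows = []
    for lbl in labels:
        sub = merged[merged["bin"] == lbl]
        if not len(sub):
            continue
        point, boot_tes = {}, []
        for cond in (0, 1):
            cc = sub[sub["assisted"] == cond]
            if not len(cc):
                raise UndefinedMetricError(f"bin {lbl}: missing condition {cond}")
            point[cond] = auroc(cc["predicted_prob"], cc["truth_label"])
        cases = sub["case_id"].unique()
        indexed = sub.set_index("case_id")
        for _ in range(n_boot):
            pick = rng.choice(cases, size=cases.size, replace=True)
            re = indexed.loc[pick]
            try:
                te = auroc(
                    re[re["assisted"] == 1]["predicted_prob"], re[re["assisted"] == 1]["truth_label"]
                ) - auroc(
                    re[re["assisted"] == 0]["predicted_prob"], re[re["assisted"] == 0]["truth_label"]
                )
            except UndefinedMetricError:
                continue
            boot_tes.append(te)
        se = float(np.std(boot_tes, ddof=1)) if len(boot_tes) > 1 else 0.0
        rows.append(
            {
                "bin": lbl,
                "te_auroc": point[1] - point[0],
                "auroc_unassisted": point[0],
                "auroc_assisted": point[1],
                "se": se,
                "n": int(len(sub)),
            }
        )
    frame = pd.DataFrame(rows)
    test = regression_core.auroc_bin_f_test(
        frame["te_auroc"], frame["se"], frame["n"]
    )
    return {"table": frame, "f_test": test}


def high_prevalence_filter(
    truths: pd.DataFrame,
    threshold: float = 0.10,
    schema=None,
) -> list[str]:
    """Labels whose binary prevalence strictly exceeds ``threshold``."""
    from hetfx.data_model import SchemaConfig

    schema = schema or SchemaConfig()
    labels = schema.binarize_truth(truths["truth_prob"])
    prev = pd.Series(labels, index=truths["pathology"].to_numpy()).groupby(level=0).mean()
    return sorted(prev.index[prev > threshold])
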
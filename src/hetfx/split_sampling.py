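"""Split-sampling regression designs and the attenuation-bias correction.

Regressing a change score (treatment effect) on a baseline computed
from the *same* noisy observations manufactures a spurious positive
slope (reversion to the mean). The designs here keep the held-out case
out of the baseline predictor:

* ``te_nonrepeated``:  y = u_i - mean(assisted),  x = leave-one-out
  mean of the other unassisted errors;
* ``te_repeated``:     y = u_i - a_i (same case),  x = leave-one-out mean;
* ``assisted_nonrepeated``: y = a_i,  x = full unassisted mean (the
  case sets are already disjoint);
* ``assisted_repeated``:    y = a_i,  x = leave-one-out mean;
* ``naive_te``: the deliberately biased diagnostic - same y as the TE
  designs but x includes the held-out case.

The slope fitted on x-with-measurement-noise is attenuated by the
reliability ratio ``lambda = signal variance / (signal + noise)``;
``attenuation_adjust`` divides the slope and its standard error by a
plug-in ``lambda``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from hetfx import regression_core
from hetfx.data_model import StudyBundle
from hetfx.metrics import error_table
from hetfx.regression_core import FitResult

logger = logging.getLogger(__name__)

DESIGN_KINDS = (
    "te_nonrepeated",
    "te_repeated",
    "assisted_nonrepeated",
    "assisted_repeated",
    "naive_te",
)


class NonIdentifiableError(ValueError):
    """Reliability ratio <= 0: measurement noise swamps the signal."""


@dataclasses.dataclass(frozen=True)
class AttenuationEstimate:
    gamma_hat: float  # uncorrected slope
    lambda_hat: float  # reliability ratio in (0, 1]
    beta_hat: float  # gamma / lambda
    se_gamma: float
    se_beta: float  # se(gamma) / lambda
    eta_sq_hat: float  # E[eta^2] plug-in (mean squared se)
    xvar_hat: float  # Var(x tilde)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _condition_tables(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    u = table[table["assisted"] == 0]
    a = table[table["assisted"] == 1]
    return u, a


def _per_reader_case_means(sub: pd.DataFrame) -> pd.DataFrame:
    """Per (reader, case) mean error (pools clinical-history conditions
    and, under scope \"all\", the pathologies of a case)."""
    return (
        sub.groupby(["radiologist_id", "case_id"], sort=False)["error"]
        .mean()
        .rename("error")
        .reset_index()
    )


def _loo_mean(frame: pd.DataFrame) -> np.ndarray:
    """Leave-one-out mean of ``error`` within reader; NaN when n < 2."""
    grp = frame.groupby("radiologist_id")["error"]
    total = grp.transform("sum").to_numpy()
    count = grp.transform("count").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (total - frame["error"].to_numpy()) / (count - 1)
    out[count < 2] = np.nan
    return out


def build_te_design(table: pd.DataFrame, design: str) -> pd.DataFrame:
    """Rows (y, x) for the treatment-effect-on-baseline regression.

    ``table`` is a long error table (see :func:`hetfx.metrics.error_table`)
    restricted to readers of one experimental design. One output row per
    unassisted case per reader; readers with fewer than two unassisted
    cases (or, non-repeated, no assisted reads) are skipped with a log
    entry.
    """
    if design not in ("non_repeated", "repeated"):
        raise ValueError(f"unknown design {design!r}")
    u, a = _condition_tables(table)
    u_case = _per_reader_case_means(u)
    a_case = _per_reader_case_means(a)
    if design == "non_repeated":
        a_mean = a_case.groupby("radiologist_id")["error"].mean()
        rows = u_case.merge(a_mean.rename("a_bar"), on="radiologist_id", how="left")
        rows["y"] = rows["error"] - rows["a_bar"]
        kind = "te_nonrepeated"
    else:
        rows = u_case.merge(
            a_case.rename(columns={"error": "a_i"}), on=["radiologist_id", "case_id"], how="left"
        )
        rows["y"] = rows["error"] - rows["a_i"]
        kind = "te_repeated"
    rows["x"] = _loo_mean(rows.rename(columns={"error": "error"}))
    before = len(rows)
    rows = rows.dropna(subset=["y", "x"])
    if len(rows) < before:
        logger.info("build_te_design(%s): dropped %d rows (skipped readers/cases)", design, before - len(rows))
    return pd.DataFrame(
        {
            "radiologist_id": rows["radiologist_id"].to_numpy(),
            "held_out_case_id": rows["case_id"].to_numpy(),
            "design_kind": kind,
            "y": rows["y"].to_numpy(dtype=float),
            "x": rows["x"].to_numpy(dtype=float),
        }
    )


def build_assisted_design(table: pd.DataFrame, design: str) -> pd.DataFrame:
    """Rows for the assisted-error-on-unassisted-baseline regression."""
    if design not in ("non_repeated", "repeated"):
        raise ValueError(f"unknown design {design!r}")
    u, a = _condition_tables(table)
    u_case = _per_reader_case_means(u)
    a_case = _per_reader_case_means(a)
    if design == "non_repeated":
        x_full = u_case.groupby("radiologist_id")["error"].agg(["mean", "count"])
        rows = a_case.merge(x_full, on="radiologist_id", how="left")
        rows = rows[rows["count"] >= 2]
        rows["x"] = rows["mean"]
        kind = "assisted_nonrepeated"
    else:
        loo = u_case.copy()
        loo["x"] = _loo_mean(u_case)
        rows = a_case.merge(
            loo[["radiologist_id", "case_id", "x"]], on=["radiologist_id", "case_id"], how="left"
        )
        kind = "assisted_repeated"
    rows = rows.dropna(subset=["x"])
    return pd.DataFrame(
        {
            "radiologist_id": rows["radiologist_id"].to_numpy(),
            "held_out_case_id": rows["case_id"].to_numpy(),
            "design_kind": kind,
            "y": rows["error"].to_numpy(dtype=float),
            "x": rows["x"].to_numpy(dtype=float),
        }
    )


def build_naive_design(table: pd.DataFrame, design: str, aggregated: bool = False) -> pd.DataFrame:
    """The reversion-to-the-mean diagnostic: x is the full unassisted mean.

    ``aggregated=True`` emits the fully reader-level variant instead
    (one row per reader: mean treatment effect on mean unassisted error).
    """
    if design not in ("non_repeated", "repeated"):
        raise ValueError(f"unknown design {design!r}")
    u, a = _condition_tables(table)
    u_case = _per_reader_case_means(u)
    a_case = _per_reader_case_means(a)
    x_full = u_case.groupby("radiologist_id")["error"].agg(["mean", "count"])
    x_full = x_full[x_full["count"] >= 2]
    if aggregated:
        a_mean = a_case.groupby("radiologist_id")["error"].mean()
        rows = x_full.join(a_mean.rename("a_bar"), how="inner").reset_index()
        return pd.DataFrame(
            {
                "radiologist_id": rows["radiologist_id"].to_numpy(),
                "held_out_case_id": "all",
                "design_kind": "naive_te",
                "y": (rows["mean"] - rows["a_bar"]).to_numpy(dtype=float),
                "x": rows["mean"].to_numpy(dtype=float),
            }
        )
    if design == "non_repeated":
        a_mean = a_case.groupby("radiologist_id")["error"].mean()
        rows = u_case.merge(a_mean.rename("a_bar"), on="radiologist_id", how="left")
        rows["y"] = rows["error"] - rows["a_bar"]
    else:
        rows = u_case.merge(
            a_case.rename(columns={"error": "a_i"}), on=["radiologist_id", "case_id"], how="left"
        )
        rows["y"] = rows["error"] - rows["a_i"]
    rows = rows.merge(x_full["mean"].rename("x"), on="radiologist_id", how="inner")
    rows = rows.dropna(subset=["y", "x"])
    return pd.DataFrame(
        {
            "radiologist_id": rows["radiologist_id"].to_numpy(),
            "held_out_case_id": rows["case_id"].to_numpy(),
            "design_kind": "naive_te",
            "y": rows["y"].to_numpy(dtype=float),
            "x": rows["x"].to_numpy(dtype=float),
        }
    )


def build_design(
    bundle_or_table,
    kind: str,
    pathology_scope: str = "all",
    naive_aggregated: bool = False,
) -> pd.DataFrame:
    """Build one of the named designs, pooling both experimental designs.

    Accepts a :class:`StudyBundle` or a pre-built error table. Rows from
    the non-repeated and repeated constructions are concatenated (no
    design indicator by default).
    """
    table = (
        error_table(bundle_or_table, pathology_scope)
        if isinstance(bundle_or_table, StudyBundle)
        else bundle_or_table
    )
    pieces = []
    for design in ("non_repeated", "repeated"):
        sub = table[table["design"] == design]
        if not len(sub):
            continue
        if kind == "te":
            pieces.append(build_te_design(sub, design))
        elif kind == "assisted":
            pieces.append(build_assisted_design(sub, design))
        elif kind == "naive":
            pieces.append(build_naive_design(sub, design, aggregated=naive_aggregated))
        else:
            raise ValueError(f"unknown design kind {kind!r}")
    if not pieces:
        raise ValueError("no rows for any experimental design")
    return pd.concat(pieces, ignore_index=True)


def estimate_lambda(
    summaries: pd.DataFrame, loo: bool = False
) -> tuple[float, float, float]:
    """Reliability ratio from per-reader unassisted-error summaries.

    ``summaries`` holds one row per reader with columns ``value``
    (observed mean), ``se`` (standard error of the mean) and ``n``.
    Returns ``(lambda_hat, eta_sq_hat, xvar_hat)`` where ``eta_sq_hat``
    is the mean squared standard error, ``xvar_hat`` the population
    variance of the observed means, and
    ``lambda_hat = (xvar_hat - eta_sq_hat) / xvar_hat``.

    ``loo=True`` rescales each se^2 by ``n/(n-1)`` so the noise term
    matches a leave-one-out mean of ``n - 1`` cases (used for the
    leave-one-out x constructions).
    """
    values = summaries["value"].to_numpy(dtype=float)
    se = summaries["se"].to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("need at least two readers")
    se_sq = se**2
    if loo:
        n = summaries["n"].to_numpy(dtype=float)
        if np.any(n < 2):
            raise ValueError("loo rescaling needs n >= 2 per reader")
        se_sq = se_sq * n / (n - 1)
    eta_sq_hat = float(se_sq.mean())
    xvar_hat = float(values.var())  # population (divide-by-n) variance
    if xvar_hat <= 0:
        raise NonIdentifiableError("zero variance of observed reader means")
    lambda_hat = (xvar_hat - eta_sq_hat) / xvar_hat
    if lambda_hat <= 0:
        raise NonIdentifiableError(
            f"reliability ratio not identifiable: xvar {xvar_hat:.6g} <= "
            f"measurement noise {eta_sq_hat:.6g}"
        )
    return lambda_hat, eta_sq_hat, xvar_hat


def attenuation_adjust(fit: FitResult, lambda_hat: float, slope_name: str = "x", eta_sq_hat: float = float("nan"), xvar_hat: float = float("nan")) -> AttenuationEstimate:
    """Divide the slope and its standard error by the reliability ratio."""
    if not 0.0 < lambda_hat <= 1.0:
        raise ValueError(f"lambda must lie in (0, 1], got {lambda_hat}")
    gamma = fit.coef(slope_name)
    se_gamma = fit.coef_se(slope_name)
    return AttenuationEstimate(
        gamma_hat=gamma,
        lambda_hat=lambda_hat,
        beta_hat=gamma / lambda_hat,
        se_gamma=se_gamma,
        se_beta=se_gamma / lambda_hat,
        eta_sq_hat=eta_sq_hat,
        xvar_hat=xvar_hat,
    )


def fit_design(rows: pd.DataFrame, df_correction: bool = False) -> FitResult:
    """OLS ``y ~ 1 + x`` on design rows, two-way clustered on
    (held-out case, reader)."""
    X = np.column_stack([np.ones(len(rows)), rows["x"].to_numpy(dtype=float)])
    case_ids = rows["held_out_case_id"].to_numpy()
    if (rows["held_out_case_id"] == "all").all():
        case_ids = None  # aggregated naive variant: reader clusters only
    return regression_core.fit_ols(
        rows["y"].to_numpy(dtype=float),
        X,
        clusters=(case_ids, rows["radiologist_id"].to_numpy()),
        names=["intercept", "x"],
        df_correction=df_correction,
    )


def unassisted_summaries_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-reader unassisted mean error summaries (value, se, n) computed
    from per-(reader, case) means -- the scale at which the split designs
    operate."""
    u = table[table["assisted"] == 0]
    per_case = _per_reader_case_means(u)
    agg = per_case.groupby("radiologist_id")["error"].agg(["mean", "std", "count"])
    agg = agg[agg["count"] >= 2]
    return pd.DataFrame(
        {
            "radiologist_id": agg.index,
            "value": agg["mean"].to_numpy(dtype=float),
            "se": (agg["std"] / np.sqrt(agg["count"])).to_numpy(dtype=float),
            "n": agg["count"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)


def split_regression(
    bundle_or_table,
    kind: str,
    pathology_scope: str = "all",
    naive_aggregated: bool = False,
    df_correction: bool = False,
) -> tuple[FitResult, AttenuationEstimate, pd.DataFrame]:
    """End-to-end: build rows, fit the clustered OLS, adjust for attenuation.

    The reliability ratio is estimated from the same readers entering the
    regression. Leave-one-out x constructions (``te``, and ``assisted``
    for the repeated design) use the leave-one-out noise rescaling; the
    naive and non-repeated assisted designs use the full-mean one.
    Returns ``(fit, attenuation, rows)``.
    """
    table = (
        error_table(bundle_or_table, pathology_scope)
        if isinstance(bundle_or_table, StudyBundle)
        else bundle_or_table
    )
    rows = build_design(table, kind, naive_aggregated=naive_aggregated)
    fit = fit_design(rows, df_correction=df_correction)
    readers = rows["radiologist_id"].unique()
    summaries = unassisted_summaries_from_table(table[table["radiologist_id"].isin(readers)])
    loo = kind == "te" or (
        kind == "assisted" and set(rows["design_kind"]) == {"assisted_repeated"}
    )
    lambda_hat, eta_sq, xvar = estimate_lambda(summaries, loo=loo)
    adjusted = attenuation_adjust(fit, lambda_hat, eta_sq_hat=eta_sq, xvar_hat=xvar)
    return fit, adjusted, rows


def split_auroc_design(
    bundle: StudyBundle,
    pathology_scope: str = "all",
    seed: int = 0,
    kind: str = "te",
) -> pd.DataFrame:
    """Reader-level split design for the aggregate AUROC metric.

    Case-level leave-one-out is ill-defined for AUROC, so each reader's
    unassisted cases are split into two seeded disjoint halves: x is the
    unassisted AUROC on one half and y uses only the other half (TE kind:
    assisted AUROC minus the held-out half's unassisted AUROC; assisted
    kind: the assisted AUROC itself). One row per reader; readers whose
    halves lack both truth classes are skipped.
    """
    from hetfx.metrics import UndefinedMetricError, auroc  # local: avoid cycle

    merged = bundle.merged(pathology_scope)
    rng = np.random.default_rng(seed)
    rows = []
    for reader, grp in merged.groupby("radiologist_id", sort=True):
        u = grp[grp["assisted"] == 0]
        a = grp[grp["assisted"] == 1]
        cases = np.sort(u["case_id"].unique())
        if cases.size < 4 or not len(a):
            continue
        perm = rng.permutation(cases)
        half_x = set(perm[: cases.size // 2])
        ux = u[u["case_id"].isin(half_x)]
        uy = u[~u["case_id"].isin(half_x)]
        try:
            x = auroc(ux["predicted_prob"], ux["truth_label"])
            a_auroc = auroc(a["predicted_prob"], a["truth_label"])
            if kind == "te":
                y = a_auroc - auroc(uy["predicted_prob"], uy["truth_label"])
            elif kind == "assisted":
                y = a_auroc
            else:
                raise ValueError(f"unknown kind {kind!r}")
        except UndefinedMetricError:
            continue
        rows.append((str(reader), "half_split", f"auroc_{kind}", y, x))
    return pd.DataFrame(rows, columns=["radiologist_id", "held_out_case_id", "design_kind", "y", "x"])
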
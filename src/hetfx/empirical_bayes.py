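"""Normal-normal empirical Bayes shrinkage of per-reader summaries.

The prior over the per-reader true metric is normal with mean the
grand mean of the observed per-reader means, and variance the
population variance of those means minus the mean squared standard
error (the method-of-moments noise correction). Each reader's
posterior mean is the precision-weighted combination of the grand mean
and the reader's own mean, which shrinks noisy readers toward the
ensemble.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ShrinkageResult:
    prior_mean: float
    prior_var: float
    table: pd.DataFrame  # radiologist_id, raw, se, posterior_mean, posterior_var
    prior_var_clipped: bool
    excluded_readers: list[str]

    @property
    def posterior_means(self) -> pd.Series:
        return self.table.set_index("radiologist_id")["posterior_mean"]

    def to_dict(self) -> dict:
        return {
            "prior_mean": self.prior_mean,
            "prior_var": self.prior_var,
            "prior_var_clipped": self.prior_var_clipped,
            "excluded_readers": list(self.excluded_readers),
            "table": self.table.to_dict(orient="list"),
        }


def estimate_prior(values, ses, ddof: int = 0) -> tuple[float, float, bool]:
    """Method-of-moments prior: (mean, variance, clipped flag).

    Variance = population variance of the observed means (``ddof=0`` by
    default, matching the plug-in derivation; ``ddof=1`` available)
    minus the mean squared standard error, clipped at zero with a flag.
    """
    values = np.asarray(values, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two readers to estimate a prior")
    if not np.all(np.isfinite(ses)):
        raise ValueError("standard errors must be finite")
    mu0 = float(values.mean())
    raw_var = float(values.var(ddof=ddof)) - float((ses**2).mean())
    clipped = raw_var < 0
    if clipped:
        logger.warning(
            "prior variance estimate negative (%.6g); clipped to 0 -- all "
            "readers shrink fully to the grand mean",
            raw_var,
        )
    return mu0, max(raw_var, 0.0), clipped


def shrink(mu_r: float, sigma_r: float, mu0: float, sigma0_sq: float) -> tuple[float, float]:
    """Normal-normal posterior (mean, variance) for one reader.

    posterior mean = (sigma_r^2 mu0 + sigma0^2 mu_r) / (sigma0^2 + sigma_r^2),
    posterior var  = sigma0^2 sigma_r^2 / (sigma0^2 + sigma_r^2).
    """
    if sigma_r < 0 or sigma0_sq < 0:
        raise ValueError("variances must be nonnegative")
    sr2 = sigma_r**2
    denom = sigma0_sq + sr2
    if denom == 0:
        raise ValueError("degenerate input: sigma_r and sigma0 both zero")
    return (sr2 * mu0 + sigma0_sq * mu_r) / denom, sigma0_sq * sr2 / denom


def shrink_all(
    summaries: pd.DataFrame,
    exclusion_rule: str = "drop_zero_se",
    ddof: int = 0,
) -> ShrinkageResult:
    """Estimate the prior and shrink every reader in ``summaries``.

    ``summaries`` has one row per reader with columns ``radiologist_id``,
    ``value`` and ``se`` (e.g. the ``condition == "effect"`` rows from
    :func:`hetfx.metrics.reader_summaries`). Readers with a zero
    standard error -- zero within-reader variance makes inference on
    them impossible -- are excluded under ``exclusion_rule="drop_zero_se"``
    (default) or kept as exact observations under ``"keep"``.
    """
    if exclusion_rule not in ("drop_zero_se", "keep"):
        raise ValueError(f"unknown exclusion_rule {exclusion_rule!r}")
    frame = summaries.copy()
    excluded: list[str] = []
    if exclusion_rule == "drop_zero_se":
        zero = frame["se"].to_numpy(dtype=float) == 0.0
        excluded = [str(r) for r in frame.loc[zero, "radiologist_id"]]
        frame = frame[~zero]
    if not len(frame):
        raise ValueError("all readers excluded; nothing to shrink")
    values = frame["value"].to_numpy(dtype=float)
    ses = frame["se"].to_numpy(dtype=float)
    mu0, sigma0_sq, clipped = estimate_prior(values, ses, ddof=ddof)
    sr2 = ses**2
    denom = sigma0_sq + sr2
    degenerate = denom == 0
    if np.any(degenerate):
        raise ValueError("degenerate input: a reader has se 0 and the prior variance is 0")
    post_mean = (sr2 * mu0 + sigma0_sq * values) / denom
    post_var = sigma0_sq * sr2 / denom
    table = pd.DataFrame(
        {
            "radiologist_id": frame["radiologist_id"].astype(str).to_numpy(),
            "raw": values,
            "se": ses,
            "posterior_mean": post_mean,
            "posterior_var": post_var,
        }
    )
    return ShrinkageResult(
        prior_mean=mu0,
        prior_var=sigma0_sq,
        table=table,
        prior_var_clipped=clipped,
        excluded_readers=excluded,
    )
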
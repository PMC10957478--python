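"""Synthetic reader-study generator with known per-reader ground truth.

Emulates the structure the analysis assumes: a pool of cases with
continuous expert-consensus truths, AI predictions with a controllable
signed-error distribution, non-repeated readers (60 cases each, half
assisted / half unassisted, half with clinical history), repeated
readers (60 cases under all four conditions across sessions), and
per-reader heterogeneous true treatment effects.

Two generative modes:

* ``direct`` -- per-read unassisted absolute error is drawn with reader
  mean ``mu_u`` and assisted error with mean ``mu_u - tau`` (truncated
  at zero); predictions are reconstructed as ``truth +/- error``.
* ``mechanistic`` -- the assisted prediction is a convex combination of
  the reader's own draw and the AI prediction with reader weight ``w``;
  the implied treatment effect is recorded as a Monte-Carlo estimate.

The true parameters live in :class:`SimTruthRecord`, which is emitted
alongside the bundle and must never feed analysis code outside tests.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from hetfx.data_model import PATHOLOGIES, SchemaConfig, StudyBundle

logger = logging.getLogger(__name__)

#: Heterogeneous default prevalences for the 15 labels (Bernoulli
#: "present" probabilities); a handful exceed the 10% high-prevalence cut.
DEFAULT_PREVALENCES: dict[str, float] = {
    "abnormal": 0.65,
    "airspace_opacity": 0.45,
    "atelectasis": 0.25,
    "bacterial_pneumonia": 0.06,
    "cardiomediastinal_abnormality": 0.30,
    "cardiomegaly": 0.17,
    "consolidation": 0.08,
    "edema": 0.14,
    "lesion": 0.05,
    "pleural_effusion": 0.22,
    "pleural_other": 0.02,
    "pneumothorax": 0.03,
    "rib_fracture": 0.02,
    "shoulder_fracture": 0.01,
    "support_device_hardware": 0.35,
}


@dataclasses.dataclass(frozen=True)
class TruthModel:
    """Scaled-Beta truth-probability distributions for absent/present cases."""

    absent_alpha: float = 1.2
    absent_beta: float = 14.0
    present_alpha: float = 14.0
    present_beta: float = 1.2


@dataclasses.dataclass(frozen=True)
class ReaderSkill:
    """Per-reader unassisted mean absolute error and per-read noise."""

    mean: float = 15.0
    sd: float = 2.0
    read_noise_sd: float = 3.0
    floor: float = 1.0  # lower clip for sampled reader means


@dataclasses.dataclass(frozen=True)
class TEHeterogeneity:
    """Per-reader true treatment effect tau_r.

    ``tau_r = mean + link_slope * (mu_u_r - skill_mean) + N(0, sd^2)``;
    ``link_slope`` plants a true slope of treatment effect on unassisted
    error (0 = independent, the null configuration).
    """

    mean: float = 0.5
    sd: float = 1.0
    link_slope: float = 0.0

    @property
    def var(self) -> float:
        return self.sd**2


@dataclasses.dataclass(frozen=True)
class AIErrorModel:
    """Signed AI error: magnitude |N(0, scale)| with sign asymmetry.

    ``prob_positive`` is the chance the AI overestimates; ``loc`` shifts
    the whole distribution. ``dist="uniform"`` draws the magnitude
    uniformly on [0, scale] instead (useful to populate every error bin
    with a comparable number of cases).
    """

    loc: float = 0.0
    scale: float = 15.0
    prob_positive: float = 0.5
    dist: str = "normal"  # "normal" or "uniform" magnitude


@dataclasses.dataclass(frozen=True)
class MechanisticModel:
    weight_mean: float = 0.3
    weight_sd: float = 0.1
    n_oracle_draws: int = 4000


@dataclasses.dataclass(frozen=True)
class SimConfig:
    n_readers_nonrepeated: int = 107
    n_readers_repeated: int = 33
    n_cases_per_reader: int = 60
    case_pool_size: int = 324
    pathology_prevalences: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    truth_model: TruthModel = TruthModel()
    reader_skill: ReaderSkill = ReaderSkill()
    te_heterogeneity: TEHeterogeneity = TEHeterogeneity()
    ai_error_model: AIErrorModel = AIErrorModel()
    mechanistic: MechanisticModel = MechanisticModel()
    mode: str = "direct"  # "direct" or "mechanistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for label, p in self.pathology_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {label!r} outside [0, 1]: {p}")
        if self.te_heterogeneity.sd < 0 or self.reader_skill.sd < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if self.n_cases_per_reader % 2:
            raise ValueError("n_cases_per_reader must be even (half assisted)")
        if self.n_cases_per_reader > self.case_pool_size:
            raise ValueError("n_cases_per_reader exceeds case_pool_size")

    @property
    def pathologies(self) -> tuple[str, ...]:
        return tuple(self.pathology_prevalences)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimConfig":
        raw = dict(raw)
        for key, sub in (
            ("truth_model", TruthModel),
            ("reader_skill", ReaderSkill),
            ("te_heterogeneity", TEHeterogeneity),
            ("ai_error_model", AIErrorModel),
            ("mechanistic", MechanisticModel),
        ):
            if key in raw and isinstance(raw[key], Mapping):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SimTruthRecord:
    """Hidden truth emitted next to a synthetic bundle (tests only)."""

    readers: pd.DataFrame  # radiologist_id, design, mu_u, tau, weight
    ai_errors: pd.DataFrame  # case_id, pathology, nominal_error, realized_error
    clip_fraction: float
    notes: list[str]
    config: SimConfig

    def to_json_dict(self) -> dict:
        return {
            "readers": self.readers.to_dict(orient="list"),
            "ai_errors": self.ai_errors.to_dict(orient="list"),
            "clip_fraction": self.clip_fraction,
            "notes": list(self.notes),
            "config": self.config.to_dict(),
        }


def _scaled_beta(rng, alpha, beta, size):
    return 100.0 * rng.beta(alpha, beta, size=size)


def _make_cases(config: SimConfig, rng) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Case truths and AI predictions for the pool."""
    n = config.case_pool_size
    case_ids = np.array([f"c{i:04d}" for i in range(n)])
    tm, am = config.truth_model, config.ai_error_model
    frames, ai_rows = [], []
    for label in config.pathologies:
        present = rng.random(n) < config.pathology_prevalences[label]
        truth = np.where(
            present,
            _scaled_beta(rng, tm.present_alpha, tm.present_beta, n),
            _scaled_beta(rng, tm.absent_alpha, tm.absent_beta, n),
        )
        if am.dist == "uniform":
            magnitude = am.scale * rng.random(n)
        elif am.dist == "normal":
            magnitude = np.abs(rng.normal(0.0, am.scale, size=n))
        else:
            raise ValueError(f"unknown AI error dist {am.dist!r}")
        sign = np.where(rng.random(n) < am.prob_positive, 1.0, -1.0)
        nominal = am.loc + sign * magnitude
        ai_prob = np.clip(truth + nominal, 0.0, 100.0)
        frames.append(pd.DataFrame({"case_id": case_ids, "pathology": label, "truth_prob": truth}))
        ai_rows.append(
            pd.DataFrame(
                {
                    "case_id": case_ids,
                    "pathology": label,
                    "ai_prob": ai_prob,
                    "nominal_error": nominal,
                    "realized_error": ai_prob - truth,
                }
            )
        )
    truths = pd.concat(frames, ignore_index=True)
    ai_full = pd.concat(ai_rows, ignore_index=True)
    ai = ai_full[["case_id", "pathology", "ai_prob"]].copy()
    return truths, ai, ai_full[["case_id", "pathology", "nominal_error", "realized_error"]]


def _reconstruct_predictions(truth: np.ndarray, error: np.ndarray, rng) -> np.ndarray:
    """Place |error| on a feasible side of truth; clip as a last resort.

    The side is a fair coin whenever both sides stay inside [0, 100], so
    the realized absolute error equals the drawn error unless the error
    exceeds both margins.
    """
    up_ok = truth + error <= 100.0
    dn_ok = truth - error >= 0.0
    coin = np.where(rng.random(truth.shape) < 0.5, 1.0, -1.0)
    sign = np.where(
        up_ok & dn_ok, coin, np.where(up_ok, 1.0, np.where(dn_ok, -1.0, np.where(truth <= 50.0, 1.0, -1.0)))
    )
    return np.clip(truth + sign * error, 0.0, 100.0)


def _case_matrix(rng, n_readers: int, pool: int, n_cases: int) -> np.ndarray:
    """Per-reader random case subsets (indices into the pool), no replacement."""
    return np.argsort(rng.random((n_readers, pool)), axis=1)[:, :n_cases]


def generate_study(
    config: SimConfig, seed: int | None = None
) -> tuple[StudyBundle, SimTruthRecord]:
    """Generate a validated study bundle plus its hidden truth record."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    notes: list[str] = []
    truths, ai, ai_errors = _make_cases(config, rng)
    case_ids = np.array([f"c{i:04d}" for i in range(config.case_pool_size)])
    n_path = len(config.pathologies)
    sk, te = config.reader_skill, config.te_heterogeneity

    reader_frames: list[pd.DataFrame] = []
    reader_records: list[dict] = []
    clipped_reads = 0
    total_reads = 0

    # truth matrix (pool x pathology) for fast slot lookup
    truth_mat = (
        truths.pivot(index="case_id", columns="pathology", values="truth_prob")
        .loc[case_ids, list(config.pathologies)]
        .to_numpy()
    )
    ai_mat = (
        ai.pivot(index="case_id", columns="pathology", values="ai_prob")
        .loc[case_ids, list(config.pathologies)]
        .to_numpy()
    )

    def _draw_readers(n: int, prefix: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        ids = np.array([f"{prefix}{i:04d}" for i in range(n)])
        mu = np.clip(rng.normal(sk.mean, sk.sd, size=n), sk.floor, None)
        tau = te.mean + te.link_slope * (mu - sk.mean) + rng.normal(0.0, te.sd, size=n)
        weight = np.clip(
            rng.normal(config.mechanistic.weight_mean, config.mechanistic.weight_sd, size=n),
            0.0,
            1.0,
        )
        return ids, mu, tau, weight

    def _emit(
        ids, mu, tau, weight, design: str, cases_idx, assisted, history, session
    ) -> None:
        """Build rows for one design. All argument arrays share the leading
        (reader, slot) shape; pathologies are expanded on a trailing axis."""
        nonlocal clipped_reads, total_reads
        n_readers, n_slots = cases_idx.shape
        shape = (n_readers, n_slots, n_path)
        truth = truth_mat[cases_idx]  # (R, S, P)
        mu3 = mu[:, None, None]
        tau3 = tau[:, None, None]
        mean_a = np.maximum(mu3 - tau3, 0.0)
        if np.any(mu - np.maximum(tau, 0) < 0):
            notes.append(f"{design}: some assisted error means truncated at 0")
        mean = np.where(assisted[:, :, None].astype(bool), np.broadcast_to(mean_a, shape), np.broadcast_to(mu3, shape))
        error = np.clip(rng.normal(mean, sk.read_noise_sd), 0.0, None)
        if config.mode == "direct":
            pred = _reconstruct_predictions(truth, error, rng)
        else:
            # mechanistic: unassisted-style own draw everywhere, blended
            # with the AI probability on assisted reads
            own_error = np.clip(rng.normal(np.broadcast_to(mu3, shape), sk.read_noise_sd), 0.0, None)
            own_pred = _reconstruct_predictions(truth, own_error, rng)
            ai_read = ai_mat[cases_idx]
            blended = (1.0 - weight[:, None, None]) * own_pred + weight[:, None, None] * ai_read
            pred = np.where(assisted[:, :, None].astype(bool), blended, own_pred)
            pred = np.clip(pred, 0.0, 100.0)
        realized = np.abs(pred - truth)
        if config.mode == "direct":
            clipped_reads += int(np.sum(np.abs(realized - error) > 1e-9))
        total_reads += error.size
        frame = pd.DataFrame(
            {
                "radiologist_id": np.repeat(ids, n_slots * n_path),
                "case_id": case_ids[cases_idx].repeat(n_path),
                "pathology": np.tile(np.array(config.pathologies), n_readers * n_slots),
                "design": design,
                "assisted": np.repeat(assisted.astype(int).ravel(), n_path),
                "clinical_history": np.repeat(history.astype(int).ravel(), n_path),
                "session": np.repeat(session.astype(int).ravel(), n_path),
                "predicted_prob": pred.ravel(),
            }
        )
        reader_frames.append(frame)

    # --- non-repeated design: disjoint assisted/unassisted halves ----------
    n_nr = config.n_readers_nonrepeated
    n_slots = config.n_cases_per_reader
    if n_nr:
        ids, mu, tau, weight = _draw_readers(n_nr, "nr")
        cases_idx = _case_matrix(rng, n_nr, config.case_pool_size, n_slots)
        rank = np.argsort(rng.random((n_nr, n_slots)), axis=1)
        half = n_slots // 2
        quarter = half // 2
        assisted = rank < half
        history = (rank % half) < quarter if quarter else np.zeros_like(rank, dtype=bool)
        session = np.ones_like(rank)
        _emit(ids, mu, tau, weight, "non_repeated", cases_idx, assisted, history, session)
        for i in range(n_nr):
            reader_records.append(
                {"radiologist_id": ids[i], "design": "non_repeated", "mu_u": mu[i], "tau": tau[i], "weight": weight[i]}
            )

    # --- repeated design: every case under all four conditions -------------
    n_rp = config.n_readers_repeated
    if n_rp:
        ids, mu, tau, weight = _draw_readers(n_rp, "rp")
        base_idx = _case_matrix(rng, n_rp, config.case_pool_size, n_slots)
        conditions = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])  # (assisted, history)
        order = np.argsort(rng.random((n_rp, 4)), axis=1)  # session order per reader
        cases_idx = np.repeat(base_idx, 4, axis=1)  # (R, S*4): case blocks of 4
        cond_tile = np.tile(conditions, (n_slots, 1))  # (S*4, 2)
        assisted = np.broadcast_to(cond_tile[:, 0], (n_rp, n_slots * 4)).copy()
        history = np.broadcast_to(cond_tile[:, 1], (n_rp, n_slots * 4)).copy()
        # session = 1 + rank of the condition in this reader's random order
        cond_index = np.tile(np.arange(4), n_slots)  # which condition each column is
        session = 1 + np.argsort(order, axis=1)[:, cond_index]
        _emit(ids, mu, tau, weight, "repeated", cases_idx, assisted.astype(bool), history.astype(bool), session)
        for i in range(n_rp):
            reader_records.append(
                {"radiologist_id": ids[i], "design": "repeated", "mu_u": mu[i], "tau": tau[i], "weight": weight[i]}
            )

    reads = (
        pd.concat(reader_frames, ignore_index=True)
        if reader_frames
        else pd.DataFrame(columns=["radiologist_id", "case_id", "pathology", "design", "assisted", "clinical_history", "session", "predicted_prob"])
    )
    schema = SchemaConfig(pathologies=config.pathologies)
    profiles = pd.DataFrame(columns=["radiologist_id", "years_experience", "thoracic_subspecialty", "ai_experience"])
    bundle = StudyBundle(reads=reads, truths=truths, ai=ai, profiles=profiles, schema=schema)
    bundle.validate()

    readers = pd.DataFrame(reader_records)
    if config.mode == "mechanistic" and len(readers):
        readers["tau"] = _mechanistic_tau_oracle(config, readers, truth_mat, ai_mat, rng)
        notes.append("mechanistic mode: tau is a Monte-Carlo oracle estimate")
    record = SimTruthRecord(
        readers=readers,
        ai_errors=ai_errors,
        clip_fraction=clipped_reads / total_reads if total_reads else 0.0,
        notes=notes,
        config=config,
    )
    return bundle, record


def _mechanistic_tau_oracle(config, readers, truth_mat, ai_mat, rng) -> np.ndarray:
    """Monte-Carlo estimate of E|u - t| - E|a - t| per mechanistic reader."""
    n_mc = config.mechanistic.n_oracle_draws
    sk = config.reader_skill
    taus = np.empty(len(readers))
    pool, n_path = truth_mat.shape
    for i, row in enumerate(readers.itertuples(index=False)):
        ci = rng.integers(0, pool, size=n_mc)
        pi = rng.integers(0, n_path, size=n_mc)
        t = truth_mat[ci, pi]
        a_ref = ai_mat[ci, pi]
        err = np.clip(rng.normal(row.mu_u, sk.read_noise_sd, size=n_mc), 0.0, None)
        own = _reconstruct_predictions(t, err, rng)
        blended = np.clip((1.0 - row.weight) * own + row.weight * a_ref, 0.0, 100.0)
        taus[i] = np.mean(np.abs(own - t)) - np.mean(np.abs(blended - t))
    return taus


@dataclasses.dataclass(frozen=True)
class CharacteristicsConfig:
    """Marginal rates for survey characteristics, with an optional linear
    link from the reader's true treatment effect (default: no link)."""

    rate_thoracic: float = 0.26
    rate_ai_experience: float = 0.54
    years_mean: float = 8.0
    years_sd: float = 5.0
    link_thoracic: float = 0.0
    link_ai_experience: float = 0.0
    link_years: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rate_thoracic", "rate_ai_experience", "missing_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {rate}")


def generate_characteristics(
    reader_ids,
    taus,
    config: CharacteristicsConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-reader survey profiles with configurable marginals.

    ``taus`` aligns with ``reader_ids``; nonzero link coefficients tilt
    each characteristic's probability (or the years mean) by the
    reader's centred treatment effect.
    """
    config = config or CharacteristicsConfig()
    reader_ids = np.asarray(reader_ids)
    if reader_ids.size == 0:
        raise ValueError("reader list is empty")
    taus = np.asarray(taus, dtype=float)
    centred = taus - taus.mean()
    rng = np.random.default_rng(seed)
    shape = (config.years_mean / config.years_sd) ** 2 if config.years_sd > 0 else 1.0
    scale = config.years_sd**2 / config.years_mean if config.years_sd > 0 else 0.0
    years = (
        rng.gamma(shape, scale, size=reader_ids.size)
        if scale > 0
        else np.full(reader_ids.size, config.years_mean)
    )
    years = np.clip(years + config.link_years * centred, 0.0, None)
    p_thor = np.clip(config.rate_thoracic + config.link_thoracic * centred, 0.0, 1.0)
    p_ai = np.clip(config.rate_ai_experience + config.link_ai_experience * centred, 0.0, 1.0)
    profiles = pd.DataFrame(
        {
            "radiologist_id": reader_ids,
            "years_experience": np.round(years, 1),
            "thoracic_subspecialty": (rng.random(reader_ids.size) < p_thor).astype(int),
            "ai_experience": (rng.random(reader_ids.size) < p_ai).astype(int),
        }
    )
    if config.missing_rate > 0:
        keep = rng.random(reader_ids.size) >= config.missing_rate
        profiles = profiles[keep].reset_index(drop=True)
    return profiles
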
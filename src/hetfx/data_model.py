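"""Domain types, validation and I/O for reader-study tables.

A study bundle consists of four delimited tables:

* ``reads``    -- one row per (radiologist, case, pathology, condition)
  with the reader's predicted probability on a 0-100 scale;
* ``truths``   -- expert-consensus continuous ground-truth probability
  per (case, pathology), 0-100;
* ``ai``       -- the assistive model's predicted probability per
  (case, pathology), 0-100;
* ``profiles`` -- per-radiologist survey characteristics (years of
  experience, thoracic subspecialty, experience with AI tools).

All files are UTF-8 CSV with a header row; identifiers are opaque
strings; booleans are serialized as 0/1.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 15 diagnostic labels used throughout; order is fixed.
PATHOLOGIES: tuple[str, ...] = (
    "abnormal",
    "airspace_opacity",
    "atelectasis",
    "bacterial_pneumonia",
    "cardiomediastinal_abnormality",
    "cardiomegaly",
    "consolidation",
    "edema",
    "lesion",
    "pleural_effusion",
    "pleural_other",
    "pneumothorax",
    "rib_fracture",
    "shoulder_fracture",
    "support_device_hardware",
)

DESIGNS = ("non_repeated", "repeated")

READS_COLUMNS = (
    "radiologist_id",
    "case_id",
    "pathology",
    "design",
    "assisted",
    "clinical_history",
    "session",
    "predicted_prob",
)
TRUTHS_COLUMNS = ("case_id", "pathology", "truth_prob")
AI_COLUMNS = ("case_id", "pathology", "ai_prob")
PROFILES_COLUMNS = (
    "radiologist_id",
    "years_experience",
    "thoracic_subspecialty",
    "ai_experience",
)


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ValidationError(ValueError):
    """A value violates a domain invariant (e.g. probability bounds)."""


class IntegrityError(ValueError):
    """A referential-integrity violation between tables."""


@dataclasses.dataclass(frozen=True)
class SchemaConfig:
    """Configurable parts of the table schema and truth binarization.

    ``truth_threshold``/``truth_op`` control how the continuous
    ground-truth probability is binarized; the default labels an exact
    consensus of 50 as "present" (``>=``).
    """

    pathologies: tuple[str, ...] = PATHOLOGIES
    truth_threshold: float = 50.0
    truth_op: str = ">="  # ">=" or ">"
    column_renames: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def binarize_truth(self, truth_prob) -> np.ndarray:
        arr = np.asarray(truth_prob, dtype=float)
        if self.truth_op == ">=":
            return (arr >= self.truth_threshold).astype(int)
        if self.truth_op == ">":
            return (arr > self.truth_threshold).astype(int)
        raise ValueError(f"unsupported truth_op {self.truth_op!r}")


def ground_truth_from_experts(expert_probs: Sequence[float]) -> float:
    """Consensus ground-truth probability: the mean of expert probabilities.

    >>> ground_truth_from_experts([91, 92, 92, 100, 100])
    95.0
    """
    probs = np.asarray(expert_probs, dtype=float)
    if probs.size == 0:
        raise ValidationError("expert probability list is empty")
    if np.any((probs < 0) | (probs > 100)):
        raise ValidationError("expert probabilities must lie in [0, 100]")
    return float(probs.mean())


@dataclasses.dataclass
class StudyBundle:
    """Validated in-memory study: reads, truths, AI predictions, profiles."""

    reads: pd.DataFrame
    truths: pd.DataFrame
    ai: pd.DataFrame
    profiles: pd.DataFrame
    schema: SchemaConfig = dataclasses.field(default_factory=SchemaConfig)

    @property
    def pathologies(self) -> tuple[str, ...]:
        return self.schema.pathologies

    def merged(self, pathology_scope: str = "all") -> pd.DataFrame:
        """Reads joined with truth and AI columns, plus derived errors.

        Adds ``truth_prob``, ``truth_label``, ``ai_prob``, ``abs_error``,
        ``signed_error``, ``ai_abs_error``, ``ai_signed_error``.
        ``pathology_scope`` is a single label or ``"all"``.
        """
        reads = self.reads
        if pathology_scope != "all":
            if pathology_scope not in self.schema.pathologies:
                raise ValueError(f"unknown pathology {pathology_scope!r}")
            reads = reads[reads["pathology"] == pathology_scope]
        out = reads.merge(self.truths, on=["case_id", "pathology"], how="left")
        out = out.merge(self.ai, on=["case_id", "pathology"], how="left")
        out["truth_label"] = self.schema.binarize_truth(out["truth_prob"])
        out["signed_error"] = out["predicted_prob"] - out["truth_prob"]
        out["abs_error"] = out["signed_error"].abs()
        out["ai_signed_error"] = out["ai_prob"] - out["truth_prob"]
        out["ai_abs_error"] = out["ai_signed_error"].abs()
        return out

    def validate(self) -> "StudyBundle":
        _check_prob(self.reads, "predicted_prob", "reads")
        _check_prob(self.truths, "truth_prob", "truths")
        _check_prob(self.ai, "ai_prob", "ai")
        known = set(self.schema.pathologies)
        for name, frame in (("reads", self.reads), ("truths", self.truths), ("ai", self.ai)):
            bad = set(frame["pathology"].unique()) - known
            if bad:
                raise ValidationError(f"{name}: unknown pathologies {sorted(bad)}")
        if self.reads["design"].isin(DESIGNS).all() is False:
            raise ValidationError("reads: design must be non_repeated or repeated")
        for name, frame, keys in (
            ("truths", self.truths, ["case_id", "pathology"]),
            ("ai", self.ai, ["case_id", "pathology"]),
            ("profiles", self.profiles, ["radiologist_id"]),
        ):
            if frame.duplicated(keys).any():
                raise ValidationError(f"{name}: duplicate rows for {keys}")
        self._check_referential_integrity()
        self._check_read_multiplicity()
        return self

    def _check_referential_integrity(self) -> None:
        for other, name in ((self.truths, "truths"), (self.ai, "ai")):
            have = set(map(tuple, other[["case_id", "pathology"]].itertuples(index=False)))
            used = set(map(tuple, self.reads[["case_id", "pathology"]].itertuples(index=False)))
            dangling = used - have
            if dangling:
                example = sorted(dangling)[:3]
                raise IntegrityError(
                    f"{len(dangling)} read (case, pathology) pairs missing from "
                    f"{name}; e.g. {example}"
                )

    def _check_read_multiplicity(self) -> None:
        nr = self.reads[self.reads["design"] == "non_repeated"]
        if nr.duplicated(["radiologist_id", "case_id", "pathology"]).any():
            raise ValidationError(
                "non_repeated design: duplicate (radiologist, case, pathology)"
            )
        rp = self.reads[self.reads["design"] == "repeated"]
        if rp.duplicated(
            ["radiologist_id", "case_id", "pathology", "assisted", "clinical_history"]
        ).any():
            raise ValidationError(
                "repeated design: duplicate (radiologist, case, pathology, condition)"
            )

    def counts(self) -> dict:
        return {
            "n_reads": int(len(self.reads)),
            "n_readers": int(self.reads["radiologist_id"].nunique()),
            "n_cases": int(self.truths["case_id"].nunique()),
            "n_truths": int(len(self.truths)),
            "n_profiles": int(len(self.profiles)),
        }


def _check_prob(frame: pd.DataFrame, column: str, name: str) -> None:
    vals = frame[column].to_numpy(dtype=float)
    bad = np.flatnonzero(~((vals >= 0) & (vals <= 100)))
    if bad.size:
        raise ValidationError(
            f"{name}: {column} outside [0, 100] at row index {int(bad[0])} "
            f"(value {vals[bad[0]]!r}; {bad.size} offending rows)"
        )


def _read_csv(path: Path, required: Sequence[str], schema: SchemaConfig) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={c: str for c in ("radiologist_id", "case_id", "pathology", "design")})
    if schema.column_renames:
        frame = frame.rename(columns=dict(schema.column_renames))
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return frame


def load_bundle(
    paths: Mapping[str, Path] | str | Path,
    schema: SchemaConfig | None = None,
) -> StudyBundle:
    """Load and validate a study bundle.

    ``paths`` is a directory containing ``reads.csv``, ``truths.csv``,
    ``ai.csv`` and ``profiles.csv``, or a mapping with those four keys.
    """
    schema = schema or SchemaConfig()
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in ("reads", "truths", "ai", "profiles")}
    reads = _read_csv(Path(paths["reads"]), READS_COLUMNS, schema)
    truths = _read_csv(Path(paths["truths"]), TRUTHS_COLUMNS, schema)
    ai = _read_csv(Path(paths["ai"]), AI_COLUMNS, schema)
    profiles = _read_csv(Path(paths["profiles"]), PROFILES_COLUMNS, schema)
    for col in ("assisted", "clinical_history"):
        reads[col] = reads[col].astype(int) if len(reads) else reads[col]
    bundle = StudyBundle(reads=reads, truths=truths, ai=ai, profiles=profiles, schema=schema)
    bundle.validate()
    logger.info("loaded bundle: %s", bundle.counts())
    return bundle


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the four CSV tables; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, frame, cols in (
        ("reads", bundle.reads, READS_COLUMNS),
        ("truths", bundle.truths, TRUTHS_COLUMNS),
        ("ai", bundle.ai, AI_COLUMNS),
        ("profiles", bundle.profiles, PROFILES_COLUMNS),
    ):
        path = out / f"{name}.csv"
        frame.loc[:, list(cols)].to_csv(path, index=False)
        written[name] = path
    return written
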
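import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests._oracles-style imports

from hetfx.data_model import SchemaConfig, StudyBundle


def make_bundle(read_rows, truth_rows=None, ai_rows=None, profile_rows=None, pathologies=None):
    """Build a validated StudyBundle from terse row dicts.

    ``read_rows`` entries need radiologist_id, case_id, pathology,
    assisted and predicted_prob; design/clinical_history/session get
    defaults. Truths default to 50 and AI to the truth for any (case,
    pathology) not given explicitly.
    """
    reads = pd.DataFrame(read_rows)
    for col, default in (("design", "non_repeated"), ("clinical_history", 0), ("session", 1)):
        if col not in reads.columns:
            reads[col] = default
    pairs = reads[["case_id", "pathology"]].drop_duplicates()
    truths = pd.DataFrame(truth_rows) if truth_rows is not None else pairs.assign(truth_prob=50.0)
    extra = pairs.merge(truths[["case_id", "pathology"]], how="left", indicator=True)
    extra = extra[extra["_merge"] == "left_only"].drop(columns="_merge")
    if len(extra):
        truths = pd.concat([truths, extra.assign(truth_prob=50.0)], ignore_index=True)
    ai = (
        pd.DataFrame(ai_rows)
        if ai_rows is not None
        else truths.rename(columns={"truth_prob": "ai_prob"}).copy()
    )
    extra_ai = truths[["case_id", "pathology"]].merge(
        ai[["case_id", "pathology"]], how="left", indicator=True
    )
    extra_ai = extra_ai[extra_ai["_merge"] == "left_only"].drop(columns="_merge")
    if len(extra_ai):
        filler = extra_ai.merge(truths, on=["case_id", "pathology"])
        ai = pd.concat([ai, filler.rename(columns={"truth_prob": "ai_prob"})], ignore_index=True)
    profiles = (
        pd.DataFrame(profile_rows)
        if profile_rows is not None
        else pd.DataFrame(columns=["radiologist_id", "years_experience", "thoracic_subspecialty", "ai_experience"])
    )
    if pathologies is None:
        pathologies = tuple(sorted(set(truths["pathology"])))
    schema = SchemaConfig(pathologies=tuple(pathologies))
    bundle = StudyBundle(reads=reads, truths=truths, ai=ai, profiles=profiles, schema=schema)
    return bundle.validate()


def error_reads(reader, errors, assisted, design="non_repeated", case_prefix="c", pathology="abnormal", truth=50.0):
    """Read rows whose absolute error against truth 50 equals ``errors``."""
    rows = []
    for i, err in enumerate(errors):
        rows.append(
            {
                "radiologist_id": reader,
                "case_id": f"{case_prefix}{i}",
                "pathology": pathology,
                "design": design,
                "assisted": int(assisted),
                "clinical_history": 0,
                "session": 1,
                "predicted_prob": truth + err,
            }
        )
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_bundle():
    """A modest default-mode synthetic study shared across read-only tests."""
    from hetfx.synthetic_data import SimConfig, generate_study

    cfg = SimConfig(
        n_readers_nonrepeated=30,
        n_readers_repeated=8,
        case_pool_size=120,
        pathology_prevalences={"abnormal": 0.5, "edema": 0.15, "lesion": 0.05},
        seed=7,
    )
    bundle, record = generate_study(cfg)
    return bundle, record
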
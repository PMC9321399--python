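"""The packaged published predictor.

Ships the published signature — 17 plasma proteins plus gender and
baseline DAS28-ESR — as package data and applies it to new patients:

    S = sum_i beta_i * x_i + b
    p = 1 / (1 + exp(-(S - t)))

Gender enters raw (M=1, F=0); baseline DAS and the protein NPX values
are z-scored against a reference cohort first.  The packaged reference
statistics are a clearly-labelled SYNTHETIC stand-in (the real internal
cohort statistics are not public); supply your own reference file for
meaningful predictions on real patients.  The baseline-DAS reference
(mean 5.4, SD 1.3) matches the published cohort summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .ingest import ReferenceStats

__all__ = [
    "PublishedModel",
    "PredictionResult",
    "load_published_model",
    "load_packaged_reference",
    "score",
    "predict_probability",
    "classify",
    "predict_patient",
]

CLINICAL_FEATURES = ("gender", "baseline_das")


@dataclass(frozen=True)
class PublishedModel:
    """Published linear scorer: coefficients, intercept and threshold."""

    coefficients: dict  # feature name -> beta, clinical + protein
    intercept: float
    threshold: float
    panels: dict  # protein -> panel label
    feature_importance: dict

    def __post_init__(self) -> None:
        if len(self.protein_features) != 17:
            raise ValueError(
                f"expected 17 protein features, got {len(self.protein_features)}"
            )
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def protein_features(self) -> tuple[str, ...]:
        return tuple(f for f in self.coefficients if f not in CLINICAL_FEATURES)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "threshold": self.threshold,
            "features": [
                {
                    "name": f,
                    "kind": "clinical" if f in CLINICAL_FEATURES else "protein",
                    "panel": self.panels.get(f),
                    "fi": self.feature_importance.get(f),
                    "beta": b,
                }
                for f, b in self.coefficients.items()
            ],
        }


@dataclass(frozen=True)
class PredictionResult:
    score: float
    probability: float
    label: str  # "responder" / "non-responder"
    contributions: dict  # feature -> beta_i * x_i

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "probability": self.probability,
            "label": self.label,
            "contributions": self.contributions,
        }


def _model_from_dict(d: dict) -> PublishedModel:
    coefs = {f["name"]: float(f["beta"]) for f in d["features"]}
    panels = {
        f["name"]: f.get("panel")
        for f in d["features"]
        if f.get("kind") == "protein"
    }
    fi = {f["name"]: f.get("fi") for f in d["features"]}
    return PublishedModel(
        coefficients=coefs,
        intercept=float(d["intercept"]),
        threshold=float(d["threshold"]),
        panels=panels,
        feature_importance=fi,
    )


def load_published_model() -> PublishedModel:
    """Load the packaged published signature."""
    text = (
        resources.files("npxpred").joinpath("data/published_model.json").read_text()
    )
    return _model_from_dict(json.loads(text))


def load_packaged_reference() -> ReferenceStats:
    """The packaged reference statistics (synthetic stand-in for the
    proteins; baseline DAS from the published cohort summary)."""
    with resources.files("npxpred").joinpath("data/reference_stats.csv").open() as fh:
        frame = pd.read_csv(fh)
    return ReferenceStats.from_frame(frame, n_cohort=89)


def score(features: dict, model: PublishedModel) -> float:
    """Linear score S from an already-standardised feature vector.

    Every model feature must be present exactly once; no silent
    zero-fill.
    """
    missing = [f for f in model.feature_ids if f not in features]
    if missing:
        raise ValueError(f"missing model features: {missing}")
    return float(
        sum(model.coefficients[f] * float(features[f]) for f in model.feature_ids)
        + model.intercept
    )


def predict_probability(s: float, t: float) -> float:
    """Map a score to a response probability via the shifted logistic."""
    if not (np.isfinite(s) and np.isfinite(t)):
        raise ValueError("score and threshold must be finite")
    return float(1.0 / (1.0 + np.exp(-(s - t))))


def classify(p: float) -> str:
    """Responder iff p > 0.5; the boundary p = 0.5 is called
    non-responder (conservative)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability outside [0, 1]")
    return "responder" if p > 0.5 else "non-responder"


def read_patient_file(path) -> dict:
    """Patient template CSV: rows of ``feature_id,value``.

    Gender may be given as M/F or 1/0.  A protein supplied twice (one
    value per panel) is kept as a list and its z-scores are averaged.
    """
    df = pd.read_csv(path, header=None, names=["feature", "value"], comment="#")
    if df.shape[1] != 2 or df["feature"].isna().any():
        raise ValueError(f"{path}: expected two columns feature,value")
    if str(df.iloc[0, 0]).strip().lower() in {"feature", "feature_id"}:
        df = df.iloc[1:]
    record: dict = {}
    for _, row in df.iterrows():
        name = str(row["feature"]).strip()
        raw = str(row["value"]).strip()
        if name.lower() == "gender":
            val = {"M": 1.0, "F": 0.0}.get(raw.upper())
            if val is None:
                val = float(raw)
            if val not in (0.0, 1.0):
                raise ValueError(f"{path}: gender must be M/F or 1/0, got {raw}")
        else:
            val = float(raw)
        if name in record:
            prev = record[name]
            record[name] = (prev if isinstance(prev, list) else [prev]) + [val]
        else:
            record[name] = val
    return record


def standardize_patient(record: dict, model: PublishedModel, ref: ReferenceStats) -> dict:
    """z-score continuous features of a patient record; gender stays raw.

    Proteins assayed on two panels may carry two values; their z-scores
    are averaged into one merged feature.
    """
    ref_map = dict(zip(ref.feature_ids, zip(ref.mean, ref.sd)))
    missing = [f for f in model.feature_ids if f not in record]
    if missing:
        raise ValueError(f"patient file missing features: {missing}")
    extra = [f for f in record if f not in model.feature_ids]
    if extra:
        raise ValueError(f"patient file has unknown features: {extra}")
    z: dict = {}
    for f in model.feature_ids:
        if f == "gender":
            z[f] = float(np.atleast_1d(record[f])[0])
            continue
        if f not in ref_map:
            raise ValueError(f"reference statistics missing feature: {f}")
        mu, sd = ref_map[f]
        vals = record[f] if isinstance(record[f], list) else [record[f]]
        z[f] = float(np.mean([(v - mu) / sd for v in vals]))
    return z


def predict_patient(
    path, model: PublishedModel | None = None, reference: ReferenceStats | None = None
) -> PredictionResult:
    """Score a single-patient template file end to end."""
    if model is None:
        model = load_published_model()
    if reference is None:
        reference = load_packaged_reference()
    record = read_patient_file(path)
    z = standardize_patient(record, model, reference)
    s = score(z, model)
    p = predict_probability(s, model.threshold)
    contributions = {
        f: model.coefficients[f] * z[f] for f in model.feature_ids
    }
    return PredictionResult(
        score=s, probability=p, label=classify(p), contributions=contributions
    )
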
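"""Subtype-specific linear pCR score and threshold classifier.

The score is a plain linear function of the two biophysical summary
features::

    score = a1 * metabolic_activity + a2 * angiogenesis + b

Coefficients are fit per breast-cancer subtype (TNBC or HR+/HER2-) by
ordinary least squares on the binary outcome coded pCR = 1, residual = 0
(a linear probability model; a logistic fit is available behind a flag for
sensitivity analysis).  A decision threshold is then chosen on the
training scores to maximize training accuracy, and patients score >=
threshold are called pCR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import PCR, RESIDUAL, _canon

__all__ = [
    "Subtype",
    "PatientFeatureRecord",
    "ScoreModel",
    "compute_score",
    "fit_score_model",
    "select_threshold",
    "classify",
    "records_to_frame",
    "frame_to_records",
]

Subtype = Literal["TNBC", "HR+/HER2-"]
_VALID_SUBTYPES = {"TNBC", "HR+/HER2-"}
_FEATURES = ("metabolic_activity", "angiogenesis")


@dataclass(frozen=True)
class PatientFeatureRecord:
    """Per-patient biophysical features and (optionally) observed outcome."""

    patient_id: str
    subtype: Subtype
    metabolic_activity: float
    angiogenesis: float
    outcome: Optional[str] = None  # "pCR" | "residual" | None

    def __post_init__(self) -> None:
        if self.subtype not in _VALID_SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        for f in _FEATURES:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1], got {v}")
        if self.outcome is not None:
            object.__setattr__(self, "outcome", _canon(self.outcome))


@dataclass
class ScoreModel:
    """Linear score coefficients plus decision threshold for one subtype."""

    subtype: Subtype
    a1: float
    a2: float
    b: float
    threshold: Optional[float] = None
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subtype not in _VALID_SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if not all(np.isfinite([self.a1, self.a2, self.b])):
            raise ValueError("coefficients must be finite")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        return cls(**json.loads(Path(path).read_text()))


def compute_score(model: ScoreModel, rec: PatientFeatureRecord) -> float:
    """Evaluate a1*metabolic + a2*angiogenesis + b for one patient."""
    if rec.subtype != model.subtype:
        raise ValueError(
            f"record subtype {rec.subtype!r} does not match model "
            f"subtype {model.subtype!r}"
        )
    return model.a1 * rec.metabolic_activity + model.a2 * rec.angiogenesis + model.b


def fit_score_model(
    records: Sequence[PatientFeatureRecord],
    subtype: Subtype,
    method: Literal["ols", "logistic"] = "ols",
) -> ScoreModel:
    """Fit the linear score for one subtype on outcome-labelled records.

    OLS regresses the {0, 1}-coded outcome on the two features.  The
    logistic variant (maximum likelihood, no penalty) is offered for
    sensitivity analysis only; its coefficients live on the log-odds scale.
    """
    recs = [r for r in records if r.subtype == subtype]
    if any(r.outcome is None for r in recs):
        raise ValueError("all records must carry an outcome for fitting")
    if len(recs) < 3:
        raise ValueError(f"need >= 3 records of subtype {subtype!r}, got {len(recs)}")
    y = np.array([1.0 if r.outcome == PCR else 0.0 for r in recs])
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present to fit")
    X = np.array([[r.metabolic_activity, r.angiogenesis] for r in recs])

    Xd = np.column_stack([X, np.ones(len(recs))])
    if np.linalg.matrix_rank(Xd) < 3:
        for j, name in enumerate(_FEATURES):
            if np.ptp(X[:, j]) == 0:
                raise np.linalg.LinAlgError(
                    f"design is rank deficient: feature {name!r} is constant"
                )
        raise np.linalg.LinAlgError(
            "design is rank deficient: metabolic_activity and angiogenesis "
            "are collinear"
        )

    if method == "ols":
        from sklearn.linear_model import LinearRegression

        fit = LinearRegression().fit(X, y)
        a1, a2 = fit.coef_
        b = fit.intercept_
    elif method == "logistic":
        import statsmodels.api as sm

        res = sm.Logit(y, sm.add_constant(X)).fit(disp=False)
        b, a1, a2 = res.params
    else:
        raise ValueError(f"unknown method {method!r}")

    return ScoreModel(
        subtype=subtype,
        a1=float(a1),
        a2=float(a2),
        b=float(b),
        threshold=None,
        fit_meta={"n": len(recs), "objective": method},
    )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Deterministic threshold candidates for an accuracy scan.

    Midpoints of adjacent sorted unique scores, bracketed by the lowest
    score (call everyone pCR under the >= rule) and a value just above the
    highest (call everyone residual).
    """
    u = np.unique(scores)
    if u.size == 1:
        return u
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0]], mids, [np.nextafter(u[-1], np.inf)]])


def select_threshold(
    model: ScoreModel, records: Sequence[PatientFeatureRecord]
) -> ScoreModel:
    """Choose the decision threshold maximizing training accuracy.

    Candidates are the midpoints of adjacent sorted unique training scores
    plus the two all-one-class extremes; ties go to the smallest
    maximizer, which makes the rule deterministic.  If every score is
    identical that score is the threshold.
    """
    recs = [r for r in records if r.subtype == model.subtype]
    if not recs or any(r.outcome is None for r in recs):
        raise ValueError("threshold selection needs outcome-labelled records")
    scores = np.array([compute_score(model, r) for r in recs])
    y = np.array([r.outcome == PCR for r in recs])

    best_t, best_acc = None, -1.0
    for t in _candidate_thresholds(scores):
        acc = float(np.mean((scores >= t) == y))
        if acc > best_acc:  # strict: keeps the smallest maximizer
            best_t, best_acc = float(t), acc

    out = ScoreModel(
        subtype=model.subtype,
        a1=model.a1,
        a2=model.a2,
        b=model.b,
        threshold=best_t,
        fit_meta=dict(model.fit_meta, training_accuracy=best_acc),
    )
    return out


def classify(model: ScoreModel, rec: PatientFeatureRecord) -> str:
    """Call pCR iff the patient's score is >= the model threshold."""
    if model.threshold is None:
        raise ValueError("model threshold is unset; run select_threshold first")
    return PCR if compute_score(model, rec) >= model.threshold else RESIDUAL


def records_to_frame(records: Iterable[PatientFeatureRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[PatientFeatureRecord]:
    cols = {"patient_id", "subtype", "metabolic_activity", "angiogenesis"}
    missing = cols - set(df.columns)
    if missing:
        raise KeyError(f"cohort table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        outcome = getattr(row, "outcome", None)
        if outcome is not None and (pd.isna(outcome) or outcome == ""):
            outcome = None
        out.append(
            PatientFeatureRecord(
                patient_id=str(row.patient_id),
                subtype=row.subtype,
                metabolic_activity=float(row.metabolic_activity),
                angiogenesis=float(row.angiogenesis),
                outcome=outcome,
            )
        )
    return out
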
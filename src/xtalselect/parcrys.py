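"""ParCrys: positive-only Parzen-window density scoring.

The model is a kernel density estimate fitted on crystallised reference
proteins only — no 'non-crystallisable' negative set has to be defined.
Eight features are used (pI, GRAVY and the frequencies of S, C, G, F, Y,
M). Each dimension is standardized by the reference mean/sd and smoothed
with a Gaussian product kernel whose per-dimension width follows the
multivariate Scott rule

    h_d = sd_std * (4 / ((d + 2) * n)) ** (1 / (d + 4)),

with sd_std = 1 after standardization. Scores are natural-log densities
(raw 8-D densities underflow); higher means more crystallisation-like.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import evaluation, seqfeat
from .errors import EvaluationError, ModelError
from .seqfeat import FEATURE_ORDER, FeatureVector, ProteinRecord

_LOG_2PI = float(np.log(2.0 * np.pi))
_LOG_FLOOR = float(np.log(np.finfo(float).tiny))


@dataclasses.dataclass(frozen=True)
class ParzenModel:
    """Standardized positive reference points plus per-dimension bandwidths."""

    reference: np.ndarray      # n_ref x d, standardized
    means: np.ndarray          # d
    sds: np.ndarray            # d, after degenerate-dimension handling
    bandwidths: np.ndarray     # d, standardized units
    feature_names: tuple[str, ...] = FEATURE_ORDER
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference.ndim != 2 or self.reference.shape[0] < 2:
            raise ModelError("reference must be an (n>=2) x d matrix")
        if np.any(self.sds <= 0) or np.any(self.bandwidths <= 0):
            raise ModelError("sds and bandwidths must be positive")

    @property
    def n_ref(self) -> int:
        return self.reference.shape[0]

    @property
    def d(self) -> int:
        return self.reference.shape[1]


def scott_bandwidth(n: int, d: int) -> float:
    """Scott/Silverman multivariate rule for unit-variance data."""
    return (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


def _as_matrix(positives) -> np.ndarray:
    if isinstance(positives, np.ndarray):
        return np.asarray(positives, dtype=float)
    return np.stack([fv.as_array() for fv in positives])


def fit_parzen(positives: Sequence[FeatureVector] | np.ndarray,
               feature_names: tuple[str, ...] = FEATURE_ORDER) -> ParzenModel:
    """Fit the density model on positive examples only. Deterministic.

    A dimension with zero variance is uninformative: its sd is replaced
    with 1 (so standardization is a shift) and a warning is emitted.
    """
    x = _as_matrix(positives)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ModelError("fit_parzen needs at least 2 positive examples")
    n, d = x.shape
    means = x.mean(axis=0)
    sds = x.std(axis=0)
    degenerate = sds == 0.0
    if np.any(degenerate):
        names = [feature_names[i] if i < len(feature_names) else str(i)
                 for i in np.flatnonzero(degenerate)]
        warnings.warn("zero-variance dimension(s) "
                      f"{names}: sd set to 1, dimension uninformative",
                      stacklevel=2)
        sds = np.where(degenerate, 1.0, sds)
    reference = (x - means) / sds
    bandwidths = np.full(d, scott_bandwidth(n, d))
    return ParzenModel(
        reference=reference, means=means, sds=sds, bandwidths=bandwidths,
        feature_names=tuple(feature_names[:d]) if d <= len(feature_names)
        else tuple(str(i) for i in range(d)),
        metadata={"model_type": "parcrys", "pka_set": seqfeat.PKA_SET_NAME},
    )


def log_density(x: np.ndarray, model: ParzenModel) -> np.ndarray:
    """Log Parzen density of raw-unit feature rows ``x`` (m x d or d,).

    Overflow-safe: the per-reference kernel log-weights are combined with
    log-sum-exp, and the result is floored at the smallest representable
    positive log so -inf is never returned.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = (x - model.means) / model.sds                      # m x d
    diff = (z[:, None, :] - model.reference[None, :, :]) / model.bandwidths
    log_kernel = (-0.5 * diff ** 2 - np.log(model.bandwidths)
                  - 0.5 * _LOG_2PI).sum(axis=2)            # m x n_ref
    scores = logsumexp(log_kernel, axis=1) - np.log(model.n_ref)
    return np.maximum(scores, _LOG_FLOOR)


def parcrys_score(feature: FeatureVector, model: ParzenModel) -> float:
    """Log-density score of one feature vector; higher = more crystallisation-like."""
    return float(log_density(feature.as_array(), model)[0])


def calibrate_threshold(model: ParzenModel,
                        labelled: Sequence[tuple[FeatureVector, int]]) -> float:
    """MCC-maximising score cut on a labelled set (score >= cut -> positive).

    Ties between equally good cuts break toward the lower threshold. The
    labelled set must contain both classes.
    """
    if not labelled:
        raise EvaluationError("empty labelled set")
    scores = [parcrys_score(fv, model) for fv, _ in labelled]
    labels = [int(lab) for _, lab in labelled]
    if len(set(labels)) < 2:
        raise EvaluationError("calibration needs both classes")
    threshold, _ = evaluation.best_mcc(scores, labels)
    return threshold


def score_records(records: Sequence[ProteinRecord], model: ParzenModel,
                  threshold: float | None = None) -> pd.DataFrame:
    """Score records, descending; adds a binary call iff a threshold is given."""
    rows = []
    for rec in records:
        fv = seqfeat.extract_features(rec)
        rows.append({"id": rec.id, "score": parcrys_score(fv, model)})
    table = pd.DataFrame(rows)
    table = (table.sort_values("score", ascending=False, kind="stable")
             .reset_index(drop=True))
    if threshold is not None:
        table["predicted"] = (table["score"] >= threshold).astype(int)
    return table


def score_fasta_parcrys(path, model: ParzenModel,
                        threshold: float | None = None) -> pd.DataFrame:
    return score_records(seqfeat.read_fasta(path), model, threshold)


def save_model(model: ParzenModel, path) -> None:
    payload = {
        "model_type": "parcrys",
        "feature_order": list(model.feature_names),
        "means": model.means.tolist(),
        "sds": model.sds.tolist(),
        "bandwidths": model.bandwidths.tolist(),
        "reference": model.reference.tolist(),
        "n_ref": model.n_ref,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ParzenModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("model_type") != "parcrys":
        raise ModelError(f"{path}: not a ParCrys model file")
    return ParzenModel(
        reference=np.array(payload["reference"], dtype=float),
        means=np.array(payload["means"], dtype=float),
        sds=np.array(payload["sds"], dtype=float),
        bandwidths=np.array(payload["bandwidths"], dtype=float),
        feature_names=tuple(payload["feature_order"]),
        metadata=payload.get("metadata", {}),
    )
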
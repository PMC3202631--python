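"""Target-selection utilities around the crystallisation scorers.

Three pieces: the Rost-curve rule that decides whether an aligned pair can
be pooled as structurally similar (admission of homologues into a
candidate pool), windowed propensity profiles that help choose construct
boundaries, and ranked candidate tables.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import obscore, parcrys, seqfeat
from .errors import XtalSelectError
from .obscore import ZScoreMatrix
from .parcrys import ParzenModel
from .seqfeat import FeatureVector, ProteinRecord


@dataclasses.dataclass(frozen=True)
class AlignmentSummary:
    """The identity/length summary of one pairwise alignment."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise XtalSelectError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise XtalSelectError("alignment_length must be >= 1")


@dataclasses.dataclass(frozen=True)
class RostParameters:
    """Calibration offset n (identity percentage points) of the Rost curve.

    The curve is search-algorithm dependent, so the offset is exposed
    rather than hard-coded; n = 5 is a conservative default.
    """

    n: float = 5.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise XtalSelectError("Rost offset n must be >= 0")


@dataclasses.dataclass(frozen=True)
class WindowProfile:
    """Per-residue crystallisation-propensity profile of one sequence."""

    sequence_id: str
    per_residue_scores: list[float]
    window: int
    model_name: str

    def to_frame(self, sequence: str | None = None) -> pd.DataFrame:
        frame = pd.DataFrame({
            "position": np.arange(1, len(self.per_residue_scores) + 1),
            "score": self.per_residue_scores,
        })
        if sequence is not None:
            frame.insert(1, "residue", list(sequence))
        return frame


#: Alignment length beyond which the identity curve is held constant. The
#: curve expression is fitted for short-to-medium alignments and misbehaves
#: (a spurious rise) if extrapolated past this point; at the plateau the
#: threshold is n + ~19.5 identity points.
ROST_PLATEAU_LENGTH = 450


def rost_threshold(length: int, params: RostParameters = RostParameters()) -> float:
    """Length-dependent percent-identity threshold for inferred structural
    similarity.

    ``n + 480 * L**(-0.32 * (1 + exp(-L/1000)))`` for L up to 450 residues,
    constant beyond (the curve's plateau, about n + 19.5), capped at 100.
    """
    if length < 1:
        raise XtalSelectError("alignment length must be >= 1")
    eff = min(length, ROST_PLATEAU_LENGTH)
    value = params.n + 480.0 * eff ** (-0.32 * (1.0 + math.exp(-eff / 1000.0)))
    return min(value, 100.0)


def filter_homologues(alignments: Sequence[AlignmentSummary],
                      params: RostParameters = RostParameters(),
                      ) -> list[AlignmentSummary]:
    """Keep alignments at or above the Rost threshold; order preserved."""
    return [a for a in alignments
            if a.percent_identity >= rost_threshold(a.alignment_length, params)]


def read_alignments_tsv(path) -> list[AlignmentSummary]:
    """Read `query_id subject_id percent_identity alignment_length` TSV."""
    table = pd.read_csv(path, sep="\t")
    return [
        AlignmentSummary(
            query_id=str(row.query_id), subject_id=str(row.subject_id),
            percent_identity=float(row.percent_identity),
            alignment_length=int(row.alignment_length))
        for row in table.itertuples(index=False)
    ]


Scorer = ZScoreMatrix | ParzenModel


def score_feature(feature: FeatureVector, scorer: Scorer) -> float:
    """Dispatch a feature vector to whichever fitted scorer was supplied."""
    if isinstance(scorer, ZScoreMatrix):
        return obscore.ob_score(feature, scorer)
    if isinstance(scorer, ParzenModel):
        return parcrys.parcrys_score(feature, scorer)
    raise XtalSelectError(f"unsupported scorer type {type(scorer).__name__}")


def scorer_name(scorer: Scorer) -> str:
    return "obscore" if isinstance(scorer, ZScoreMatrix) else "parcrys"


def window_profile(record: ProteinRecord, scorer: Scorer,
                   window: int = 60, stride: int = 1) -> WindowProfile:
    """Score every window of the sequence; per-residue value is the mean
    over all windows covering that residue.

    A sequence shorter than the window gets one whole-sequence window.
    With stride > 1 a final window flush with the C-terminus is added when
    needed so every residue is covered.
    """
    if window < 10:
        raise XtalSelectError("window must be >= 10 "
                              "(features are meaningless on shorter fragments)")
    if stride < 1:
        raise XtalSelectError("stride must be >= 1")
    seq = record.sequence
    length = len(seq)
    if length <= window:
        starts = [0]
        window_eff = length
    else:
        starts = list(range(0, length - window + 1, stride))
        if starts[-1] != length - window:
            starts.append(length - window)
        window_eff = window
    totals = np.zeros(length)
    cover = np.zeros(length, dtype=int)
    for start in starts:
        sub = ProteinRecord(id=f"{record.id}|{start}",
                            sequence=seq[start:start + window_eff])
        value = score_feature(seqfeat.extract_features(sub), scorer)
        totals[start:start + window_eff] += value
        cover[start:start + window_eff] += 1
    return WindowProfile(
        sequence_id=record.id,
        per_residue_scores=(totals / cover).tolist(),
        window=window,
        model_name=scorer_name(scorer),
    )


def rank_targets(records: Sequence[ProteinRecord], scorer: Scorer,
                 secondary_keys: Sequence[tuple[str, bool]] | None = None,
                 ) -> pd.DataFrame:
    """Candidate table ranked by score (descending), stable for ties.

    ``secondary_keys`` is an optional list of (column, ascending) pairs
    applied after the score, e.g. ``[("length", True)]`` to prefer shorter
    constructs among equal scores.
    """
    rows = []
    for rec in records:
        fv = seqfeat.extract_features(rec)
        rows.append({"id": rec.id, "score": score_feature(fv, scorer),
                     "pI": fv.pI, "gravy": fv.gravy, "length": fv.length})
    table = pd.DataFrame(rows)
    by = ["score"]
    ascending = [False]
    for column, asc in secondary_keys or []:
        by.append(column)
        ascending.append(asc)
    table = (table.sort_values(by, ascending=ascending, kind="stable")
             .reset_index(drop=True))
    table["rank"] = np.arange(1, len(table) + 1)
    return table
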
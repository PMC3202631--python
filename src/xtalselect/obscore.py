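"""OB-Score: a binned pI x hydrophobicity Z-score lookup predictor.

The model is a 2-D grid over isoelectric point and GRAVY. For each bin the
Z-score contrasts the count of crystallised reference proteins with the
count expected from a background sequence population: a positive Z marks a
(pI, GRAVY) region enriched for crystallisable proteins. Scoring a sequence
is a single bin lookup, which is why the OB-Score scales trivially to whole
proteomes.

Z construction: with smoothed background fraction
``b = (bg[i,j] + pc) / (n_bg + pc*K)`` (K = total bin count, pc = Laplace
pseudocount on the background), expected positives ``E = n_pos * b`` and
``Z = (pos[i,j] - E) / sqrt(E * (1 - b))``.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import seqfeat
from .errors import ModelError
from .seqfeat import FeatureVector, ProteinRecord

PI_RANGE = (0.0, 14.0)
GRAVY_RANGE = (-4.5, 4.5)


@dataclasses.dataclass(frozen=True)
class BinGrid:
    """Strictly increasing bin edges spanning the full pI and GRAVY ranges."""

    pi_edges: np.ndarray
    gravy_edges: np.ndarray

    def __post_init__(self) -> None:
        for name, edges, (lo, hi) in (
            ("pi_edges", self.pi_edges, PI_RANGE),
            ("gravy_edges", self.gravy_edges, GRAVY_RANGE),
        ):
            edges = np.asarray(edges, dtype=float)
            object.__setattr__(self, name, edges)
            if edges.ndim != 1 or edges.size < 2:
                raise ModelError(f"{name}: need >=2 edges")
            if not np.all(np.diff(edges) > 0):
                raise ModelError(f"{name}: edges must be strictly increasing")
            if edges[0] > lo or edges[-1] < hi:
                raise ModelError(f"{name}: edges must cover [{lo}, {hi}]")

    @property
    def n_pi(self) -> int:
        return self.pi_edges.size - 1

    @property
    def n_gravy(self) -> int:
        return self.gravy_edges.size - 1

    @property
    def n_bins(self) -> int:
        return self.n_pi * self.n_gravy

    def bin_of(self, pi: float, gravy: float) -> tuple[int, int]:
        """Bin indices of a (pI, GRAVY) point; out-of-range values clamp."""
        i = int(np.clip(np.digitize(pi, self.pi_edges) - 1, 0, self.n_pi - 1))
        j = int(np.clip(np.digitize(gravy, self.gravy_edges) - 1,
                        0, self.n_gravy - 1))
        return i, j


def default_grid(pi_step: float = 0.5, gravy_step: float = 0.25) -> BinGrid:
    """Regular grid: pI every 0.5 pH over [0,14], GRAVY every 0.25 over [-4.5,4.5]."""
    n_pi = round((PI_RANGE[1] - PI_RANGE[0]) / pi_step)
    n_gr = round((GRAVY_RANGE[1] - GRAVY_RANGE[0]) / gravy_step)
    return BinGrid(
        pi_edges=np.linspace(*PI_RANGE, n_pi + 1),
        gravy_edges=np.linspace(*GRAVY_RANGE, n_gr + 1),
    )


@dataclasses.dataclass(frozen=True)
class ZScoreMatrix:
    """The fitted OB-Score model: per-bin Z values plus the raw counts."""

    grid: BinGrid
    z: np.ndarray
    pos_counts: np.ndarray
    bg_counts: np.ndarray
    n_pos: int
    n_bg: int
    pseudocount: float
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (self.grid.n_pi, self.grid.n_gravy)
        if self.z.shape != shape:
            raise ModelError(f"z shape {self.z.shape} != grid shape {shape}")
        if int(self.pos_counts.sum()) != self.n_pos:
            raise ModelError("pos_counts do not sum to n_pos")
        if int(self.bg_counts.sum()) != self.n_bg:
            raise ModelError("bg_counts do not sum to n_bg")
        if not np.all(np.isfinite(self.z)):
            raise ModelError("non-finite Z value in matrix")


def _count_bins(features: Iterable[FeatureVector], grid: BinGrid) -> np.ndarray:
    counts = np.zeros((grid.n_pi, grid.n_gravy), dtype=int)
    for fv in features:
        i, j = grid.bin_of(fv.pI, fv.gravy)
        counts[i, j] += 1
    return counts


def z_values(pos_counts: np.ndarray, bg_counts: np.ndarray,
             n_pos: int, n_bg: int, pseudocount: float) -> np.ndarray:
    """The pinned binomial-expectation Z transform, elementwise over bins."""
    k = pos_counts.size
    b = (bg_counts + pseudocount) / (n_bg + pseudocount * k)
    expected = n_pos * b
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (pos_counts - expected) / np.sqrt(expected * (1.0 - b))
    # pseudocount 0 leaves empty-background bins with E=0; an empty positive
    # bin there carries no evidence either way -> Z := 0
    return np.where(np.isfinite(z), z, 0.0)


def build_zscore_matrix(
    positives: Sequence[FeatureVector],
    background: Sequence[FeatureVector],
    grid: BinGrid | None = None,
    pseudocount: float = 1.0,
    min_pos: int = 10,
    min_bg: int = 10,
) -> ZScoreMatrix:
    """Fit the OB-Score matrix from positive and background feature sets."""
    if grid is None:
        grid = default_grid()
    if len(positives) < min_pos or len(background) < min_bg:
        raise ModelError(
            f"need >= {min_pos} positives and >= {min_bg} background "
            f"feature vectors (got {len(positives)}, {len(background)})")
    if pseudocount < 0:
        raise ModelError("pseudocount must be >= 0")
    pos_counts = _count_bins(positives, grid)
    bg_counts = _count_bins(background, grid)
    z = z_values(pos_counts, bg_counts, len(positives), len(background),
                 pseudocount)
    return ZScoreMatrix(
        grid=grid, z=z, pos_counts=pos_counts, bg_counts=bg_counts,
        n_pos=len(positives), n_bg=len(background), pseudocount=pseudocount,
        metadata={
            "model_type": "obscore",
            "pka_set": seqfeat.PKA_SET_NAME,
            "created": datetime.datetime.now(datetime.UTC).isoformat(),
        },
    )


def ob_score(feature: FeatureVector, matrix: ZScoreMatrix) -> float:
    """Z-score of the bin containing (pI, GRAVY); out-of-range clamps."""
    i, j = matrix.grid.bin_of(feature.pI, feature.gravy)
    return float(matrix.z[i, j])


def score_records(records: Sequence[ProteinRecord],
                  matrix: ZScoreMatrix) -> pd.DataFrame:
    """Score records; descending by score, ties keep input order."""
    rows = []
    for rec in records:
        fv = seqfeat.extract_features(rec)
        rows.append({"id": rec.id, "pI": fv.pI, "gravy": fv.gravy,
                     "score": ob_score(fv, matrix)})
    table = pd.DataFrame(rows)
    return (table.sort_values("score", ascending=False, kind="stable")
            .reset_index(drop=True))


def score_fasta_obscore(path, matrix: ZScoreMatrix) -> pd.DataFrame:
    return score_records(seqfeat.read_fasta(path), matrix)


def save_model(matrix: ZScoreMatrix, path) -> None:
    payload = {
        "model_type": "obscore",
        "pi_edges": matrix.grid.pi_edges.tolist(),
        "gravy_edges": matrix.grid.gravy_edges.tolist(),
        "z": matrix.z.tolist(),
        "pos_counts": matrix.pos_counts.tolist(),
        "bg_counts": matrix.bg_counts.tolist(),
        "n_pos": matrix.n_pos,
        "n_bg": matrix.n_bg,
        "pseudocount": matrix.pseudocount,
        "metadata": matrix.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> ZScoreMatrix:
    payload = json.loads(Path(path).read_text())
    if payload.get("model_type") != "obscore":
        raise ModelError(f"{path}: not an OB-Score model file")
    return ZScoreMatrix(
        grid=BinGrid(pi_edges=np.array(payload["pi_edges"]),
                     gravy_edges=np.array(payload["gravy_edges"])),
        z=np.array(payload["z"], dtype=float),
        pos_counts=np.array(payload["pos_counts"], dtype=int),
        bg_counts=np.array(payload["bg_counts"], dtype=int),
        n_pos=payload["n_pos"],
        n_bg=payload["n_bg"],
        pseudocount=payload["pseudocount"],
        metadata=payload.get("metadata", {}),
    )
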
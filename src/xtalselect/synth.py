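"""Seeded synthetic protein-sequence populations.

Generates two distinguishable populations — a "crystallisable-like"
positive set and a background set — so the predictors, the evaluation
machinery and the selection utilities can be exercised end to end without
any external data. Residues are sampled i.i.d. from a per-population
composition (the implemented scorers are composition-only, so positional
structure would add nothing testable) and lengths from a clipped
log-normal.

The background composition is a built-in average-proteome amino-acid
frequency table (the familiar Swiss-Prot average); the positive
composition perturbs exactly the residues the ParCrys feature set models
(G and F up 1.4x, S and C down 0.6x, renormalized), so the populations
differ in the modelled features and (through the hydropathy of those
residues) mildly in GRAVY.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import XtalSelectError
from .seqfeat import STANDARD_AA, ProteinRecord

LENGTH_CLIP = (30, 2000)

#: Average-proteome residue frequencies (Swiss-Prot composition statistics),
#: normalized to sum to 1. A documented modelling constant of this package.
BACKGROUND_COMPOSITION = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_total = sum(BACKGROUND_COMPOSITION.values())
BACKGROUND_COMPOSITION = {k: v / _total
                          for k, v in BACKGROUND_COMPOSITION.items()}

#: Multiplicative composition shifts defining the positive population.
POSITIVE_SHIFTS = {"G": 1.4, "F": 1.4, "S": 0.6, "C": 0.6}


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic population.

    length_mean/length_sd are the mean and standard deviation of the
    log-normal length distribution in residues; samples are clipped to
    [30, 2000].
    """

    n: int
    composition: dict[str, float]
    seed: int
    length_mean: float = 300.0
    length_sd: float = 150.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise XtalSelectError("n must be >= 1")
        if self.length_mean <= 0 or self.length_sd <= 0:
            raise XtalSelectError("length parameters must be positive")
        if set(self.composition) != set(STANDARD_AA):
            raise XtalSelectError(
                "composition must map exactly the 20 standard residues")
        probs = np.array([self.composition[a] for a in STANDARD_AA])
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise XtalSelectError(
                "composition probabilities must be >= 0 and sum to 1")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_set(spec: GeneratorSpec) -> list[ProteinRecord]:
    """Draw ``spec.n`` records, bit-reproducible for a given seed.

    Ids are ``syn_<seed>_<k>`` with k counting from 0.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sigma = _lognormal_params(spec.length_mean, spec.length_sd)
    lengths = np.clip(np.round(rng.lognormal(mu, sigma, size=spec.n)),
                      *LENGTH_CLIP).astype(int)
    letters = np.array(list(STANDARD_AA))
    probs = np.array([spec.composition[a] for a in STANDARD_AA])
    probs = probs / probs.sum()
    records = []
    for k, length in enumerate(lengths):
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append(ProteinRecord(id=f"syn_{spec.seed}_{k}", sequence=seq))
    return records


def default_background_spec(n: int, seed: int) -> GeneratorSpec:
    """Background population: average-proteome composition, mean length 300."""
    return GeneratorSpec(n=n, composition=dict(BACKGROUND_COMPOSITION),
                         seed=seed)


def shifted_composition(base: dict[str, float],
                        shifts: dict[str, float]) -> dict[str, float]:
    """Apply multiplicative per-residue shifts and renormalize."""
    comp = {aa: p * shifts.get(aa, 1.0) for aa, p in base.items()}
    total = sum(comp.values())
    return {aa: p / total for aa, p in comp.items()}


def default_positive_spec(n: int, seed: int) -> GeneratorSpec:
    """Crystallisable-like population: background shifted in the modelled
    residues (G, F enriched; S, C depleted)."""
    return GeneratorSpec(
        n=n,
        composition=shifted_composition(BACKGROUND_COMPOSITION,
                                        POSITIVE_SHIFTS),
        seed=seed)


def generate_labelled_dataset(n_pos: int, n_neg: int, seed: int,
                              ) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Shuffled positive + background records with a two-column label table.

    Positives use ``seed``, background ``seed + 1`` (distinct id spaces),
    and the shuffle draws from ``seed + 2``; everything is reproducible
    from the single argument.
    """
    positives = generate_set(default_positive_spec(n_pos, seed))
    negatives = generate_set(default_background_spec(n_neg, seed + 1))
    records = positives + negatives
    labels = [1] * n_pos + [0] * n_neg
    order = np.random.default_rng(seed + 2).permutation(len(records))
    records = [records[i] for i in order]
    labels = [labels[i] for i in order]
    table = pd.DataFrame({"id": [r.id for r in records], "label": labels})
    return records, table


def write_labels_tsv(table: pd.DataFrame, path) -> None:
    """Write the plain two-column (id, label) TSV, no header."""
    table.to_csv(path, sep="\t", index=False, header=False)


def read_labels_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["id", "label"])
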
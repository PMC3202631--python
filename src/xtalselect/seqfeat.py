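"""Sequence-derived features for crystallisation-propensity prediction.

This module is the feature layer shared by the OB-Score and ParCrys
predictors: FASTA I/O, sequence validation, grand average of hydropathy
(GRAVY, Kyte–Doolittle scale), isoelectric point (pI, fixed pKa model,
bisection), and single-residue frequencies.

Ambiguity codes X/B/Z/U are accepted on input but masked: they contribute
to sequence length, never to GRAVY, charge groups or frequency denominators.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaFormatError, SequenceError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA = "XBZU"
_ALLOWED = set(STANDARD_AA) | set(AMBIGUOUS_AA)

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: EMBOSS default pKa values for the titratable groups of the charge model.
#: Models built with one pKa set are only comparable within that set, so the
#: set name travels in model metadata.
PKA_SET_NAME = "EMBOSS"
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_ACIDIC = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
PKA_BASIC = {"H": 6.5, "K": 10.8, "R": 12.5}

#: Fixed feature order of the ParCrys model; recorded in model files.
FEATURE_ORDER = ("pI", "gravy", "freq_S", "freq_C", "freq_G", "freq_F",
                 "freq_Y", "freq_M")
PARCRYS_RESIDUES = ("S", "C", "G", "F", "Y", "M")


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence, cleaned and validated."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be a non-empty token")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """The 8 predictive features plus length for one sequence.

    pI is a pH in [0, 14]; gravy is the mean Kyte–Doolittle hydropathy in
    [-4.5, 4.5]; freq_* are residue fractions of the six residues S, C, G,
    F, Y, M used by ParCrys.
    """

    pI: float
    gravy: float
    freq_S: float
    freq_C: float
    freq_G: float
    freq_F: float
    freq_Y: float
    freq_M: float
    length: int

    def as_array(self):
        import numpy as np

        return np.array([getattr(self, name) for name in FEATURE_ORDER],
                        dtype=float)


def validate_sequence(raw: str) -> str:
    """Clean a raw sequence: uppercase, strip whitespace and '*'.

    Ambiguity codes X/B/Z/U are kept (they are masked downstream). Any
    other non-standard character raises :class:`SequenceError` naming the
    character and its 1-based position in the cleaned string.
    """
    cleaned = "".join(raw.split()).replace("*", "").upper()
    if not cleaned:
        raise SequenceError("sequence empty after cleaning")
    for pos, char in enumerate(cleaned, start=1):
        if char not in _ALLOWED:
            raise SequenceError(
                f"illegal character {char!r} at position {pos}")
    return cleaned


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into cleaned :class:`ProteinRecord` objects.

    Preserves file order; multi-line bodies are concatenated. Raises
    :class:`FastaFormatError` on an empty file, an empty record body or
    duplicate ids.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            body = str(rec.seq)
            if not body.strip().replace("*", ""):
                raise FastaFormatError(
                    f"{path}: record {rec.id!r} has an empty sequence body")
            seen[rec.id] = seen.get(rec.id, 0) + 1
            records.append(ProteinRecord(
                id=rec.id,
                sequence=validate_sequence(body),
                description=rec.description.removeprefix(rec.id).strip(),
            ))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    duplicates = sorted(k for k, v in seen.items() if v > 1)
    if duplicates:
        raise FastaFormatError(f"{path}: duplicate ids: {', '.join(duplicates)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def compute_gravy(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy over scoreable (non-masked) residues.

    Computed from residue counts (fraction * scale value) so a homopolymer
    returns its scale value exactly, with no accumulation error.
    """
    counts = {aa: sequence.count(aa) for aa in KYTE_DOOLITTLE}
    n = sum(counts.values())
    if n == 0:
        raise SequenceError("no scoreable residues for GRAVY "
                            "(all positions ambiguity-masked)")
    return sum((c / n) * KYTE_DOOLITTLE[aa]
               for aa, c in counts.items() if c)


def _net_charge(counts: dict[str, int], ph: float) -> float:
    # Henderson-Hasselbalch per titratable group; counts include the termini
    # as pseudo-residues "Nterm"/"Cterm" with count 1.
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - ph))
    for aa, pka in PKA_BASIC.items():
        charge += counts.get(aa, 0) / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in PKA_ACIDIC.items():
        charge -= counts.get(aa, 0) / (1.0 + 10.0 ** (pka - ph))
    return charge


def net_charge(sequence: str, ph: float) -> float:
    """Net charge of the sequence at a given pH under the fixed pKa model."""
    counts = {aa: sequence.count(aa) for aa in (*PKA_ACIDIC, *PKA_BASIC)}
    return _net_charge(counts, ph)


def compute_pI(sequence: str, tol: float = 1e-3, max_iter: int = 100) -> float:
    """Isoelectric point: pH of zero net charge, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so bisection always
    converges. Charge at pH 0 is positive and at pH 14 negative for every
    sequence (the termini alone guarantee both signs).
    """
    counts = {aa: sequence.count(aa) for aa in (*PKA_ACIDIC, *PKA_BASIC)}
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _net_charge(counts, mid) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def residue_frequencies(sequence: str) -> dict[str, float]:
    """Fractions of the 20 standard residues; masked positions excluded.

    Fractions sum to 1 over counted residues.
    """
    counted = [c for c in sequence if c in KYTE_DOOLITTLE]
    if not counted:
        raise SequenceError("no countable residues "
                            "(all positions ambiguity-masked)")
    n = len(counted)
    return {aa: counted.count(aa) / n for aa in STANDARD_AA}


def extract_features(record: ProteinRecord) -> FeatureVector:
    """Compute the full feature vector for one record.

    Pure function of the sequence: the id and description never influence
    the result.
    """
    freqs = residue_frequencies(record.sequence)
    return FeatureVector(
        pI=compute_pI(record.sequence),
        gravy=compute_gravy(record.sequence),
        freq_S=freqs["S"],
        freq_C=freqs["C"],
        freq_G=freqs["G"],
        freq_F=freqs["F"],
        freq_Y=freqs["Y"],
        freq_M=freqs["M"],
        length=len(record.sequence),
    )


def features_table(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    """Feature table with one row per record, in input order."""
    rows = []
    for rec in records:
        fv = extract_features(rec)
        rows.append({"id": rec.id, **dataclasses.asdict(fv)})
    return pd.DataFrame(rows)


def write_features_tsv(table: pd.DataFrame, path) -> None:
    """Write a feature table as TSV with 6-decimal fixed-point floats."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
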
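"""In-silico molecular properties of cystine-dense peptide sequences.

Masses assume full disulfide oxidation: every pair of cysteines forms a
bond, and each formed bond removes two hydrogen atoms from the linear
peptide mass. Net charge at a given pH follows the Henderson-Hasselbalch
sum over ionizable groups, with disulfide-bonded cysteines excluded from
the acidic set. Hydrophobicity is the mean per-residue scale value (GRAVY
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from . import _constants as C


class SequenceError(ValueError):
    """Invalid amino-acid sequence."""


@dataclass(frozen=True)
class PeptideSequence:
    """Validated uppercase sequence with derived cysteine/disulfide counts."""

    sequence: str
    n_cys: int
    n_disulfides: int

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_free_thiols(self) -> int:
        return self.n_cys - 2 * self.n_disulfides


def parse_sequence(text: str) -> PeptideSequence:
    """Canonicalize and validate an amino-acid string.

    Whitespace is stripped, case normalized to upper. Characters outside the
    20 standard one-letter codes are rejected; the common ambiguity codes
    (B, J, O, U, X, Z) get a named-residue error message.
    """
    seq = "".join(text.split()).upper()
    if not seq:
        raise SequenceError("empty sequence")
    for ch in seq:
        if ch not in C.RESIDUE_MONO_MASS:
            name = C.NONSTANDARD_RESIDUE_NAMES.get(ch)
            detail = f" ({name})" if name else ""
            raise SequenceError(
                f"invalid residue {ch!r}{detail}: only the 20 standard "
                "one-letter codes are accepted"
            )
    n_cys = seq.count("C")
    return PeptideSequence(sequence=seq, n_cys=n_cys, n_disulfides=n_cys // 2)


def _as_peptide(seq: PeptideSequence | str) -> PeptideSequence:
    return seq if isinstance(seq, PeptideSequence) else parse_sequence(seq)


def monoisotopic_mass(seq: PeptideSequence | str) -> float:
    """Monoisotopic mass (Da) with the disulfide correction.

    mass = sum(residue monoisotopic masses) + water
           - n_disulfides * 2 * m_H(monoisotopic)
    """
    pep = _as_peptide(seq)
    linear = sum(C.RESIDUE_MONO_MASS[a] for a in pep.sequence) + C.WATER_MONO
    return linear - pep.n_disulfides * 2 * C.MONO_H


def average_mass(seq: PeptideSequence | str) -> float:
    """Average mass (Da) with the disulfide correction (average H mass)."""
    pep = _as_peptide(seq)
    linear = sum(C.RESIDUE_AVG_MASS[a] for a in pep.sequence) + C.WATER_AVG
    return linear - pep.n_disulfides * 2 * C.HYDROGEN_AVG


def net_charge(
    seq: PeptideSequence | str,
    ph: float = 7.4,
    pka_table: str = C.DEFAULT_PKA_TABLE,
) -> float:
    """Net charge (elementary charges) at the given pH.

    Basic groups (N-terminus, K, R, H) each contribute
    ``+1 / (1 + 10**(ph - pKa))``; acidic groups (C-terminus, D, E, Y, and
    free-thiol cysteines only) each contribute ``-1 / (1 + 10**(pKa - ph))``.
    The ``2 * n_disulfides`` bonded cysteines carry no thiol charge.
    """
    if not 0 < ph < 14:
        raise ValueError("ph must be in (0, 14)")
    try:
        pka = C.PKA_TABLES[pka_table]
    except KeyError:
        raise ValueError(
            f"unknown pKa table {pka_table!r}; available: {sorted(C.PKA_TABLES)}"
        ) from None
    pep = _as_peptide(seq)

    def basic(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def acidic(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = basic(pka["n_term"]) + acidic(pka["c_term"])
    for aa in C.BASIC_SIDECHAINS:
        charge += pep.sequence.count(aa) * basic(pka[aa])
    for aa in C.ACIDIC_SIDECHAINS:
        charge += pep.sequence.count(aa) * acidic(pka[aa])
    charge += pep.n_free_thiols * acidic(pka["C"])
    return charge


def hydrophobicity(
    seq: PeptideSequence | str,
    scale: str = C.DEFAULT_HYDROPHOBICITY_SCALE,
) -> float:
    """Mean per-residue hydrophobicity (GRAVY for the default scale)."""
    try:
        table = C.HYDROPHOBICITY_SCALES[scale]
    except KeyError:
        raise ValueError(
            f"unknown hydrophobicity scale {scale!r}; "
            f"available: {sorted(C.HYDROPHOBICITY_SCALES)}"
        ) from None
    pep = _as_peptide(seq)
    return sum(table[a] for a in pep.sequence) / len(pep)


@dataclass(frozen=True)
class ChargeStateMatch:
    observed_mz: float
    matched_charge: int | None
    theoretical_mz: float | None
    valid: bool
    tol_ppm: float


def theoretical_mz(seq: PeptideSequence | str, charge: int) -> float:
    """m/z of the [M + zH]^z+ ion (proton mass, not hydrogen atom mass)."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(seq) + charge * C.PROTON_MASS) / charge


def validate_mz(
    observed_mz: float,
    seq: PeptideSequence | str,
    max_charge: int = 6,
    tol_ppm: float = 20.0,
) -> ChargeStateMatch:
    """Check an observed m/z against charge states 1..max_charge.

    The match is valid when some charge state's theoretical m/z lies within
    ``tol_ppm`` parts-per-million of the observation; the smallest matching
    charge is reported.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    if not observed_mz > 0:
        raise ValueError("observed_mz must be > 0")
    pep = _as_peptide(seq)
    for z in range(1, max_charge + 1):
        mz = theoretical_mz(pep, z)
        if abs(observed_mz - mz) <= tol_ppm * 1e-6 * mz:
            return ChargeStateMatch(
                observed_mz=observed_mz,
                matched_charge=z,
                theoretical_mz=mz,
                valid=True,
                tol_ppm=tol_ppm,
            )
    return ChargeStateMatch(
        observed_mz=observed_mz,
        matched_charge=None,
        theoretical_mz=None,
        valid=False,
        tol_ppm=tol_ppm,
    )


@dataclass(frozen=True)
class DuplicateRecord:
    index: int            # position in the new-sequence list
    sequence: str
    matches: str          # "registry" or "batch"


def find_duplicates(
    new_seqs: Sequence[PeptideSequence | str],
    registry: Iterable[PeptideSequence | str] = (),
) -> list[DuplicateRecord]:
    """Report new sequences identical to registry entries or earlier new ones.

    Comparison is exact string match after canonicalization, so case and
    whitespace differences do not evade the check.
    """
    known = {_as_peptide(s).sequence for s in registry}
    seen_batch: set[str] = set()
    duplicates: list[DuplicateRecord] = []
    for i, raw in enumerate(new_seqs):
        seq = _as_peptide(raw).sequence
        if seq in known:
            duplicates.append(DuplicateRecord(index=i, sequence=seq, matches="registry"))
        elif seq in seen_batch:
            duplicates.append(DuplicateRecord(index=i, sequence=seq, matches="batch"))
        seen_batch.add(seq)
    return duplicates


@dataclass(frozen=True)
class MolecularProperties:
    average_mass: float
    monoisotopic_mass: float
    net_charge_ph74: float
    hydrophobicity: float


def molecular_properties(seq: PeptideSequence | str, ph: float = 7.4) -> MolecularProperties:
    pep = _as_peptide(seq)
    return MolecularProperties(
        average_mass=average_mass(pep),
        monoisotopic_mass=monoisotopic_mass(pep),
        net_charge_ph74=net_charge(pep, ph=ph),
        hydrophobicity=hydrophobicity(pep),
    )


__all__ = [
    "PeptideSequence",
    "SequenceError",
    "MolecularProperties",
    "ChargeStateMatch",
    "DuplicateRecord",
    "parse_sequence",
    "monoisotopic_mass",
    "average_mass",
    "net_charge",
    "hydrophobicity",
    "theoretical_mz",
    "validate_mz",
    "find_duplicates",
    "molecular_properties",
]
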
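"""ProtParam-style physicochemical profiling of protein sequences.

Implements the standard panel used to characterize gene-family members:
average molecular weight, isoelectric point (bisection on the
Henderson-Hasselbalch net charge with the Bjellqvist pK set), GRAVY
(mean Kyte-Doolittle hydropathy), the Guruprasad instability index, and
the Ikai aliphatic index.  An instability index below 40 predicts
in-vitro stability.

Unknown residues (``X``) are tolerated up to a configurable fraction
(default 5%) and excluded from the sums; beyond the tolerance the profile
is refused because the indices are undefined for unknowns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .io_formats import ProteinRecord, ValidationError
from .physchem_data import (
    DIWV, KYTE_DOOLITTLE, PK_NEGATIVE, PK_POSITIVE, RESIDUE_MASS, WATER_MASS,
)

INSTABILITY_THRESHOLD = 40.0


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    mw_kda: float
    pi: float
    gravy: float
    instability_index: float
    aliphatic_index: float
    stable: bool

    def __post_init__(self) -> None:
        assert self.mw_kda > 0 and 0 < self.pi < 14
        assert self.stable == (self.instability_index < INSTABILITY_THRESHOLD)


def _known_residues(protein: ProteinRecord, max_unknown_frac: float) -> str:
    frac = protein.n_unknown / len(protein)
    if frac > max_unknown_frac:
        raise ValidationError(
            f"{protein.id}: {frac:.1%} unknown residues exceeds the "
            f"{max_unknown_frac:.0%} tolerance")
    return protein.sequence.replace("X", "")


def molecular_weight(protein: ProteinRecord, max_unknown_frac: float = 0.05) -> float:
    """Average molecular weight in kDa (residue masses + one water)."""
    seq = _known_residues(protein, max_unknown_frac)
    if not seq:
        raise ValidationError(f"{protein.id}: no known residues")
    return (sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS) / 1000.0


def gravy(protein: ProteinRecord, max_unknown_frac: float = 0.05) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    seq = _known_residues(protein, max_unknown_frac)
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def _net_charge(seq: str, ph: float) -> float:
    pos = 1.0 / (1.0 + 10.0 ** (ph - PK_POSITIVE["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (PK_NEGATIVE["Cterm"] - ph))
    for aa, pk in PK_POSITIVE.items():
        if aa != "Nterm":
            pos += seq.count(aa) / (1.0 + 10.0 ** (ph - pk))
    for aa, pk in PK_NEGATIVE.items():
        if aa != "Cterm":
            neg += seq.count(aa) / (1.0 + 10.0 ** (pk - ph))
    return pos - neg


def isoelectric_point(protein: ProteinRecord, max_unknown_frac: float = 0.05,
                      tol: float = 1e-4) -> float:
    """pH at which the Henderson-Hasselbalch net charge vanishes (bisection)."""
    seq = _known_residues(protein, max_unknown_frac)
    lo, hi = 0.0, 14.0
    mid = 7.0
    # bisect to 1e-6 pH units; the net charge at the returned pH is then
    # well inside the charge tolerance as well
    while hi - lo > 1e-6 or abs(_net_charge(seq, mid)) >= tol:
        mid = (lo + hi) / 2.0
        if _net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    return mid


def instability_index(protein: ProteinRecord, max_unknown_frac: float = 0.05) -> float:
    """Guruprasad index: (10/L) x sum of dipeptide weight values."""
    seq = _known_residues(protein, max_unknown_frac)
    if len(seq) < 2:
        raise ValidationError(f"{protein.id}: need >= 2 residues for instability index")
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def aliphatic_index(protein: ProteinRecord, max_unknown_frac: float = 0.05) -> float:
    """Ikai index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), X in mole percent."""
    seq = _known_residues(protein, max_unknown_frac)
    n = len(seq)
    x = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def profile(protein: ProteinRecord, max_unknown_frac: float = 0.05) -> PhyschemProfile:
    ii = instability_index(protein, max_unknown_frac)
    return PhyschemProfile(
        protein_id=protein.id,
        length=len(protein),
        mw_kda=molecular_weight(protein, max_unknown_frac),
        pi=isoelectric_point(protein, max_unknown_frac),
        gravy=gravy(protein, max_unknown_frac),
        instability_index=ii,
        aliphatic_index=aliphatic_index(protein, max_unknown_frac),
        stable=ii < INSTABILITY_THRESHOLD,
    )


def profile_table(proteins, max_unknown_frac: float = 0.05):
    """Profiles for a batch of proteins as a pandas DataFrame (2-decimal report)."""
    import pandas as pd

    rows = [asdict(profile(p, max_unknown_frac)) for p in proteins]
    df = pd.DataFrame(rows)
    for col in ("mw_kda", "pi", "gravy", "instability_index", "aliphatic_index"):
        df[col] = df[col].round(2)
    return df
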
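"""Codon-level Ka/Ks by Nei-Gojobori (1986) counting and molecular-clock dating.

The method counts synonymous (S) and nonsynonymous (N) *sites* per codon as
the expected fraction of the three possible single-nucleotide changes at
each position that preserve the encoded amino acid, and synonymous (Sd) and
nonsynonymous (Nd) *differences* between codon pairs by averaging over all
mutational pathways (orders of the differing positions).  Proportions are
corrected for multiple hits with the Jukes-Cantor formula

    d = -(3/4) ln(1 - (4/3) p)

and divergence time is dated with the molecular clock T = Ks / (2 lambda),
with lambda the per-site per-year synonymous substitution rate.

Conventions (NG86 implementations differ; these are documented choices):

* a change producing a stop codon counts as nonsynonymous for site counting,
  so S + N = 3 x (codon count) exactly;
* pathways passing through a stop codon are excluded from the Sd/Nd average;
  if every pathway does, all pathways are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .genetics import NUCLEOTIDES, STOP_CODONS, codons_of, translate_cds, translate_codon
from .io_formats import CdsRecord, ValidationError


class SaturationError(ValueError):
    """Observed difference proportion too large for the distance correction."""


@dataclass(frozen=True)
class CodonAlignment:
    """Two gapless, in-frame, codon-aligned sequences of equal codon count."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValidationError("codon sequences differ in length")
        for codons in (self.codons_a, self.codons_b):
            for c in codons:
                if c in STOP_CODONS:
                    raise ValidationError(f"internal stop codon {c}")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    omega: float | None          # None when ks == 0 (undefined, not 0 or inf)
    S: float
    N: float
    Sd: float
    Nd: float
    positive_selection: bool
    divergence_time_mya: float | None

    @property
    def purifying(self) -> bool:
        return self.omega is not None and self.omega < 1.0


def codon_align(cds_a: CdsRecord, cds_b: CdsRecord,
                aligned_a: str, aligned_b: str) -> CodonAlignment:
    """Back-thread a pairwise protein alignment onto the two CDS records.

    ``aligned_a``/``aligned_b`` are the two gapped rows of a protein
    alignment of the translations.  Columns where either row is a gap are
    dropped; every retained residue pair maps to its codon pair.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("alignment rows differ in length")
    prot_a, prot_b = translate_cds(cds_a.sequence), translate_cds(cds_b.sequence)
    if aligned_a.replace("-", "") != prot_a:
        raise ValidationError(f"alignment row does not match translation of {cds_a.id}")
    if aligned_b.replace("-", "") != prot_b:
        raise ValidationError(f"alignment row does not match translation of {cds_b.id}")
    cod_a, cod_b = codons_of(cds_a.sequence), codons_of(cds_b.sequence)
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for col_a, col_b in zip(aligned_a, aligned_b):
        if col_a != "-" and col_b != "-":
            out_a.append(cod_a[i])
            out_b.append(cod_b[j])
        if col_a != "-":
            i += 1
        if col_b != "-":
            j += 1
    return CodonAlignment(tuple(out_a), tuple(out_b))


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3); changes to stops are nonsynonymous."""
    aa = translate_codon(codon)
    syn = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, pathway-averaged."""
    diff_positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_positions:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []       # (syn steps, nonsyn steps)
    clean_paths: list[tuple[int, int]] = []  # paths avoiding stop intermediates
    for order in permutations(diff_positions):
        current = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
                nonsyn += 1
            elif current in STOP_CODONS:
                through_stop = True
                nonsyn += 1
            elif translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        paths.append((syn, nonsyn))
        if not through_stop:
            clean_paths.append((syn, nonsyn))
    used = clean_paths if clean_paths else paths
    sd = sum(p[0] for p in used) / len(used)
    nd = sum(p[1] for p in used) / len(used)
    return sd, nd


def ng86_counts(aln: CodonAlignment) -> tuple[float, float, float, float]:
    """Return (S, N, Sd, Nd); site counts averaged over the two sequences."""
    s_a = sum(_codon_sites(c) for c in aln.codons_a)
    s_b = sum(_codon_sites(c) for c in aln.codons_b)
    S = (s_a + s_b) / 2.0
    N = 3.0 * aln.n_codons - S
    Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(
            f"difference proportion p={p:.4f} >= 3/4: distance is saturated")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def date_pair(ks: float, lambda_rate: float = 8.12e-9) -> float:
    """Divergence time in Mya from Ks via the molecular clock T = Ks / (2 lambda)."""
    if lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    if ks < 0 or not math.isfinite(ks):
        raise ValueError("ks must be finite and nonnegative")
    return ks / (2.0 * lambda_rate) / 1e6


def kaks(aln: CodonAlignment, lambda_rate: float = 8.12e-9) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction and clock dating."""
    S, N, Sd, Nd = ng86_counts(aln)
    if S <= 0 or N <= 0:
        raise ValidationError("degenerate alignment: zero synonymous or nonsynonymous sites")
    ks = jukes_cantor(Sd / S)
    ka = jukes_cantor(Nd / N)
    omega = ka / ks if ks > 0 else None
    return KaKsResult(
        ka=ka, ks=ks, omega=omega, S=S, N=N, Sd=Sd, Nd=Nd,
        positive_selection=(omega is not None and omega > 1.0),
        divergence_time_mya=date_pair(ks, lambda_rate),
    )
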
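"""Synthetic genomes, gene families, expression and qPCR data with planted truth.

The generator emulates the input structure of a genome-wide gene-family
study in an allotetraploid plant: two subgenomes (Chr.01-10 and Chr.11-20),
homeologous whole-genome-duplicate (WGD) gene pairs at low synonymous
divergence, older segmental duplicates at high divergence, one adjacent
tandem duplicate, family proteins carrying the diagnostic motifs of
heavy-metal P-type ATPases, tissue-preferential expression forming two
clusters, and qPCR Ct values with cultivar x treatment effects.

Every planted parameter is written to a truth table so each downstream
analysis stage can be validated by exact or statistical recovery.  With a
fixed seed all outputs are byte-identical; each artifact draws from its own
random stream derived from the master seed, so adding an artifact never
perturbs the others.

Sequence divergence is planted as a uniform-rate codon substitution
process: the number of synonymous events is Poisson with mean Ks x S (S =
Nei-Gojobori synonymous site count) and the number of nonsynonymous events
Poisson with mean omega x Ks x N; proposed point mutations creating stop
codons are rejected.  Realized event counts are recorded, making recovery
tests self-calibrating.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import CODON_TABLE, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS, translate_cds
from .io_formats import (
    CdsRecord, DomainHit, GeneModel, ProteinRecord, SimilarityHit,
    assign_ranks, write_blast_tabular, write_domain_table, write_fasta,
    write_gff3,
)
from .molecular_evolution import _codon_sites

CORE_MOTIFS = ("TGE", "DKTGT", "CPC", "GDGANDAP", "HP", "PGGK")
_MOTIF_SCRUB = re.compile(r"TGE|DKTGT|[CS]PC|GDG.ND.P")

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Master parameters of a synthetic study.

    Defaults mirror the emulated study design: a 20-chromosome
    allotetraploid (10 per subgenome), a 21-member family in six
    subfamilies with a 10 WGD / 4 segmental / 1 tandem duplication split,
    2 cultivars x 4 treatments (control, Cu, Zn, Cd) x 3 replicates.
    """

    seed: int = 0
    n_chromosomes_per_subgenome: int = 10
    n_background_genes: int = 30       # per chromosome
    n_family_codons: int = 300         # ancestral CDS length (sense codons)
    n_background_codons: int = 200
    block_length: int = 8              # planted collinear run, in anchors
    block_start_rank: int = 10
    n_replicates: int = 3
    ct_noise_sd: float = 0.15
    expression_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("ANOVA needs within-group degrees of freedom: "
                             "n_replicates must be >= 2")


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str
    gene_b: str
    event_type: str       # wgd | segmental | tandem
    planted_ks: float
    planted_omega: float
    structure_event: str  # identical | gain_loss | insertion_deletion | exonization


#: Planted family design: subfamily -> member names, and the 15 duplicate
#: pairs with Ks/omega magnitudes matching a recent allopolyploidy (low-Ks
#: WGD pairs), older segmental duplicates (high Ks), and one very recent
#: tandem copy.  Pair Ks values for members generated along a shared
#: lineage are path sums; the truth table records realized counts.
DEFAULT_PAIRS: tuple[PlantedPair, ...] = (
    PlantedPair("SynHMA1.1", "SynHMA1.2", "wgd", 0.024, 0.089, "insertion_deletion"),
    PlantedPair("SynHMA3.1", "SynHMA3.2", "wgd", 0.043, 0.228, "identical"),
    PlantedPair("SynHMA5.1", "SynHMA5.5", "wgd", 0.030, 0.208, "exonization"),
    PlantedPair("SynHMA5.2", "SynHMA5.6", "wgd", 0.040, 0.343, "insertion_deletion"),
    PlantedPair("SynHMA5.3", "SynHMA5.7", "wgd", 0.064, 0.384, "exonization"),
    PlantedPair("SynHMA5.4", "SynHMA5.8", "wgd", 0.020, 0.565, "insertion_deletion"),
    PlantedPair("SynHMA6.1", "SynHMA6.2", "wgd", 0.012, 0.122, "gain_loss"),
    PlantedPair("SynHMA7.1", "SynHMA7.4", "wgd", 0.019, 0.256, "gain_loss"),
    PlantedPair("SynHMA7.2", "SynHMA7.5", "wgd", 0.039, 0.399, "insertion_deletion"),
    PlantedPair("SynHMA8.1", "SynHMA8.2", "wgd", 0.098, 0.489, "gain_loss"),
    PlantedPair("SynHMA5.1", "SynHMA5.2", "segmental", 0.631, 0.157, "identical"),
    PlantedPair("SynHMA5.5", "SynHMA5.6", "segmental", 0.701, 0.119, "na"),
    PlantedPair("SynHMA7.1", "SynHMA7.2", "segmental", 0.631, 0.157, "identical"),
    PlantedPair("SynHMA7.4", "SynHMA7.5", "segmental", 0.689, 0.130, "na"),
    PlantedPair("SynHMA7.2", "SynHMA7.3", "tandem", 0.009, 0.755, "identical"),
)

#: member -> (chromosome, rank); WGD partners sit at matching ranks on the
#: homeologous chromosome (Chr.i <-> Chr.i+10); tandem partner is adjacent.
DEFAULT_PLACEMENT: dict[str, tuple[str, int]] = {
    "SynHMA1.1": ("Chr.01", 13), "SynHMA1.2": ("Chr.11", 13),
    "SynHMA3.1": ("Chr.03", 12), "SynHMA3.2": ("Chr.13", 12),
    "SynHMA5.1": ("Chr.02", 13), "SynHMA5.5": ("Chr.12", 13),
    "SynHMA5.2": ("Chr.05", 13), "SynHMA5.6": ("Chr.15", 13),
    "SynHMA5.3": ("Chr.03", 16), "SynHMA5.7": ("Chr.13", 16),
    "SynHMA5.4": ("Chr.04", 13), "SynHMA5.8": ("Chr.14", 13),
    "SynHMA6.1": ("Chr.06", 13), "SynHMA6.2": ("Chr.16", 13),
    "SynHMA7.1": ("Chr.07", 13), "SynHMA7.4": ("Chr.17", 13),
    "SynHMA7.2": ("Chr.10", 13), "SynHMA7.5": ("Chr.20", 13),
    "SynHMA7.3": ("Chr.10", 14),
    "SynHMA8.1": ("Chr.08", 13), "SynHMA8.2": ("Chr.18", 13),
}

#: planted collinear blocks as chromosome pairs; anchors run over the
#: configured rank window on both chromosomes.
DEFAULT_BLOCKS: tuple[tuple[str, str], ...] = (
    ("Chr.01", "Chr.11"), ("Chr.03", "Chr.13"), ("Chr.02", "Chr.12"),
    ("Chr.05", "Chr.15"), ("Chr.04", "Chr.14"), ("Chr.06", "Chr.16"),
    ("Chr.07", "Chr.17"), ("Chr.10", "Chr.20"), ("Chr.08", "Chr.18"),
    ("Chr.02", "Chr.05"), ("Chr.12", "Chr.15"),
    ("Chr.07", "Chr.10"), ("Chr.17", "Chr.20"),
)

#: generation lineage: member -> (parent member or subfamily ancestor, branch Ks, omega)
_LINEAGE: tuple[tuple[str, str, float, float], ...] = (
    ("SynHMA1.1", "anc1", 0.0, 0.3), ("SynHMA1.2", "SynHMA1.1", 0.024, 0.089),
    ("SynHMA3.1", "anc3", 0.0, 0.3), ("SynHMA3.2", "SynHMA3.1", 0.043, 0.228),
    ("SynHMA5.1", "anc5", 0.0, 0.3), ("SynHMA5.2", "SynHMA5.1", 0.631, 0.157),
    ("SynHMA5.5", "SynHMA5.1", 0.030, 0.208), ("SynHMA5.6", "SynHMA5.2", 0.040, 0.343),
    ("SynHMA5.3", "anc5b", 0.0, 0.3), ("SynHMA5.7", "SynHMA5.3", 0.064, 0.384),
    ("SynHMA5.4", "anc5c", 0.0, 0.3), ("SynHMA5.8", "SynHMA5.4", 0.020, 0.565),
    ("SynHMA6.1", "anc6", 0.0, 0.3), ("SynHMA6.2", "SynHMA6.1", 0.012, 0.122),
    ("SynHMA7.1", "anc7", 0.0, 0.3), ("SynHMA7.2", "SynHMA7.1", 0.631, 0.157),
    ("SynHMA7.3", "SynHMA7.2", 0.009, 0.755), ("SynHMA7.4", "SynHMA7.1", 0.019, 0.256),
    ("SynHMA7.5", "SynHMA7.2", 0.039, 0.399),
    ("SynHMA8.1", "anc8", 0.0, 0.3), ("SynHMA8.2", "SynHMA8.1", 0.098, 0.489),
)

SUBFAMILY_OF = {name: name.split("HMA")[1].split(".")[0]
                for name in DEFAULT_PLACEMENT}
#: phylogenetic group labels per subfamily (six groups)
GROUP_OF_SUBFAMILY = {"1": "I", "3": "II", "6": "III", "8": "IV", "7": "V", "5": "VI"}

HIGH_CLUSTER = ("SynHMA1.1", "SynHMA1.2", "SynHMA3.1", "SynHMA3.2",
                "SynHMA5.7", "SynHMA6.1", "SynHMA6.2", "SynHMA7.1",
                "SynHMA7.4", "SynHMA7.5", "SynHMA8.1", "SynHMA8.2")
TISSUES = ("root", "shoot_tip", "leaf", "nodule", "flower",
           "perianth", "pistil", "pericarp", "seed", "seedling")
HIGH_PREF = ("root", "shoot_tip", "leaf", "nodule", "seed")
LOW_PREF = ("perianth", "pistil")

QPCR_GENES = ("SynHMA1.1", "SynHMA1.2", "SynHMA3.1", "SynHMA3.2",
              "SynHMA5.7", "SynHMA6.1", "SynHMA6.2", "SynHMA7.1",
              "SynHMA7.4", "SynHMA7.5", "SynHMA8.1", "SynHMA8.2")
CULTIVARS = ("cvA", "cvB")   # cvB is the high-accumulation cultivar
TREATMENTS = ("control", "Cu", "Zn", "Cd")
ZN_INDUCED = ("SynHMA1.1", "SynHMA1.2", "SynHMA3.1", "SynHMA3.2",
              "SynHMA7.1", "SynHMA7.4", "SynHMA7.5", "SynHMA8.1")


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_BY_AA[aa]
        codons.append(options[rng.integers(0, len(options))])
    return "".join(codons)


def _random_family_protein(rng: np.random.Generator, n_codons: int) -> str:
    """Random protein carrying the diagnostic motif panel at spaced positions."""
    aas = [AA_LETTERS[i] for i in rng.integers(0, 20, size=n_codons)]
    aas[0] = "M"
    gdg = "GDG" + AA_LETTERS[rng.integers(0, 20)] + "ND" + AA_LETTERS[rng.integers(0, 20)] + "P"
    slots = {40: "TGE", 90: "DKTGT", 140: "CPC", 190: gdg, 230: "HP", 250: "PGGK"}
    for pos, motif in slots.items():
        aas[pos:pos + len(motif)] = list(motif)
    return "".join(aas)


def _random_background_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame CDS whose translation avoids the diagnostic motifs."""
    for _ in range(50):
        codons = _random_codons(rng, n_codons)
        codons[0] = "ATG"
        prot = "".join(CODON_TABLE[c] for c in codons)
        if not _MOTIF_SCRUB.search(prot):
            stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
            return "".join(codons) + stop
        # scrub in place: re-randomize the codons under each motif match
        for m in _MOTIF_SCRUB.finditer(prot):
            for k in range(m.start(), m.end()):
                codons[k] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
        prot = "".join(CODON_TABLE[c] for c in codons)
        if not _MOTIF_SCRUB.search(prot):
            stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
            return "".join(codons) + stop
    raise RuntimeError("could not scrub diagnostic motifs from background gene")


def diverge_cds(cds: str, ks: float, omega: float,
                rng: np.random.Generator,
                max_attempts_factor: int = 500,
                protected_residues: frozenset[int] = frozenset()) -> tuple[str, int, int]:
    """Apply the planted substitution process to a CDS (terminal stop kept).

    Returns (mutated cds, realized synonymous events, realized
    nonsynonymous events).  Event counts are Poisson with means Ks x S and
    omega x Ks x N; proposals creating stop codons are rejected, as are
    nonsynonymous proposals inside ``protected_residues`` (0-based residue
    indices; used to keep diagnostic motifs intact over deep branches —
    event counts, hence planted rates, are unaffected).
    """
    if ks < 0 or omega <= 0:
        raise ValueError("ks must be >= 0 and omega > 0")
    body = cds[:-3] if cds[-3:] in STOP_CODONS else cds
    stop = cds[len(body):]
    seq = list(body)
    n_cod = len(body) // 3
    S = sum(_codon_sites(body[i * 3:(i + 1) * 3]) for i in range(n_cod))
    N = 3.0 * n_cod - S
    n_syn = int(rng.poisson(ks * S))
    n_nonsyn = int(rng.poisson(omega * ks * N))
    need_syn, need_nonsyn = n_syn, n_nonsyn
    attempts_left = max_attempts_factor * (need_syn + need_nonsyn + 1)
    while (need_syn > 0 or need_nonsyn > 0) and attempts_left > 0:
        attempts_left -= 1
        pos = int(rng.integers(0, len(seq)))
        old = seq[pos]
        alts = [nt for nt in NUCLEOTIDES if nt != old]
        new = alts[rng.integers(0, 3)]
        c0 = pos // 3 * 3
        codon_old = "".join(seq[c0:c0 + 3])
        codon_new = codon_old[:pos - c0] + new + codon_old[pos - c0 + 1:]
        if codon_new in STOP_CODONS:
            continue
        syn = CODON_TABLE[codon_new] == CODON_TABLE[codon_old]
        if not syn and pos // 3 in protected_residues:
            continue
        if syn and need_syn > 0:
            seq[pos] = new
            need_syn -= 1
        elif not syn and need_nonsyn > 0:
            seq[pos] = new
            need_nonsyn -= 1
    if need_syn > 0 or need_nonsyn > 0:
        raise RuntimeError("substitution planting did not converge; "
                           "planted divergence too large for sequence length")
    return "".join(seq) + stop, n_syn, n_nonsyn


MOTIF_PROTECTED = frozenset(
    set(range(40, 43)) | set(range(90, 95)) | set(range(140, 143)) |
    set(range(190, 198)) | set(range(230, 232)) | set(range(250, 254)))


def simulate_divergent_pair(n_codons: int, ks: float, omega: float,
                            rng: np.random.Generator
                            ) -> tuple[CdsRecord, CdsRecord, int, int]:
    """One ancestral/derived CDS pair with planted divergence (no motifs).

    The building block of the parameter-recovery harness: returns the two
    records plus the realized synonymous and nonsynonymous event counts.
    """
    codons = _random_codons(rng, n_codons)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    cds_a = "".join(codons) + stop
    cds_b, n_syn, n_nonsyn = diverge_cds(cds_a, ks, omega, rng)
    return (CdsRecord("pairA", cds_a), CdsRecord("pairB", cds_b),
            n_syn, n_nonsyn)


# ---------------------------------------------------------------------------
# Exon layouts and structural-divergence edits
# ---------------------------------------------------------------------------

def _split_exons(total_nt: int, n_exons: int, rng: np.random.Generator,
                 min_codons: int = 10,
                 forbidden_codons: frozenset[int] = frozenset()) -> list[int]:
    """Exon lengths (CDS order, all codon multiples) summing to total_nt.

    Cut positions inside ``forbidden_codons`` (e.g. diagnostic motif spans)
    are rejected so no junction interrupts a protected stretch.
    """
    n_cod = total_nt // 3
    assert total_nt % 3 == 0 and n_cod >= n_exons * min_codons
    while True:
        cuts = sorted(rng.choice(np.arange(min_codons, n_cod - min_codons + 1),
                                 size=n_exons - 1, replace=False))
        bounds = [0] + [int(c) for c in cuts] + [n_cod]
        lengths = [3 * (b - a) for a, b in zip(bounds, bounds[1:])]
        if (all(l >= 3 * min_codons for l in lengths) and
                not any(c in forbidden_codons for c in cuts)):
            return lengths


#: codon indices strictly inside a diagnostic motif: a junction or insertion
#: at these positions would interrupt the motif
def _motif_interior(protected: frozenset[int]) -> frozenset[int]:
    return frozenset(c for c in protected if c - 1 in protected)


def _edit_gain_loss(cds: str, exons: list[int],
                    rng: np.random.Generator,
                    forbidden_codons: frozenset[int] = frozenset()) -> tuple[str, list[int]]:
    i = max(range(len(exons)), key=lambda k: (exons[k], -k))
    start_cod = sum(exons[:i]) // 3
    mid = exons[i] // 6
    candidates = sorted(range(1, exons[i] // 3),
                        key=lambda o: (abs(o - mid), o))
    off = next(o for o in candidates if start_cod + o not in forbidden_codons)
    exons[i:i + 1] = [3 * off, exons[i] - 3 * off]
    return cds, exons


def _edit_insertion(cds: str, exons: list[int],
                    rng: np.random.Generator, n_ins_codons: int = 10,
                    forbidden_codons: frozenset[int] = frozenset()) -> tuple[str, list[int]]:
    internal = list(range(len(exons) - 1)) or [0]
    i = max(internal, key=lambda k: (exons[k], -k))
    start_cod = sum(exons[:i]) // 3
    mid = exons[i] // 6           # codon offset near the exon middle
    candidates = sorted(range(1, exons[i] // 3),
                        key=lambda o: (abs(o - mid), o))
    off = next(o for o in candidates if start_cod + o not in forbidden_codons)
    p = sum(exons[:i]) + 3 * off
    ins = "".join(_random_codons(rng, n_ins_codons))
    exons[i] += 3 * n_ins_codons
    return cds[:p] + ins + cds[p:], exons


def _edit_exonization(cds: str, exons: list[int],
                      rng: np.random.Generator, n_ins_codons: int = 5,
                      forbidden_codons: frozenset[int] = frozenset()) -> tuple[str, list[int]]:
    # junctions are planted outside motif interiors, so extending an exon at
    # an internal junction cannot interrupt a motif
    k = (len(exons) - 1) // 2
    p = sum(exons[:k + 1])
    ins = "".join(_random_codons(rng, n_ins_codons))
    exons[k] += 3 * n_ins_codons
    return cds[:p] + ins + cds[p:], exons


_STRUCTURE_EDITS = {
    "identical": lambda cds, exons, rng, forb: (cds, exons),
    "na": lambda cds, exons, rng, forb: (cds, exons),
    "gain_loss": lambda cds, exons, rng, forb: _edit_gain_loss(
        cds, exons, rng, forbidden_codons=forb),
    "insertion_deletion": lambda cds, exons, rng, forb: _edit_insertion(
        cds, exons, rng, forbidden_codons=forb),
    "exonization": lambda cds, exons, rng, forb: _edit_exonization(
        cds, exons, rng, forbidden_codons=forb),
}


# ---------------------------------------------------------------------------
# Family bundle
# ---------------------------------------------------------------------------

@dataclass
class FamilyBundle:
    """All synthetic artifacts of one simulated study, plus planted truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    cds: dict[str, CdsRecord]
    proteins: dict[str, ProteinRecord]
    refs: dict[str, ProteinRecord]
    reference_groups: dict[str, list[str]]
    homolog_pairs: list[tuple[str, str]]
    pairs: tuple[PlantedPair, ...]
    truth: pd.DataFrame
    hits: list[SimilarityHit]
    domain_hits: list[DomainHit]
    family_ids: tuple[str, ...]
    decoys_domainless: tuple[str, ...]
    decoys_outside: tuple[str, ...]
    exon_layout: dict[str, list[int]]

    @property
    def family_proteins(self) -> list[ProteinRecord]:
        return [self.proteins[g] for g in self.family_ids]


def _lineage_events(parent: dict[str, str],
                    events: dict[str, tuple[int, int]],
                    a: str, b: str) -> tuple[int, int]:
    """Sum of substitution events along the lineage path between a and b."""
    chain_a = [a]
    while chain_a[-1] in parent:
        chain_a.append(parent[chain_a[-1]])
    syn = nonsyn = 0
    node = b
    while node not in chain_a:
        s, n = events.get(node, (0, 0))
        syn, nonsyn = syn + s, nonsyn + n
        node = parent[node]
    for x in chain_a[:chain_a.index(node)]:
        s, n = events.get(x, (0, 0))
        syn, nonsyn = syn + s, nonsyn + n
    return syn, nonsyn


def simulate_family(config: SimulationConfig) -> FamilyBundle:
    """Generate the full genome/family bundle with planted ground truth."""
    rng_seq = np.random.default_rng([config.seed, 1])
    rng_genome = np.random.default_rng([config.seed, 2])

    # --- family sequences along the lineage -------------------------------
    root_prot = _random_family_protein(rng_seq, config.n_family_codons)
    root_cds = _reverse_translate(root_prot, rng_seq) + "TAA"
    parent: dict[str, str] = {}
    events: dict[str, tuple[int, int]] = {}
    seqs: dict[str, str] = {"root": root_cds}
    for anc, ks in (("anc1", 0.6), ("anc3", 0.6), ("anc5", 0.6),
                    ("anc6", 0.6), ("anc7", 0.6), ("anc8", 0.6)):
        parent[anc] = "root"
        seqs[anc], s, n = diverge_cds(root_cds, ks, 0.3, rng_seq,
                                      protected_residues=MOTIF_PROTECTED)
        events[anc] = (s, n)
    for anc, src, ks in (("anc5b", "anc5", 0.15), ("anc5c", "anc5", 0.20)):
        parent[anc] = src
        seqs[anc], s, n = diverge_cds(seqs[src], ks, 0.3, rng_seq,
                                      protected_residues=MOTIF_PROTECTED)
        events[anc] = (s, n)
    for name, src, ks, omega in _LINEAGE:
        parent[name] = src
        if ks == 0.0:
            seqs[name], events[name] = seqs[src], (0, 0)
        else:
            seqs[name], s, n = diverge_cds(seqs[src], ks, omega, rng_seq,
                                           protected_residues=MOTIF_PROTECTED)
            events[name] = (s, n)

    # reference proteins: two per subfamily group, near the subfamily ancestor
    refs: dict[str, ProteinRecord] = {}
    reference_groups: dict[str, list[str]] = {}
    for sub, group in sorted(GROUP_OF_SUBFAMILY.items()):
        anc = f"anc{sub}"
        for k, ks in enumerate((0.30, 0.40), start=1):
            rid = f"Ref{group}_{k}"
            cds_r, _, _ = diverge_cds(seqs[anc], ks, 0.3, rng_seq,
                                      protected_residues=MOTIF_PROTECTED)
            refs[rid] = ProteinRecord(rid, translate_cds(cds_r))
            reference_groups.setdefault(group, []).append(rid)

    # --- structural edits on the derived WGD member -----------------------
    layout_by_sub = {"1": 8, "3": 8, "5": 6, "6": 9, "7": 7, "8": 9}
    exon_layout: dict[str, list[int]] = {}
    final_cds: dict[str, str] = {}
    anc_layout: dict[str, list[int]] = {}
    for name in DEFAULT_PLACEMENT:
        sub = SUBFAMILY_OF[name]
        anc_key = parent[name] if parent[name].startswith("anc") else None
        base_anc = name
        while not base_anc.startswith("anc"):
            base_anc = parent[base_anc]
        if base_anc not in anc_layout:
            anc_layout[base_anc] = _split_exons(
                len(seqs[base_anc]), layout_by_sub[sub], rng_seq,
                forbidden_codons=_motif_interior(MOTIF_PROTECTED))
        exon_layout[name] = list(anc_layout[base_anc])
        final_cds[name] = seqs[name]
    for pair in DEFAULT_PAIRS:
        if pair.event_type != "wgd":
            continue
        edit = _STRUCTURE_EDITS[pair.structure_event]
        cds_b, exons_b = edit(final_cds[pair.gene_b],
                              list(exon_layout[pair.gene_b]), rng_seq,
                              _motif_interior(MOTIF_PROTECTED))
        final_cds[pair.gene_b], exon_layout[pair.gene_b] = cds_b, exons_b

    # --- outsider decoys: a related non-family clade ----------------------
    # (they carry both diagnostic domains in the hit tables but sit outside
    # the reference clade on the tree; making them a coherent clade mirrors
    # a paralogous sister family and keeps their placement stable)
    decoy_root = _random_background_cds(rng_seq, config.n_family_codons)
    decoy_seqs: dict[str, str] = {}
    for i in range(1, 5):
        decoy_seqs[f"BG.Chr.19.{i:03d}"], _, _ = diverge_cds(
            decoy_root, 0.15, 0.5, rng_seq)

    # --- genome layout ----------------------------------------------------
    n_chrom = 2 * config.n_chromosomes_per_subgenome
    chroms = [f"Chr.{i:02d}" for i in range(1, n_chrom + 1)]
    slot_of_family: dict[tuple[str, int], str] = {
        (c, r): name for name, (c, r) in DEFAULT_PLACEMENT.items()}
    genes: list[GeneModel] = []
    cds_records: dict[str, CdsRecord] = {}
    proteins: dict[str, ProteinRecord] = {}
    background_at: dict[tuple[str, int], str] = {}
    for chrom in chroms:
        for slot in range(1, config.n_background_genes + 1):
            fam_name = slot_of_family.get((chrom, slot))
            if fam_name is not None:
                name, cds_seq = fam_name, final_cds[fam_name]
                exons_cds = exon_layout[fam_name]
                strand = "+"
            else:
                name = f"BG.{chrom}.{slot:03d}"
                cds_seq = decoy_seqs.get(name) or _random_background_cds(
                    rng_genome, config.n_background_codons)
                exons_cds = _split_exons(len(cds_seq),
                                         int(rng_genome.integers(2, 5)),
                                         rng_genome, min_codons=15)
                strand = "+" if rng_genome.random() < 0.5 else "-"
                background_at[(chrom, slot)] = name
            genomic = list(reversed(exons_cds)) if strand == "-" else exons_cds
            start = (slot - 1) * 20000 + 1
            pos, exons = start, []
            for ln in genomic:
                exons.append((pos, pos + ln - 1))
                pos += ln + 200
            genes.append(GeneModel(name, chrom, strand, start,
                                   exons[-1][1], tuple(exons)))
            cds_records[name] = CdsRecord(name, cds_seq)
            proteins[name] = ProteinRecord(name, translate_cds(cds_seq))
    genes = assign_ranks(genes)

    # --- homology pairs (planted pairs + collinear anchor runs) -----------
    homolog_pairs: list[tuple[str, str]] = [
        (p.gene_a, p.gene_b) for p in DEFAULT_PAIRS]
    planted = set(map(frozenset, homolog_pairs))
    r0, L = config.block_start_rank, config.block_length
    for ca, cb in DEFAULT_BLOCKS:
        for off in range(L):
            ga = slot_of_family.get((ca, r0 + off)) or background_at[(ca, r0 + off)]
            gb = slot_of_family.get((cb, r0 + off)) or background_at[(cb, r0 + off)]
            a_fam, b_fam = not ga.startswith("BG."), not gb.startswith("BG.")
            if a_fam != b_fam:
                continue            # family gene opposite a background gene
            if frozenset((ga, gb)) in planted:
                continue            # planted family anchor already listed
            if a_fam and b_fam:
                continue            # family-family but not a planted pair
            homolog_pairs.append((ga, gb))

    # --- identification artifacts -----------------------------------------
    family_ids = tuple(sorted(DEFAULT_PLACEMENT))
    decoys_domainless = tuple(f"BG.Chr.09.{i:03d}" for i in range(1, 9))
    decoys_outside = tuple(f"BG.Chr.19.{i:03d}" for i in range(1, 5))
    weak_hits = tuple(f"BG.Chr.09.{i:03d}" for i in range(20, 26))
    hits: list[SimilarityHit] = []

    def _hit(query: str, subject: str, evalue: float) -> SimilarityHit:
        return SimilarityHit(query, subject, 55.0, 280, 120, 2,
                             1, 280, 1, 280, evalue, 310.0)

    ref_of_sub = {sub: f"Ref{grp}_1" for sub, grp in GROUP_OF_SUBFAMILY.items()}
    for name in family_ids:
        hits.append(_hit(ref_of_sub[SUBFAMILY_OF[name]], name, 1e-50))
        # a second, redundant hit from the other reference of the group
        other = ref_of_sub[SUBFAMILY_OF[name]].replace("_1", "_2")
        hits.append(_hit(other, name, 1e-45))
    for d in decoys_domainless:
        hits.append(_hit("RefI_1", d, 1e-20))
    for d in decoys_outside:
        hits.append(_hit("RefV_1", d, 1e-12))
    for d in weak_hits:
        hits.append(_hit("RefI_1", d, 1e-5))

    domain_hits: list[DomainHit] = []
    for name in family_ids + decoys_outside:
        plen = len(proteins[name])
        domain_hits.append(DomainHit(name, "PF00122", "E1-E2_ATPase",
                                     1e-40, 60, min(200, plen)))
        domain_hits.append(DomainHit(name, "PF00702", "Hydrolase",
                                     1e-30, min(210, plen - 10), min(290, plen)))
    for name in decoys_domainless:
        domain_hits.append(DomainHit(name, "PF00122", "E1-E2_ATPase",
                                     1e-15, 20, 150))

    # --- truth table -------------------------------------------------------
    rows = []
    by_id = {g.gene_id: g for g in genes}
    for p in DEFAULT_PAIRS:
        syn, nonsyn = _lineage_events(parent, events, p.gene_a, p.gene_b)
        body = final_cds[p.gene_a]
        body = body[:-3] if body[-3:] in STOP_CODONS else body
        S = sum(_codon_sites(body[i:i + 3]) for i in range(0, len(body), 3))
        N = len(body) - S
        rows.append(dict(
            pair_id=f"{p.gene_a}/{p.gene_b}", gene_a=p.gene_a, gene_b=p.gene_b,
            event_type=p.event_type, planted_ks=p.planted_ks,
            planted_omega=p.planted_omega,
            realized_syn_events=syn, realized_nonsyn_events=nonsyn,
            realized_ks=syn / S, realized_ka=nonsyn / N,
            structure_event=p.structure_event,
            chrom_a=by_id[p.gene_a].chromosome,
            chrom_b=by_id[p.gene_b].chromosome,
        ))
    truth = pd.DataFrame(rows)

    return FamilyBundle(
        config=config, genes=genes, cds=cds_records, proteins=proteins,
        refs=refs, reference_groups=reference_groups,
        homolog_pairs=homolog_pairs, pairs=DEFAULT_PAIRS, truth=truth,
        hits=hits, domain_hits=domain_hits, family_ids=family_ids,
        decoys_domainless=decoys_domainless, decoys_outside=decoys_outside,
        exon_layout=exon_layout,
    )


# ---------------------------------------------------------------------------
# Expression and qPCR
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Genes x tissues TPM matrix with two planted expression clusters.

    'high' genes are strongly and root/shoot-preferentially expressed,
    'low' genes weakly and flower-preferentially (lognormal on the
    log10(TPM+1) scale).  Returns (tpm, gene -> cluster label).
    """
    rng = np.random.default_rng([config.seed, 3])
    genes = sorted(DEFAULT_PLACEMENT)
    labels = {g: ("high" if g in HIGH_CLUSTER else "low") for g in genes}
    data = {}
    for g in genes:
        base, pref_set, bump = ((1.6, HIGH_PREF, 0.8) if labels[g] == "high"
                                else (0.15, LOW_PREF, 0.45))
        lg = []
        for t in TISSUES:
            mu = base + (bump if t in pref_set else 0.0)
            lg.append(max(0.0, mu + rng.normal(0.0, config.expression_noise_sd)))
        data[g] = [10.0 ** v - 1.0 for v in lg]
    tpm = pd.DataFrame.from_dict(data, orient="index", columns=list(TISSUES))
    tpm.index.name = "gene"
    return tpm, labels


def planted_log2fc(gene: str, cultivar: str, treatment: str) -> float:
    """The planted qPCR treatment effect (log2 fold change vs control)."""
    if treatment == "control":
        return 0.0
    if treatment == "Zn":
        if gene in ZN_INDUCED:
            return 2.0
        if gene in ("SynHMA6.1", "SynHMA6.2"):
            return -1.0
        return 0.3
    if treatment == "Cu":
        if gene == "SynHMA5.7":
            return 1.5
        return -1.0 if cultivar == "cvA" else 0.5
    if treatment == "Cd":
        if gene in ("SynHMA3.2", "SynHMA7.5"):
            return 2.0
        return -0.5 if cultivar == "cvA" else 1.0
    raise ValueError(f"unknown treatment {treatment!r}")


def simulate_qpcr(config: SimulationConfig
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long-form qPCR Ct table, metal-concentration table, planted effects.

    Ct(target) = Ct(reference) + baseline dCt - planted log2FC + noise;
    the metal table carries planted treatment effects so planted
    expression-accumulation correlations are recoverable (n = cultivars x
    treatments x replicates samples).
    """
    rng = np.random.default_rng([config.seed, 4])
    rng_metal = np.random.default_rng([config.seed, 5])
    rows = []
    base_dct = {g: 5.0 + 0.3 * i for i, g in enumerate(QPCR_GENES)}
    for g in QPCR_GENES:
        for cv in CULTIVARS:
            for tr in TREATMENTS:
                fc = planted_log2fc(g, cv, tr)
                for rep in range(1, config.n_replicates + 1):
                    ct_ref = 20.0 + rng.normal(0.0, 0.1)
                    dct = base_dct[g] - fc + rng.normal(0.0, config.ct_noise_sd)
                    rows.append(dict(gene=g, cultivar=cv, treatment=tr,
                                     replicate=rep, ct_target=ct_ref + dct,
                                     ct_reference=ct_ref))
    qpcr = pd.DataFrame(rows)

    base = dict(cu_root=10.0, cu_shoot=5.0, cu_shoot_pct=33.0,
                zn_root=50.0, zn_shoot=30.0, zn_shoot_pct=37.0)
    effect = {
        "control": dict(),
        "Cu": dict(cu_root=6.0, cu_shoot=3.0, cu_shoot_pct=-12.0),
        "Zn": dict(zn_root=6.0, zn_shoot=4.0, zn_shoot_pct=-12.0),
        "Cd": dict(zn_root=1.5, cu_root=1.2),
    }
    mrows = []
    for cv in CULTIVARS:
        cv_scale = 1.15 if cv == "cvB" else 1.0
        for tr in TREATMENTS:
            for rep in range(1, config.n_replicates + 1):
                row = dict(cultivar=cv, treatment=tr, replicate=rep)
                for trait, b in base.items():
                    eff = effect[tr].get(trait, 1.0 if not trait.endswith("pct") else 0.0)
                    if trait.endswith("pct"):
                        val = b + eff + rng_metal.normal(0.0, 1.5)
                    else:
                        val = (b * eff * cv_scale *
                               float(np.exp(rng_metal.normal(0.0, 0.08))))
                    row[trait] = val
                mrows.append(row)
    metals = pd.DataFrame(mrows)

    fc_rows = [dict(gene=g, cultivar=cv, treatment=tr,
                    log2fc=planted_log2fc(g, cv, tr))
               for g in QPCR_GENES for cv in CULTIVARS for tr in TREATMENTS]
    return qpcr, metals, pd.DataFrame(fc_rows)


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_bundle(bundle: FamilyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact of a bundle to ``outdir``; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    order = [g.gene_id for g in bundle.genes]
    paths["cds"] = outdir / "cds.fa"
    write_fasta([bundle.cds[g] for g in order], paths["cds"])
    paths["proteins"] = outdir / "proteins.fa"
    write_fasta([bundle.proteins[g] for g in order], paths["proteins"])
    paths["refs"] = outdir / "refs.fa"
    write_fasta([bundle.refs[r] for r in sorted(bundle.refs)], paths["refs"])
    paths["gff"] = outdir / "genes.gff3"
    write_gff3(bundle.genes, paths["gff"])
    paths["homologs"] = outdir / "homologs.tsv"
    with open(paths["homologs"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in bundle.homolog_pairs:
            fh.write(f"{a}\t{b}\n")
    paths["truth"] = outdir / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["hits"] = outdir / "hits.tsv"
    write_blast_tabular(bundle.hits, paths["hits"])
    paths["domains"] = outdir / "domains.tsv"
    write_domain_table(bundle.domain_hits, paths["domains"])
    paths["ref_groups"] = outdir / "ref_groups.tsv"
    with open(paths["ref_groups"], "w") as fh:
        fh.write("group\treference_id\n")
        for grp in sorted(bundle.reference_groups):
            for rid in bundle.reference_groups[grp]:
                fh.write(f"{grp}\t{rid}\n")

    tpm, labels = simulate_expression(bundle.config)
    paths["tpm"] = outdir / "tpm.tsv"
    tpm.to_csv(paths["tpm"], sep="\t")
    paths["expression_truth"] = outdir / "expression_truth.tsv"
    pd.Series(labels, name="cluster").rename_axis("gene").to_csv(
        paths["expression_truth"], sep="\t")

    qpcr, metals, fc = simulate_qpcr(bundle.config)
    paths["qpcr"] = outdir / "qpcr.tsv"
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    paths["metals"] = outdir / "metals.tsv"
    metals.to_csv(paths["metals"], sep="\t", index=False)
    paths["qpcr_truth"] = outdir / "qpcr_truth.tsv"
    fc.to_csv(paths["qpcr_truth"], sep="\t", index=False)
    return paths
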
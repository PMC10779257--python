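"""Candidate-identification funnel for a gene family.

Stages mirror the standard genome-wide identification workflow:

1. collect similarity-search hits of reference family proteins against the
   proteome below an E-value threshold (non-redundant subject ids);
2. require every diagnostic Pfam domain (conjunctive filter) — for
   heavy-metal P-type ATPases the E1-E2 ATPase (PF00122) and haloacid
   dehalogenase-like hydrolase (PF00702) domains;
3. audit diagnostic motifs (TGE, DKTGT, CPC/SPC, GDGxNDxP, HP, PxxK) —
   reported descriptively, never used to filter;
4. confirm family membership as the candidates nesting inside the smallest
   clade of a midpoint-rooted NJ tree that contains every reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_formats import DomainHit, ProteinRecord, SimilarityHit, ValidationError
from .phylogeny import PhyloTree

DEFAULT_REQUIRED_DOMAINS = frozenset({"PF00122", "PF00702"})

#: Diagnostic motif patterns of heavy-metal P-type ATPases.  ``x`` in the
#: field notation means any residue.
MOTIF_PATTERNS: dict[str, str] = {
    "TGE": r"TGE",
    "DKTGT": r"DKTGT",
    "CPC/SPC": r"[CS]PC",
    "GDGxNDxP": r"GDG.ND.P",
    "HP": r"HP",
    "PxxK": r"P..K",
}


@dataclass(frozen=True)
class IdentificationConfig:
    e_value_threshold: float = 1e-10
    required_domains: frozenset[str] = DEFAULT_REQUIRED_DOMAINS
    reference_ids: tuple[str, ...] = ()
    domain_i_e_value_cutoff: float | None = None  # off by default

    def __post_init__(self) -> None:
        if self.e_value_threshold <= 0:
            raise ValidationError("e_value_threshold must be > 0")
        if not self.required_domains:
            raise ValidationError("required_domains must be non-empty")


@dataclass(frozen=True)
class MotifReport:
    protein_id: str
    matches: dict[str, tuple[int, ...]]  # motif -> 1-based match start positions

    def present(self, motif: str) -> bool:
        return bool(self.matches.get(motif))

    @property
    def core_motifs_present(self) -> bool:
        """All four canonical motifs (TGE, DKTGT, CPC/SPC, GDGxNDxP)."""
        return all(self.present(m)
                   for m in ("TGE", "DKTGT", "CPC/SPC", "GDGxNDxP"))


def collect_candidates(hits: list[SimilarityHit],
                       config: IdentificationConfig) -> set[str]:
    """Non-redundant subject ids with E-value strictly below the threshold.

    Reference proteins appearing as subjects (self-matches of the queries)
    are excluded from the candidate set.
    """
    refs = set(config.reference_ids)
    return {h.subject for h in hits
            if h.e_value < config.e_value_threshold and h.subject not in refs}


def filter_by_domains(candidates: set[str], domains: list[DomainHit],
                      config: IdentificationConfig) -> set[str]:
    """Keep candidates with at least one hit for EVERY required accession."""
    cutoff = config.domain_i_e_value_cutoff
    by_protein: dict[str, set[str]] = {}
    for d in domains:
        if cutoff is not None and d.i_e_value > cutoff:
            continue
        by_protein.setdefault(d.protein_id, set()).add(d.domain_accession)
    return {c for c in candidates
            if config.required_domains <= by_protein.get(c, set())}


def scan_motifs(protein: ProteinRecord) -> MotifReport:
    """Report every diagnostic motif with its 1-based match positions.

    Overlapping occurrences are all reported.  The HP dipeptide has a high
    chance rate and is reported descriptively only.
    """
    matches: dict[str, tuple[int, ...]] = {}
    for name, pattern in MOTIF_PATTERNS.items():
        rx = re.compile(f"(?=({pattern}))")
        matches[name] = tuple(m.start() + 1 for m in rx.finditer(protein.sequence))
    return MotifReport(protein.id, matches)


def confirm_by_clade(candidates: set[str], tree: PhyloTree,
                     config: IdentificationConfig) -> set[str]:
    """Candidates inside the smallest clade containing all references.

    The tree (which must contain every candidate and reference as a leaf)
    is midpoint-rooted first so the clade is reproducibly defined.
    """
    refs = list(config.reference_ids)
    if not refs:
        raise ValidationError("no reference ids configured")
    missing = set(refs) - tree.leaf_ids
    if missing:
        raise ValidationError(f"references missing from tree: {sorted(missing)}")
    rooted = tree.midpoint_rooted()
    clade = rooted.clade_leafset(refs)
    return candidates & clade


@dataclass(frozen=True)
class FunnelResult:
    collected: frozenset[str]
    domain_filtered: frozenset[str]
    confirmed: frozenset[str]
    motif_reports: tuple[MotifReport, ...] = ()

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.collected), len(self.domain_filtered), len(self.confirmed)


def run_funnel(hits: list[SimilarityHit], domains: list[DomainHit],
               proteins: list[ProteinRecord], tree: PhyloTree | None,
               config: IdentificationConfig) -> FunnelResult:
    """Run the full identification funnel; funnel counts are monotone."""
    collected = collect_candidates(hits, config)
    filtered = filter_by_domains(collected, domains, config)
    confirmed = (confirm_by_clade(filtered, tree, config)
                 if tree is not None else filtered)
    by_id = {p.id: p for p in proteins}
    reports = tuple(scan_motifs(by_id[c]) for c in sorted(confirmed) if c in by_id)
    return FunnelResult(frozenset(collected), frozenset(filtered),
                        frozenset(confirmed), reports)
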
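"""Readers and writers for the external formats the pipeline consumes.

All coordinates are 1-based inclusive (GFF3 convention) throughout the
package; any half-open interop is converted at this boundary.  Readers
validate aggressively so downstream stages can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_ALPHABET = set("ACGT")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Syntactically valid input violating a semantic invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence keyed by a gene/protein identifier.

    ``X`` residues are permitted but counted; physicochemical operations
    reject sequences whose unknown fraction exceeds their tolerance.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid record id: {self.id!r}")
        if not self.sequence:
            raise ValidationError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - PROTEIN_ALPHABET - {"X"}
        if bad:
            raise ValidationError(
                f"non-amino-acid characters {sorted(bad)} in {self.id!r}"
            )

    @property
    def n_unknown(self) -> int:
        return self.sequence.count("X")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """A coding nucleotide sequence (``N`` permitted, flagged)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"invalid record id: {self.id!r}")
        if not self.sequence:
            raise ValidationError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET - {"N"}
        if bad:
            raise ValidationError(
                f"non-nucleotide characters {sorted(bad)} in {self.id!r}"
            )

    @property
    def n_unknown(self) -> int:
        return self.sequence.count("N")

    @property
    def is_complete_cds(self) -> bool:
        return len(self.sequence) % 3 == 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SimilarityHit:
    """One row of 12-column tabular similarity-search output (outfmt 6)."""

    query: str
    subject: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValidationError(
                f"q_start > q_end for {self.query}/{self.subject}"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"negative e-value for {self.query}/{self.subject}"
            )


@dataclass(frozen=True)
class DomainHit:
    """One profile-domain hit (hmmscan-style) for a protein."""

    protein_id: str
    domain_accession: str
    domain_name: str
    i_e_value: float
    env_start: int
    env_end: int

    def __post_init__(self) -> None:
        if self.env_start > self.env_end:
            raise ValidationError(
                f"env_start > env_end for {self.protein_id}/{self.domain_accession}"
            )
        if self.i_e_value < 0:
            raise ValidationError(
                f"negative i-e-value for {self.protein_id}/{self.domain_accession}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its exon chain, in genomic coordinate order.

    ``rank`` is the 1-based position of the gene along its chromosome by
    ascending start coordinate (ties broken by gene id); it is the unit in
    which tandem adjacency and collinear anchors are expressed.
    """

    gene_id: str
    chromosome: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...]
    rank: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValidationError(f"inverted exon ({s},{e}) in {self.gene_id}")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = e
        if self.gene_start > min(s for s, _ in self.exons):
            raise ValidationError(f"gene_start after first exon in {self.gene_id}")
        if self.gene_end < max(e for _, e in self.exons):
            raise ValidationError(f"gene_end before last exon in {self.gene_id}")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str = "protein") -> list[ProteinRecord] | list[CdsRecord]:
    """Read a FASTA file into protein or CDS records.

    Sequences are uppercased and wrapped lines concatenated.  Duplicate ids
    are rejected; the id is the first whitespace-delimited token of the
    header.
    """
    cls = {"protein": ProteinRecord, "cds": CdsRecord}.get(kind)
    if cls is None:
        raise ValueError(f"unknown record kind {kind!r}")
    records: list = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        nonlocal current_id, chunks
        if current_id is not None:
            seq = "".join(chunks).upper()
            if not seq:
                raise ValidationError(f"empty sequence for {current_id!r}")
            records.append(cls(current_id, seq))
            current_id, chunks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: malformed header at line {lineno}")
                current_id = header.split()[0]
                if current_id in seen:
                    raise ValidationError(f"{path}: duplicate id {current_id!r}")
                seen.add(current_id)
            else:
                if current_id is None:
                    raise ParseError(f"{path}: sequence before header at line {lineno}")
                chunks.append(line.strip())
    _flush()
    return records


def write_fasta(records: Iterable[ProteinRecord | CdsRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular similarity hits (outfmt 6)
# ---------------------------------------------------------------------------

def read_blast_tabular(path: str | Path) -> list[SimilarityHit]:
    """Parse 12-column tab-separated similarity hits, preserving row order."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: expected 12 columns, got {len(fields)} at row {lineno}"
                )
            try:
                hits.append(SimilarityHit(
                    query=fields[0], subject=fields[1],
                    pct_identity=float(fields[2]), align_len=int(fields[3]),
                    mismatches=int(fields[4]), gap_opens=int(fields[5]),
                    q_start=int(fields[6]), q_end=int(fields[7]),
                    s_start=int(fields[8]), s_end=int(fields[9]),
                    e_value=float(fields[10]), bit_score=float(fields[11]),
                ))
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path}: bad numeric field at row {lineno}: {exc}")
    return hits


def write_blast_tabular(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query, h.subject, h.pct_identity, h.align_len, h.mismatches,
                h.gap_opens, h.q_start, h.q_end, h.s_start, h.s_end,
                f"{h.e_value:.3g}" if h.e_value else "0.0", h.bit_score)) + "\n")


# ---------------------------------------------------------------------------
# Domain hit tables
# ---------------------------------------------------------------------------

def _strip_version(accession: str) -> str:
    return accession.split(".", 1)[0]


def read_domain_table(path: str | Path, dialect: str = "simple_tsv") -> list[DomainHit]:
    """Read domain hits from hmmscan ``domtblout`` or a simple TSV.

    The simple TSV has columns: protein_id, accession, name, i_e_value,
    start, end (header row optional).  Domain accession version suffixes
    (``PF00122.21`` -> ``PF00122``) are stripped in both dialects.
    """
    if dialect not in {"domtblout", "simple_tsv"}:
        raise ValueError(f"unknown domain-table dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "domtblout":
                # whitespace-separated; description field (22+) may hold spaces
                f = line.split()
                if len(f) < 23:
                    raise ParseError(
                        f"{path}: short domtblout row at line {lineno}")
                # domtblout: target name, target acc, tlen, query name, ...
                hits.append(DomainHit(
                    protein_id=f[3], domain_accession=_strip_version(f[1]),
                    domain_name=f[0], i_e_value=float(f[12]),
                    env_start=int(f[19]), env_end=int(f[20]),
                ))
            else:
                f = line.split("\t")
                if len(f) != 6:
                    raise ParseError(
                        f"{path}: expected 6 columns, got {len(f)} at line {lineno}")
                if f[0] == "protein_id":  # header row
                    continue
                hits.append(DomainHit(
                    protein_id=f[0], domain_accession=_strip_version(f[1]),
                    domain_name=f[2], i_e_value=float(f[3]),
                    env_start=int(f[4]), env_end=int(f[5]),
                ))
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write domain hits in the simple TSV dialect (with header)."""
    with open(path, "w") as fh:
        fh.write("protein_id\taccession\tname\ti_e_value\tstart\tend\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_accession}\t{h.domain_name}\t"
                     f"{h.i_e_value:.3g}\t{h.env_start}\t{h.env_end}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ParseError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon linked by ID/Parent).

    When a gene has several mRNAs the longest spliced form is retained
    (ties broken by mRNA id).  Ranks are assigned per chromosome by
    ascending gene start, ties broken by gene id.
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(f"{path}: expected 9 columns at line {lineno}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
            start_i, end_i = int(start), int(end)
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ParseError(f"{path}: gene without ID at line {lineno}")
                genes[gid] = dict(chromosome=chrom, strand=strand,
                                  start=start_i, end=end_i, mrnas=[])
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid is None or parent is None:
                    raise ParseError(f"{path}: mRNA missing ID/Parent at line {lineno}")
                mrnas[mid] = dict(gene=parent, exons=[])
            elif ftype == "exon":
                parent = a.get("Parent")
                if parent is None:
                    raise ValidationError(
                        f"{path}: exon without Parent at line {lineno}")
                if parent not in mrnas:
                    raise ValidationError(
                        f"{path}: exon references unknown mRNA {parent!r}")
                mrnas[parent]["exons"].append((start_i, end_i))

    for mid, m in mrnas.items():
        if m["gene"] not in genes:
            raise ValidationError(f"{path}: mRNA {mid!r} references unknown gene")
        genes[m["gene"]]["mrnas"].append((mid, m["exons"]))

    models: list[GeneModel] = []
    for gid, g in genes.items():
        if not g["mrnas"]:
            raise ValidationError(f"{path}: gene {gid!r} has no mRNA")
        # longest spliced form; ties by mRNA id for determinism
        best_mid, best_exons = min(
            g["mrnas"],
            key=lambda t: (-sum(e - s + 1 for s, e in t[1]), t[0]),
        )
        exons = tuple(sorted(best_exons))
        models.append(GeneModel(
            gene_id=gid, chromosome=g["chromosome"], strand=g["strand"],
            gene_start=g["start"], gene_end=g["end"], exons=exons,
        ))
    return assign_ranks(models)


def assign_ranks(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Return models with per-chromosome 1-based ranks by ascending start."""
    out: list[GeneModel] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom_models in by_chrom.values():
        chrom_models.sort(key=lambda m: (m.gene_start, m.gene_id))
        for i, m in enumerate(chrom_models, 1):
            out.append(GeneModel(m.gene_id, m.chromosome, m.strand,
                                 m.gene_start, m.gene_end, m.exons, rank=i))
    out.sort(key=lambda m: (m.chromosome, m.rank))
    return out


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(f"{m.chromosome}\tgenefamkit\tgene\t{m.gene_start}\t"
                     f"{m.gene_end}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
            mid = f"{m.gene_id}.t1"
            fh.write(f"{m.chromosome}\tgenefamkit\tmRNA\t{m.gene_start}\t"
                     f"{m.gene_end}\t.\t{m.strand}\t.\tID={mid};Parent={m.gene_id}\n")
            for s, e in m.exons:
                fh.write(f"{m.chromosome}\tgenefamkit\texon\t{s}\t{e}\t.\t"
                         f"{m.strand}\t.\tParent={mid}\n")


# ---------------------------------------------------------------------------
# Derived arithmetic
# ---------------------------------------------------------------------------

def protein_length_from_cds(cds_length_bp: int) -> int:
    """Amino-acid count of a complete CDS (one terminal stop codon).

    A CDS of ``3(n+1)`` bp encodes ``n`` residues: the terminal codon is
    the stop and is not translated.
    """
    if cds_length_bp <= 0 or cds_length_bp % 3 != 0:
        raise ValidationError(
            f"CDS length {cds_length_bp} is not a positive multiple of 3")
    return cds_length_bp // 3 - 1
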
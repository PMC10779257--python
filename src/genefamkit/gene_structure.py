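"""Exon/intron architecture comparison between duplicate gene-pair members.

Duplicated genes often diverge in coding structure after the duplication;
the divergence mechanisms reported here follow the standard taxonomy:

* identical — same intron count, every exon junction conserved, exon
  lengths equal within the indel tolerance;
* gain_loss — intron counts differ (an intron was gained or lost);
* insertion_deletion — junctions conserved but an exon length changed by at
  least the indel threshold (sequence inserted into / deleted from an exon);
* exonization_pseudoexonization — a junction migrated, so sequence that is
  exonic in one member corresponds to an intronic span in the other.

Junctions are compared through the pairwise protein alignment of the CDS
translations (mapped back to CDS nucleotide coordinates), never through a
genomic alignment, so intron sequences are not needed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel, ValidationError


@dataclass(frozen=True)
class StructureComparison:
    gene_a: str
    gene_b: str
    n_exons_a: int
    n_exons_b: int
    shared_boundaries: int
    mechanisms: frozenset[str]

    def __post_init__(self) -> None:
        assert self.mechanisms, "mechanisms set must be non-empty"
        if "identical" in self.mechanisms:
            assert self.mechanisms == frozenset({"identical"})

    @property
    def n_introns_a(self) -> int:
        return self.n_exons_a - 1

    @property
    def n_introns_b(self) -> int:
        return self.n_exons_b - 1


def cds_exon_lengths(model: GeneModel) -> tuple[int, ...]:
    """Exon lengths in transcription (CDS) order; minus-strand reversed."""
    lengths = model.exon_lengths
    return tuple(reversed(lengths)) if model.strand == "-" else lengths


def cds_junctions(model: GeneModel) -> tuple[int, ...]:
    """Positions of exon/exon junctions in spliced-CDS nucleotide coordinates.

    Junction k is the index of the last nucleotide of exon k (1-based);
    a gene with n exons has n-1 junctions.
    """
    lengths = cds_exon_lengths(model)
    out = []
    acc = 0
    for ln in lengths[:-1]:
        acc += ln
        out.append(acc)
    return tuple(out)


def _residue_map(aligned_a: str, aligned_b: str) -> dict[int, int]:
    """1-based residue index of a -> residue index of b for aligned columns."""
    out: dict[int, int] = {}
    i = j = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
        if ca != "-" and cb != "-":
            out[i] = j
    return out


def _map_position(pos_a: int, res_map: dict[int, int], max_res_a: int) -> int | None:
    """Map a CDS-a nucleotide position into CDS-b coordinates via residues."""
    res_a = (pos_a + 2) // 3
    phase = (pos_a - 1) % 3
    # nearest aligned residue if the containing one sits in a gap
    for offset in range(max_res_a + 1):
        for cand in (res_a - offset, res_a + offset):
            if cand in res_map:
                res_b = res_map[cand] + (res_a - cand)
                return (res_b - 1) * 3 + phase + 1
    return None


def compare_structures(a: GeneModel, b: GeneModel,
                       aligned_a: str, aligned_b: str,
                       junction_tolerance_nt: int = 3,
                       indel_min_nt: int = 9) -> StructureComparison:
    """Compare exon/intron architecture of two duplicate-pair members.

    ``aligned_a``/``aligned_b`` are the gapped rows of the pairwise protein
    alignment of the two CDS translations.
    """
    if not a.exons or not b.exons:
        raise ValidationError("gene model without exons")
    res_map = _residue_map(aligned_a, aligned_b)
    if not res_map:
        raise ValidationError(f"no aligned residues between {a.gene_id} and {b.gene_id}")
    junc_a, junc_b = cds_junctions(a), cds_junctions(b)
    len_a, len_b = cds_exon_lengths(a), cds_exon_lengths(b)
    max_res_a = len(aligned_a.replace("-", ""))

    shared = 0
    shifted = False
    for ja in junc_a:
        mapped = _map_position(ja, res_map, max_res_a)
        if mapped is None:
            shifted = True
            continue
        if junc_b and min(abs(mapped - jb) for jb in junc_b) <= junction_tolerance_nt:
            shared += 1
        else:
            shifted = True

    mechanisms: set[str] = set()
    if a.n_introns != b.n_introns:
        mechanisms.add("gain_loss")
    elif shifted:
        mechanisms.add("exonization_pseudoexonization")
    else:
        indel = (len(len_a) == len(len_b) and
                 any(abs(x - y) >= indel_min_nt for x, y in zip(len_a, len_b)))
        mechanisms.add("insertion_deletion" if indel else "identical")

    return StructureComparison(
        gene_a=a.gene_id, gene_b=b.gene_id,
        n_exons_a=a.n_exons, n_exons_b=b.n_exons,
        shared_boundaries=shared, mechanisms=frozenset(mechanisms),
    )
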
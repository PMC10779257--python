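"""Protein alignment helpers.

The pipeline treats the multiple alignment as an input: any aligner may
produce it.  For self-contained synthetic runs this module provides global
pairwise alignment (Needleman-Wunsch, BLOSUM62, affine gaps) and a simple
deterministic center-star multiple alignment built from it.  It is not a
production MSA tool; synthetic family sequences are substitution-derived
and close to trivially alignable.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_align(seq_a: str, seq_b: str) -> tuple[str, str, float]:
    """Globally align two protein sequences; returns (row_a, row_b, score)."""
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]  # first optimal alignment: deterministic
    return str(aln[0]), str(aln[1]), aln.score


def _merge_into_msa(msa_rows: list[str], center_row_old: str,
                    center_row_new: str, new_row: str) -> tuple[list[str], str]:
    """Merge a new pairwise alignment against the center into the MSA.

    ``center_row_old`` is the center as currently gapped in the MSA;
    ``center_row_new``/``new_row`` come from the fresh pairwise alignment.
    Gap patterns are united column by column.
    """
    i = j = 0
    out_old = [""] * len(msa_rows)
    out_center = []
    out_new = []
    n_old, n_new = len(center_row_old), len(center_row_new)
    while i < n_old or j < n_new:
        a = center_row_old[i] if i < n_old else None
        b = center_row_new[j] if j < n_new else None
        if a is not None and b is not None and a != "-" and b != "-":
            for k, row in enumerate(msa_rows):
                out_old[k] += row[i]
            out_center.append(a)
            out_new.append(new_row[j])
            i += 1
            j += 1
        elif a == "-":
            for k, row in enumerate(msa_rows):
                out_old[k] += row[i]
            out_center.append("-")
            out_new.append("-")
            i += 1
        else:  # b == "-" or old exhausted
            for k in range(len(msa_rows)):
                out_old[k] += "-"
            out_center.append("-")
            out_new.append(new_row[j])
            j += 1
    return out_old + ["".join(out_new)], "".join(out_center)


def center_star_msa(records: list[ProteinRecord]) -> tuple[list[str], list[str]]:
    """Center-star multiple alignment; returns (ids, aligned rows).

    The center is the sequence maximizing the summed pairwise score against
    all others (ties broken by id).  All rows come out equal length.
    """
    if len(records) < 2:
        return [r.id for r in records], [r.sequence for r in records]
    aligner = _make_aligner()
    n = len(records)
    scores = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(records[i].sequence, records[j].sequence)
            scores[i][j] = scores[j][i] = s
    center = min(range(n), key=lambda i: (-sum(scores[i]), records[i].id))

    order = [i for i in range(n) if i != center]
    msa_rows: list[str] = []
    center_row = records[center].sequence
    ids = [records[center].id]
    for idx in order:
        c_new, s_new, _ = _pair_rows(aligner, center_row.replace("-", ""),
                                     records[idx].sequence)
        msa_rows, center_row = _merge_into_msa(msa_rows, center_row, c_new, s_new)
        ids.append(records[idx].id)
    rows = [center_row] + msa_rows
    assert len({len(r) for r in rows}) == 1
    return ids, rows


def _pair_rows(aligner: Align.PairwiseAligner, seq_a: str, seq_b: str) -> tuple[str, str, float]:
    aln = aligner.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1]), aln.score
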
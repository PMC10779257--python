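"""Collinear-block detection and duplication-type classification.

Collinear blocks are chains of homologous gene pairs (anchors) in conserved
order between two chromosomal regions, found by dynamic programming over
rank-sorted homolog matches (a simplified MCScanX-style chainer scored by
anchor count).  Duplicate gene pairs are then classified with a total,
deterministic precedence:

    tandem  >  whole-genome  >  segmental  >  dispersed

* tandem: same chromosome, gene ranks within a small gap;
* whole-genome: anchor of a block joining homeologous chromosomes of the
  two subgenomes of the allotetraploid (default map Chr.i <-> Chr.i+10),
  optionally restricted to a synonymous-divergence (Ks) window;
* segmental: anchor of any other collinear block;
* dispersed: none of the above.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel, ValidationError


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: tuple[tuple[str, str], ...]       # (gene_id on a, gene_id on b)
    anchor_ranks: tuple[tuple[int, int], ...]  # matching (rank_a, rank_b)
    orientation: str                           # 'same' | 'inverted'

    @property
    def score(self) -> int:
        return len(self.anchors)

    def contains_pair(self, id_a: str, id_b: str) -> bool:
        return (id_a, id_b) in self.anchors or (id_b, id_a) in self.anchors


@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    label: str     # whole-genome | segmental | tandem | dispersed
    evidence: str


def default_homeolog_map(n_per_subgenome: int = 10) -> dict[str, str]:
    """Chr.i <-> Chr.(i+n) pairing for a two-subgenome allotetraploid."""
    out: dict[str, str] = {}
    for i in range(1, n_per_subgenome + 1):
        a, b = f"Chr.{i:02d}", f"Chr.{i + n_per_subgenome:02d}"
        out[a] = b
        out[b] = a
    return out


def _chain(matches: list[tuple[int, int, str, str]], min_anchors: int,
           max_gap: int, inverted: bool) -> list[CollinearBlock] | list:
    """Longest chains over matches sorted by rank_a; greedy chain extraction.

    A step from anchor (r1, s1) to (r2, s2) is allowed when
    0 < r2 - r1 <= max_gap and 0 < s2 - s1 <= max_gap (s decreasing for
    inverted chains).  Chains are extracted best-first; anchors are not
    reused across chains.
    """
    sign = -1 if inverted else 1
    matches = sorted(matches)
    blocks = []
    used = [False] * len(matches)
    while True:
        n = len(matches)
        best_len = [1] * n
        prev = [-1] * n
        for i in range(n):
            if used[i]:
                continue
            for j in range(i):
                if used[j]:
                    continue
                dr = matches[i][0] - matches[j][0]
                ds = sign * (matches[i][1] - matches[j][1])
                if 0 < dr <= max_gap and 0 < ds <= max_gap:
                    if best_len[j] + 1 > best_len[i]:
                        best_len[i] = best_len[j] + 1
                        prev[i] = j
        cand = [i for i in range(n) if not used[i]]
        if not cand:
            break
        end = max(cand, key=lambda i: (best_len[i], -matches[i][0]))
        if best_len[end] < min_anchors:
            break
        chain = []
        k = end
        while k != -1:
            chain.append(k)
            k = prev[k]
        chain.reverse()
        for k in chain:
            used[k] = True
        blocks.append(chain_anchors := [matches[k] for k in chain])
    return blocks


def find_blocks(genes: list[GeneModel], homolog_pairs: list[tuple[str, str]],
                min_anchors: int = 5, max_gap: int = 25) -> list[CollinearBlock]:
    """Detect collinear blocks from ranked gene models and homolog pairs.

    Both orientations are searched per chromosome pair; chains shorter than
    ``min_anchors`` are discarded.
    """
    by_id = {g.gene_id: g for g in genes}
    per_chrom_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in homolog_pairs:
        if a not in by_id or b not in by_id:
            missing = a if a not in by_id else b
            raise ValidationError(f"homolog pair references unknown gene {missing!r}")
        ga, gb = by_id[a], by_id[b]
        ca, cb = ga.chromosome, gb.chromosome
        if (cb, ca) < (ca, cb):
            ga, gb = gb, ga
            ca, cb = cb, ca
        per_chrom_pair.setdefault((ca, cb), []).append(
            (ga.rank, gb.rank, ga.gene_id, gb.gene_id))

    blocks: list[CollinearBlock] = []
    for (ca, cb), matches in sorted(per_chrom_pair.items()):
        for inverted in (False, True):
            for chain in _chain(matches, min_anchors, max_gap, inverted):
                blocks.append(CollinearBlock(
                    chrom_a=ca, chrom_b=cb,
                    anchors=tuple((m[2], m[3]) for m in chain),
                    anchor_ranks=tuple((m[0], m[1]) for m in chain),
                    orientation="inverted" if inverted else "same",
                ))
    return blocks


def classify_pair(gene_a: GeneModel, gene_b: GeneModel,
                  blocks: list[CollinearBlock],
                  homeolog_map: dict[str, str] | None = None,
                  tandem_max_rank_gap: int = 2,
                  ks: float | None = None,
                  wgd_ks_window: tuple[float, float] | None = None) -> DuplicationCall:
    """Classify one duplicate pair with the tandem > WGD > segmental >
    dispersed precedence.

    ``wgd_ks_window`` optionally restricts the whole-genome label to pairs
    whose Ks falls inside the window (the allopolyploidy event is recent,
    so its pairs sit in a narrow low-Ks band); pairs failing the window
    fall through to segmental.
    """
    if homeolog_map is None:
        homeolog_map = default_homeolog_map()
    a, b = gene_a, gene_b
    if a.chromosome == b.chromosome and abs(a.rank - b.rank) <= tandem_max_rank_gap:
        return DuplicationCall(a.gene_id, b.gene_id, "tandem",
                               f"rank gap {abs(a.rank - b.rank)}")
    anchor_blocks = [blk for blk in blocks
                     if blk.contains_pair(a.gene_id, b.gene_id)]
    homeo = [blk for blk in anchor_blocks
             if homeolog_map.get(blk.chrom_a) == blk.chrom_b]
    if homeo:
        ks_ok = (wgd_ks_window is None or ks is None or
                 wgd_ks_window[0] <= ks <= wgd_ks_window[1])
        if ks_ok:
            blk = homeo[0]
            return DuplicationCall(a.gene_id, b.gene_id, "whole-genome",
                                   f"block {blk.chrom_a}~{blk.chrom_b} "
                                   f"({blk.score} anchors)")
    if anchor_blocks:
        blk = anchor_blocks[0]
        return DuplicationCall(a.gene_id, b.gene_id, "segmental",
                               f"block {blk.chrom_a}~{blk.chrom_b} "
                               f"({blk.score} anchors)")
    return DuplicationCall(a.gene_id, b.gene_id, "dispersed", "no block")


def classify_pairs(genes: list[GeneModel], pairs: list[tuple[str, str]],
                   blocks: list[CollinearBlock],
                   **kwargs) -> list[DuplicationCall]:
    by_id = {g.gene_id: g for g in genes}
    calls = []
    for a, b in pairs:
        if a not in by_id or b not in by_id:
            missing = a if a not in by_id else b
            raise ValidationError(f"pair references unknown gene {missing!r}")
        calls.append(classify_pair(by_id[a], by_id[b], blocks, **kwargs))
    return calls
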
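import pytest

from genefamkit.duplication_synteny import (
    classify_pair, classify_pairs, default_homeolog_map, find_blocks,
)
from genefamkit.io_formats import GeneModel, ValidationError, assign_ranks


def gene(gid, chrom, rank):
    start = rank * 1000
    return GeneModel(gid, chrom, "+", start, start + 99,
                     ((start, start + 99),), rank=rank)


def run_of_genes(chrom, n, prefix):
    return [gene(f"{prefix}{i}", chrom, i) for i in range(1, n + 1)]


class TestFindBlocks:
    def test_six_consecutive_anchors_form_one_block(self):
        ga = run_of_genes("Chr.01", 10, "a")
        gb = run_of_genes("Chr.11", 10, "b")
        pairs = [(f"a{i}", f"b{i}") for i in range(2, 8)]
        blocks = find_blocks(ga + gb, pairs)
        assert len(blocks) == 1 and blocks[0].score == 6
        assert blocks[0].orientation == "same"

    def test_min_anchor_threshold(self):
        ga = run_of_genes("Chr.01", 10, "a")
        gb = run_of_genes("Chr.11", 10, "b")
        pairs = [(f"a{i}", f"b{i}") for i in range(2, 6)]  # 4 anchors
        assert find_blocks(ga + gb, pairs, min_anchors=5) == []
        assert len(find_blocks(ga + gb, pairs, min_anchors=4)) == 1

    def test_inverted_chain_detected(self):
        ga = run_of_genes("Chr.01", 10, "a")
        gb = run_of_genes("Chr.11", 10, "b")
        pairs = [(f"a{i}", f"b{10 - i}") for i in range(1, 7)]
        (block,) = find_blocks(ga + gb, pairs)
        assert block.orientation == "inverted" and block.score == 6

    def test_gap_limit_breaks_chain(self):
        ga = run_of_genes("Chr.01", 100, "a")
        gb = run_of_genes("Chr.11", 100, "b")
        ranks = [1, 2, 3, 4, 5, 60, 61, 62, 63, 64]  # gap 55 > max_gap
        pairs = [(f"a{r}", f"b{r}") for r in ranks]
        blocks = find_blocks(ga + gb, pairs, min_anchors=5, max_gap=25)
        assert sorted(b.score for b in blocks) == [5, 5]

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            find_blocks(run_of_genes("Chr.01", 3, "a"), [("a1", "ghost")])

    def test_id_renaming_invariance(self):
        ga = run_of_genes("Chr.01", 10, "a")
        gb = run_of_genes("Chr.11", 10, "b")
        pairs = [(f"a{i}", f"b{i}") for i in range(2, 8)]
        ranks1 = [b.anchor_ranks for b in find_blocks(ga + gb, pairs)]
        ga2 = run_of_genes("Chr.01", 10, "x")
        gb2 = run_of_genes("Chr.11", 10, "y")
        pairs2 = [(f"x{i}", f"y{i}") for i in range(2, 8)]
        ranks2 = [b.anchor_ranks for b in find_blocks(ga2 + gb2, pairs2)]
        assert ranks1 == ranks2


class TestClassifyPair:
    def _blocks(self):
        ga = run_of_genes("Chr.03", 10, "a")
        gb = run_of_genes("Chr.13", 10, "b")
        gc = run_of_genes("Chr.04", 10, "c")
        pairs = ([(f"a{i}", f"b{i}") for i in range(2, 8)] +
                 [(f"a{i}", f"c{i}") for i in range(2, 8)])
        genes = ga + gb + gc
        return genes, find_blocks(genes, pairs)

    def test_tandem_beats_everything(self):
        genes, blocks = self._blocks()
        call = classify_pair(gene("a4", "Chr.03", 4), gene("a5", "Chr.03", 5), blocks)
        assert call.label == "tandem"

    def test_homeologous_anchor_is_whole_genome(self):
        genes, blocks = self._blocks()
        call = classify_pair(gene("a4", "Chr.03", 4), gene("b4", "Chr.13", 4), blocks)
        assert call.label == "whole-genome"

    def test_within_subgenome_anchor_is_segmental(self):
        genes, blocks = self._blocks()
        call = classify_pair(gene("a4", "Chr.03", 4), gene("c4", "Chr.04", 4), blocks)
        assert call.label == "segmental"

    def test_no_block_is_dispersed(self):
        genes, blocks = self._blocks()
        call = classify_pair(gene("a9", "Chr.03", 9), gene("b2", "Chr.13", 2), blocks)
        assert call.label == "dispersed"

    def test_ks_window_demotes_old_homeologous_pairs(self):
        genes, blocks = self._blocks()
        call = classify_pair(gene("a4", "Chr.03", 4), gene("b4", "Chr.13", 4),
                             blocks, ks=1.2, wgd_ks_window=(0.0, 0.3))
        assert call.label == "segmental"

    def test_every_pair_gets_exactly_one_label(self):
        genes, blocks = self._blocks()
        for pa, pb in [("a4", "a5"), ("a4", "b4"), ("a4", "c4"), ("a9", "b2")]:
            call = classify_pair(gene(pa, "Chr.03", int(pa[1])),
                                 gene(pb, f"Chr.{dict(a='03', b='13', c='04')[pb[0]]}",
                                      int(pb[1])), blocks)
            assert call.label in {"tandem", "whole-genome", "segmental", "dispersed"}


class TestBundleRecovery:
    def test_planted_blocks_recovered_exactly(self, bundle):
        from genefamkit.synthetic_data import DEFAULT_BLOCKS

        blocks = find_blocks(bundle.genes, bundle.homolog_pairs)
        found = {(b.chrom_a, b.chrom_b) for b in blocks}
        assert found == set(DEFAULT_BLOCKS)
        assert len(blocks) == len(DEFAULT_BLOCKS)  # no spurious blocks

    def test_duplication_split_10_4_1(self, bundle):
        blocks = find_blocks(bundle.genes, bundle.homolog_pairs)
        calls = classify_pairs(bundle.genes,
                               [(p.gene_a, p.gene_b) for p in bundle.pairs],
                               blocks)
        want = {"wgd": "whole-genome", "segmental": "segmental", "tandem": "tandem"}
        truth = {(p.gene_a, p.gene_b): want[p.event_type] for p in bundle.pairs}
        for call in calls:
            assert call.label == truth[(call.gene_a, call.gene_b)]
        labels = [c.label for c in calls]
        assert (labels.count("whole-genome"), labels.count("segmental"),
                labels.count("tandem")) == (10, 4, 1)
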
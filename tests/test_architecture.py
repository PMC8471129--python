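"""Gene order comparison, spacer/overlap accounting, shared overlap motifs."""

import pytest

from mitochar import (
    GeneOrder,
    ancestral_gene_order,
    architecture_closure,
    compare_orders,
    gene_order,
    iupac_consensus,
    shared_overlap_motifs,
    spacers_and_overlaps,
)
from mitochar.model import AnnotatedMitogenome, GeneFeature
from tests.conftest import trio_specs
from mitochar import GeneratorSpec, generate


def naive_breakpoints(a, b):
    """Brute-force adjacency oracle for circular signed orders.

    Enumerates every adjacency of ``a`` and searches for it in ``b`` read in
    both directions (reversal flips strands), counting those absent.
    """
    flip = {"J": "N", "N": "J"}
    genes = {t[0] for t in a} & {t[0] for t in b}
    a = [t for t in a if t[0] in genes]
    b = [t for t in b if t[0] in genes]
    b_adj = set()
    for i in range(len(b)):
        x, y = b[i], b[(i + 1) % len(b)]
        b_adj.add((x, y))
        b_adj.add(((y[0], flip[y[1]]), (x[0], flip[x[1]])))
    missing = 0
    for i in range(len(a)):
        x, y = a[i], a[(i + 1) % len(a)]
        if (x, y) not in b_adj:
            missing += 1
    return missing


class TestGeneOrder:
    def test_synthetic_genome_matches_ancestral_reference(self, genome):
        assert gene_order(genome).tokens == ancestral_gene_order().tokens

    def test_rotation_invariance(self, genome):
        # rotate the molecule so a mid-genome gene starts the linear sequence
        pivot = genome.feature_by_name("COX1").start
        L = genome.length_bp
        rotated_seq = genome.sequence[pivot:] + genome.sequence[:pivot]
        feats = []
        for f in genome.features:
            s, e = (f.start - pivot) % L, (f.end - pivot) % L or L
            if e <= s:  # now wraps the new origin
                feats.append(GeneFeature(f.name, s, (f.end - pivot) % L,
                                         f.strand, f.kind, wraps_origin=True))
            else:
                feats.append(GeneFeature(f.name, s, e, f.strand, f.kind))
        rotated = AnnotatedMitogenome("ROT", rotated_seq, features=feats)
        assert gene_order(rotated).tokens == gene_order(genome).tokens


class TestCompareOrders:
    def test_identical_orders_have_zero_breakpoints(self):
        anc = ancestral_gene_order()
        cmp_ = compare_orders(anc, anc)
        assert cmp_.identical and cmp_.breakpoints == 0

    def test_swapped_trna_pair_detected(self):
        anc = ancestral_gene_order()
        toks = list(anc.tokens)
        i, j = toks.index(("trnA", "J")), toks.index(("trnR", "J"))
        toks[i], toks[j] = toks[j], toks[i]
        cmp_ = compare_orders(anc, GeneOrder(tuple(toks)))
        assert not cmp_.identical
        assert {"trnA", "trnR"} <= set(cmp_.displaced_genes)
        assert cmp_.breakpoints == naive_breakpoints(anc.tokens, tuple(toks))

    def test_breakpoints_match_brute_force_oracle_on_transposition(self):
        a = (("g1", "J"), ("g2", "J"), ("g3", "N"), ("g4", "J"), ("g5", "J"))
        b = (("g1", "J"), ("g3", "N"), ("g2", "J"), ("g4", "J"), ("g5", "J"))
        cmp_ = compare_orders(GeneOrder(a), GeneOrder(b))
        assert cmp_.breakpoints == naive_breakpoints(a, b)

    def test_reversed_order_matches_oracle(self):
        anc = ancestral_gene_order()
        flip = {"J": "N", "N": "J"}
        rev = tuple((n, flip[s]) for n, s in reversed(anc.tokens))
        cmp_ = compare_orders(anc, GeneOrder(rev))
        # a full reversal is the same circle read backwards: no breakpoints
        assert cmp_.breakpoints == naive_breakpoints(anc.tokens, rev) == 0

    def test_symmetry_and_private_genes_excluded(self):
        a = (("g1", "J"), ("g2", "J"), ("g3", "J"))
        b = (("g1", "J"), ("g3", "J"), ("g4", "J"))
        ab, ba = compare_orders(GeneOrder(a), GeneOrder(b)), \
            compare_orders(GeneOrder(b), GeneOrder(a))
        assert ab.breakpoints == ba.breakpoints
        assert ab.only_in_a == ("g2",) and ab.only_in_b == ("g4",)


class TestSpacersAndOverlaps:
    def _two_gene_genome(self, i2_start, i2_end):
        seq = "ACGTACGTACGTACGTACGTACGTACGT"  # 28 bp
        return AnnotatedMitogenome("X", seq, features=[
            GeneFeature("trnI", 0, 10, "J", "tRNA"),
            GeneFeature("trnQ", i2_start, i2_end, "N", "tRNA")],
            is_circular=False)

    def test_simple_spacer(self):
        junctions, summary = spacers_and_overlaps(self._two_gene_genome(13, 20))
        assert junctions[0].kind == "spacer" and junctions[0].length_bp == 3
        assert summary.n_spacers == 1 and summary.total_spacer_bp == 3

    def test_simple_overlap(self):
        junctions, summary = spacers_and_overlaps(self._two_gene_genome(6, 20))
        assert junctions[0].kind == "overlap" and junctions[0].length_bp == 4
        assert junctions[0].sequence == "GTAC"  # J-strand bases 6..10
        assert summary.n_overlaps == 1 and summary.total_overlap_bp == 4

    def test_abutting_genes(self):
        junctions, _ = spacers_and_overlaps(self._two_gene_genome(10, 20))
        assert junctions[0].kind == "abutting" and junctions[0].length_bp == 0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_closure_around_the_circle(self, seed):
        g, _ = generate(GeneratorSpec(seed=seed))
        assert architecture_closure(g) == g.length_bp

    def test_planted_junction_table_recovered_exactly(self, trio):
        for g, truth in trio:
            junctions, _ = spacers_and_overlaps(g, include_cr_junctions=True)
            found = [(j.upstream_gene, j.downstream_gene, j.kind, j.length_bp)
                     for j in junctions]
            assert found == truth.junctions

    def test_cr_junction_convention(self, genome):
        all_in, _ = spacers_and_overlaps(genome, include_cr_junctions=True)
        _, summary = spacers_and_overlaps(genome, include_cr_junctions=False)
        cr_spacers = [j for j in all_in
                      if j.kind == "spacer" and "CR" in (j.upstream_gene,
                                                         j.downstream_gene)]
        total_spacers = sum(1 for j in all_in if j.kind == "spacer")
        assert summary.n_spacers == total_spacers - len(cr_spacers)


class TestSharedOverlapMotifs:
    def test_conserved_overlaps_with_degenerate_consensus(self, trio_genomes):
        shared = shared_overlap_motifs(trio_genomes)
        # the four junctions planted in every genome
        assert shared[("trnW", "trnC")]["length"] == 8
        assert shared[("trnW", "trnC")]["consensus"] == "AAGYCTTA"
        assert shared[("COX1", "trnL2")]["consensus"] == "TCTAA"
        assert shared[("ATP8", "ATP6")]["length"] == 4
        assert shared[("ATP6", "COX3")]["consensus"] == "A"

    def test_pair_missing_from_one_genome_excluded(self, trio_genomes):
        # trnK/trnD overlap planted in only two of the three genomes
        assert ("trnK", "trnD") not in shared_overlap_motifs(trio_genomes)

    def test_single_genome_reports_own_overlaps(self, genome):
        shared = shared_overlap_motifs([genome])
        assert shared[("trnW", "trnC")]["consensus"] == "AAGTCTTA"


@pytest.mark.parametrize("seqs,expected", [
    (["AAGTCTTA", "AAGCCTTA"], "AAGYCTTA"),
    (["ACGT"], "ACGT"),
    (["AAAA", "CCCC", "GGGG", "TTTT"], "NNNN"),
    (["AG", "GA"], "RR"),
])
def test_iupac_consensus(seqs, expected):
    assert iupac_consensus(seqs) == expected
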
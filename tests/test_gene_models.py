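"""Annotation parsing, divergent-pair detection, controls, and binning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divergon.gene_models import (
    AnnotationError,
    GeneRecord,
    H2HPair,
    PairSet,
    bin_tss_distances,
    canonical_key,
    detect_h2h_pairs,
    read_annotation,
    same_strand_adjacent_pairs,
    sample_random_pairs,
)

from _oracles import brute_force_adjacent, brute_force_h2h


GFF = """##gff-version 3
chr1\ttest\tgene\t100\t900\t.\t+\t.\tID=gA
chr1\ttest\tgene\t2000\t3000\t.\t-\t.\tID=gB
"""


def _random_toy_genes(rng, n=50, chroms=("chr1", "chr2")):
    genes = []
    for i in range(n):
        tss = int(rng.integers(500, 20000))
        length = int(rng.integers(50, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        tes = tss + length if strand == "+" else tss - length
        genes.append(
            GeneRecord(f"g{i:03d}", str(rng.choice(list(chroms))), strand, tss, tes)
        )
    # drop accidental duplicate (chrom, tss) to keep "strictly between" crisp
    seen, out = set(), []
    for g in genes:
        if (g.chrom, g.tss) not in seen:
            seen.add((g.chrom, g.tss))
            out.append(g)
    return out


class TestGeneRecord:
    def test_strand_orients_tss_and_tes(self):
        GeneRecord("a", "chr1", "+", 100, 900)
        GeneRecord("b", "chr1", "-", 900, 100)
        with pytest.raises(AnnotationError):
            GeneRecord("c", "chr1", "+", 900, 100)
        with pytest.raises(AnnotationError):
            GeneRecord("d", "chr1", ".", 100, 900)


class TestReadAnnotation:
    def test_gff3_tss_follows_strand(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(GFF)
        records = {g.gene_id: g for g in read_annotation(str(path))}
        assert records["gA"].tss == 100 and records["gA"].tes == 900
        assert records["gB"].tss == 3000 and records["gB"].tes == 2000

    def test_empty_file_warns_and_returns_nothing(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert read_annotation(str(path)) == []
        assert "empty" in caplog.text

    def test_tsv_roundtrip_and_duplicate_error(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "gene_id\tchrom\tstrand\ttss\ttes\n"
            "gA\tchr1\t+\t100\t900\n"
            "gB\tchr1\t-\t3000\t2000\n"
        )
        assert [g.gene_id for g in read_annotation(str(path))] == ["gA", "gB"]
        path.write_text(
            "gene_id\tchrom\tstrand\ttss\ttes\n"
            "gA\tchr1\t+\t100\t900\n"
            "gA\tchr1\t+\t100\t900\n"
        )
        with pytest.raises(AnnotationError, match="duplicate"):
            read_annotation(str(path))


class TestDetectH2H:
    def test_simple_divergent_pair(self):
        genes = [
            GeneRecord("m", "chr1", "-", 1000, 500),
            GeneRecord("p", "chr1", "+", 1150, 1600),
        ]
        (pair,) = detect_h2h_pairs(genes)
        assert pair.tss_distance == 150 and not pair.overlapping
        assert pair.minus_gene == "m" and pair.plus_gene == "p"

    @pytest.mark.parametrize(
        "genes",
        [
            # same strand only
            [GeneRecord("a", "chr1", "+", 100, 600),
             GeneRecord("b", "chr1", "+", 2000, 2500)],
            # beyond max distance
            [GeneRecord("m", "chr1", "-", 1000, 500),
             GeneRecord("p", "chr1", "+", 2500, 3000)],
            # different chromosomes
            [GeneRecord("m", "chr1", "-", 1000, 500),
             GeneRecord("p", "chr2", "+", 1150, 1600)],
        ],
    )
    def test_no_pair_cases(self, genes):
        assert detect_h2h_pairs(genes, max_distance=1000) == []

    def test_intervening_tss_breaks_adjacency(self):
        genes = [
            GeneRecord("m", "chr1", "-", 1000, 500),
            GeneRecord("x", "chr1", "+", 1050, 1500),
            GeneRecord("p", "chr1", "+", 1150, 1600),
        ]
        pairs = detect_h2h_pairs(genes)
        assert [(p.minus_gene, p.plus_gene) for p in pairs] == [("m", "x")]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        genes = _random_toy_genes(rng)
        for max_overlap in (None, 200):
            got = {p.key for p in detect_h2h_pairs(genes, 1000, max_overlap)}
            assert got == brute_force_h2h(genes, 1000, max_overlap)

    def test_permutation_invariance_and_pair_invariants(self):
        rng = np.random.default_rng(9)
        genes = _random_toy_genes(rng)
        ref = detect_h2h_pairs(genes)
        by_id = {g.gene_id: g for g in genes}
        for p in ref:
            assert by_id[p.minus_gene].chrom == by_id[p.plus_gene].chrom
            assert by_id[p.minus_gene].strand != by_id[p.plus_gene].strand
            assert p.tss_distance == by_id[p.plus_gene].tss - by_id[p.minus_gene].tss
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert detect_h2h_pairs(shuffled) == ref


class TestAdjacentControl:
    def test_neighbour_on_each_side(self):
        genes = [
            GeneRecord("l", "chr1", "+", 100, 500),
            GeneRecord("f", "chr1", "+", 1000, 1500),
            GeneRecord("r", "chr1", "+", 2000, 2500),
            GeneRecord("other", "chr1", "-", 3000, 2600),
        ]
        ps = same_strand_adjacent_pairs(genes, ["f"])
        assert ps.keys == {("f", "l"), ("f", "r")}

    def test_lonely_strand_contributes_nothing(self):
        genes = [
            GeneRecord("f", "chr1", "+", 1000, 1500),
            GeneRecord("o", "chr1", "-", 3000, 2600),
        ]
        assert len(same_strand_adjacent_pairs(genes, ["f"])) == 0

    def test_missing_focal_gene_is_an_error(self):
        genes = [GeneRecord("a", "chr1", "+", 100, 500)]
        with pytest.raises(KeyError, match="ghost"):
            same_strand_adjacent_pairs(genes, ["ghost"])

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        genes = _random_toy_genes(rng, n=12, chroms=("chr1",))
        focal = [g.gene_id for g in genes[:5]]
        got = same_strand_adjacent_pairs(genes, focal)
        assert got.keys == brute_force_adjacent(genes, focal)


class TestRandomPairs:
    def test_count_and_determinism(self):
        ids = [f"g{i}" for i in range(40)]
        a = sample_random_pairs(ids, n_per_rep=13, n_reps=7, seed=3)
        b = sample_random_pairs(ids, n_per_rep=13, n_reps=7, seed=3)
        assert len(a) == 13 * 7
        assert a.pairs == b.pairs and a.replicate == b.replicate
        assert all(x != y for x, y in a)

    def test_two_genes_forces_the_single_pair(self):
        ps = sample_random_pairs(["a", "b"], n_per_rep=5, n_reps=1, seed=0)
        assert ps.pairs == [("a", "b")] * 5

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            sample_random_pairs(["only"], 1, 1, seed=0)


class TestPairSet:
    def test_rejects_self_pairs_and_duplicates(self):
        with pytest.raises(ValueError, match="self-pair"):
            PairSet("x", [("a", "a")])
        with pytest.raises(ValueError, match="duplicate"):
            PairSet("x", [("a", "b"), ("b", "a")])
        ps = PairSet("x", [("b", "a")], unique=False)
        assert ps.pairs == [("a", "b")]


class TestBinning:
    def test_boundary_convention(self):
        pairs = [H2HPair("m", f"p{i}", "chr1", d) for i, d in enumerate((50, 100, 150))]
        df = bin_tss_distances(pairs, edges=(0, 100, 200)).set_index("bin")
        assert df.loc["(0, 100]", "count"] == 2
        assert df.loc["(100, 200]", "count"] == 1

    def test_all_overlapping(self):
        pairs = [H2HPair("m", f"p{i}", "chr1", -d) for i, d in enumerate((0, 5, 50))]
        df = bin_tss_distances(pairs, edges=(0, 100)).set_index("bin")
        assert df.loc["overlapping", "count"] == 3
        assert df.drop("overlapping")["count"].sum() == 0

    def test_empty_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_tss_distances([], edges=())

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-500, max_value=3000), min_size=1, max_size=200)
    )
    def test_mass_conservation_and_percent_sum(self, distances):
        pairs = [H2HPair("m", f"p{i}", "chr1", d) for i, d in enumerate(distances)]
        df = bin_tss_distances(pairs, edges=(0, 100, 200, 400, 1000))
        assert df["count"].sum() == len(distances)
        assert np.isclose(df["percent"].sum(), 100.0)
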
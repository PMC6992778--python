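"""Feature assignment, UMI deduplication, matrix merging and MTX I/O."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nucquant.genome_annotation import GenomicInterval
from nucquant.umi_quant import (
    AlignedRead,
    CountMatrix,
    FeatureAssignment,
    GeneIndex,
    assign_read,
    count_umis,
    merge_matrices,
    read_mtx,
    read_sam,
    write_mtx,
    write_sam,
)

from conftest import make_gene


def read_at(start, end, strand="+", cb="A" * 12, umi="C" * 8, chrom="chr1"):
    return AlignedRead(cb, umi, GenomicInterval(chrom, start, end, strand))


@pytest.fixture
def simple_index():
    g1 = make_gene("g1", (0, 1000), [(0, 100), (600, 1000)])  # intron [100,600)
    g2 = make_gene("g2", (2000, 3000), [(2000, 2100), (2900, 3000)], strand="-")
    return GeneIndex([g1, g2])


class TestAssignRead:
    def test_exon_overlap(self, simple_index):
        a = assign_read(read_at(50, 110), simple_index)
        assert (a.gene_id, a.region) == ("g1", "exonic")

    def test_intronic_read(self, simple_index):
        a = assign_read(read_at(350, 400), simple_index)
        assert (a.gene_id, a.region) == ("g1", "intronic")

    def test_exon_precedence_within_one_gene(self, simple_index):
        # spans the exon/intron boundary of g1 only -> exonic
        a = assign_read(read_at(80, 140), simple_index)
        assert (a.gene_id, a.region) == ("g1", "exonic")

    def test_intergenic(self, simple_index):
        a = assign_read(read_at(1200, 1260), simple_index)
        assert (a.gene_id, a.region) == (None, "intergenic")

    def test_unknown_chromosome_is_intergenic(self, simple_index):
        a = assign_read(read_at(10, 50, chrom="chrUn"), simple_index)
        assert a.region == "intergenic"

    def test_stranded_mode_ignores_antisense_features(self, simple_index):
        a = assign_read(read_at(2950, 2990, strand="+"), simple_index, stranded=True)
        assert a.region == "intergenic"
        a = assign_read(read_at(2950, 2990, strand="-"), simple_index, stranded=True)
        assert (a.gene_id, a.region) == ("g2", "exonic")

    def test_two_gene_overlap_is_ambiguous_by_default(self):
        gA = make_gene("gA", (0, 500), [(0, 200), (400, 500)])
        gB = make_gene("gB", (100, 800), [(100, 120), (700, 800)])
        index = GeneIndex([gA, gB])
        # read in gA's exon [0,200) and gB's intron [120,700)
        a = assign_read(read_at(150, 200), index)
        assert a.region == "ambiguous"
        a = assign_read(read_at(150, 200), index, exon_priority=True)
        assert (a.gene_id, a.region) == ("gA", "exonic")

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_base_membership_oracle(self, seed):
        """On random (possibly overlapping) gene layouts, assignment equals
        a brute-force per-base membership scan."""
        rng = np.random.default_rng(seed)
        genes = []
        for k in range(8):
            start = int(rng.integers(0, 3000))
            n_ex = int(rng.integers(2, 4))
            exons, p = [], start
            for _ in range(n_ex):
                exons.append((p, p + int(rng.integers(30, 120))))
                p = exons[-1][1] + int(rng.integers(50, 200))
            genes.append(
                make_gene(f"g{k}", (exons[0][0], exons[-1][1]), exons,
                          strand="+" if rng.random() < 0.5 else "-")
            )
        index = GeneIndex(genes)
        for _ in range(300):
            s = int(rng.integers(0, 4000))
            read = read_at(s, s + 60)
            got = assign_read(read, index)
            bases = set(range(s, s + 60))
            ex = {g.gene_id for g in genes
                  if any(bases & set(range(e.start, e.end)) for e in g.exons)}
            intr = {g.gene_id for g in genes
                    if any(bases & set(range(i.start, i.end)) for i in g.introns)}
            hit = ex | intr
            if not hit:
                expected = (None, "intergenic")
            elif len(hit) == 1:
                gid = next(iter(hit))
                expected = (gid, "exonic" if gid in ex else "intronic")
            else:
                expected = (None, "ambiguous")
            assert (got.gene_id, got.region) == expected


def asn(cb, umi, gene, region):
    return FeatureAssignment(read_at(0, 60, cb=cb, umi=umi), gene, region)


class TestCountUmis:
    def test_manual_enumeration(self):
        rows = (
            [asn("c1" + "A" * 10, "u1" + "A" * 6, "gA", "exonic")] * 3
            + [asn("c1" + "A" * 10, "u2" + "A" * 6, "gA", "exonic")]
            + [asn("c1" + "A" * 10, "u1" + "A" * 6, "gB", "exonic")]
        )
        m = count_umis(rows, "exon_only")
        df = m.to_frame()
        assert df.loc["gA", "c1" + "A" * 10] == 2
        assert df.loc["gB", "c1" + "A" * 10] == 1

    def test_umi_in_exon_and_intron_of_same_gene_counts_once(self):
        rows = [
            asn("c1" + "A" * 10, "u1" + "A" * 6, "gA", "exonic"),
            asn("c1" + "A" * 10, "u1" + "A" * 6, "gA", "intronic"),
        ]
        m = count_umis(rows, "exon_plus_intron")
        assert m.to_frame().iloc[0, 0] == 1

    def test_ambiguous_and_intergenic_contribute_nothing(self):
        rows = [
            asn("c1" + "A" * 10, "u1" + "A" * 6, "gA", "exonic"),
            FeatureAssignment(read_at(0, 60), None, "ambiguous"),
            FeatureAssignment(read_at(0, 60), None, "intergenic"),
        ]
        m = count_umis(rows, "exon_plus_intron")
        assert m.counts.sum() == 1

    def test_500_planted_triplets_match_set_count_oracle(self):
        """Duplicated reads over 500 known (cell, gene, UMI) triplets
        collapse to exactly the brute-force set count."""
        rng = np.random.default_rng(3)
        cells = [f"c{i:02d}" + "A" * 9 for i in range(10)]
        genes = [f"g{i}" for i in range(20)]
        triplets = set()
        while len(triplets) < 500:
            triplets.add(
                (
                    cells[rng.integers(10)],
                    genes[rng.integers(20)],
                    "".join(rng.choice(list("ACGT"), 8)),
                )
            )
        rows = []
        for c, g, u in triplets:
            region = "intronic" if rng.random() < 0.5 else "exonic"
            rows += [asn(c, u, g, region)] * int(rng.integers(1, 4))
        rng.shuffle(rows)
        m = count_umis(rows, "exon_plus_intron")
        brute = {}
        for c, g, u in triplets:
            brute.setdefault((g, c), set()).add(u)
        df = m.to_frame()
        for (g, c), umis in brute.items():
            assert df.loc[g, c] == len(umis)
        assert int(m.counts.sum()) == 500

    def test_exon_plus_intron_dominates_exon_only(self):
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(400):
            rows.append(
                asn(
                    f"c{rng.integers(5)}" + "A" * 10,
                    "".join(rng.choice(list("ACGT"), 8)),
                    f"g{rng.integers(8)}",
                    "intronic" if rng.random() < 0.5 else "exonic",
                )
            )
        genes = sorted({r.gene_id for r in rows})
        cells = sorted({r.read.cell_barcode for r in rows})
        exon = count_umis(rows, "exon_only", genes, cells)
        both = count_umis(rows, "exon_plus_intron", genes, cells)
        diff = (both.counts - exon.counts).toarray()
        assert (diff >= 0).all()


class TestMergeMatrices:
    def mat(self, genes, cells, dense, mode="exon_plus_intron"):
        return CountMatrix(genes, cells, sp.csr_matrix(np.array(dense)), mode)

    def test_union_with_zero_fill(self):
        merged = merge_matrices(
            [self.mat(["gA"], ["c1"], [[5]]), self.mat(["gB"], ["c2"], [[7]])]
        )
        expected = pd.DataFrame(
            [[5, 0], [0, 7]], index=["gA", "gB"], columns=["c1", "c2"]
        )
        pd.testing.assert_frame_equal(merged.to_frame(), expected, check_dtype=False)

    def test_single_matrix_is_identity(self):
        m = self.mat(["gA", "gB"], ["c1"], [[1], [2]])
        merged = merge_matrices([m])
        pd.testing.assert_frame_equal(merged.to_frame(), m.to_frame())

    def test_split_then_merge_round_trips(self):
        rng = np.random.default_rng(5)
        dense = rng.integers(0, 5, size=(12, 9))
        genes = [f"g{i}" for i in range(12)]
        cells = [f"c{i}" for i in range(9)]
        m = self.mat(genes, cells, dense)
        left = self.mat(genes, cells[:4], dense[:, :4])
        right = self.mat(genes, cells[4:], dense[:, 4:])
        merged = merge_matrices([left, right])
        # merged gene axis is the sorted union; compare on that ordering
        pd.testing.assert_frame_equal(
            merged.to_frame(), m.to_frame().loc[sorted(genes)]
        )

    def test_duplicate_barcodes_error_unless_suffixed(self):
        a = self.mat(["gA"], ["c1"], [[1]])
        b = self.mat(["gA"], ["c1"], [[2]])
        with pytest.raises(ValueError, match="c1"):
            merge_matrices([a, b])
        merged = merge_matrices([a, b], suffixes=["-1", "-2"])
        assert merged.cell_barcodes == ["c1-1", "c1-2"]

    def test_mode_mismatch_rejected(self):
        a = self.mat(["gA"], ["c1"], [[1]], "exon_only")
        b = self.mat(["gA"], ["c2"], [[2]], "exon_plus_intron")
        with pytest.raises(ValueError, match="mode"):
            merge_matrices([a, b])


class TestMtxRoundTrip:
    def test_random_sparse_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        dense = (rng.random((200, 300)) < 0.02) * rng.integers(1, 9, (200, 300))
        m = CountMatrix(
            [f"g{i}" for i in range(200)],
            [f"c{i}" for i in range(300)],
            sp.csr_matrix(dense),
            "exon_only",
        )
        write_mtx(m, tmp_path / "m")
        back = read_mtx(tmp_path / "m", mode="exon_only")
        assert back.gene_ids == m.gene_ids
        assert back.cell_barcodes == m.cell_barcodes
        assert (back.counts != m.counts).nnz == 0

    def test_empty_matrix_round_trip(self, tmp_path):
        m = CountMatrix(["gA", "gB"], ["c1"], sp.csr_matrix((2, 1)), "exon_only")
        write_mtx(m, tmp_path / "m")
        back = read_mtx(tmp_path / "m", mode="exon_only")
        assert back.counts.nnz == 0

    def test_header_id_mismatch_rejected(self, tmp_path):
        m = CountMatrix(["gA"], ["c1"], sp.csr_matrix([[1]]), "exon_only")
        write_mtx(m, tmp_path / "m")
        (tmp_path / "m.genes.tsv").write_text("gA\ngB\n")
        with pytest.raises(ValueError, match="match"):
            read_mtx(tmp_path / "m")


class TestSamRoundTrip:
    def test_reads_survive_sam_round_trip(self, tmp_path):
        reads = [
            read_at(10, 70, cb="ACGTACGTACGT", umi="AAAACCCC"),
            read_at(200, 260, strand="-", cb="TTTTGGGGCCCC", umi="GGGGTTTT"),
            AlignedRead(
                "ACGTACGTACGT",
                "AAAATTTT",
                GenomicInterval("chr2", 5, 65, "+"),
                species="speciesB",
            ),
        ]
        path = tmp_path / "r.sam"
        write_sam(reads, {"chr1": 1000, "chr2": 1000}, path)
        back = list(read_sam(path))
        assert [(r.cell_barcode, r.umi, r.interval, r.species) for r in back] == [
            (r.cell_barcode, r.umi, r.interval, r.species) for r in reads
        ]
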
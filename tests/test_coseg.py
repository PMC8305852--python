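"""Gene projection, co-segregation set logic, and the published gene matrix."""
import numpy as np
import pandas as pd
import pytest

from dhblocks import coseg, fixtures, hmm, simulate as sim
from dhblocks._util import HET, NA, P1, P2

#: The ten pathway genes bolded in the published matrix: every high-GSL line
#: carries the high parent's haplotype and every low-GSL line the low parent's.
EXPECTED_COSEG = [
    ("MYB28.1", "Bra012961"),
    ("MYB34.2", "Bra013000"),
    ("BCAT-4", "Bra001761"),
    ("MAM1", "Bra013007"),
    ("MAM3", "Bra013009"),
    ("MAM3", "Bra013011"),
    ("BAT5", "Bra000760"),
    ("AOP1", "Bra000847"),
    ("AOP2", "Bra000848"),
    ("APK1", "Bra013120"),
]


def _gene(start, stop, name="g", gid="Bra000001", chrom="A03", stage=None):
    return coseg.GeneModel(chrom, start, stop, name, gid, pathway_stage=stage)


def _block(start, end, label, line="DH1", chrom="A03", n=10):
    return hmm.Block(line, chrom, start, end, label, n, 0)


class TestAssignGeneOrigin:
    def test_midpoint_inside_block(self):
        blocks = [_block(1_000, 50_000, P1), _block(60_000, 90_000, P2)]
        call = coseg.assign_gene_origin(blocks, _gene(10_000, 20_000))
        assert call == coseg.GeneCall(P1, boundary=False)

    def test_midpoint_in_gap_is_na(self):
        blocks = [_block(1_000, 50_000, P1), _block(60_000, 90_000, P2)]
        assert coseg.assign_gene_origin(blocks, _gene(52_000, 58_000)).label == NA

    def test_boundary_spanning_gene_is_flagged(self):
        blocks = [_block(1_000, 50_000, P1), _block(50_500, 90_000, P2)]
        call = coseg.assign_gene_origin(blocks, _gene(40_000, 55_000))
        assert call.label == P1 and call.boundary

    def test_wrong_chromosome_gives_na(self):
        blocks = [_block(1_000, 90_000, P1, chrom="A01")]
        assert coseg.assign_gene_origin(blocks, _gene(10_000, 20_000)).label == NA


class TestBuildGeneMatrix:
    def test_parent_columns_are_their_own_label(self):
        genes = [_gene(10_000, 20_000, gid="Bra000001")]
        blocks = {"DH1": [_block(1_000, 90_000, P2)]}
        m = coseg.build_gene_matrix(blocks, genes, parents={"LP08": P1, "LP21": P2})
        assert m.loc["Bra000001", "LP08"] == P1
        assert m.loc["Bra000001", "LP21"] == P2
        assert m.loc["Bra000001", "DH1"] == P2

    def test_zero_lines_gives_gene_rows_only(self):
        genes = [_gene(10_000, 20_000, gid="Bra000001")]
        m = coseg.build_gene_matrix({}, genes)
        assert list(m.index) == ["Bra000001"] and m.shape[1] == 0

    def test_column_order_follows_line_order(self):
        genes = [_gene(10_000, 20_000, gid="Bra000001")]
        blocks = {"B": [_block(1, 90_000, P1)], "A": [_block(1, 90_000, P2)]}
        m = coseg.build_gene_matrix(blocks, genes)
        assert list(m.columns) == ["B", "A"]


class TestCosegGenes:
    def test_published_matrix_yields_the_ten_bold_genes(self):
        matrix = fixtures.load_table3()
        ids = coseg.find_cosegregating_genes(
            matrix, fixtures.HGSL_LINES, fixtures.LGSL_LINES,
            parental_labels=("LP08", "LP21"),
        )
        assert ids == [gid for _, gid in EXPECTED_COSEG]
        by_id = {g.gene_id_v1_5: g for g in matrix.attrs["genes"]}
        assert [(by_id[g].name, g) for g in ids] == EXPECTED_COSEG
        # all ten lie in the A03 co-segregating interval
        for gid in ids:
            g = by_id[gid]
            assert g.chromosome == "A03"
            assert 12_929_867 <= g.start and g.stop <= 23_248_122

    def test_orientation_is_symmetric(self):
        matrix = fixtures.load_table3()
        fwd = coseg.find_cosegregating_genes(
            matrix, fixtures.HGSL_LINES, fixtures.LGSL_LINES, parental_labels=("LP08", "LP21"))
        rev = coseg.find_cosegregating_genes(
            matrix, fixtures.LGSL_LINES, fixtures.HGSL_LINES, parental_labels=("LP08", "LP21"))
        assert fwd == rev

    def test_overlapping_or_empty_groups_rejected(self):
        matrix = fixtures.load_table3()
        with pytest.raises(ValueError):
            coseg.find_cosegregating_genes(matrix, ["DH005"], ["DH005", "DH009"])
        with pytest.raises(ValueError):
            coseg.find_cosegregating_genes(matrix, [], ["DH009"])

    def test_uniform_matrix_has_no_separation(self):
        m = pd.DataFrame({"A": [P1, P1], "B": [P1, P1]}, index=["g1", "g2"])
        assert coseg.find_cosegregating_genes(m, ["A"], ["B"], parental_labels=(P1, P2)) == []

    def test_het_or_na_cell_disqualifies(self):
        m = pd.DataFrame({"A": [P1, P1], "B": [HET, NA]}, index=["g1", "g2"])
        assert coseg.find_cosegregating_genes(m, ["A"], ["B"], parental_labels=(P1, P2)) == []

    def test_adding_a_line_never_grows_the_set(self):
        matrix = fixtures.load_table3()
        full = coseg.find_cosegregating_genes(
            matrix, fixtures.HGSL_LINES, fixtures.LGSL_LINES, parental_labels=("LP08", "LP21"))
        for k in range(1, len(fixtures.HGSL_LINES)):
            subset = coseg.find_cosegregating_genes(
                matrix, fixtures.HGSL_LINES[:k], fixtures.LGSL_LINES,
                parental_labels=("LP08", "LP21"))
            assert set(full) <= set(subset)

    def test_line_and_gene_order_do_not_matter(self):
        matrix = fixtures.load_table3()
        base = coseg.find_cosegregating_genes(
            matrix, fixtures.HGSL_LINES, fixtures.LGSL_LINES, parental_labels=("LP08", "LP21"))
        shuffled = matrix.sample(frac=1.0, axis=0, random_state=5)
        shuffled.attrs = matrix.attrs
        out = coseg.find_cosegregating_genes(
            shuffled, list(reversed(fixtures.HGSL_LINES)), fixtures.LGSL_LINES,
            parental_labels=("LP08", "LP21"))
        assert set(out) == set(base)

    def test_max_violations_relaxes_filter(self):
        matrix = fixtures.load_table3()
        strict = coseg.find_cosegregating_genes(
            matrix, fixtures.HGSL_LINES, fixtures.LGSL_LINES, parental_labels=("LP08", "LP21"))
        relaxed = coseg.find_cosegregating_genes(
            matrix, fixtures.HGSL_LINES, fixtures.LGSL_LINES,
            parental_labels=("LP08", "LP21"), max_violations=1)
        assert set(strict) < set(relaxed)


class TestCosegRegions:
    @staticmethod
    def _markers(positions, chrom="A03"):
        return [
            sim.ParentalMarker(chrom, p, "A", "G", "A", "G", "SNP") for p in positions
        ]

    def test_simple_separating_run_found(self):
        pos = list(range(10_000, 310_000, 10_000))  # 30 markers
        markers = self._markers(pos)
        blocks = {
            "H1": [_block(1, 310_000, P1, line="H1")],
            "H2": [_block(1, 150_000, P2, line="H2"), _block(150_001, 310_000, P1, line="H2")],
            "L1": [_block(1, 310_000, P2, line="L1")],
        }
        regions = coseg.find_cosegregating_regions(markers, blocks, ["H1", "H2"], ["L1"])
        assert len(regions) == 1
        r = regions[0]
        assert r.start == 160_000 and r.end == 300_000
        assert (r.groupA_label, r.groupB_label) == (P1, P2)
        assert r.n_markers == 15

    def test_group_swap_exchanges_labels(self):
        pos = list(range(10_000, 310_000, 10_000))
        markers = self._markers(pos)
        blocks = {
            "H1": [_block(1, 310_000, P1, line="H1")],
            "L1": [_block(1, 310_000, P2, line="L1")],
        }
        fwd = coseg.find_cosegregating_regions(markers, blocks, ["H1"], ["L1"])
        rev = coseg.find_cosegregating_regions(markers, blocks, ["L1"], ["H1"])
        assert [(r.start, r.end) for r in fwd] == [(r.start, r.end) for r in rev]
        assert fwd[0].groupA_label == rev[0].groupB_label == P1

    def test_short_runs_suppressed(self):
        pos = list(range(10_000, 100_000, 10_000))  # 9 markers < default minimum
        markers = self._markers(pos)
        blocks = {
            "H1": [_block(1, 100_000, P1, line="H1")],
            "L1": [_block(1, 100_000, P2, line="L1")],
        }
        assert coseg.find_cosegregating_regions(markers, blocks, ["H1"], ["L1"]) == []
        assert len(coseg.find_cosegregating_regions(
            markers, blocks, ["H1"], ["L1"], min_markers=5)) == 1

    def test_planted_region_recovered_from_called_blocks(self, small_population):
        """End-to-end on simulated data: called regions equal the truth-scan oracle."""
        res = small_population
        pos = [m.position for m in res.markers]
        high = [l for l in res.truth.lines if res.truth.groups[l] == "high"]
        low = [l for l in res.truth.lines if res.truth.groups[l] == "low"]
        called_blocks = {
            l: hmm.call_blocks({"A03": (pos, res.calls[l]["A03"])}, line=l)
            for l in res.truth.lines
        }
        called = coseg.find_cosegregating_regions(res.markers, called_blocks, high, low)
        oracle = coseg.find_cosegregating_regions(
            res.markers, sim.truth_to_blocks(res.truth, res.markers), high, low)
        assert [(r.start, r.end) for r in called] == [(r.start, r.end) for r in oracle]
        cr = res.config.causal_region
        assert any(r.start <= cr.midpoint <= r.end for r in called)

    def test_random_groups_rarely_separate(self, small_population, rng):
        res = small_population
        pos = [m.position for m in res.markers]
        called_blocks = {
            l: hmm.call_blocks({"A03": (pos, res.calls[l]["A03"])}, line=l)
            for l in res.truth.lines
        }
        clean = 0
        for _ in range(20):
            lines = list(res.truth.lines)
            rng.shuffle(lines)
            regions = coseg.find_cosegregating_regions(
                res.markers, called_blocks, lines[:10], lines[10:])
            clean += not regions
        assert clean >= 18


class TestPathwayProfile:
    def test_side_chain_elongation_genes_of_the_top_line_are_high_parent(self):
        """The MAM1/MAM3 trio in the A03 cluster is high-parent in DH005."""
        matrix = fixtures.load_table3()
        prof = coseg.pathway_profile(matrix, "DH005")
        stage = prof[prof["stage"] == "Side chain elongation"]
        lp08_genes = stage.loc[stage["label"] == "LP08", "genes"].iloc[0]
        for gid in ("Bra013007", "Bra013009", "Bra013011"):
            assert gid in lp08_genes

    def test_parent_column_is_uniform(self):
        matrix = fixtures.load_table3()
        prof = coseg.pathway_profile(matrix, "LP21")
        assert set(prof["label"]) == {"LP21"}

    def test_counts_partition_each_stage(self):
        matrix = fixtures.load_table3()
        prof = coseg.pathway_profile(matrix, "DH009")
        genes = matrix.attrs["genes"]
        for stage, sub in prof.groupby("stage"):
            n_stage = sum(g.pathway_stage == stage for g in genes)
            assert sub["n_genes"].sum() == n_stage

    def test_unknown_line_rejected(self):
        with pytest.raises(ValueError):
            coseg.pathway_profile(fixtures.load_table3(), "DH999")
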
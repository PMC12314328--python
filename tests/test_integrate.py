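"""Integration stage: peak-to-gene assignment, filters, Combined Score,
ranking, and the published-target overlap counter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bach1sig import integrate as ig
from bach1sig.iotables import DERecord, GeneModel, Peak
from bach1sig.synthetic_data import SimulationConfig, simulate_experiment

from conftest import make_de, make_gene, make_peak

CFG = ig.IntegrationConfig()


class TestAssignment:
    def test_peak_inside_gene_assigned(self):
        assigned = ig.assign_peaks_to_genes([make_peak(start=900, end=1100)], [make_gene()])
        assert [p.peak_id for p in assigned["GENE1"]] == ["pk1"]

    @pytest.mark.parametrize(
        "gap, expected",
        [(9998, True), (9999, True), (10000, True), (10001, False), (10002, False)],
    )
    @pytest.mark.parametrize("side", ["upstream", "downstream"])
    def test_window_boundary_is_inclusive(self, gap, expected, side):
        gene = make_gene(start=50_000, end=60_000)
        if side == "upstream":
            peak = make_peak(start=gene.start - gap - 1000, end=gene.start - gap)
        else:
            peak = make_peak(start=gene.end + gap, end=gene.end + gap + 1000)
        assigned = ig.assign_peaks_to_genes([peak], [gene], window_bp=10_000)
        assert ("GENE1" in assigned) is expected

    def test_different_chromosome_never_assigned(self):
        assigned = ig.assign_peaks_to_genes(
            [make_peak(chrom="chr2")], [make_gene(chrom="chr1")]
        )
        assert assigned == {}

    def test_one_peak_may_hit_multiple_genes(self):
        genes = [make_gene("A", start=0, end=1000), make_gene("B", start=1500, end=2500)]
        assigned = ig.assign_peaks_to_genes([make_peak(start=1100, end=1300)], genes)
        assert set(assigned) == {"A", "B"}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_peaks = rng.integers(1, 50), rng.integers(0, 200)
        window = int(rng.choice([0, 100, 10_000]))
        genes = [
            GeneModel(f"g{i}", f"chr{rng.integers(1, 3)}", s := int(rng.integers(0, 100_000)), s + int(rng.integers(1, 5000)))
            for i in range(n_genes)
        ]
        peaks = [
            Peak(f"p{i}", f"chr{rng.integers(1, 3)}", s := int(rng.integers(0, 100_000)), s + int(rng.integers(1, 500)), 0.0)
            for i in range(n_peaks)
        ]

        def gap(p, g):
            if p.chrom != g.chrom:
                return None
            if p.end <= g.start:
                return g.start - p.end
            if g.end <= p.start:
                return p.start - g.end
            return 0

        brute = {}
        for g in genes:
            hits = [p.peak_id for p in peaks if gap(p, g) is not None and gap(p, g) <= window]
            if hits:
                brute[g.gene_id] = sorted(hits)
        fast = {
            gid: sorted(p.peak_id for p in ps)
            for gid, ps in ig.assign_peaks_to_genes(peaks, genes, window).items()
        }
        assert fast == brute

    def test_enlarging_window_never_removes_assignments(self, rng):
        genes = [make_gene(f"g{i}", start=i * 30_000, end=i * 30_000 + 5000) for i in range(10)]
        peaks = [
            make_peak(f"p{i}", start=(s := int(rng.integers(0, 300_000))), end=s + 200)
            for i in range(100)
        ]
        small = ig.assign_peaks_to_genes(peaks, genes, 1000)
        large = ig.assign_peaks_to_genes(peaks, genes, 20_000)
        for gid, ps in small.items():
            assert {p.peak_id for p in ps} <= {p.peak_id for p in large[gid]}


class TestFiltersAndScore:
    def test_binding_value_is_max_over_peaks(self):
        peaks = [make_peak("a", log2_ratio=0.5), make_peak("b", log2_ratio=1.2)]
        assert ig.gene_binding_value(peaks) == pytest.approx(1.2)
        assert ig.gene_binding_value([]) is None

    @pytest.mark.parametrize(
        "padj, expected", [(0.05, True), (0.0999, True), (0.10, False), (0.2, False), (None, False)]
    )
    def test_replicate_mode_padj_strictly_below_cutoff(self, padj, expected):
        assert ig.de_significant(DERecord("g", 1.0, padj), CFG) is expected

    @pytest.mark.parametrize("lfc, expected", [(0.30, False), (0.35, True), (-0.35, True), (0.0, False)])
    def test_no_replicate_mode_lfc_strictly_above_cutoff(self, lfc, expected):
        cfg = ig.IntegrationConfig(no_replicate_mode=True)
        assert ig.de_significant(DERecord("g", lfc, None), cfg) is expected

    @pytest.mark.parametrize(
        "binding, lfc, padj, expected",
        [(0.0, 0.0, 1.0, 0.0), (1.0, 1.0, 0.1, 1.0), (2.0, -3.0, 1e-4, 2.75)],
    )
    def test_combined_score_worked_examples(self, binding, lfc, padj, expected):
        assert ig.combined_score(binding, lfc, padj) == pytest.approx(expected)

    def test_combined_score_is_affine_in_each_term(self, rng):
        for _ in range(20):
            b, f, p = rng.uniform(0, 3), rng.uniform(-4, 4), rng.uniform(1e-10, 1)
            base = ig.combined_score(b, f, p)
            assert ig.combined_score(b + 1, f, p) - base == pytest.approx(0.5)
            df = abs(f) + 1  # unit increment of |log2fc|
            assert ig.combined_score(b, df, p) - base == pytest.approx(0.25)

    def test_neglog10_capped(self):
        score = ig.combined_score(0.0, 0.0, 1e-320)
        assert score == pytest.approx(0.25 * 300)

    def test_zero_padj_is_contract_violation(self):
        with pytest.raises(ValueError):
            ig.combined_score(1.0, 1.0, 0.0)


class TestIntegrateAndRank:
    def _toy(self):
        genes = [make_gene(f"g{i}", start=i * 100_000, end=i * 100_000 + 5000) for i in range(4)]
        peaks = [
            make_peak(f"p{i}", start=g.start + 100, end=g.start + 300, log2_ratio=r)
            for i, (g, r) in enumerate(zip(genes, [2.0, 1.5, 0.6, 1.0]))
        ]
        de = [
            make_de("g0", 3.0, 1e-8),
            make_de("g1", -2.0, 1e-4),
            make_de("g2", 5.0, 1e-10),  # fails binding
            make_de("g3", 1.0, 0.5),  # fails DE
        ]
        return genes, peaks, de

    def test_filters_and_ranks(self):
        genes, peaks, de = self._toy()
        ranked = ig.integrate_and_rank(de, peaks, genes)
        assert [g.gene_id for g in ranked] == ["g0", "g1"]
        assert [g.rank for g in ranked] == [1, 2]
        g0 = ranked[0]
        # score recomputable from the reported fields
        assert g0.combined_score == pytest.approx(
            0.5 * g0.binding_value + 0.25 * abs(g0.log2fc) + 0.25 * -np.log10(g0.padj)
        )

    def test_direction_filter(self):
        genes, peaks, de = self._toy()
        up = ig.integrate_and_rank(de, peaks, genes, ig.IntegrationConfig(direction="up"))
        down = ig.integrate_and_rank(de, peaks, genes, ig.IntegrationConfig(direction="down"))
        assert [g.gene_id for g in up] == ["g0"]
        assert [g.gene_id for g in down] == ["g1"]

    def test_flip_log2fc_swaps_directions(self):
        genes, peaks, de = self._toy()
        flipped_up = ig.integrate_and_rank(
            de, peaks, genes, ig.IntegrationConfig(direction="up", flip_log2fc=True)
        )
        assert [g.gene_id for g in flipped_up] == ["g1"]

    def test_all_genes_failing_binding_gives_empty_list(self):
        genes, peaks, de = self._toy()
        cfg = ig.IntegrationConfig(binding_cutoff=10.0)
        assert ig.integrate_and_rank(de, peaks, genes, cfg) == []

    def test_unknown_de_genes_skipped(self, caplog):
        genes, peaks, de = self._toy()
        de.append(make_de("not_in_annotation", 5.0, 1e-9))
        with caplog.at_level("WARNING"):
            ranked = ig.integrate_and_rank(de, peaks, genes)
        assert all(g.gene_id != "not_in_annotation" for g in ranked)

    def test_tightening_filters_never_adds_genes(self):
        genes, peaks, de = self._toy()
        base = {g.gene_id for g in ig.integrate_and_rank(de, peaks, genes)}
        for cfg in [
            ig.IntegrationConfig(binding_cutoff=1.2),
            ig.IntegrationConfig(de_padj_cutoff=0.001),
        ]:
            tightened = {g.gene_id for g in ig.integrate_and_rank(de, peaks, genes, cfg)}
            assert tightened <= base

    def test_deterministic_tie_breaking(self):
        genes = [make_gene("b", start=0, end=1000), make_gene("a", start=100_000, end=101_000)]
        peaks = [
            make_peak("p1", start=100, end=300, log2_ratio=1.0),
            make_peak("p2", start=100_100, end=100_300, log2_ratio=1.0),
        ]
        de = [make_de("b", 2.0, 1e-4), make_de("a", 2.0, 1e-4)]
        ranked = ig.integrate_and_rank(de, peaks, genes)
        assert [g.gene_id for g in ranked] == ["a", "b"]  # gene_id ascending on full tie

    def test_identical_inputs_give_identical_output(self):
        exp = simulate_experiment(SimulationConfig(seed=3))
        r1 = ig.integrate_and_rank(exp.de_table, exp.peaks, exp.genes)
        r2 = ig.integrate_and_rank(list(exp.de_table), list(exp.peaks), list(exp.genes))
        assert r1 == r2

    def test_planted_targets_occupy_top_ranks(self):
        exp = simulate_experiment(SimulationConfig(seed=1))
        ranked = ig.integrate_and_rank(exp.de_table, exp.peaks, exp.genes)
        top5 = {g.gene_id for g in ranked[:5]}
        assert top5 == set(exp.true_targets)


class TestOverlapCounts:
    def test_identical_tables_put_everything_in_the_intersection(self):
        table = [make_de("A", 2.0, None), make_de("B", 0.5, None), make_de("C", -1.5, None)]
        res = ig.overlap_counts({"t1": table, "t2": table}, ["A", "B", "C"])
        assert res.count("t1", "t2") == 2  # A and C pass 2-fold; B does not
        assert res.count("t1") == 0 and res.count("t2") == 0
        assert res.totals == {"t1": 2, "t2": 2}

    def test_disjoint_qualifying_sets(self):
        t1 = [make_de("A", 2.0, None), make_de("B", 0.1, None)]
        t2 = [make_de("A", 0.1, None), make_de("B", -2.0, None)]
        res = ig.overlap_counts({"t1": t1, "t2": t2}, ["A", "B"])
        assert res.count("t1", "t2") == 0
        assert res.count("t1") == 1 and res.count("t2") == 1

    def test_single_gene_consistent_across_four_lines(self):
        # mirrors the published four-cell-line comparison where exactly one
        # gene (HMOX1) clears the 2-fold cutoff in every table
        gene_list = [f"G{i}" for i in range(29)] + ["HMOX1"]
        tables = {}
        for t in range(4):
            rows = [make_de("HMOX1", 3.0, None)]
            for i in range(29):
                # each other gene clears the cutoff in at most one table
                lfc = 2.5 if i % 4 == t and i < 12 else 0.2
                rows.append(make_de(f"G{i}", lfc, None))
            tables[f"line{t}"] = rows
        res = ig.overlap_counts(tables, gene_list, fold_cutoff=2.0)
        assert res.count("line0", "line1", "line2", "line3") == 1

    def test_cutoff_is_inclusive_on_the_linear_scale(self):
        table = [make_de("A", 1.0, None)]  # exactly 2-fold
        res = ig.overlap_counts({"t1": table, "t2": table}, ["A"], fold_cutoff=2.0)
        assert res.totals["t1"] == 1

    def test_fewer_than_two_tables_rejected(self):
        with pytest.raises(ValueError):
            ig.overlap_counts({"t1": []}, [])
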
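import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pausescape import annotation as ann
from pausescape import pausing, tags

from conftest import brute_count_antisense, brute_count_overlap, make_library


class TestPausingIndex:
    def test_density_ratio(self):
        # 100/500 bp vs 50/5000 bp: 200 vs 10 per kb
        assert pausing.pausing_index(100, 50, 500, 5000) == 20.0

    def test_empty_body_infinite(self):
        assert math.isinf(pausing.pausing_index(10, 0, 500, 5000))

    def test_empty_tss_zero(self):
        assert pausing.pausing_index(0, 100, 500, 5000) == 0.0

    def test_no_signal_undefined(self):
        assert math.isnan(pausing.pausing_index(0, 0, 500, 5000))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pausing.pausing_index(-1, 0, 500, 5000)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 500), st.integers(1, 500), st.integers(1, 20))
    def test_scale_invariance(self, tss, body, k):
        pi1 = pausing.pausing_index(tss, body, 500, 4000)
        pi2 = pausing.pausing_index(tss * k, body * k, 500, 4000)
        assert pi2 == pytest.approx(pi1)


class TestGrouping:
    @pytest.mark.parametrize("pi,active,group", [
        (3.0, True, 1),   # boundary inclusive
        (2.9, True, 2),
        (1.5, True, 2),
        (1.49, True, 3),
        (50.0, False, 3),  # inactive TSS overrides PI
        (math.inf, True, 1),
        (math.nan, True, 3),
    ])
    def test_boundaries(self, pi, active, group):
        assert pausing.classify_pausing(pi, active) == group

    def test_bad_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            pausing.classify_pausing(2.0, True, high=1.0, moderate=1.5)


class TestPausingTable:
    def _random_fixture(self, seed, n_genes=10):
        rng = np.random.default_rng(seed)
        genes, cursor = [], 10_000
        for i in range(n_genes):
            length = int(rng.integers(1_500, 6_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(ann.GeneModel(f"g{i}", f"t{i}", "chr1", strand,
                                       cursor, cursor + length))
            cursor += length + int(rng.integers(5_000, 10_000))
        regions = [ann.define_regions(g) for g in genes]
        pos = rng.integers(0, cursor, 3_000)
        strands = np.where(rng.random(3_000) < 0.5, "+", "-")
        chip = make_library(
            [("chr1", int(p), int(p) + 150, s) for p, s in zip(pos, strands)],
            state="extended",
        )
        pro = make_library(
            [("chr1", int(p), int(p) + 1, s) for p, s in zip(pos, strands)],
            assay="proseq", state="reduced",
        )
        return regions, chip, pro

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_brute_force_recount(self, seed):
        regions, chip, pro = self._random_fixture(seed)
        for lib, brute in ((chip, brute_count_overlap), (pro, None)):
            records = pausing.pausing_table(lib, regions, threshold=5)
            for r, rec in zip(regions, records):
                if lib.assay == "chip":
                    tc = brute_count_overlap(lib, "chr1", *r.tss_window)
                    bc = brute_count_overlap(lib, "chr1", *r.body)
                else:
                    tc = brute_count_antisense(lib, "chr1", *r.tss_window,
                                               r.gene.strand)
                    bc = brute_count_antisense(lib, "chr1", *r.body, r.gene.strand)
                assert (rec.tss_count, rec.body_count) == (tc, bc)
                expect_pi = pausing.pausing_index(tc, bc, r.tss_len, r.body_len)
                assert rec.pi == expect_pi or (
                    math.isnan(rec.pi) and math.isnan(expect_pi)
                )
                assert rec.tss_active == (tc > 5)
                assert rec.group == pausing.classify_pausing(rec.pi, rec.tss_active)

    def test_all_zero_library_all_group3(self):
        regions, _, _ = self._random_fixture(0)
        records = pausing.pausing_table(make_library([], state="extended"),
                                        regions, threshold=5)
        assert all(r.group == 3 for r in records)


class TestDistributionComparison:
    def test_identical_vectors(self):
        out = pausing.compare_pi_distributions(np.arange(10.0), np.arange(10.0))
        assert out["statistic"] == 0.0 and out["pvalue"] == 1.0

    def test_disjoint_supports(self):
        out = pausing.compare_pi_distributions([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert out["statistic"] == 1.0

    def test_infinite_pi_capped_not_dropped(self):
        out = pausing.compare_pi_distributions(
            [1.0, 2.0, np.inf], [1.0, 2.0, 2.0]
        )
        assert np.isfinite(out["statistic"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pausing.compare_pi_distributions([], [1.0, 2.0])


class TestBoxedSignal:
    def _matrix(self):
        values = np.zeros((6, 300))
        values[:3, 95:105] = 10.0  # strong TSS signal
        values[3:, 95:105] = 1.0
        return tags.SignalMatrix([f"g{i}" for i in range(6)], values, 10, 1000, 2000)

    def test_box_covers_expected_bins(self):
        m = self._matrix()
        _, per_gene = pausing.boxed_signal_test(
            m, {"hi": ["g0", "g1", "g2"], "lo": ["g3", "g4", "g5"]}, (-250, 250)
        )
        # 50 bins summed; signal bins all inside the box
        assert per_gene["g0"] == 100.0 and per_gene["g3"] == 10.0

    def test_mwu_matches_reference(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        values = rng.poisson(5.0, size=(40, 300)).astype(float)
        m = tags.SignalMatrix([f"g{i}" for i in range(40)], values, 10, 1000, 2000)
        groups = {"a": [f"g{i}" for i in range(20)],
                  "b": [f"g{i}" for i in range(20, 40)]}
        table, per_gene = pausing.boxed_signal_test(m, groups, (-150, 50))
        xa = per_gene[groups["a"]].to_numpy()
        xb = per_gene[groups["b"]].to_numpy()
        ref = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        assert abs(table["pvalue"][0] - ref.pvalue) < 1e-12

    def test_box_outside_window_rejected(self):
        with pytest.raises(ValueError):
            pausing.boxed_signal_test(self._matrix(), {"a": ["g0"], "b": ["g1"]},
                                      (-2000, 0))


class TestGroupSummary:
    def _records(self):
        mk = lambda s, g: pausing.PausingRecord(s, 10, 10, 500, 1000, 1.0, True,
                                                g, "chip")
        return [mk("g1a", 1), mk("g1b", 1), mk("g2", 2), mk("g3", 3)]

    def test_conditional_directions(self):
        out = pausing.summarize_groups(self._records(),
                                       {"lab": {"g1a", "g1b", "g2"}})
        lab = out["labels"]["lab"]
        assert lab["p_label_given_group"][1] == 1.0
        assert lab["p_group_given_label"][1] == pytest.approx(2 / 3)

    def test_empty_label(self):
        out = pausing.summarize_groups(self._records(), {"none": set()})
        assert all(v == 0.0 for v in out["labels"]["none"]["p_group_given_label"].values())

    def test_label_of_all_genes(self):
        out = pausing.summarize_groups(
            self._records(), {"all": {"g1a", "g1b", "g2", "g3"}}
        )
        assert all(v == 1.0 for v in out["labels"]["all"]["p_label_given_group"].values())

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            pausing.summarize_groups(self._records(), {"x": {"nope"}})

    def test_fractions_sum_to_one(self):
        out = pausing.summarize_groups(self._records(), {})
        assert sum(out["fractions"].values()) == pytest.approx(1.0)
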
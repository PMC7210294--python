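import numpy as np
import pytest
from scipy import stats as sps

from pausescape import annotation as ann
from pausescape import enrichment, tags
from pausescape.synthetic import generate_null_background

from conftest import make_library


class TestBackground:
    def test_lambda_closed_form(self):
        layout = ann.GenomeLayout({"chr1": 100_000_000})
        # 1-bp tags: the plain total * window / genome rate
        lib = make_library([("chr1", 0, 1, "+")], total=1_000_000)
        m = enrichment.fit_background(lib, layout, 500)
        assert m.lam == 5.0
        assert m.n_windows == 100_000_000 // 250
        # wider tags widen the overlap corridor by width - 1
        lib36 = make_library([("chr1", 0, 36, "+")], total=1_000_000)
        assert enrichment.fit_background(lib36, layout, 500).lam == 5.35

    def test_zero_depth_rejected(self):
        lib = make_library([], total=0)
        with pytest.raises(ValueError):
            enrichment.fit_background(lib, ann.GenomeLayout({"chr1": 1000}), 500)

    def test_window_exceeding_genome_rejected(self):
        lib = make_library([("chr1", 0, 36, "+")], total=10)
        with pytest.raises(ValueError):
            enrichment.fit_background(lib, ann.GenomeLayout({"chr1": 400}), 500)


def _spiked_counts(rng, lam, n_null, n_spike, spike):
    return np.concatenate([rng.poisson(lam, n_null), np.full(n_spike, spike)])


class TestFdrThreshold:
    def test_spiked_threshold_against_brute_scan(self):
        rng = np.random.default_rng(0)
        obs = _spiked_counts(rng, 5.0, 200_000, 100, 40)
        model = enrichment.BackgroundModel(5.0, 500, obs.size, 0)
        thr = enrichment.fdr_threshold(model, obs, 0.001)
        # independent brute-force scan over integer cutoffs
        expected = None
        for c in range(1, int(obs.max()) + 1):
            est = obs.size * sps.poisson.sf(c - 1, 5.0) / max(1, int((obs >= c).sum()))
            if est < 0.001:
                expected = c
                break
        assert thr.threshold == expected
        assert thr.threshold <= 40

    def test_threshold_bracketing_invariant(self):
        rng = np.random.default_rng(1)
        obs = _spiked_counts(rng, 3.0, 50_000, 50, 30)
        model = enrichment.BackgroundModel(3.0, 500, obs.size, 0)
        thr = enrichment.fdr_threshold(model, obs, 0.001)
        curve = enrichment.estimated_fdr_curve(model, obs)
        assert curve[thr.threshold - 1] < 0.001
        if thr.threshold > 1:
            assert curve[thr.threshold - 2] >= 0.001

    def test_monotone_in_lambda_and_fdr(self):
        rng = np.random.default_rng(2)
        obs = _spiked_counts(rng, 8.0, 100_000, 200, 60)
        thresholds = []
        for lam in (2.0, 4.0, 8.0):
            m = enrichment.BackgroundModel(lam, 500, obs.size, 0)
            thresholds.append(enrichment.fdr_threshold(m, obs, 0.001).threshold)
        assert thresholds == sorted(thresholds)
        m = enrichment.BackgroundModel(8.0, 500, obs.size, 0)
        by_fdr = [enrichment.fdr_threshold(m, obs, f).threshold
                  for f in (0.1, 0.01, 0.001)]
        assert by_fdr == sorted(by_fdr)

    def test_pure_null_raises_or_calls_almost_nothing(self):
        rng = np.random.default_rng(3)
        obs = rng.poisson(5.0, 100_000)
        model = enrichment.BackgroundModel(5.0, 500, obs.size, 0)
        try:
            thr = enrichment.fdr_threshold(model, obs, 0.001)
            assert (obs >= thr.threshold).sum() / obs.size <= 0.002
        except enrichment.NoEnrichmentError:
            pass

    def test_degenerate_fdr_one(self):
        model = enrichment.BackgroundModel(5.0, 500, 100, 0)
        thr = enrichment.fdr_threshold(model, np.array([0, 1, 2]), 1.0)
        assert thr.threshold == 1


class TestActiveTss:
    def test_strictly_greater_than_threshold(self):
        model = enrichment.BackgroundModel(5.0, 500, 100, 0)
        thr = enrichment.EnrichmentThreshold(38, 0.001, model, 0.0)
        flags = enrichment.classify_active_tss([0, 38, 39, 100], thr)
        assert flags.tolist() == [False, False, True, True]


class TestPeakCalling:
    def _planted(self, rng, sites, per_site=60, n_bg=8000, length=2_000_000):
        """Library with uniform background plus stacks of reads at sites."""
        recs = []
        for p in rng.integers(0, length, n_bg):
            recs.append(("chr1", int(p), int(p) + 36, "+"))
        for s in sites:
            for _ in range(per_site):
                recs.append(("chr1", s - 18, s + 18, "+"))
        lib = make_library(recs)
        return tags.extend_chip_tags(lib, 150)

    def test_planted_site_recovery(self):
        rng = np.random.default_rng(4)
        layout = ann.GenomeLayout({"chr1": 2_000_000})
        sites = list(range(100_000, 1_100_000, 100_000))  # 10 well-spaced sites
        lib = self._planted(rng, sites)
        peaks = enrichment.call_peaks(lib, layout)
        assert len(peaks) == 10
        for p, s in zip(peaks, sites):
            assert p.start <= s < p.end
            assert abs(p.summit - s) <= 80

    def test_self_background_yields_nothing(self):
        rng = np.random.default_rng(5)
        layout = ann.GenomeLayout({"chr1": 2_000_000})
        lib = self._planted(rng, [500_000])
        assert enrichment.call_peaks(lib, layout, background=lib) == []

    def test_fdr_one_merges_everything_nonzero(self):
        layout = ann.GenomeLayout({"chr1": 10_000})
        lib = tags.extend_chip_tags(make_library([("chr1", 5_000, 5_036, "+")]), 150)
        peaks = enrichment.call_peaks(lib, layout, fdr=1.0)
        assert len(peaks) == 1 and peaks[0].count == 1

    def test_zero_depth_background_rejected(self):
        layout = ann.GenomeLayout({"chr1": 10_000})
        lib = tags.extend_chip_tags(make_library([("chr1", 0, 36, "+")]), 150)
        empty = make_library([], state="extended")
        with pytest.raises(ValueError):
            enrichment.call_peaks(lib, layout, background=empty)


class TestAnnotation:
    def _regions(self):
        genes = [
            ann.GeneModel("A", "t1", "chr1", "+", 10_000, 20_000),
            ann.GeneModel("B", "t2", "chr1", "+", 50_000, 60_000),
        ]
        return [ann.define_regions(g) for g in genes]

    def _peak(self, summit):
        return enrichment.Peak("chr1", summit - 100, summit + 100, 10, 1.0, summit)

    def test_category_precedence_and_fractions(self):
        regions = self._regions()
        # 7 tss / 2 body / 1 intergenic planted summits
        peaks = (
            [self._peak(10_000 + i) for i in range(7)]
            + [self._peak(15_000), self._peak(55_000)]
            + [self._peak(30_000)]
        )
        summary = enrichment.annotate_peaks(peaks, regions)
        assert summary == {"tss": 0.7, "gene_body": 0.2, "intergenic": 0.1}
        assert peaks[0].annotation == "tss" and peaks[0].nearest_gene == "A"

    def test_tss_of_one_gene_beats_body_of_another(self):
        genes = [
            ann.GeneModel("A", "t1", "chr1", "+", 10_000, 20_000),
            ann.GeneModel("B", "t2", "chr1", "+", 19_900, 30_000),
        ]
        regions = [ann.define_regions(g) for g in genes]
        peak = self._peak(19_900)  # inside A's body and B's TSS window
        enrichment.annotate_peaks([peak], regions)
        assert peak.annotation == "tss" and peak.nearest_gene == "B"


class TestNullCalibration:
    def test_window_call_rate_bounded_on_null(self):
        """Uniform background: the fraction of windows called at nominal FDR
        0.001 stays within twice the nominal rate (quick 5-seed version; the
        full 20-seed run lives in the acceptance suite)."""
        layout = ann.GenomeLayout({"chrN": 25_000_000})
        rates = []
        for seed in range(5):
            lib = generate_null_background(250_000, 25_000_000, seed)
            lib = tags.extend_chip_tags(lib, 150)
            model = enrichment.fit_background(lib, layout, 500)
            _, _, counts = enrichment.window_counts(lib, layout, 500)
            try:
                thr = enrichment.fdr_threshold(model, counts, 0.001)
                rates.append((counts >= thr.threshold).sum() / counts.size)
            except enrichment.NoEnrichmentError:
                rates.append(0.0)
        assert np.mean(rates) <= 0.002
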
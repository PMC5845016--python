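"""PRR window signals, filters, differential release, metagene profiles."""

import numpy as np
import pandas as pd
import pytest

from uvphos import (
    CoverageTrack,
    GeneModel,
    WindowSpec,
    compute_prr,
    compute_window_signal,
    differential_prr,
    metagene_profile,
)


def track_from(arrays, condition="mock", replicate=1):
    return CoverageTrack(condition=condition, replicate=replicate,
                         coverage={k: np.asarray(v, float) for k, v in arrays.items()})


def flat_track(size=30_000, value=2.0, **kw):
    return track_from({"chr1": np.full(size, value)}, **kw)


class TestWindowSignal:
    def test_uniform_coverage_window_independent(self):
        t = flat_track()
        g = GeneModel("g1", "chr1", "+", tss=10_000, tes=25_000)
        s1 = compute_window_signal(t, g, (-300, 1000))
        s2 = compute_window_signal(t, g, (1000, 3000))
        assert s1 == pytest.approx(s2)

    def test_strand_symmetry(self):
        size = 30_000
        arr = np.zeros(size)
        arr[10_100:10_300] = 7.0  # bump at +100..+300 relative to a TSS at 10k
        plus = track_from({"chr1": arr})
        gp = GeneModel("gp", "chr1", "+", tss=10_000, tes=20_000)
        # mirrored construction for a minus-strand gene with TSS at 19_999
        arr_m = np.zeros(size)
        arr_m[19_700:19_900] = 7.0  # +100..+300 in transcription direction
        minus = track_from({"chr1": arr_m})
        gm = GeneModel.from_interval("gm", "chr1", 10_000, 20_000, "-")
        for window in [(-300, 1000), (1000, 3000), (0, 500)]:
            assert compute_window_signal(plus, gp, window) == pytest.approx(
                compute_window_signal(minus, gm, window)
            )

    def test_depth_invariance(self):
        g = GeneModel("g1", "chr1", "+", tss=10_000, tes=25_000)
        rng = np.random.default_rng(0)
        arr = rng.poisson(3.0, size=30_000).astype(float)
        t1 = track_from({"chr1": arr})
        t2 = track_from({"chr1": 2.0 * arr})
        assert compute_window_signal(t1, g, (-300, 1000)) == pytest.approx(
            compute_window_signal(t2, g, (-300, 1000))
        )

    def test_off_chromosome_truncation(self):
        t = flat_track(size=5_000)
        g = GeneModel("g1", "chr1", "+", tss=100, tes=4_000)
        with pytest.warns(UserWarning, match="truncated"):
            s = compute_window_signal(t, g, (-300, 1000))
        assert np.isfinite(s)


class TestComputePRR:
    def test_flat_gene_prr_zero(self):
        tracks = {"mock": [flat_track()]}
        g = GeneModel("g1", "chr1", "+", tss=10_000, tes=25_000)
        table = compute_prr(tracks, [g])
        assert table.loc["g1", "prr:mock"] == pytest.approx(0.0, abs=1e-12)

    def test_double_downstream_prr_one(self):
        arr = np.zeros(40_000)
        arr[9_700:11_000] = 4.0  # TSS window
        arr[11_000:13_000] = 8.0  # downstream window, exactly 2x
        g = GeneModel("g1", "chr1", "+", tss=10_000, tes=25_000)
        table = compute_prr({"mock": [track_from({"chr1": arr})]}, [g])
        assert table.loc["g1", "prr:mock"] == pytest.approx(1.0, abs=1e-4)

    def test_short_gene_ineligible(self):
        tracks = {"mock": [flat_track()]}
        g_short = GeneModel("short", "chr1", "+", tss=10_000, tes=12_500)
        g_ok = GeneModel("ok", "chr1", "+", tss=14_000, tes=24_000)
        table = compute_prr(tracks, [g_short, g_ok])
        assert not table.loc["short", "eligible"]
        assert np.isnan(table.loc["short", "prr:mock"])
        assert table.loc["ok", "eligible"]

    def test_tss_signal_filter_monotone(self, coverage_sim):
        _, genes, tracks, _ = coverage_sim
        lo = compute_prr(tracks, genes, WindowSpec(tss_min_signal=1.0), "mock")
        hi = compute_prr(tracks, genes, WindowSpec(tss_min_signal=50.0), "mock")
        assert hi["eligible"].sum() <= lo["eligible"].sum()
        assert (hi["eligible"] <= lo["eligible"]).all()

    def test_no_eligible_genes_raises(self):
        tracks = {"mock": [flat_track(value=0.0)]}
        g = GeneModel("g1", "chr1", "+", tss=10_000, tes=25_000)
        with pytest.raises(ValueError, match="eligible"):
            compute_prr(tracks, [g])


class TestDifferentialPRR:
    def test_identical_tracks_null(self):
        t = flat_track()
        g1 = GeneModel("g1", "chr1", "+", tss=5_000, tes=15_000)
        g2 = GeneModel("g2", "chr1", "+", tss=16_000, tes=28_000)
        tracks = {"mock": [t, t], "UV": [t, t]}
        table = compute_prr(tracks, [g1, g2])
        table, global_test = differential_prr(table, "mock", "UV")
        np.testing.assert_allclose(table["delta_prr"], 0.0, atol=1e-12)
        assert (table["p_delta"] == 1.0).all()
        assert global_test.p_value == pytest.approx(1.0)

    def test_replicate_mismatch_rejected(self):
        t = flat_track()
        g = GeneModel("g1", "chr1", "+", tss=5_000, tes=15_000)
        table = compute_prr({"mock": [t, t], "UV": [t]}, [g])
        with pytest.raises(ValueError, match="replicate"):
            differential_prr(table, "mock", "UV")

    def test_planted_shift_recovery(self, prr_results):
        table, global_test, truth = prr_results
        joined = table.join(truth.drop(columns=["length"]))
        eligible = joined[joined["eligible"]]
        released = eligible[eligible["released"]]
        still = eligible[~eligible["released"]]
        assert abs(released["delta_prr"].mean() - 1.0) < 0.1
        assert abs(still["delta_prr"].mean()) < 0.05
        assert global_test.p_value < 0.01
        n_up = (eligible["prr_call"] == "up").sum()
        n_down = (eligible["prr_call"] == "down").sum()
        assert n_up > 10 * max(n_down, 1)

    def test_delta_estimator_unbiased(self, prr_results):
        table, _, truth = prr_results
        joined = table.join(truth.drop(columns=["length"]))
        eligible = joined[joined["eligible"]]
        resid = eligible["delta_prr"] - eligible["delta_prr_planted"]
        se = resid.std() / np.sqrt(len(resid))
        assert abs(resid.mean()) < 4 * se + 0.02


class TestMetagene:
    def test_delta_bump_peaks_at_center(self):
        size = 30_000
        genes = [
            GeneModel("g1", "chr1", "+", tss=10_000, tes=20_000),
            GeneModel("g2", "chr1", "+", tss=22_000, tes=28_000),
        ]
        arr = np.zeros(size)
        for g in genes:
            arr[g.tss] = 100.0
        prof = metagene_profile([track_from({"chr1": arr})], genes, span=2000, bins=100)
        assert abs(prof["signal"].idxmax()) <= 20  # central bin

    def test_uniform_coverage_flat_profile(self):
        genes = [GeneModel("g1", "chr1", "+", tss=10_000, tes=20_000)]
        prof = metagene_profile([flat_track()], genes)
        assert prof["signal"].std() == pytest.approx(0.0, abs=1e-9)

    def test_strand_mixing_invariance(self):
        size = 40_000
        arr = np.zeros(size)
        g_plus = GeneModel("gp", "chr1", "+", tss=10_000, tes=20_000)
        g_minus = GeneModel.from_interval("gm", "chr1", 25_000, 35_000, "-")
        # identical bump at +50..+150 downstream of each TSS (oriented)
        arr[10_050:10_150] = 9.0
        arr[g_minus.tss - 149 : g_minus.tss - 49] = 9.0
        t = track_from({"chr1": arr})
        p_plus = metagene_profile([t], [g_plus])
        p_mix = metagene_profile([t], [g_plus, g_minus])
        np.testing.assert_allclose(p_mix["signal"], p_plus["signal"], atol=1e-9)
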
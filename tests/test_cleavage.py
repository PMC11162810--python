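import numpy as np
import pytest

from dusmap.cleavage import (CleavageProfile, call_sites, dose_response,
                             heatmap_matrix, normcount,
                             panel_attribution_from_seq, read_count_table,
                             stop_ratio)
from dusmap.trna import TRNAError

from conftest import make_trna


def profile(counts, coverage=1000, **kw):
    counts = np.asarray(counts)
    return CleavageProfile("t", counts, np.full(len(counts), coverage), **kw)


class TestNormcount:
    def test_flat_profile_scores_one(self):
        p = profile([7] * 30)
        for i in range(5, 25):
            assert normcount(p, i) == 1.0

    def test_spike_over_background(self):
        # 40 cleavages attributed to the residue, flanks at 2 -> score 20
        counts = np.full(21, 2)
        counts[11] = 40   # read start at 11 reports residue 10
        assert normcount(profile(counts), 10) == 20.0

    def test_zero_background_floor(self):
        counts = np.zeros(21, dtype=int)
        counts[11] = 7
        assert normcount(profile(counts), 10) == 7.0

    def test_scale_invariance(self):
        counts = np.full(21, 3)
        counts[11] = 60
        base = normcount(profile(counts), 10)
        for k in (2, 5, 10):
            assert normcount(profile(counts * k), 10) == pytest.approx(base)

    def test_truncated_window_at_ends(self):
        counts = np.full(8, 2)
        counts[1] = 30
        assert normcount(profile(counts), 0) == 15.0

    def test_short_profile_rejected(self):
        with pytest.raises(TRNAError, match="too short"):
            normcount(profile([1, 2]), 0)


class TestStopRatio:
    def test_fraction_of_coverage(self):
        counts = np.zeros(21, dtype=int)
        counts[11] = 30
        p = CleavageProfile("t", counts, np.full(21, 100))
        assert stop_ratio(p, 10) == pytest.approx(0.30)

    def test_bounds(self):
        counts = np.zeros(10, dtype=int)
        p = CleavageProfile("t", counts, np.full(10, 100))
        assert stop_ratio(p, 3) == 0.0
        counts[5] = 100
        p = CleavageProfile("t", counts, np.full(10, 100))
        assert stop_ratio(p, 4) == 1.0

    def test_zero_coverage_is_undetected_not_zero(self):
        counts = np.zeros(10, dtype=int)
        cov = np.full(10, 100)
        cov[6] = 0
        p = CleavageProfile("t", counts, cov)
        assert stop_ratio(p, 5) is None
        assert stop_ratio(p, 4) == 0.0

    def test_counts_cannot_exceed_coverage(self):
        with pytest.raises(TRNAError, match="exceed"):
            CleavageProfile("t", np.array([5, 5]), np.array([4, 10]))


class TestCallSites:
    def _spiked(self, seq, spike_at, factor=20, background=2):
        counts = np.full(len(seq), background)
        counts[spike_at + 1] = background * factor
        return profile(counts)

    def test_single_spiked_u_called(self):
        t = make_trna("t", "ACGU" * 6)
        calls = call_sites(self._spiked(t.sequence, 11), t, score_threshold=5.0)
        assert [str(c.site) for c in calls.d_sites] == ["12"]
        assert calls.d_sites[0].substoichiometric  # stop_ratio 0.04 < 1
        assert calls.other_sites == []

    def test_flat_profile_calls_nothing(self):
        t = make_trna("t", "ACGU" * 6)
        calls = call_sites(profile([3] * 24), t, score_threshold=5.0)
        assert calls.d_sites == [] and calls.other_sites == []

    def test_spike_at_g_goes_to_codetection_channel(self):
        # strong signal at a guanosine (the m7G-type interference) is
        # reported separately, never as a D call
        t = make_trna("t", "ACGU" * 6)
        calls = call_sites(self._spiked(t.sequence, 10), t, score_threshold=5.0)
        assert calls.d_sites == []
        assert [str(c.site) for c in calls.other_sites] == ["11"]
        assert calls.other_sites[0].base == "G"

    def test_threshold_must_exceed_background(self):
        with pytest.raises(TRNAError, match="threshold"):
            call_sites(profile([2] * 24), score_threshold=1.0)


class TestHeatmap:
    def _prof(self, sample, rep, ratio):
        counts = np.zeros(21, dtype=int)
        counts[11] = int(ratio * 1000)
        return CleavageProfile("t", counts, np.full(21, 1000),
                               sample=sample, replicate=rep)

    def test_mean_over_replicates(self):
        profs = [self._prof("WT", r + 1, x)
                 for r, x in enumerate([0.30, 0.32, 0.28])]
        mat = heatmap_matrix(profs, {"t": [10]})
        assert mat.loc["t:10", "WT"] == pytest.approx(0.30)

    def test_absent_site_zero_not_nan(self):
        profs = [self._prof("WT", 1, 0.4), self._prof("dB1dB2", 1, 0.0)]
        mat = heatmap_matrix(profs, {"t": [10]})
        assert mat.loc["t:10", "dB1dB2"] == 0.0

    def test_missing_sample_stays_nan(self):
        profs = [self._prof("WT", 1, 0.4)]
        mat = heatmap_matrix(profs, {"t": [10], "u": [5]})
        assert np.isnan(mat.loc["u:5", "WT"])

    def test_inconsistent_lengths_rejected(self):
        a = CleavageProfile("t", np.zeros(10, int), np.full(10, 10), sample="WT")
        b = CleavageProfile("t", np.zeros(12, int), np.full(12, 10), sample="WT")
        with pytest.raises(TRNAError, match="inconsistent"):
            heatmap_matrix([a, b], {"t": [3]})


class TestDoseResponse:
    def _series(self, ratios):
        out = []
        for x in ratios:
            counts = np.full(21, 2)
            counts[11] = 2 + int(x * 1000)
            out.append(profile(counts))
        return out

    def test_rising_series_monotone(self):
        profs = self._series([0.0, 0.2, 0.4, 0.8])
        dr = dose_response(profs, [0.1, 1.0, 5.0, 25.0], 10)
        assert dr.monotone and not dr.flat
        assert dr.scores == sorted(dr.scores)

    def test_constant_series_flat(self):
        profs = self._series([0.3, 0.3, 0.3])
        dr = dose_response(profs, [1.0, 5.0, 25.0], 10)
        assert dr.monotone and dr.flat

    def test_shuffled_series_not_monotone(self):
        profs = self._series([0.4, 0.1, 0.8, 0.2])
        dr = dose_response(profs, [0.1, 1.0, 5.0, 25.0], 10)
        assert not dr.monotone

    def test_needs_three_points(self):
        with pytest.raises(TRNAError, match="3"):
            dose_response(self._series([0.1, 0.2]), [1.0, 2.0], 10)


class TestSeqPanelAttribution:
    def test_b1_only_pattern(self):
        panel = panel_attribution_from_seq(
            {"WT": 0.4, "dB1": 0.0, "dB2": 0.4, "dB1dB2": 0.0})
        assert panel.attribution == "B1_only"

    def test_redundant_b2_preferred_pattern(self):
        panel = panel_attribution_from_seq(
            {"WT": 0.5, "dB1": 0.45, "dB2": 0.15, "dB1dB2": 0.0})
        assert panel.attribution == "redundant_B2_preferred"

    def test_all_zero_none(self):
        panel = panel_attribution_from_seq(
            {s: 0.0 for s in ("WT", "dB1", "dB2", "dB1dB2")})
        assert panel.attribution == "none"

    def test_undetected_column_allowed(self):
        panel = panel_attribution_from_seq(
            {"WT": 0.4, "dB1": None, "dB2": 0.4, "dB1dB2": 0.0})
        assert panel.attribution == "inconsistent"


def test_read_count_table_round_trip(tmp_path):
    path = tmp_path / "counts.tsv"
    lines = ["trna_id\tposition_index\tread_start_count\tcoverage"]
    lines += [f"t\t{i}\t{c}\t100" for i, c in enumerate([1, 2, 40, 2, 1])]
    path.write_text("\n".join(lines) + "\n")
    (p,) = read_count_table(path, sample="WT")
    assert p.sample == "WT"
    assert list(p.counts) == [1, 2, 40, 2, 1]
    assert stop_ratio(p, 1) == pytest.approx(0.40)
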
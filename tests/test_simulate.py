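import numpy as np
import pytest

from dusmap.cleavage import call_sites, dose_response, normcount, stop_ratio
from dusmap.maldi import STRAINS, attribute_panel, select_diagnostics
from dusmap.simulate import (EnzymeSpecificityMap, NoiseConfig, ZERO_NOISE,
                             gen_cleavage_profiles, gen_kinetics,
                             gen_maldi_panel, gen_maldi_strain_panels,
                             gen_trna_set)


def run_panel(trnas, truth, noise, rng_seed=0):
    """Digest, diagnose, simulate spectra, attribute; count matches to truth."""
    rng = np.random.default_rng(rng_seed)
    correct = total = 0
    for t in trnas:
        sites = [r.label for r in t.residues if r.modification == "D"]
        diags, _ = select_diagnostics(t, "RNaseT1", sites)
        pls = {g: gen_maldi_panel(t, truth, g, noise, rng=rng) for g in STRAINS}
        for p in attribute_panel(pls, diags):
            total += 1
            correct += (p.attribution == truth.expected_attribution(t.id, p.site))
    return correct, total


class TestTRNAGeneration:
    def test_sites_are_u_with_truth_attached(self):
        trnas, truth = gen_trna_set(3, seed=5)
        for t in trnas:
            sites = truth.sites(t.id)
            assert sites
            for label in sites:
                r = t.residues[t.label_to_index(label)]
                assert r.base == "U" and r.modification == "D"

    def test_same_seed_same_output(self):
        a, truth_a = gen_trna_set(4, seed=11)
        b, truth_b = gen_trna_set(4, seed=11)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        assert dict(truth_a.items()) == dict(truth_b.items())
        c, _ = gen_trna_set(4, seed=12)
        assert [t.sequence for t in a] != [t.sequence for t in c]

    def test_requested_profile_respected(self):
        profile = {"17": {"B1": 0.9}, "20": {"B1": 0.5, "B2": 0.8}}
        trnas, truth = gen_trna_set(1, seed=1, site_profile=profile)
        sites = truth.sites(trnas[0].id)
        assert set(sites) == {"17", "20"}
        assert sites["20"] == {"B1": 0.5, "B2": 0.8}

    def test_adjacent_cluster_one_site_per_trna(self):
        profile = {"20": {"B1": 0.5}, "20a": {"B2": 0.5}}
        trnas, truth = gen_trna_set(30, seed=2, site_profile=profile)
        picks = [set(truth.sites(t.id)) for t in trnas]
        assert all(len(p) == 1 for p in picks)
        assert {frozenset(p) for p in picks} == {frozenset({"20"}),
                                                 frozenset({"20a"})}

    def test_site_efficiencies_in_substoichiometric_range(self):
        _, truth = gen_trna_set(20, seed=3)
        effs = [v for (_, _), m in truth.items() for v in m.values()]
        assert all(0.3 <= e <= 0.9 for e in effs)


class TestSpecificityMap:
    def _map(self):
        m = EnzymeSpecificityMap()
        m.add("t", "17", {"B1": 0.6})
        m.add("t", "20", {"B1": 0.5, "B2": 0.8})
        return m

    def test_stoichiometry_combines_independently(self):
        m = self._map()
        assert m.stoichiometry("t", "20", "WT") == pytest.approx(1 - 0.5 * 0.2)
        assert m.stoichiometry("t", "20", "dB1") == pytest.approx(0.8)
        assert m.stoichiometry("t", "20", "dB2") == pytest.approx(0.5)
        assert m.stoichiometry("t", "20", "dB1dB2") == 0.0

    def test_expected_attribution(self):
        m = self._map()
        assert m.expected_attribution("t", "17") == "B1_only"
        assert m.expected_attribution("t", "20") == "redundant_B2_preferred"


class TestMaldiPanel:
    def test_double_mutant_has_no_modified_peaks(self):
        trnas, truth = gen_trna_set(2, seed=7)
        for t in trnas:
            pl = gen_maldi_panel(t, truth, "dB1dB2", ZERO_NOISE)
            diags, _ = select_diagnostics(
                t, "RNaseT1", [r.label for r in t.residues if r.modification == "D"])
            for d in diags:
                hits = [p for p in pl if abs(p.mz - d.mz_modified) < 0.25]
                assert hits == []

    def test_single_mutant_split_matches_efficiency(self):
        profile = {"20": {"B2": 0.9}}
        trnas, truth = gen_trna_set(1, seed=9, site_profile=profile)
        t = trnas[0]
        pl = gen_maldi_panel(t, truth, "dB1", ZERO_NOISE)
        diags, _ = select_diagnostics(t, "RNaseT1", ["20"])
        d = diags[0]
        i_mod = sum(p.intensity for p in pl if abs(p.mz - d.mz_modified) < 0.25)
        i_unmod = sum(p.intensity for p in pl if abs(p.mz - d.mz_unmodified) < 0.25)
        assert i_mod / (i_mod + i_unmod) == pytest.approx(0.9)

    def test_zero_noise_full_attribution_recovery(self):
        trnas, truth = gen_trna_set(10, seed=13)
        correct, total = run_panel(trnas, truth, ZERO_NOISE)
        assert total >= 10
        assert correct == total

    def test_panel_determinism(self):
        trnas, truth = gen_trna_set(1, seed=21)
        noise = NoiseConfig(seed=21)
        a = gen_maldi_strain_panels(trnas[0], truth, noise)
        b = gen_maldi_strain_panels(trnas[0], truth, noise)
        for g in STRAINS:
            assert [(p.mz, p.intensity) for p in a[g]] == \
                [(p.mz, p.intensity) for p in b[g]]


class TestCleavageProfiles:
    def test_unmodified_strain_statistically_flat(self):
        trnas, truth = gen_trna_set(1, seed=31)
        (p,) = gen_cleavage_profiles(trnas, truth, "dB1dB2",
                                     noise=NoiseConfig(seed=31))
        att = p.attributed_counts()
        # no position should stand out against Poisson background
        assert att.max() <= np.quantile(att, 0.5) + 6 * np.sqrt(5.0) + 1

    def test_stop_ratio_tracks_stoichiometry_within_binomial_error(self):
        profile = {"20": {"B2": 0.5}}
        trnas, truth = gen_trna_set(1, seed=33, site_profile=profile)
        t = trnas[0]
        noise = NoiseConfig(seed=33)
        (p,) = gen_cleavage_profiles([t], truth, "WT", noise=noise)
        sr = stop_ratio(p, t.label_to_index("20"))
        p_true = 0.5
        margin = 3 * np.sqrt(p_true * (1 - p_true) / noise.coverage)
        background = noise.background_lambda / noise.coverage
        assert abs(sr - p_true) < margin + background

    def test_spiked_site_scores_high(self):
        trnas, truth = gen_trna_set(1, seed=35)
        t = trnas[0]
        (p,) = gen_cleavage_profiles([t], truth, "WT", noise=NoiseConfig(seed=35))
        for label in truth.sites(t.id):
            assert normcount(p, t.label_to_index(label)) >= 5.0

    def test_rising_stoichiometry_gives_monotone_dose_response(self):
        profile = {"17": {"B1": 0.8}}
        trnas, truth = gen_trna_set(1, seed=37, site_profile=profile)
        t = trnas[0]
        concs = [0.05, 0.5, 5.0, 50.0]
        effs = [0.0, 0.2, 0.5, 0.8]
        profs = []
        for i, eff in enumerate(effs):
            (p,) = gen_cleavage_profiles(
                [t], truth, "WT", noise=NoiseConfig(seed=100 + i),
                stoichiometry_override={(t.id, "17"): eff})
            profs.append(p)
        dr = dose_response(profs, concs, t.label_to_index("17"))
        assert dr.monotone

    def test_replicates_and_determinism(self):
        trnas, truth = gen_trna_set(2, seed=41)
        kw = dict(replicates=3, noise=NoiseConfig(seed=41))
        a = gen_cleavage_profiles(trnas, truth, "WT", **kw)
        b = gen_cleavage_profiles(trnas, truth, "WT", **kw)
        assert len(a) == 6
        assert all((x.counts == y.counts).all() for x, y in zip(a, b))


class TestKineticsGenerator:
    grid = np.array([0.5, 1, 2, 4, 8, 16.0])

    def test_zero_cv_exact_curve(self):
        s = gen_kinetics(0.7, 2.1, 0.01, self.grid, cv=0.0)
        expected = 0.7 * 0.01 * self.grid / (2.1 + self.grid)
        assert s.initial_rate == pytest.approx(expected)

    def test_same_seed_same_series(self):
        a = gen_kinetics(0.7, 2.1, 0.01, self.grid, cv=0.05, seed=4)
        b = gen_kinetics(0.7, 2.1, 0.01, self.grid, cv=0.05, seed=4)
        assert (a.initial_rate == b.initial_rate).all()

    def test_grid_must_span_km(self):
        from dusmap.trna import TRNAError
        with pytest.raises(TRNAError, match="span"):
            gen_kinetics(0.7, 2.1, 0.01, np.array([10.0, 20, 40, 80, 160, 320]))


class TestBenchmarkAccuracy:
    def test_call_sites_sensitivity_and_fdr(self):
        """Site calling on ~200 spiked sites: sensitivity >= 0.95, FDR <= 0.05."""
        trnas, truth = gen_trna_set(67, seed=77)
        profiles = gen_cleavage_profiles(trnas, truth, "WT",
                                         noise=NoiseConfig(seed=77))
        tp = fp = fn = 0
        for t, p in zip(trnas, profiles):
            true_pos = {t.label_to_index(lab) for lab in truth.sites(t.id)}
            called = {t.label_to_index(c.site)
                      for c in call_sites(p, t).d_sites}
            tp += len(called & true_pos)
            fp += len(called - true_pos)
            fn += len(true_pos - called)
        assert tp + fn >= 200
        assert tp / (tp + fn) >= 0.95
        assert fp / max(tp + fp, 1) <= 0.05

    def test_attribution_accuracy_at_default_noise(self):
        """>= 95% correct attributions over ~200 sites at the default noise."""
        trnas, truth = gen_trna_set(67, seed=20240101)
        correct, total = run_panel(trnas, truth, NoiseConfig(seed=20240101),
                                   rng_seed=20240101)
        assert total >= 200
        assert correct / total >= 0.95
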
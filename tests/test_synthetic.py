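"""Determinism and statistical fidelity of the synthetic bioassay generator."""

import numpy as np
import pytest
from scipy import stats

from epfassay.screening import bei
from epfassay.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_truth,
    simulate_dose_mortality,
    simulate_screening_assays,
)


class TestTruth:
    def test_same_seed_identical_truth(self):
        cfg = SyntheticConfig(seed=1, n_isolates=5)
        assert generate_truth(cfg) == generate_truth(cfg)

    def test_point_ranges_collapse(self):
        cfg = SyntheticConfig(seed=3, n_isolates=6,
                              alpha_range=(-1.5, -1.5), beta_range=(0.5, 0.5))
        truth = generate_truth(cfg)
        assert all(t.alpha == -1.5 and t.beta == 0.5 for t in truth.isolates)
        assert all(t.lc50 == pytest.approx(1e3) for t in truth.isolates)

    def test_adding_isolates_preserves_earlier_draws(self):
        small = generate_truth(SyntheticConfig(seed=5, n_isolates=3))
        big = generate_truth(SyntheticConfig(seed=5, n_isolates=10))
        assert big.isolates[:3] == small.isolates

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SyntheticConfig(seed=1, beta_range=(0.9, 0.3))


class TestDoseMortality:
    def test_final_mortality_converges_to_truth_curve(self):
        # one huge replicate per dose: empirical rate within 3 binomial SDs
        cfg = SyntheticConfig(seed=9, n_isolates=1, replicates=1,
                              larvae_per_replicate=10_000,
                              alpha_range=(-2.5, -2.5), beta_range=(0.5, 0.5),
                              control_mortality_range=(0.0, 0.0))
        truth = generate_truth(cfg)
        assays = [a for a in simulate_dose_mortality(truth) if a.dose]
        for a in assays:
            p = stats.norm.cdf(-2.5 + 0.5 * np.log10(a.dose))
            sd = np.sqrt(p * (1 - p) / a.n_exposed)
            assert abs(a.final_deaths / a.n_exposed - p) < 3 * sd + 1e-9

    def test_half_mortality_at_true_lc50(self):
        cfg = SyntheticConfig(seed=2, n_isolates=1, replicates=1,
                              larvae_per_replicate=100_000, dose_grid=(1e3,),
                              alpha_range=(-1.5, -1.5), beta_range=(0.5, 0.5),
                              control_mortality_range=(0.02, 0.02))
        truth = generate_truth(cfg)
        assert truth.isolates[0].lc50 == pytest.approx(1e3)
        a = [x for x in simulate_dose_mortality(truth) if x.dose == 1e3][0]
        expected = 0.02 + 0.98 * 0.5
        assert a.final_deaths / a.n_exposed == pytest.approx(expected, abs=0.005)

    def test_flat_truth_gives_flat_mortality(self):
        cfg = SyntheticConfig(seed=4, n_isolates=1, replicates=3,
                              larvae_per_replicate=1000,
                              alpha_range=(0.0, 0.0), beta_range=(0.0, 0.0))
        truth = generate_truth(cfg)
        assays = [a for a in simulate_dose_mortality(truth) if a.dose]
        rates = [a.final_deaths / a.n_exposed for a in assays]
        assert np.ptp(rates) < 0.1  # all near Phi(0) = 0.5 up to binomial noise

    def test_death_days_within_window(self):
        truth = generate_truth(SyntheticConfig(seed=6, n_isolates=2))
        for a in simulate_dose_mortality(truth):
            assert len(a.deaths_by_day) == a.window_days
            assert a.deaths_by_day[-1] <= a.n_exposed


class TestScreeningAssays:
    def test_certain_germination(self):
        cfg = SyntheticConfig(seed=7, n_isolates=2, germination_range=(1.0, 1.0))
        germ, _, _ = simulate_screening_assays(generate_truth(cfg))
        assert all(g.n_germinated == 100 for g in germ)

    def test_zero_host_mortality_leaves_sg_rsr_terms(self):
        cfg = SyntheticConfig(seed=8, n_isolates=3, galleria_mortality_range=(0.0, 0.0))
        truth = generate_truth(cfg)
        germ, spor, mort = simulate_screening_assays(truth)
        assert all(m.final_deaths == 0 for m in mort)
        iso = truth.isolates[0].isolate_id
        sg = np.mean([g.n_germinated for g in germ if g.isolate_id == iso])
        days = [s.dpcs_day for s in spor if s.isolate_id == iso]
        rsr = 20.0 / np.mean(days)
        expected = 0.37 * sg + 0.13 * rsr
        got = bei(sg, rsr, 0.0)
        assert got == pytest.approx(expected)

    def test_bei_distribution_spans_plausible_band(self):
        cfg = SyntheticConfig(seed=10, n_isolates=100)
        truth = generate_truth(cfg)
        germ, spor, mort = simulate_screening_assays(truth)
        beis = []
        for t in truth.isolates:
            sg = np.mean([100 * g.n_germinated / g.n_counted
                          for g in germ if g.isolate_id == t.isolate_id])
            rsr = 20.0 / np.mean([s.dpcs_day for s in spor if s.isolate_id == t.isolate_id])
            lm = np.mean([100 * m.final_deaths / m.n_exposed
                          for m in mort if m.isolate_id == t.isolate_id])
            beis.append(bei(sg, rsr, lm))
        assert 55 < min(beis) and max(beis) < 95
        assert np.ptp(beis) > 5  # genuinely spread out


class TestGenerateDataset:
    def test_bundle_parses_and_regenerates_identically(self, tmp_path):
        from epfassay.io import read_dataset

        cfg = SyntheticConfig(seed=11, n_isolates=4)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        data = read_dataset(tmp_path / "a")
        assert len(data["isolates"]) == 4
        assert {m.isolate_id for m in data["mortality"]} == {
            i.isolate_id for i in data["isolates"]}
        for f in ("isolates.csv", "germination.csv", "sporulation.csv",
                  "mortality.csv", "truth.csv", "manifest.json"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_refuses_to_overwrite_without_force(self, tmp_path):
        cfg = SyntheticConfig(seed=12, n_isolates=2)
        generate_dataset(cfg, tmp_path)
        with pytest.raises(FileExistsError):
            generate_dataset(cfg, tmp_path)
        generate_dataset(cfg, tmp_path, force=True)
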
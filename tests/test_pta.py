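"""Monte Carlo PTA engine: parameter sampling, table structure, adequacy."""

import numpy as np
import pandas as pd
import pytest

import meropkpd as m

NARROW_F = dict(f_low=0.9, f_high=0.9 + 1e-9)


class TestSampleParameters:
    def test_zero_sd_gives_constant_draws(self):
        dist = m.SimDistribution("x", 7.7, 0.0, 22.6, 0.0)
        d = m.sample_parameters(dist, 100, seed=0)
        assert np.all(d.cl == 7.7) and np.all(d.vd == 22.6)

    def test_same_seed_identical_sequences(self):
        d1 = m.sample_parameters(m.CRCL_NORMAL, 1000, seed=5)
        d2 = m.sample_parameters(m.CRCL_NORMAL, 1000, seed=5)
        assert np.array_equal(d1.cl, d2.cl)
        assert np.array_equal(d1.vd, d2.vd)
        assert np.array_equal(d1.fu, d2.fu)

    def test_all_draws_positive_and_f_in_range(self):
        tight = m.SimDistribution("tight", 0.5, 1.0, 0.5, 1.0)  # heavy truncation
        d = m.sample_parameters(tight, 5000, seed=1)
        assert np.all(d.cl > 0) and np.all(d.vd > 0)
        assert np.all((d.fu >= 0.85) & (d.fu <= 0.98))

    def test_sample_mean_near_truncated_normal_mean(self):
        # At mean/sd = 7.7/1.8 the truncation correction is ~1e-5, so the
        # sample mean should sit within ~3.5 standard errors of 7.7.
        d = m.sample_parameters(m.CRCL_NORMAL, 100_000, seed=2)
        assert d.cl.mean() == pytest.approx(7.7, abs=0.02)

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            m.sample_parameters(m.CRCL_NORMAL, 0, seed=0)


@pytest.fixture(scope="module")
def small_table():
    return m.compute_pta(
        m.CRCL_NORMAL, m.STUDY_REGIMENS, m.MIC_GRID, m.DEFAULT_TARGETS,
        n_sim=2000, seed=11,
    )


class TestComputePTA:
    def test_complete_grid(self, small_table):
        assert len(small_table.frame) == 12 * 9 * 8
        assert small_table.n_sim == 2000

    def test_degenerate_distribution_matches_deterministic_indicator(self):
        dist = m.SimDistribution("fixed", 7.7, 0.0, 22.6, 0.0, **NARROW_F)
        tab = m.compute_pta(
            dist, [m.Regimen(1000, 8, 0.5)], [1.0, 8.0, 64.0],
            [m.PDTarget(40, 1), m.PDTarget(100, 1)], n_sim=50, seed=0,
        )
        params = m.PKParameters(7.7, 22.6, 0.9)
        for _, row in tab.frame.iterrows():
            ft = m.percent_ft_above(params, m.Regimen(1000, 8, 0.5), row["mic"])
            expected = 100.0 if ft >= row["target_pct"] else 0.0
            assert row["pta_pct"] == expected

    def test_monotone_nonincreasing_in_mic(self, small_table):
        g = small_table.frame.sort_values("mic").groupby(
            ["dose_mg", "tau_h", "tinf_h", "target_pct", "multiplier"]
        )["pta_pct"]
        for _, series in g:
            assert (series.diff().dropna() <= 1e-12).all()

    def test_nested_targets(self, small_table):
        f = small_table.frame.set_index(
            ["dose_mg", "tau_h", "tinf_h", "mic", "multiplier", "target_pct"]
        )["pta_pct"]
        lax = f.xs(40, level="target_pct")
        strict = f.xs(100, level="target_pct")
        assert (lax >= strict).all()

    def test_multiplier_four_never_easier(self, small_table):
        f = small_table.frame.set_index(
            ["dose_mg", "tau_h", "tinf_h", "mic", "target_pct", "multiplier"]
        )["pta_pct"]
        assert (f.xs(1, level="multiplier") >= f.xs(4, level="multiplier")).all()

    def test_low_mic_near_certain_attainment(self, small_table):
        sel = small_table.frame.query("mic == 0.25 and target_pct == 40 and multiplier == 1")
        assert (sel["pta_pct"] >= 99).all()

    def test_high_mic_low_dose_rarely_attained(self, small_table):
        val = small_table.pta(m.Regimen(500, 6, 0.5), 64.0, m.PDTarget(40, 1))
        assert val < 5

    def test_ci_brackets_point_estimate(self, small_table):
        f = small_table.frame
        assert ((f["ci_low"] <= f["pta_pct"]) & (f["pta_pct"] <= f["ci_high"])).all()

    def test_seed_to_seed_variation_within_binomial_bound(self):
        reg = [m.Regimen(1000, 8, 0.5)]
        targets = [m.PDTarget(40, 1), m.PDTarget(100, 1)]
        t1 = m.compute_pta(m.CRCL_NORMAL, reg, m.MIC_GRID, targets, n_sim=10_000, seed=1)
        t2 = m.compute_pta(m.CRCL_NORMAL, reg, m.MIC_GRID, targets, n_sim=10_000, seed=2)
        merged = t1.frame.merge(
            t2.frame, on=["dose_mg", "tau_h", "tinf_h", "mic", "target_pct", "multiplier"]
        )
        mid = merged[(merged["pta_pct_x"] > 5) & (merged["pta_pct_x"] < 95)]
        assert (mid["pta_pct_x"] - mid["pta_pct_y"]).abs().max() < 1.5


class TestAdequacy:
    def test_known_cells(self, small_table):
        adq = m.adequacy(small_table)
        sel = adq.query("target_pct == 40 and multiplier == 1")
        assert (sel["max_adequate_mic"] >= 4).all()

    def test_all_zero_table_has_no_adequate_mic(self):
        frame = pd.DataFrame(
            {
                "subgroup": ["x"] * 3, "dose_mg": [500.0] * 3, "tau_h": [6.0] * 3,
                "tinf_h": [0.5] * 3, "mic": [1.0, 2.0, 4.0],
                "target_pct": [40] * 3, "multiplier": [1] * 3,
                "pta_pct": [0.0] * 3, "ci_low": [0.0] * 3, "ci_high": [0.0] * 3,
            }
        )
        adq = m.adequacy(m.PTATable(frame, n_sim=10))
        assert adq["max_adequate_mic"].isna().all()

    def test_rounding_rule_at_boundary(self):
        frame = pd.DataFrame(
            {
                "subgroup": ["x"] * 2, "dose_mg": [500.0] * 2, "tau_h": [6.0] * 2,
                "tinf_h": [0.5] * 2, "mic": [1.0, 2.0], "target_pct": [40] * 2,
                "multiplier": [1] * 2, "pta_pct": [89.96, 89.94],
                "ci_low": [0.0] * 2, "ci_high": [100.0] * 2,
            }
        )
        adq = m.adequacy(m.PTATable(frame, n_sim=10))
        # 89.96 rounds to 90.0 and qualifies; 89.94 rounds to 89.9 and does not
        assert adq["max_adequate_mic"].tolist() == [1.0]
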
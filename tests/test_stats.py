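"""Distance codings, outlier screening, ANOVA/LME/regression stages."""

import itertools

import numpy as np
import pandas as pd
import pytest

from soflow.stats import (compare_so_vs_nonso, d_sink_so, d_source_sink,
                          d_source_so, exclude_outliers, peak_height_lme,
                          relative_distance, significance_tier,
                          wpa_regressions)

SOURCES = ["Fz", "Cz", "Pz", "POz"]
REGIONS = ["F", "C", "P", "O"]


class TestDistanceCodings:
    def test_paper_worked_example(self):
        # SO at Cz, source Fz, sink O: D_sink_SO = 2, D_source_SO = 1 -> +1
        assert d_sink_so("O", "Cz") == 2
        assert d_source_so("Fz", "Cz") == 1
        assert relative_distance("O", "Fz", "Cz") == 1

    def test_same_position_source_and_sink(self):
        assert relative_distance("F", "Fz", "Fz") == 0

    def test_extreme_codings(self):
        assert relative_distance("F", "Fz", "POz") == 0   # 3 - 3
        assert relative_distance("F", "POz", "Fz") == -3  # 0 - 3

    def test_all_codings_match_brute_force_table(self):
        # independent enumeration over the 4 x 4 x 4 grid
        pos = {c: i + 1 for i, c in enumerate(SOURCES)}
        rpos = {r: i + 1 for i, r in enumerate(REGIONS)}
        for src, so, sink in itertools.product(SOURCES, SOURCES, REGIONS):
            assert d_source_so(src, so) == abs(pos[src] - pos[so])
            assert d_sink_so(sink, so) == abs(rpos[sink] - pos[so])
            assert d_source_sink(src, sink) == abs(rpos[sink] - pos[src])
            assert relative_distance(sink, src, so) == \
                abs(rpos[sink] - pos[so]) - abs(pos[src] - pos[so])

    def test_unknown_labels_rejected(self):
        with pytest.raises(KeyError):
            d_source_so("T7", "Fz")


class TestOutlierExclusion:
    def test_far_outlier_dropped(self):
        values = np.array([1.0] * 9 + [50.0])
        kept, dropped = exclude_outliers(values)
        # mean 5.9, sd 14.7 -> upper bound 35.3: 50 is excluded
        assert dropped == 1 and 50.0 not in kept

    def test_equal_values_all_kept(self):
        kept, dropped = exclude_outliers(np.full(10, 3.3))
        assert dropped == 0 and kept.size == 10

    def test_normal_sample_drops_two_sided_tail_mass(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        _, dropped = exclude_outliers(x)
        assert dropped / 10_000 == pytest.approx(0.046, abs=0.007)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            exclude_outliers(np.array([1.0, 2.0]))


class TestSignificanceTiers:
    def test_tier_boundaries(self):
        assert significance_tier(0.001) == "strong"
        assert significance_tier(0.01) == "significant"
        assert significance_tier(0.07) == "marginal"
        assert significance_tier(0.5) == "ns"


class TestSOvsNonSO:
    PHASES = ["-pi", "-pi/2", "0", "pi/2", "pi"]

    def _simulate(self, rng, n=40, bump=0.0):
        phase_vals = {}
        for name in self.PHASES:
            mu = 1.0 + (bump if name in ("-pi/2", "pi/2") else 0.0)
            phase_vals[name] = rng.normal(mu, 0.3, n)
        return phase_vals, rng.normal(1.0, 0.3, n)

    def test_planted_peaks_detected_trough_not(self):
        hits_peak, hits_null = 0, 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            phase_vals, non_so = self._simulate(rng, bump=0.4)
            res = compare_so_vs_nonso(phase_vals, non_so)
            cmp = res.comparisons.set_index("pair")["p_value"]
            if (cmp["-pi/2 vs non-SO"] < 0.05 and cmp["pi/2 vs non-SO"] < 0.05):
                hits_peak += 1
            if cmp["0 vs non-SO"] > 0.05:
                hits_null += 1
        assert hits_peak >= 0.9 * n_seeds
        assert hits_null >= 0.9 * n_seeds

    def test_null_anova_type_one_rate(self):
        rejections = 0
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            phase_vals, non_so = self._simulate(rng, bump=0.0)
            res = compare_so_vs_nonso(phase_vals, non_so)
            if res.coefficients["p_value"].iloc[0] < 0.05:
                rejections += 1
        assert rejections / n_seeds == pytest.approx(0.05, abs=0.025)

    def test_identical_groups_give_zero_f(self):
        vals = np.arange(10, dtype=float)
        res = compare_so_vs_nonso({k: vals for k in self.PHASES}, vals)
        assert res.coefficients["estimate"].iloc[0] == pytest.approx(0.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            compare_so_vs_nonso({k: np.ones(2) for k in self.PHASES},
                                np.ones(2))


def synthesize_peak_table(rng, n_subjects=40, d_coef=-0.4,
                          subject_sd=0.3, noise_sd=0.3):
    rows = []
    for s in range(n_subjects):
        offset = rng.normal(0, subject_sd)
        for src, so, phase in itertools.product(SOURCES, SOURCES, (1, 2)):
            d = d_source_so(src, so)
            rows.append({
                "subject": f"S{s}", "source_idx": SOURCES.index(src) + 1,
                "so_channel_idx": SOURCES.index(so) + 1,
                "D_source_SO": d, "phase_code": phase,
                "peak_height": 2.0 + d_coef * d + offset
                + rng.normal(0, noise_sd),
            })
    return pd.DataFrame(rows)


class TestPeakHeightLME:
    TERMS = ["source_idx", "so_channel_idx", "D_source_SO", "phase_code"]

    def test_recovers_planted_distance_coefficient(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = synthesize_peak_table(rng)
            res = peak_height_lme(table, self.TERMS)
            row = res.coefficients.set_index("term").loc["D_source_SO"]
            if abs(row["estimate"] + 0.4) < 0.1 and row["p_value"] < 0.01:
                hits += 1
        assert hits >= 19

    def test_null_term_rejection_rate_near_alpha(self):
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table = synthesize_peak_table(rng, n_subjects=15, d_coef=0.0)
            res = peak_height_lme(table, self.TERMS)
            p = res.coefficients.set_index("term").loc["D_source_SO", "p_value"]
            if p < 0.05:
                rejections += 1
        assert 0.005 <= rejections / n_seeds <= 0.12

    def test_zero_group_variance_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        table = synthesize_peak_table(rng, n_subjects=10, subject_sd=0.0)
        res = peak_height_lme(table, ["D_source_SO", "phase_code"])
        x = sm.add_constant(table[["D_source_SO", "phase_code"]])
        ols = sm.OLS(table["peak_height"], x).fit()
        lme_coef = res.coefficients.set_index("term")["estimate"]
        assert lme_coef["D_source_SO"] == pytest.approx(
            ols.params["D_source_SO"], abs=1e-6)

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(2)
        table = synthesize_peak_table(rng, n_subjects=1)
        with pytest.raises(ValueError):
            peak_height_lme(table, self.TERMS)

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(3)
        table = synthesize_peak_table(rng, n_subjects=5)
        table["dup"] = table["D_source_SO"]
        with pytest.raises(ValueError, match="collinear"):
            peak_height_lme(table, ["D_source_SO", "dup"])


class TestWPARegressions:
    def _tables(self, rng, n=40, attenuation=0.25, noise=0.05, slope=0.2):
        z = rng.normal(0, 1, n)
        rows = []
        for s in range(n):
            for d in range(4):
                rows.append({"subject": f"S{s}", "D_source_SO": d,
                             "flow": z[s] * (1 - attenuation * d)
                             + rng.normal(0, noise)})
        flow = pd.DataFrame(rows)
        behavior = pd.DataFrame({
            "subject": [f"S{s}" for s in range(n)],
            "improvement": 1 + slope * z + rng.normal(0, 0.05, n),
        })
        return flow, behavior

    def test_planted_gradient_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            flow, behavior = self._tables(rng)
            res = wpa_regressions(flow, behavior)
            table = res.comparisons.set_index("group")
            ok = (table.loc[0, "p_adjusted"] < 0.05 and table.loc[0, "r"] > 0
                  and table.loc[0, "r"] > table.loc[3, "r"])
            hits += ok
        assert hits >= 18

    def test_null_familywise_error_controlled(self):
        fw_errors = 0
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(50_000 + seed)
            flow, behavior = self._tables(rng, slope=0.0, attenuation=0.0,
                                          noise=1.0)
            res = wpa_regressions(flow, behavior)
            if (res.comparisons["p_adjusted"] < 0.05).any():
                fw_errors += 1
        assert fw_errors / n_seeds <= 0.065

    def test_perfect_collinearity_gives_r_one(self):
        flow = pd.DataFrame({"subject": [f"S{i}" for i in range(10)],
                             "D_source_SO": [0] * 10,
                             "flow": np.arange(10, dtype=float)})
        behavior = pd.DataFrame({"subject": [f"S{i}" for i in range(10)],
                                 "improvement": np.arange(10, dtype=float)})
        res = wpa_regressions(flow, behavior)
        assert res.comparisons["r"].iloc[0] == pytest.approx(1.0)
        assert res.comparisons["p_raw"].iloc[0] < 1e-12

    def test_small_groups_skipped_not_crashed(self):
        flow = pd.DataFrame({"subject": ["A", "B"], "D_source_SO": [0, 0],
                             "flow": [1.0, 2.0]})
        behavior = pd.DataFrame({"subject": ["A", "B"],
                                 "improvement": [1.0, 1.1]})
        res = wpa_regressions(flow, behavior)
        assert res.comparisons["skipped"].all()

    def test_fdr_adjustment_monotone_in_raw_p(self):
        rng = np.random.default_rng(9)
        flow, behavior = self._tables(rng)
        res = wpa_regressions(flow, behavior, correction="fdr_bh")
        t = res.comparisons.sort_values("p_raw")
        assert t["p_adjusted"].is_monotonic_increasing
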
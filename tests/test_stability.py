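"""Stability classification, FDR, correlations, factorial comparisons."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import coinvasion as cv
import coinvasion.stability as stab


def brute_force_bh(p):
    """Step-up by definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def rgr_table(values_by_tid, focal="A", invasion_type="co"):
    rows = []
    for tid, vals in values_by_tid.items():
        for i, v in enumerate(vals, 1):
            rows.append(
                {
                    "treatment_id": tid,
                    "replicate": i,
                    "focal": focal,
                    "residents": "",
                    "co_invaders": "",
                    "invasion_type": invasion_type,
                    "rgr": v,
                }
            )
    return pd.DataFrame(rows)


class TestBhFdr:
    def test_hand_executed_example(self):
        np.testing.assert_allclose(
            cv.bh_fdr([0.002, 0.01, 0.03, 0.04]), [0.008, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert cv.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_equal_ps_stay_at_p(self):
        np.testing.assert_allclose(cv.bh_fdr([0.2] * 5), [0.2] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cv.bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            cv.bh_fdr([-0.1])

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
    def test_matches_brute_force_and_statsmodels(self, p):
        ours = cv.bh_fdr(p)
        np.testing.assert_allclose(ours, brute_force_bh(p), atol=1e-12)
        _, sm_q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(ours, sm_q, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=25))
    def test_monotone_in_raw_order(self, p):
        # BH is not idempotent in general, but adjusted values must
        # preserve the ordering of the raw values
        q = cv.bh_fdr(p)
        idx = np.argsort(p, kind="stable")
        assert (np.diff(q[idx]) >= -1e-12).all()
        assert (q >= np.asarray(p) - 1e-12).all()


class TestClassify:
    def test_seventy_groups_give_seventy_tests(self, stabilized_rgr):
        calls = cv.classify(stabilized_rgr)
        assert len(calls) == 70
        assert (~calls["untestable"]).sum() == 70
        assert calls["p_adjusted"].notna().sum() == 70
        assert (calls["p_adjusted"] >= calls["p_raw"] - 1e-15).all()

    def test_t_statistic_closed_form_example(self):
        calls = cv.classify(rgr_table({"t1": [1.1, 1.2, 1.3]}), adjust="none")
        row = calls.iloc[0]
        assert row["mean_rgr"] == pytest.approx(1.2)
        assert row["t_statistic"] == pytest.approx(3.4641016, rel=1e-6)
        assert row["df"] == 2

    def test_zero_variance_group_is_untestable(self):
        calls = cv.classify(rgr_table({"t1": [1.0, 1.0, 1.0]}))
        row = calls.iloc[0]
        assert row["untestable"]
        assert not row["stable"]
        assert row["mean_rgr"] == pytest.approx(1.0)

    def test_all_missing_group_is_untestable(self):
        calls = cv.classify(rgr_table({"t1": [np.nan, np.nan]}))
        assert calls.iloc[0]["untestable"]

    def test_stable_requires_both_mean_and_significance(self):
        table = rgr_table(
            {
                "up": [2.0, 2.1, 1.9, 2.0],  # clearly above 1
                "down": [0.3, 0.32, 0.28, 0.3],  # clearly below 1
                "null": [1.0, 1.05, 0.95, 1.02],  # straddles 1
            }
        )
        calls = cv.classify(table).set_index("treatment_id")
        assert calls.loc["up", "stable"]
        assert not calls.loc["down", "stable"]  # significant but mean < 1
        assert not calls.loc["null", "stable"]

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0.0, 5.0), min_size=3, max_size=12),
    )
    def test_t_matches_closed_form(self, vals):
        vals = np.asarray(vals)
        if np.std(vals, ddof=1) == 0:
            return
        calls = cv.classify(rgr_table({"g": list(vals)}), adjust="none")
        n = len(vals)
        expected_t = (vals.mean() - 1.0) / (vals.std(ddof=1) / np.sqrt(n))
        assert calls.iloc[0]["t_statistic"] == pytest.approx(
            expected_t, rel=1e-10, abs=1e-12
        )


def spearman_oracle(x, y):
    """Rank with average ties, then Pearson: the definition of rho."""
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    return np.corrcoef(rx, ry)[0, 1]


class TestCorrelateBySpecies:
    def paired(self, mapping):
        rows = []
        for sp, pairs in mapping.items():
            for s, c in pairs:
                rows.append(
                    {"species": sp, "mean_rgr_single": s, "mean_rgr_co": c}
                )
        return pd.DataFrame(rows)

    def test_perfect_monotone_and_antitone(self):
        out = cv.correlate_by_species(
            self.paired(
                {"A": [(1, 2), (2, 4), (3, 6)], "B": [(1, 3), (2, 2), (3, 1)]}
            )
        ).set_index("species")
        assert out.loc["A", "rho"] == pytest.approx(1.0)
        assert out.loc["B", "rho"] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        out = cv.correlate_by_species(
            self.paired({"A": [(1, 2), (1, 3), (1, 4)]})
        )
        assert out.iloc[0]["flag"] == "constant_vector"
        assert np.isnan(out.iloc[0]["rho"])

    def test_default_design_gives_five_species_tables(self, rng):
        mapping = {
            sp: [(rng.normal(), rng.normal()) for _ in range(14)]
            for sp in "AOPSV"
        }
        out = cv.correlate_by_species(self.paired(mapping))
        assert len(out) == 5
        assert out["n_pairs"].eq(14).all()
        assert out["p_adjusted"].notna().all()
        assert out["rho"].between(-1, 1).all()

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 5)),
            min_size=4,
            max_size=20,
        )
    )
    def test_matches_rank_then_pearson_oracle_with_ties(self, pairs):
        x = np.array([a for a, _ in pairs], float)
        y = np.array([b for _, b in pairs], float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        out = cv.correlate_by_species(self.paired({"A": pairs}))
        assert out.iloc[0]["rho"] == pytest.approx(
            spearman_oracle(x, y), rel=1e-10, abs=1e-12
        )


class TestInteractionModel:
    def exact_paired(self, slope=0.5, offsets=(0.0, 1.0, -0.5), n=6):
        rows = []
        x = np.linspace(0.5, 3.0, n)
        for sp, b0 in zip("ABC", offsets):
            for xi in x:
                rows.append(
                    {
                        "species": sp,
                        "mean_rgr_single": xi,
                        "mean_rgr_co": b0 + slope * xi,
                    }
                )
        return pd.DataFrame(rows)

    def test_recovers_exact_common_slope_and_intercepts(self):
        fit = cv.fit_interaction_model(self.exact_paired())
        assert fit.slope == pytest.approx(0.5, abs=1e-8)
        assert fit.intercepts["A"] == pytest.approx(0.0, abs=1e-8)
        assert fit.intercepts["B"] == pytest.approx(1.0, abs=1e-8)
        assert fit.intercepts["C"] == pytest.approx(-0.5, abs=1e-8)
        terms = fit.terms.set_index("term")
        assert terms.loc["interaction", "statistic"] == pytest.approx(0.0, abs=1e-6)

    def test_identity_line_recovered(self):
        data = self.exact_paired(slope=1.0, offsets=(0.0, 0.0, 0.0))
        fit = cv.fit_interaction_model(data)
        assert fit.slope == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(fit.intercepts.to_numpy(), 0.0, atol=1e-8)

    def test_species_specific_slopes_detected(self, rng):
        # distinct true slopes per species with mild noise: the
        # interaction term must be retained at alpha = 0.05
        rows = []
        for sp, b1 in zip("ABC", (0.2, 1.0, 2.0)):
            x = np.linspace(0.5, 3.0, 10)
            y = b1 * x + rng.normal(0, 0.05, x.size)
            rows += [
                {"species": sp, "mean_rgr_single": xi, "mean_rgr_co": yi}
                for xi, yi in zip(x, y)
            ]
        fit = cv.fit_interaction_model(pd.DataFrame(rows))
        terms = fit.terms.set_index("term")
        assert terms.loc["interaction", "p"] < 0.05
        slopes = fit.per_species_slopes
        assert slopes["C"] > slopes["B"] > slopes["A"]

    def test_chi2_variant_agrees_on_strong_effects(self):
        data = self.exact_paired()
        f_fit = cv.fit_interaction_model(data, method="f")
        chi_fit = cv.fit_interaction_model(data, method="chi2")
        f_terms = f_fit.terms.set_index("term")
        chi_terms = chi_fit.terms.set_index("term")
        assert (f_terms.loc["species", "p"] < 1e-6) and (
            chi_terms.loc["species", "p"] < 1e-6
        )

    def test_too_few_points_rejected(self):
        data = self.exact_paired(n=2)
        with pytest.raises(ValueError, match=">= 3 points"):
            cv.fit_interaction_model(data)


class TestWithinTreatmentContrasts:
    def make_long(self, n_pairs, rng, effect_pair=None, effect=0.0, sd=0.1,
                  n_rep=6):
        rows = []
        for i in range(n_pairs):
            pid = f"pair{i:02d}"
            for itype in ("single", "co"):
                mu = 1.5 + (effect if (pid == effect_pair and itype == "co") else 0)
                for rep in range(n_rep):
                    rows.append(
                        {
                            "pair_id": pid,
                            "invasion_type": itype,
                            "replicate": rep + 1,
                            "rgr": mu + rng.normal(0, sd),
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_contrasts(self, rng):
        data = self.make_long(5, rng)
        data["rgr"] = data.groupby(["pair_id", "replicate"])["rgr"].transform(
            "first"
        )
        res = cv.within_treatment_contrasts(data)
        assert np.allclose(res.table["diff_co_minus_single"], 0.0, atol=1e-12)
        assert not res.table["significant"].any()

    def test_one_row_per_pair(self, rng):
        res = cv.within_treatment_contrasts(self.make_long(70, rng))
        assert len(res.table) == 70
        assert res.interaction_df[0] == 69

    def test_planted_effect_is_the_only_significant_contrast(self, rng):
        # one pair's co-invasion values shifted by 10 residual SDs
        data = self.make_long(70, rng, effect_pair="pair33", effect=1.0, sd=0.1)
        res = cv.within_treatment_contrasts(data)
        hits = res.table.loc[res.table["significant"], "pair_id"].tolist()
        assert hits == ["pair33"]

    def test_underreplicated_pairs_excluded_with_warning(self, rng):
        data = self.make_long(4, rng)
        data = data[~((data["pair_id"] == "pair00") & (data["invasion_type"] == "co"))]
        with pytest.warns(UserWarning, match="pair00"):
            res = cv.within_treatment_contrasts(data)
        assert "pair00" not in set(res.table["pair_id"])


class TestModelObjects:
    def test_stability_model_summary_and_by_focal(self, stabilized_rgr):
        res = cv.StabilityModel(stabilized_rgr).fit()
        assert res.n_tests == 70
        text = res.summary()
        assert "tests performed: 70" in text
        bf = res.by_focal()
        assert bf["n_treatments"].eq(14).all()

    def test_single_vs_co_model_end_to_end(self, pool, co_design, single_design):
        pairing = cv.pair_by_residents(co_design, single_design)
        params = cv.preset("stabilized")
        rgr_co = cv.compute_all(
            cv.generate_dataset(co_design, params, master_seed=3), co_design, pool
        )
        needed = [s for _, s in pairing.pairs]
        rgr_single = cv.compute_all(
            cv.generate_dataset(single_design, params, master_seed=4),
            single_design,
            pool,
        )
        res = cv.SingleVsCoModel(rgr_co, rgr_single, pairing.pairs).fit()
        assert len(res.model.means) == 70
        assert len(res.correlations) == 5
        assert len(res.contrasts.table) == 70
        assert "Spearman" in res.summary()
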
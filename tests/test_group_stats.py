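import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nirspipe.errors import ParameterError
from nirspipe.group_stats import (
    anova_by_roi,
    fdr_bh,
    group_activation,
    make_tmap,
    one_sample_t,
    posthoc_paired,
    repeated_anova_2x2,
    roi_means,
)


def naive_bh_stepup(p, q):
    """Independent oracle: literal step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= q * i / m:
            k_max = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestOneSampleT:
    def test_symmetric_values_t_zero(self):
        t, df, p = one_sample_t([-1.0, 1.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # [1,2,3]: mean 2, sample sd 1, t = 2/(1/sqrt(3))
        t, df, p = one_sample_t([1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert df == 2

    def test_df_is_n_minus_1(self, rng):
        t, df, _ = one_sample_t(rng.normal(size=16))
        assert df == 15

    def test_matches_scipy(self, rng):
        x = rng.normal(size=20)
        t, df, p = one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            one_sample_t([2.0, 2.0, 2.0])

    def test_one_sided_tails(self, rng):
        x = rng.normal(size=10) + 1.0
        t, _, p2 = one_sample_t(x)
        _, _, pg = one_sample_t(x, tail="greater")
        _, _, pl = one_sample_t(x, tail="less")
        assert pg + pl == pytest.approx(1.0)
        assert pg == pytest.approx(p2 / 2) if t > 0 else True


class TestFdrBH:
    def test_single_p_unchanged(self):
        adj, rej = fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_all_equal_p_unchanged(self):
        adj, _ = fdr_bh([0.04] * 7)
        np.testing.assert_allclose(adj, 0.04)

    @given(seed=st.integers(0, 2**20), m=st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_stepup_oracle(self, seed, m):
        p = np.random.default_rng(seed).uniform(size=m)
        _, rej = fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(rej, naive_bh_stepup(p, 0.05))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=31)
        adj, rej = fdr_bh(p, q=0.05)
        ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(adj, ref_adj)
        np.testing.assert_array_equal(rej, ref_rej)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.uniform(size=25)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            fdr_bh([0.5, 1.2])


def _mean_betas(layout, rng, n_subjects=6, conditions=("ME_left",)):
    rows = []
    for s in range(n_subjects):
        for cond in conditions:
            for ch in layout.channel_ids:
                rows.append(
                    {
                        "subject": f"S{s:02d}",
                        "condition": cond,
                        "channel": ch,
                        "mean_beta": float(rng.normal()),
                    }
                )
    return pd.DataFrame(rows)


class TestRoiMeans:
    def test_pfc_left_uses_exactly_its_channels(self, layout, rng):
        mb = _mean_betas(layout, rng)
        out = roi_means(mb, layout)
        row = out.query("roi == 'PFC' and hemisphere == 'left' and subject == 'S00'")
        expected = mb.query("subject == 'S00' and channel in [1, 2, 5, 6]")[
            "mean_beta"
        ].mean()
        assert float(row["roi_beta"].iloc[0]) == pytest.approx(expected)

    def test_equal_betas_give_that_value(self, layout):
        mb = pd.DataFrame(
            {
                "subject": "S00",
                "condition": "ME_left",
                "channel": layout.channel_ids,
                "mean_beta": 0.7,
            }
        )
        out = roi_means(mb, layout)
        np.testing.assert_allclose(out["roi_beta"], 0.7)

    def test_unassigned_channels_excluded(self, layout, rng):
        mb = _mean_betas(layout, rng)
        mb.loc[mb["channel"].isin([9, 16, 25]), "mean_beta"] = 1e9
        out = roi_means(mb, layout)
        assert np.abs(out["roi_beta"]).max() < 1e6


def _cells(rng, n=8, effects=(0.0, 0.0, 0.0)):
    te, he, ie = effects
    rows = []
    for s in range(n):
        base = rng.normal()
        for ti, task in enumerate(("ME", "MI")):
            for hi, hand in enumerate(("left", "right")):
                sign_t = 1 if ti == 0 else -1
                sign_h = 1 if hi == 0 else -1
                rows.append(
                    {
                        "subject": f"S{s}",
                        "task": task,
                        "hand": hand,
                        "value": base
                        + 0.5 * (sign_t * te + sign_h * he + sign_t * sign_h * ie)
                        + 0.3 * rng.normal(),
                    }
                )
    return pd.DataFrame(rows)


class TestRepeatedAnova:
    def test_identical_cells_F_zero(self):
        rows = [
            {"subject": f"S{s}", "task": tk, "hand": hd, "value": float(s)}
            for s in range(5)
            for tk in ("ME", "MI")
            for hd in ("left", "right")
        ]
        out = repeated_anova_2x2(pd.DataFrame(rows))
        np.testing.assert_allclose(out["F"], 0.0)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_main_effect_F_equals_paired_t_squared(self, rng):
        for _ in range(10):
            cells = _cells(rng, effects=(0.4, 0.2, 0.1))
            out = repeated_anova_2x2(cells).set_index("effect")
            wide = cells.pivot_table(
                index="subject", columns=["task", "hand"], values="value"
            )
            me = wide[("ME",)].mean(axis=1)
            mi = wide[("MI",)].mean(axis=1)
            t_ref = sps.ttest_rel(me, mi)
            assert out.loc["task", "F"] == pytest.approx(t_ref.statistic**2)
            assert out.loc["task", "p"] == pytest.approx(t_ref.pvalue)
            left = wide.xs("left", axis=1, level="hand").mean(axis=1)
            right = wide.xs("right", axis=1, level="hand").mean(axis=1)
            t_ref = sps.ttest_rel(left, right)
            assert out.loc["hand", "F"] == pytest.approx(t_ref.statistic**2)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        cells = _cells(rng, n=10, effects=(0.5, 0.0, 0.3))
        ours = repeated_anova_2x2(cells).set_index("effect")
        ref = pg.rm_anova(
            data=cells, dv="value", within=["task", "hand"], subject="subject",
            detailed=True,
        )
        ref_map = {"task": "task", "hand": "hand", "task * hand": "interaction"}
        for src, effect in ref_map.items():
            row = ref[ref["Source"] == src].iloc[0]
            assert ours.loc[effect, "F"] == pytest.approx(row["F"], rel=1e-6)
            assert ours.loc[effect, "p"] == pytest.approx(row["p_unc"], rel=1e-6)
            # pingouin reports generalized eta^2; check partial eta^2 via
            # the exact df1=1 identity instead
            F, df2 = ours.loc[effect, "F"], ours.loc[effect, "df2"]
            assert ours.loc[effect, "partial_eta_sq"] == pytest.approx(
                F / (F + df2), rel=1e-9
            )

    def test_eta_invariant_under_affine_response(self, rng):
        cells = _cells(rng, effects=(0.6, 0.1, 0.0))
        a = repeated_anova_2x2(cells)
        shifted = cells.assign(value=3.0 * cells["value"] + 11.0)
        b = repeated_anova_2x2(shifted)
        np.testing.assert_allclose(a["partial_eta_sq"], b["partial_eta_sq"], atol=1e-10)
        np.testing.assert_allclose(a["F"], b["F"], atol=1e-8)

    def test_missing_cell_rejected(self, rng):
        cells = _cells(rng).iloc[:-1]
        with pytest.raises(ParameterError):
            repeated_anova_2x2(cells)

    def test_monte_carlo_calibration(self):
        rng = np.random.default_rng(555)
        n_reps = 250
        null_rej = alt_rej = 0
        for _ in range(n_reps):
            null = repeated_anova_2x2(_cells(rng, n=16)).set_index("effect")
            if null.loc["task", "p"] < 0.05:
                null_rej += 1
            alt = repeated_anova_2x2(
                _cells(rng, n=16, effects=(0.4, 0.0, 0.0))
            ).set_index("effect")
            if alt.loc["task", "p"] < 0.05:
                alt_rej += 1
        assert null_rej / n_reps == pytest.approx(0.05, abs=0.04)
        assert alt_rej / n_reps > 0.5


class TestPosthoc:
    def test_identical_vectors(self, rng):
        x = rng.normal(size=10)
        out = posthoc_paired([("same", x, x.copy())])
        assert out["mean_difference"].iloc[0] == 0.0
        assert out["p_bonferroni"].iloc[0] == 1.0

    def test_single_comparison_unadjusted(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        out = posthoc_paired([("ab", a, b)])
        assert out["p_bonferroni"].iloc[0] == pytest.approx(out["p_raw"].iloc[0])

    def test_two_comparisons_double_p(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        out = posthoc_paired([("ab", a, b), ("ba", b, a)])
        for row in out.itertuples():
            assert row.p_bonferroni == pytest.approx(min(1.0, 2 * row.p_raw))

    def test_md_is_mean_difference(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        out = posthoc_paired([("ab", a, b)])
        assert out["mean_difference"].iloc[0] == pytest.approx((a - b).mean())

    def test_too_small_rejected(self):
        with pytest.raises(ParameterError):
            posthoc_paired([("bad", [1.0], [2.0])])


class TestActivationMap:
    def test_group_activation_columns_and_df(self, layout, rng):
        mb = _mean_betas(layout, rng, n_subjects=16)
        act = group_activation(mb)
        assert (act["df"] == 15).all()
        assert act["p_raw"].between(0, 1).all()
        assert act["p_fdr"].between(0, 1).all()

    def test_negative_t_never_flagged_activated(self, layout):
        rng = np.random.default_rng(8)
        mb = _mean_betas(layout, rng, n_subjects=16)
        # push one channel strongly negative
        mb.loc[mb["channel"] == 5, "mean_beta"] -= 10.0
        act = group_activation(mb)
        row = act.query("channel == 5").iloc[0]
        assert row["t"] < 0 and not row["significant"]

    def test_tmap_round_trip(self, layout, rng, tmp_path):
        mb = _mean_betas(layout, rng, n_subjects=16)
        act = group_activation(mb)
        table = make_tmap(act, layout)
        path = tmp_path / "tmap.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_array_equal(
            back["significant"].to_numpy(), table["significant"].to_numpy()
        )

    def test_anova_by_roi_runs_all_rois(self, layout, rng):
        mb = _mean_betas(
            layout, rng, n_subjects=8,
            conditions=("ME_left", "ME_right", "MI_left", "MI_right"),
        )
        out = anova_by_roi(roi_means(mb, layout))
        assert set(out["roi"]) == {"PFC", "preSMA", "M1", "SMC"}
        assert len(out) == 4 * 2 * 3  # roi x hemisphere x effect
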
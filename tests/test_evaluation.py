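"""AUC, DeLong, JZS Bayes factor, and the two restriction protocols."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppeboost import evaluation as ev, model_harness as mh, slam_io
from conftest import make_log


def pairwise_auc(labels, scores):
    """Brute-force Mann-Whitney oracle over all positive-negative pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize(
        "labels, scores, expected",
        [
            ([1, 0], [0.9, 0.1], 1.0),
            ([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], 0.5),
            ([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2], 0.75),
        ],
    )
    def test_values(self, labels, scores, expected):
        assert ev.auc(labels, scores) == pytest.approx(expected)

    def test_degenerate_labels_return_chance(self):
        assert ev.auc([0, 0, 0], [0.1, 0.5, 0.9]) == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ev.auc([0, 1], [0.5])

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounded to force ties
            assert ev.auc(labels, scores) == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)


class TestDeLong:
    def test_identical_scores_no_evidence(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.random(40)
        z, p = ev.delong(y, s, s)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_in_score_order(self, rng):
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        z1, p1 = ev.delong(y, a, b)
        z2, p2 = ev.delong(y, b, a)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_degenerate_labels_flagged(self):
        z, p = ev.delong([1, 1, 1], [0.1, 0.2, 0.3], [0.3, 0.2, 0.1])
        assert np.isnan(z) and np.isnan(p)

    def test_se_matches_bootstrap_oracle(self):
        """Paired bootstrap of the AUC difference on a small fixture should
        agree with the DeLong standard error within 15%."""
        rng = np.random.default_rng(42)
        n = 10
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        sig = rng.random(n)
        a = sig + 0.3 * rng.random(n)
        b = sig + 0.3 * rng.random(n)
        z, _ = ev.delong(y, a, b)
        d_auc = ev.auc(y, a) - ev.auc(y, b)
        se_delong = d_auc / z

        def rank_auc(yy, ss):
            # row-wise Mann-Whitney AUC over a (B, n) resample matrix
            ranks = stats.rankdata(ss, axis=1)
            m = yy.sum(axis=1)
            pos_rank_sum = (ranks * yy).sum(axis=1)
            return (pos_rank_sum - m * (m + 1) / 2) / (m * (n - m))

        idx = rng.integers(0, n, size=(100_000, n))
        yy = y[idx]
        keep = (yy.sum(axis=1) > 0) & (yy.sum(axis=1) < n)
        yy = yy[keep]
        boots = rank_auc(yy, a[idx][keep]) - rank_auc(yy, b[idx][keep])
        se_boot = np.std(boots)
        assert se_delong == pytest.approx(se_boot, rel=0.15)


class TestPairedBayesT:
    def test_noise_supports_null(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0, 1, size=100)
        assert ev.paired_bayes_t(d) > 1

    def test_large_effect_supports_alternative(self):
        rng = np.random.default_rng(2)
        d = rng.normal(1.0, 0.1, size=50)
        assert ev.paired_bayes_t(d) < 0.01

    def test_zero_differences_maximal_null_support(self):
        assert ev.paired_bayes_t(np.zeros(10)) == np.inf

    def test_matches_independent_jzs_oracle(self):
        """Fixture vector vs pingouin's JZS implementation, 3 significant digits."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        d = rng.normal(0.25, 1.0, size=40)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        bf10_oracle = float(pingouin.bayesfactor_ttest(t, nx=len(d), paired=True))
        bf01 = ev.paired_bayes_t(d)
        assert 1.0 / bf01 == pytest.approx(bf10_oracle, rel=1e-3)


class TestRestrictedHistory:
    def test_day_arithmetic_and_flags(self):
        rows = []
        rng = np.random.default_rng(0)
        for ui in range(4):
            for d in range(6):
                for r in range(3):
                    rows.append((f"u{ui}", f"w{rng.integers(5)}", d + 0.1 * r, int(rng.random() < 0.3)))
        log = make_log(rows)
        res = ev.run_restricted_history(log, config=mh.ModelConfig(n_estimators=10))
        assert res["day"].max() <= 4  # trains through day x, predicts x+1
        assert len(res) <= 5
        assert {"auc_default", "auc_ppe", "n_train_events", "train_data_percent"} <= set(res.columns)

    def test_auc_improves_with_longer_history_on_simulated_data(self):
        """Day-by-day forecasting on a PPE-governed population: more
        accumulated history yields better next-day predictions."""
        import dataclasses

        from ppeboost import synthetic_data as sd

        cfg = dataclasses.replace(sd.SimConfig(), n_users=40)
        log, _ = sd.simulate(cfg, seed=13)
        res = ev.run_restricted_history(log, config=mh.ModelConfig(n_estimators=60), max_day=24)
        ok = res[~res["empty"]]
        early = ok[ok["day"].between(1, 6)]["auc_ppe"].mean()
        late = ok[ok["day"].between(12, 23)]["auc_ppe"].mean()
        assert late > early

    def test_day_with_no_next_day_events_flagged(self):
        # user practices on days 0 and 2 only: day-1 row must be flagged empty
        log = make_log([("u", "w", 0.0, 0), ("u", "w", 0.5, 1), ("u", "w", 2.0, 0), ("u", "w", 2.5, 1)])
        res = ev.run_restricted_history(log, config=mh.ModelConfig(n_estimators=5))
        row = res[res["day"] == 1].iloc[0]
        assert bool(row["empty"]) and np.isnan(row["auc_ppe"])


class TestGrid:
    def test_reproducible_and_bounded(self, sim_split):
        split, _ = sim_split
        cfg = mh.ModelConfig(n_estimators=30)
        kw = dict(users_levels=[5, 10], tokens_levels=[5, 10], iterations=2, master_seed=9, config=cfg)
        g1 = ev.run_user_token_grid(split, **kw)
        g2 = ev.run_user_token_grid(split, **kw)
        assert len(g1) <= 8
        pd.testing.assert_frame_equal(g1, g2)

    def test_oversized_cell_skipped_with_warning(self, sim_split):
        split, _ = sim_split
        with pytest.warns(UserWarning, match="exceeds available"):
            g = ev.run_user_token_grid(
                split, users_levels=[10_000], tokens_levels=[5], iterations=1,
                config=mh.ModelConfig(n_estimators=5),
            )
        assert len(g) == 0

    def test_full_lists_reproduce_full_comparison(self, sim_split):
        """Sampling every user and every token must equal the plain
        full-data comparison."""
        split, kept = sim_split
        cfg = mh.ModelConfig(n_estimators=40)
        n_users = split.train["user"].nunique()
        n_tokens = split.train["token"].nunique()
        g = ev.run_user_token_grid(
            split, users_levels=[n_users], tokens_levels=[n_tokens], iterations=1,
            master_seed=3, config=cfg,
        )
        res = ev.compare_variants(split.train, kept, config=cfg)
        assert g.iloc[0]["auc_default"] == pytest.approx(res.auc_default, abs=1e-12)
        assert g.iloc[0]["auc_ppe"] == pytest.approx(res.auc_ppe, abs=1e-12)

    def test_summarize_grid_hand_checked(self):
        raw = pd.DataFrame(
            {
                "n_users": [5] * 3 + [10] * 2,
                "n_tokens": [5] * 3 + [10] * 2,
                "iteration": [1, 2, 3, 1, 2],
                "auc_default": [0.5, 0.6, 0.7, 0.5, 0.9],
                "auc_ppe": [0.5, 0.8, 0.6, 0.7, 0.9],
                "at_chance_default": [True, False, False, True, False],
                "at_chance_ppe": [True, False, False, False, False],
            }
        )
        summ = ev.summarize_grid(raw).set_index(["n_users", "n_tokens"])
        cell = summ.loc[(5, 5)]
        assert cell["median_auc_default"] == pytest.approx(0.6)
        assert cell["median_auc_ppe"] == pytest.approx(0.6)
        assert cell["delta_pp"] == pytest.approx(0.0)
        assert cell["at_chance_default_pct"] == pytest.approx(100 / 3)
        cell2 = summ.loc[(10, 10)]
        assert cell2["median_auc_ppe"] == pytest.approx(0.8)
        assert cell2["delta_pp"] == pytest.approx(10.0)
        assert cell2["at_chance_ppe_pct"] == 0.0
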
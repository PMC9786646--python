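"""Model comparison statistics and limited-data evaluation protocols.

Predictive accuracy is measured by the area under the ROC curve (AUC),
which equals the Mann–Whitney probability that a randomly chosen error
outscores a randomly chosen correct response (0.5 = chance, 1 = perfect).
Two correlated AUCs from the same test instances are compared with
DeLong's test; the similarity of the two models' per-instance predictions
is quantified with a JZS (Cauchy-prior) paired Bayes factor reported as
BF01, the evidence for the null of equal means.

Two protocols probe how the feature variants cope with limited data:

* restricted learning history — train on all events up to day ``x``,
  predict the first next-day repetition of trained pairs, for each ``x``;
* restricted users x tokens — repeatedly subsample ``n_users`` users and
  ``n_tokens`` tokens from the training set, train on the intersection,
  and score the (re-filtered) test set, over a grid of sizes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from sklearn.metrics import roc_auc_score

from . import model_harness as mh
from . import ppe_features, slam_io

__all__ = [
    "ComparisonResult",
    "auc",
    "delong",
    "paired_bayes_t",
    "compare_variants",
    "run_restricted_history",
    "run_user_token_grid",
    "summarize_grid",
    "derive_cell_seed",
]

AT_CHANCE_TOL = 1e-9
GRID_LEVELS = (5, 10, 20, 50, 100, 250, 500)


@dataclass
class ComparisonResult:
    """Head-to-head result of the default and PPE-enhanced variants."""

    auc_default: float
    auc_ppe: float
    pearson_r: float
    delong_z: float
    delong_p: float
    bf01: float
    n_test: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def auc(labels, scores) -> float:
    """Area under the ROC curve; 0.5 when only one label class is present.

    Equals the Mann–Whitney statistic P(score_pos > score_neg) + 0.5 *
    P(tie) over all positive-negative instance pairs.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError(f"labels and scores have different lengths ({y.shape} vs {s.shape})")
    if len(np.unique(y)) < 2:
        return 0.5
    return float(roc_auc_score(y, s))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    a = v10.mean()
    return a, v10, v01


def delong(labels, scores_a, scores_b):
    """DeLong's paired test for the difference of two correlated AUCs.

    Returns ``(z, p)`` for ``auc(scores_a) - auc(scores_b)`` on the same
    labeled instances, with the variance of the difference computed from
    the covariance of the structural components of the Mann–Whitney
    statistic and ``p`` two-sided from the standard normal. Degenerate
    labels (single class) give ``(nan, nan)``.
    """
    y = np.asarray(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if not (y.shape == sa.shape == sb.shape):
        raise ValueError("labels and both score vectors must have equal length")
    if len(np.unique(y)) < 2:
        return float("nan"), float("nan")
    auc_a, v10_a, v01_a = _delong_components(y, sa)
    auc_b, v10_b, v01_b = _delong_components(y, sb)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        # identical score vectors (or perfectly coupled ranks): no evidence
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def paired_bayes_t(x, y=None, r: float = np.sqrt(2) / 2) -> float:
    """JZS Bayes factor BF01 for a paired (or one-sample) t comparison.

    The alternative places a zero-centered Cauchy prior with scale ``r``
    on the standardized effect of the paired differences; the marginal
    likelihood is obtained by numerical integration over the Cauchy's
    inverse-gamma mixing variable. Returns the Bayes factor in favor of
    the *null* (BF01 > 1 supports equal means). All-zero differences give
    ``inf`` — maximal support for the null.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    sd = d.std(ddof=1)
    if sd == 0:
        return float("inf") if np.allclose(d, 0) else 0.0
    t = d.mean() / (sd / np.sqrt(n))
    nu = n - 1

    def integrand(g: float) -> float:
        return (
            (1.0 + n * g) ** -0.5
            * (1.0 + t * t / ((1.0 + n * g) * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * r
            * g**-1.5
            * np.exp(-r * r / (2.0 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    bf10 = num / den
    return float(1.0 / bf10)


def _train_and_score(train_table, test_table, config):
    model = mh.train(train_table, config)
    return model, mh.predict(model, test_table)


def compare_variants(
    train_log: pd.DataFrame,
    test_log: pd.DataFrame,
    config: mh.ModelConfig | None = None,
    mode: str = "slice",
    x: float = 0.6,
    max_lags: int = 10,
) -> ComparisonResult:
    """Train both feature variants on ``train_log`` and compare on ``test_log``.

    ``test_log`` should already be filtered to first repetitions of trained
    pairs (see :func:`ppeboost.slam_io.filter_test_first_repetition`).
    Features are computed causally over the concatenated train + test
    events so a test event sees its full prior history.
    """
    config = config or mh.ModelConfig()
    combined = pd.concat([train_log, test_log], ignore_index=True)
    feats = ppe_features.annotate(combined, x=x, max_lags=max_lags)
    n_train = len(train_log)
    is_train = np.arange(len(combined)) < n_train
    scores = {}
    for variant in ("default", "ppe"):
        table = mh.build_feature_table(combined, feats, variant=variant, mode=mode, max_lags=max_lags)
        model, s = _train_and_score(table.subset(is_train), table.subset(~is_train), config)
        scores[variant] = s
    y = test_log["label"].to_numpy(dtype=np.int8)
    z, p = delong(y, scores["default"], scores["ppe"])
    if len(y) >= 2 and np.std(scores["default"]) > 0 and np.std(scores["ppe"]) > 0:
        r = float(np.corrcoef(scores["default"], scores["ppe"])[0, 1])
    else:
        r = float("nan")
    bf01 = paired_bayes_t(scores["default"], scores["ppe"]) if len(y) >= 2 else float("nan")
    return ComparisonResult(
        auc_default=auc(y, scores["default"]),
        auc_ppe=auc(y, scores["ppe"]),
        pearson_r=r,
        delong_z=z,
        delong_p=p,
        bf01=bf01,
        n_test=len(y),
    )


def run_restricted_history(
    log: pd.DataFrame,
    config: mh.ModelConfig | None = None,
    max_day: int | None = None,
    x: float = 0.6,
    max_lags: int = 10,
    min_added_percent: float = 0.0,
) -> pd.DataFrame:
    """Day-by-day forecasting: train on days <= x, predict day x + 1.

    For each day ``x`` the training slice is every event up to and
    including day ``x`` and the evaluation set is the day-``x + 1`` events
    that are first repetitions of pairs present in that slice. Rows where
    no evaluable events exist (or labels are single-class) carry NaN AUCs
    and ``empty=True``. ``min_added_percent`` drops trailing days that add
    less than that percentage of training data (unreliable late-horizon
    AUCs); 0 keeps everything.
    """
    config = config or mh.ModelConfig()
    feats = ppe_features.annotate(log, x=x, max_lags=max_lags)
    day_int = np.floor(log["day"].to_numpy(dtype=float)).astype(int)
    last_day = int(day_int.max()) if max_day is None else int(max_day)
    tables = {
        v: mh.build_feature_table(log, feats, variant=v, mode="slice", max_lags=max_lags)
        for v in ("default", "ppe")
    }
    total = len(log)
    users_arr = log["user"].to_numpy()
    tokens_arr = log["token"].to_numpy()
    rows = []
    for day_x in range(int(day_int.min()), last_day):
        train_mask = day_int <= day_x
        next_mask = day_int == day_x + 1
        n_train = int(train_mask.sum())
        added_pct = 100.0 * (n_train - int((day_int <= day_x - 1).sum())) / total
        if min_added_percent > 0 and added_pct < min_added_percent and day_x > int(day_int.min()):
            continue
        # evaluable day-(x+1) events: first repetition of pairs in the slice
        pair_ok = set(zip(users_arr[train_mask], tokens_arr[train_mask]))
        test_mask = np.zeros(total, dtype=bool)
        seen_pairs: set = set()
        for i in np.flatnonzero(next_mask):
            key = (users_arr[i], tokens_arr[i])
            if key in pair_ok and key not in seen_pairs:
                seen_pairs.add(key)
                test_mask[i] = True
        y = log["label"].to_numpy(dtype=np.int8)[test_mask]
        row = {
            "day": day_x,
            "n_train_events": n_train,
            "n_test_events": int(test_mask.sum()),
            "train_data_percent": 100.0 * n_train / total,
            "empty": False,
        }
        if test_mask.sum() == 0 or len(np.unique(y)) < 2:
            row.update({"auc_default": np.nan, "auc_ppe": np.nan, "empty": True})
        else:
            for v in ("default", "ppe"):
                _, s = _train_and_score(tables[v].subset(train_mask), tables[v].subset(test_mask), config)
                row[f"auc_{v}"] = auc(y, s)
        rows.append(row)
    return pd.DataFrame(rows)


def derive_cell_seed(master_seed: int, n_users: int, n_tokens: int, iteration: int) -> int:
    """Stable per-cell seed so each grid cell is independently reproducible."""
    key = f"{master_seed}:{n_users}:{n_tokens}:{iteration}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


def run_user_token_grid(
    split: slam_io.SplitLog,
    users_levels=GRID_LEVELS,
    tokens_levels=GRID_LEVELS,
    iterations: int = 100,
    master_seed: int = 0,
    config: mh.ModelConfig | None = None,
    x: float = 0.6,
    max_lags: int = 10,
) -> pd.DataFrame:
    """Restricted users x tokens protocol over a grid of subsample sizes.

    For each cell ``(n_users, n_tokens)`` and iteration, sample that many
    users and tokens without replacement from the training set (per-cell
    seed derived from ``master_seed``), train both variants on the events
    of sampled users practicing sampled tokens, and score the test events
    that are first repetitions of pairs in the restricted slice. Cells
    requesting more users/tokens than exist are skipped with a warning.
    Degenerate fits (single-class training labels or constant scores)
    record AUC 0.5 and ``at_chance=True``.
    """
    import warnings

    config = config or mh.ModelConfig()
    train_log, test_log = split.train, split.test
    combined = pd.concat([train_log, test_log], ignore_index=True)
    feats = ppe_features.annotate(combined, x=x, max_lags=max_lags)
    n_train = len(train_log)
    is_train = np.arange(len(combined)) < n_train
    tables = {
        v: mh.build_feature_table(combined, feats, variant=v, mode="slice", max_lags=max_lags)
        for v in ("default", "ppe")
    }
    users = train_log["user"].unique()
    tokens = train_log["token"].unique()
    tr_users = train_log["user"].to_numpy()
    tr_tokens = train_log["token"].to_numpy()
    te_users = test_log["user"].to_numpy()
    te_tokens = test_log["token"].to_numpy()
    te_labels = test_log["label"].to_numpy(dtype=np.int8)
    rows = []
    for nu in users_levels:
        for nt in tokens_levels:
            if nu > len(users) or nt > len(tokens):
                warnings.warn(
                    f"grid cell ({nu} users, {nt} tokens) exceeds available "
                    f"({len(users)}, {len(tokens)}); skipped"
                )
                continue
            for it in range(1, iterations + 1):
                seed = derive_cell_seed(master_seed, nu, nt, it)
                rng = np.random.default_rng(seed)
                u_sample = set(rng.choice(users, size=nu, replace=False))
                t_sample = set(rng.choice(tokens, size=nt, replace=False))
                tr_mask = np.array(
                    [u in u_sample and t in t_sample for u, t in zip(tr_users, tr_tokens)]
                )
                pair_ok = set(zip(tr_users[tr_mask], tr_tokens[tr_mask]))
                te_keep = np.array([(u, t) in pair_ok for u, t in zip(te_users, te_tokens)])
                # first test repetition per pair
                seen: set = set()
                for i in np.flatnonzero(te_keep):
                    key = (te_users[i], te_tokens[i])
                    if key in seen:
                        te_keep[i] = False
                    else:
                        seen.add(key)
                row = {
                    "n_users": nu,
                    "n_tokens": nt,
                    "iteration": it,
                    "seed": seed,
                    "n_train_events": int(tr_mask.sum()),
                    "n_test_events": int(te_keep.sum()),
                }
                y = te_labels[te_keep]
                full_train_mask = np.zeros(len(combined), dtype=bool)
                full_train_mask[:n_train] = tr_mask
                full_test_mask = np.zeros(len(combined), dtype=bool)
                full_test_mask[n_train:] = te_keep
                for v in ("default", "ppe"):
                    if tr_mask.sum() == 0 or te_keep.sum() == 0:
                        a, chance = 0.5, True
                    else:
                        model, s = _train_and_score(
                            tables[v].subset(full_train_mask),
                            tables[v].subset(full_test_mask),
                            config,
                        )
                        a = auc(y, s)
                        chance = model.degenerate or abs(a - 0.5) < AT_CHANCE_TOL
                    row[f"auc_{v}"] = a
                    row[f"at_chance_{v}"] = chance
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Per-cell medians, percentage-point deltas, and at-chance percentages."""
    def _cell(g: pd.DataFrame) -> pd.Series:
        med_d = g["auc_default"].median()
        med_p = g["auc_ppe"].median()
        return pd.Series(
            {
                "median_auc_default": med_d,
                "median_auc_ppe": med_p,
                "delta_pp": 100.0 * (med_p - med_d),
                "at_chance_default_pct": 100.0 * g["at_chance_default"].mean(),
                "at_chance_ppe_pct": 100.0 * g["at_chance_ppe"].mean(),
                "n_iterations": len(g),
            }
        )

    out = results.groupby(["n_users", "n_tokens"]).apply(_cell, include_groups=False)
    return out.reset_index()
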
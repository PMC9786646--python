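"""Predictive performance equation (PPE) timing transformations.

The PPE is a knowledge-tracing model that summarizes a learner's practice
history for one item as a memory *activation*

    M = N^c * T^(-d)

where ``N`` is the number of prior repetitions, ``T`` is *model time* — a
recency-weighted sum of the elapsed times since each repetition — and ``d``
is a decay rate whose *stability* component encodes the spacing of practice:
massed repetitions (short lags) decay quickly, spaced repetitions slowly.

The functions here compute those quantities causally from per-(user, token)
event histories, in days. Two of them, model time ``T`` and the stability
term, are parameter-free given the weight exponent ``x`` and serve as the
engineered input features of the PPE-enhanced classifier; the full
activation (which additionally needs the fitted constants ``c``, ``b``,
``m``) is used by the synthetic-learner simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PPEParams",
    "MIN_ELAPSED_DAYS",
    "recency_weights",
    "model_time",
    "stability",
    "decay",
    "activation",
    "annotate",
]

#: Floor for elapsed times entering the t^(-x) weight kernel, in days.
#: A repetition logged at the same timestamp would otherwise make the
#: weight diverge; one second preserves ordering with bounded weights.
MIN_ELAPSED_DAYS = 1.0 / 86400.0

#: Feature columns emitted by :func:`annotate` before the lag columns.
PPE_FEATURE_COLUMNS = ["n", "model_time", "stability"]


@dataclass(frozen=True)
class PPEParams:
    """Free parameters of the PPE.

    Parameters
    ----------
    c
        Learning-rate exponent of the power-law learning term ``N^c``.
    b, m
        Additive and multiplicative constants of the decay rate
        ``d = b + m * stability``; in applications they are optimized on
        training data. The engineered classifier features never use them;
        they matter only when the full activation is evaluated (simulator).
    x
        Exponent of the recency weights ``t^(-x)``; conventional default 0.6.
    """

    c: float = 0.1
    b: float = 0.3
    m: float = 0.3
    x: float = 0.6

    def __post_init__(self) -> None:
        if not self.x > 0:
            raise ValueError(f"weight exponent x must be positive, got {self.x}")
        for name in ("c", "b", "m"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")


def _as_positive_array(elapsed: Sequence[float]) -> np.ndarray:
    t = np.asarray(elapsed, dtype=float)
    if t.size and not np.all(t > 0):
        raise ValueError("elapsed times must be strictly positive (floor them first)")
    return t


def recency_weights(elapsed: Sequence[float], x: float = 0.6) -> np.ndarray:
    """Normalized recency weights ``w_i = t_i^(-x) / sum_j t_j^(-x)``.

    More recent repetitions (smaller elapsed time ``t_i``) receive strictly
    larger weights. The weights sum to one for any nonempty input.
    """
    if not x > 0:
        raise ValueError(f"x must be positive, got {x}")
    t = _as_positive_array(elapsed)
    if t.size == 0:
        return t
    # work in log space so tiny elapsed times cannot overflow t**(-x)
    logw = -x * np.log(t)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def model_time(elapsed: Sequence[float], x: float = 0.6) -> float:
    """Model time ``T = sum_i w_i t_i``, the recency-weighted age of the item.

    Lies between min and max of the elapsed times; ``nan`` for an empty
    history (the item has never been seen).
    """
    t = _as_positive_array(elapsed)
    if t.size == 0:
        return float("nan")
    return float(recency_weights(t, x) @ t)


def stability(lags: Sequence[float]) -> float:
    """Stability term of the decay rate, a pure transform of raw lag times.

    For a history of ``n`` repetitions with the ``n - 1`` inter-repetition
    lags ``lag_j`` (days), returns

        (1 / (n + 1)) * sum_{j=1}^{n-1} 1 / ln(lag_j + e).

    Longer lags (spaced practice) give a smaller value, hence a smaller
    decay rate and more durable memory; zero for a single-exposure history.
    """
    lag = np.asarray(lags, dtype=float)
    if lag.size and np.any(lag < 0):
        raise ValueError("lags must be nonnegative")
    n = lag.size + 1
    if lag.size == 0:
        return 0.0
    return float(np.sum(1.0 / np.log(lag + np.e)) / (n + 1))


def decay(lags: Sequence[float], params: PPEParams) -> float:
    """Decay rate ``d_n = b + m * stability(lags)``."""
    return params.b + params.m * stability(lags)


def activation(n: int, T: float, params: PPEParams, lags: Sequence[float] = ()) -> float:
    """PPE activation ``M = n^c * T^(-d)`` for an item seen ``n`` times.

    ``T`` is the model time and ``lags`` the inter-repetition intervals that
    set the decay rate. Increasing in ``n`` (practice strengthens) and, for
    positive decay, decreasing in ``T`` (memories age).
    """
    if n < 1:
        raise ValueError(f"activation requires at least one repetition, got n={n}")
    if not T > 0:
        raise ValueError(f"model time must be positive, got {T}")
    d = decay(lags, params)
    return float(n**params.c * T**-d)


def _check_ordered(log: pd.DataFrame) -> None:
    day = log["day"].to_numpy(dtype=float)
    # stable order within user: day must be non-decreasing per user block
    for _, idx in log.groupby("user", sort=False).indices.items():
        d = day[np.sort(idx)]
        if np.any(np.diff(d) < 0):
            raise ValueError("event log is not ordered: day decreases within a user")


def annotate(
    log: pd.DataFrame,
    x: float = 0.6,
    max_lags: int = 10,
    min_elapsed: float = MIN_ELAPSED_DAYS,
) -> pd.DataFrame:
    """Per-event PPE timing features, strictly causal per (user, token) pair.

    For each event at day ``t`` whose (user, token) pair was previously seen
    at days ``s_1 < ... < s_n`` (strictly earlier events only), emits:

    ``n``
        prior repetition count (0 on first exposure),
    ``model_time``
        ``T`` over the elapsed times ``t - s_i`` (floored at ``min_elapsed``),
    ``stability``
        stability term over the history's internal lags ``s_{j+1} - s_j``,
    ``lag_1 .. lag_<max_lags>``
        raw elapsed time since the last, second-to-last, ... repetition.

    All timing features are NaN where no history exists (``n = 0``), and lag
    columns are NaN beyond the available history. The result aligns to
    ``log``'s index, one row per event.

    Raises
    ------
    ValueError
        If the log is not ordered by day within each user.
    """
    if max_lags < 1:
        raise ValueError(f"max_lags must be >= 1, got {max_lags}")
    _check_ordered(log)

    n_events = len(log)
    n_col = np.zeros(n_events, dtype=np.int64)
    mt_col = np.full(n_events, np.nan)
    st_col = np.full(n_events, np.nan)
    lag_cols = np.full((n_events, max_lags), np.nan)

    days = log["day"].to_numpy(dtype=float)
    for _, idx in log.groupby(["user", "token"], sort=False).indices.items():
        idx = np.sort(idx)
        d = days[idx]
        for i in range(len(idx)):
            n = i
            row = idx[i]
            n_col[row] = n
            if n == 0:
                continue
            prior = d[:i]
            elapsed = np.maximum(d[i] - prior, min_elapsed)
            mt_col[row] = model_time(elapsed, x)
            st_col[row] = stability(np.diff(prior))
            k = min(max_lags, n)
            # lag_1 = time since most recent repetition, ascending thereafter
            lag_cols[row, :k] = (d[i] - prior)[::-1][:k]

    out = pd.DataFrame({"n": n_col, "model_time": mt_col, "stability": st_col}, index=log.index)
    for k in range(max_lags):
        out[f"lag_{k + 1}"] = lag_cols[:, k]
    return out
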
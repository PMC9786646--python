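"""Compute PPE timing features for a single learning history.

A learner practices the word "perro" at days 0, 1, and 3, and we ask what
the predictive performance equation says about the state of that memory
just before the day-3 exposure: how many prior repetitions there were (N),
how "old" the memory is in recency-weighted terms (model time T), and how
massed or spaced the practice was (the stability term of the decay rate).
"""

import pandas as pd

from ppeboost import annotate, model_time, recency_weights, stability

history = pd.DataFrame(
    {
        "user": ["maria"] * 3,
        "token": ["perro"] * 3,
        "day": [0.0, 1.0, 3.0],
        "label": [1, 0, 0],
    }
)

features = annotate(history, x=0.6, max_lags=3)
print("Per-event PPE features (row i describes the history BEFORE event i):")
print(features.round(4).to_string())

elapsed = [3.0, 2.0]  # days since the first and second exposure, at day 3
print("\nRecency weights over elapsed times", elapsed, "->", recency_weights(elapsed).round(4))
print("Model time T =", round(model_time(elapsed), 4), "days (between min and max elapsed)")
print("Stability over the single internal lag [1.0] =", round(stability([1.0]), 4))
print(
    "\nThe first row is all-missing: a first exposure has no history. By the"
    "\nthird event the memory is N=2 repetitions old, T~2.44 days in weighted"
    "\nage, and the 1-day spacing gives a moderate stability (smaller = more"
    "\nspaced = slower forgetting)."
)
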
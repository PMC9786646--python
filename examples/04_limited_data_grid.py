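"""Where cognition-engineered features pay off: tiny training sets.

Repeatedly subsample n users x n tokens from the training set, train both
feature variants on the slice, and score the correspondingly filtered test
set. With very little data the PPE-enhanced model overtakes the default,
and fewer of its fits collapse to chance.
"""

from ppeboost import chronological_split, simulate
from ppeboost.evaluation import run_user_token_grid, summarize_grid

log, _ = simulate(seed=11)
split = chronological_split(log, 0.9)

grid = run_user_token_grid(
    split, users_levels=[5, 20, 50], tokens_levels=[5, 20, 50],
    iterations=10, master_seed=11,
)
summary = summarize_grid(grid)
cols = ["n_users", "n_tokens", "median_auc_default", "median_auc_ppe",
        "delta_pp", "at_chance_default_pct", "at_chance_ppe_pct"]
print(summary[cols].round(3).to_string(index=False))
print(
    "\ndelta_pp is the PPE-enhanced minus default median AUC in percentage "
    "points: positive in the data-starved cells, near zero in the largest. "
    "The at-chance columns show the share of fits stuck at AUC = 0.5, which "
    "shrinks as cells grow."
)
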
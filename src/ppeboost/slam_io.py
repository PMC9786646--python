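"""Event-log I/O: SLAM-format parsing, chronological splitting, test filtering.

The canonical in-memory representation of a learning log is a pandas
DataFrame (one row per *instance*, i.e. one token within one exercise) with
the columns in :data:`COLUMNS`. Required fields are ``user``, ``token``,
``day`` (days since the user's first session) and ``label`` (0 = correct,
1 = incorrect); everything else is optional exercise metadata and encoded
as missing (NaN / <NA>) when absent.

Within each user, events are ordered by day with ties preserving input
order; all downstream feature computation relies on that stable order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "REQUIRED_COLUMNS",
    "SplitLog",
    "ParseError",
    "FormatError",
    "empty_log",
    "canonicalize",
    "validate_log",
    "parse_slam",
    "chronological_split",
    "filter_test_first_repetition",
    "read_canonical",
    "write_canonical",
]

#: Canonical column order of an event log.
COLUMNS = [
    "user",
    "token",
    "day",
    "seconds",
    "label",
    "format",
    "session",
    "client",
    "countries",
    "prompt",
    "part_of_speech",
    "dependency_label",
    "root_dependency",
    "prev_token",
    "next_token",
    "exercise_total_tokens",
    "token_length",
]

REQUIRED_COLUMNS = ["user", "token", "day", "label"]

_STRING_COLUMNS = [
    "user",
    "token",
    "format",
    "session",
    "client",
    "countries",
    "prompt",
    "part_of_speech",
    "dependency_label",
    "root_dependency",
    "prev_token",
    "next_token",
]
_FLOAT_COLUMNS = ["day", "seconds"]
_INT_COLUMNS = ["exercise_total_tokens", "token_length"]


class ParseError(ValueError):
    """Raised when a SLAM-format file cannot be parsed."""


class FormatError(ValueError):
    """Raised when a canonical CSV does not match the documented schema."""


@dataclass
class SplitLog:
    """Per-user chronological train/test partition of an event log."""

    train: pd.DataFrame
    test: pd.DataFrame
    train_fraction: float


def empty_log() -> pd.DataFrame:
    """An event log with the full canonical schema and zero rows."""
    return canonicalize(pd.DataFrame({c: [] for c in COLUMNS}))


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce an event-log frame to canonical dtypes and column order.

    Missing optional columns are added as all-missing; extra columns are an
    error so silent schema drift cannot occur.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event log is missing required columns: {missing}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise FormatError(f"event log has unknown columns: {extra}")
    out = df.copy()
    for c in COLUMNS:
        if c not in out.columns:
            out[c] = pd.NA
    for c in _STRING_COLUMNS:
        out[c] = out[c].astype("string")
    for c in _FLOAT_COLUMNS:
        out[c] = pd.to_numeric(out[c], errors="raise").astype(float)
    for c in _INT_COLUMNS:
        out[c] = pd.to_numeric(out[c], errors="raise").astype("Int64")
    out["label"] = pd.to_numeric(out["label"], errors="raise").astype(np.int8)
    if len(out) and not out["label"].isin([0, 1]).all():
        raise FormatError("label column must be binary 0/1")
    return out[COLUMNS].reset_index(drop=True)


def validate_log(log: pd.DataFrame) -> None:
    """Check event-log invariants: binary labels, nonnegative non-decreasing days."""
    if len(log) == 0:
        return
    if not log["label"].isin([0, 1]).all():
        raise FormatError("label must be 0 or 1")
    if (log["day"] < 0).any():
        raise FormatError("day must be nonnegative")
    for _, grp in log.groupby("user", sort=False):
        if np.any(np.diff(grp["day"].to_numpy(dtype=float)) < 0):
            raise FormatError("day must be non-decreasing within each user")


# SLAM dialect tables. Metadata lines look like
#   # user:XEinXf5+  countries:CO  days:0.003  client:web  session:lesson  format:reverse_translate  time:9
# optionally followed by a "# prompt:..." line; token lines carry
#   <token id> <token> <part of speech> <morphology> <dependency label> <head index> [<label>]
_METADATA_KEYS = {
    "user": "user",
    "days": "day",
    "client": "client",
    "session": "session",
    "format": "format",
    "time": "seconds",
    "countries": "countries",
    "prompt": "prompt",
}
_TOKEN_LINE_FIELDS = 6  # before the optional trailing label


def _flush_exercise(meta: dict, tokens: list[dict], rows: list[dict]) -> None:
    if not tokens:
        return
    total = len(tokens)
    words = [t["token"] for t in tokens]
    for i, tok in enumerate(tokens):
        head = tok.pop("_head")
        row = dict(meta)
        row.update(tok)
        row["prev_token"] = words[i - 1] if i > 0 else None
        row["next_token"] = words[i + 1] if i < total - 1 else None
        row["exercise_total_tokens"] = total
        row["token_length"] = len(tok["token"])
        # head index is 1-based into the exercise; 0 marks the root itself
        row["root_dependency"] = words[head - 1] if 1 <= head <= total else None
        rows.append(row)
    tokens.clear()


def parse_slam(path, labeled: bool = True) -> pd.DataFrame:
    """Parse a SLAM-format text file into a canonical event log.

    Exercise metadata (user, days, format, response time, ...) is copied onto
    each of the exercise's token events; ``prev_token``/``next_token`` are
    taken from adjacent token lines of the same exercise and are absent at
    exercise boundaries.

    Parameters
    ----------
    path
        Path to a SLAM text file (UTF-8).
    labeled
        Whether token lines carry a trailing 0/1 correctness label (the
        released training files do). With ``labeled=False`` labels are set
        to 0 and must be supplied separately.
    """
    rows: list[dict] = []
    meta: dict = {}
    tokens: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                _flush_exercise(meta, tokens, rows)
                continue
            if line.startswith("#"):
                if tokens:  # metadata block starts a new exercise
                    _flush_exercise(meta, tokens, rows)
                body = line.lstrip("#").strip()
                if body.startswith("prompt:"):
                    meta["prompt"] = body[len("prompt:") :].strip()
                    continue
                meta = {}
                for field in body.split():
                    if ":" not in field:
                        raise ParseError(f"line {lineno}: malformed metadata field {field!r}")
                    key, value = field.split(":", 1)
                    col = _METADATA_KEYS.get(key)
                    if col is None:
                        warnings.warn(f"line {lineno}: ignoring unknown metadata key {key!r}")
                        continue
                    meta[col] = float(value) if col in ("day", "seconds") else value
                continue
            parts = line.split()
            if len(parts) < _TOKEN_LINE_FIELDS:
                raise ParseError(f"line {lineno}: token line has {len(parts)} fields, expected >= {_TOKEN_LINE_FIELDS}")
            if labeled:
                if len(parts) < _TOKEN_LINE_FIELDS + 1:
                    raise ParseError(f"line {lineno}: missing correctness label")
                label = parts[_TOKEN_LINE_FIELDS]
                if label not in ("0", "1"):
                    raise ParseError(f"line {lineno}: label must be 0 or 1, got {label!r}")
            else:
                label = "0"
            try:
                head = int(parts[5])
            except ValueError as err:
                raise ParseError(f"line {lineno}: dependency head must be an integer") from err
            tokens.append(
                {
                    "token": parts[1],
                    "part_of_speech": parts[2],
                    "dependency_label": parts[4],
                    "_head": head,
                    "label": int(label),
                }
            )
    _flush_exercise(meta, tokens, rows)
    if not rows:
        return empty_log()
    df = pd.DataFrame(rows)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns or df[c].isna().all()]
    if missing:
        raise ParseError(f"file is missing required fields: {missing}")
    log = canonicalize(df)
    validate_log(log)
    return log


def chronological_split(log: pd.DataFrame, train_fraction: float = 0.9) -> SplitLog:
    """Per-user chronological split: first ``floor(fraction * k)`` events to train.

    Each user's events are partitioned independently in stable order, so
    every train event precedes every test event within that user. A user
    with a single event lands entirely in test (``floor(0.9 * 1) = 0``).
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(log) == 0:
        return SplitLog(log.copy(), log.copy(), train_fraction)
    grp = log.groupby("user", sort=False)
    n_train = np.floor(train_fraction * grp["user"].transform("size")).astype(int)
    in_train = grp.cumcount() < n_train
    return SplitLog(
        train=log[in_train].reset_index(drop=True),
        test=log[~in_train].reset_index(drop=True),
        train_fraction=train_fraction,
    )


def filter_test_first_repetition(split: SplitLog, scope: str = "pair") -> pd.DataFrame:
    """Keep only each (user, token) pair's first test event, for pairs with history.

    Mirrors next-exposure forecasting: a model predicts the next repetition
    of an item it has trained on, then observes the outcome. With
    ``scope="pair"`` (default) a test event survives iff its exact
    (user, token) pair occurs in the training set; with ``scope="token"``
    it suffices that the token was seen by *any* training user. In both
    scopes only the chronologically first qualifying test event per
    (user, token) pair is retained.
    """
    if scope not in ("pair", "token"):
        raise ValueError(f"scope must be 'pair' or 'token', got {scope!r}")
    test = split.test
    if len(test) == 0 or len(split.train) == 0:
        return test.iloc[0:0].copy()
    if scope == "pair":
        train_keys = set(zip(split.train["user"], split.train["token"]))
        seen = [(u, t) in train_keys for u, t in zip(test["user"], test["token"])]
    else:
        train_tokens = set(split.train["token"])
        seen = test["token"].isin(train_tokens).tolist()
    kept = test[np.asarray(seen, dtype=bool)]
    return kept.drop_duplicates(subset=["user", "token"], keep="first").reset_index(drop=True)


def write_canonical(log: pd.DataFrame, path) -> None:
    """Write an event log as canonical CSV (header + one row per event, UTF-8)."""
    out = canonicalize(log)
    out.to_csv(path, index=False)


def read_canonical(path) -> pd.DataFrame:
    """Read a canonical CSV written by :func:`write_canonical`.

    Raises
    ------
    FormatError
        If the header does not contain the required columns or contains
        unknown ones.
    """
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in _STRING_COLUMNS},
        keep_default_na=True,
    )
    return canonicalize(df)
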
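"""Trial filtering and aggregation to the mean-RT tables the ANOVAs consume."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUB_BLOCK_LEN = 50
VALID_FACTORS = ("block", "event", "last_var")

_REQUIRED = {"subject_id", "group", "rt_ms", "correct"}


class SchemaError(ValueError):
    pass


def _check_schema(trials: pd.DataFrame, extra: Iterable[str] = ()) -> None:
    missing = (_REQUIRED | set(extra)) - set(trials.columns)
    if missing:
        raise SchemaError(f"trial table missing columns: {sorted(missing)}")


def filter_trials(
    trials: pd.DataFrame, rt_ceiling_ms: float = 2000.0
) -> tuple[pd.DataFrame, dict]:
    """Keep correct responses strictly faster than the response window.

    Returns the retained trials and an exclusion report: incorrect trials are
    counted first, then too-slow (rt >= ceiling) among the correct ones.
    """
    _check_schema(trials)
    correct = trials["correct"].astype(bool)
    fast = trials["rt_ms"] < rt_ceiling_ms
    kept = trials[correct & fast].copy()
    report = {
        "total": int(len(trials)),
        "excluded_incorrect": int((~correct).sum()),
        "excluded_too_slow": int((correct & ~fast).sum()),
        "retained": int(len(kept)),
    }
    return kept, report


def cell_means(
    trials: pd.DataFrame,
    factors: Sequence[str],
    min_cell_trials: int = 1,
    drop_no_last_var: bool = True,
    block_collapse: str = "pooled",
) -> pd.DataFrame:
    """Per-subject mean RT in each factor-level combination.

    ``factors`` is a subset of {block, event, last_var}.  When ``last_var``
    is a factor, trials before the first variable event (last_var = NONE)
    are excluded.  ``block_collapse`` controls designs that ignore block:
    "pooled" averages over all retained trials (each trial weighted equally,
    sensible because variable-event counts differ across blocks), while
    "block_mean" averages the per-block means.
    """
    factors = list(factors)
    bad = set(factors) - set(VALID_FACTORS)
    if bad:
        raise ValueError(f"unknown factors {sorted(bad)}; choose from {VALID_FACTORS}")
    _check_schema(trials, extra=factors)
    df = trials
    if "last_var" in factors and drop_no_last_var:
        df = df[df["last_var"] != "NONE"]

    keys = ["subject_id", "group"] + factors
    if block_collapse == "block_mean" and "block" not in factors:
        per_block = (
            df.groupby(keys + ["block"], observed=True)["rt_ms"]
            .agg(["mean", "size"]).reset_index()
        )
        out = per_block.groupby(keys, observed=True).agg(
            mean_rt=("mean", "mean"), n_trials=("size", "sum")
        ).reset_index()
    elif block_collapse == "pooled" or "block" in factors:
        out = df.groupby(keys, observed=True)["rt_ms"].agg(
            mean_rt="mean", n_trials="size"
        ).reset_index()
    else:
        raise ValueError(f"unknown block_collapse {block_collapse!r}")

    thin = out["n_trials"] < min_cell_trials
    if thin.any():
        log.warning("dropping %d cells with fewer than %d trials",
                    int(thin.sum()), min_cell_trials)
        out = out[~thin].reset_index(drop=True)
    return out


def subblock_means(trials: pd.DataFrame, sub_len: int = SUB_BLOCK_LEN) -> pd.DataFrame:
    """Mean RT per (subject, block, 50-trial sub-block), stimulus type ignored.

    Sub-blocks partition each block without overlap; excluded trials simply
    reduce a cell's count.
    """
    _check_schema(trials, extra=["block", "trial_in_block"])
    block_len = int(trials["trial_in_block"].max())
    if block_len % sub_len != 0:
        raise ValueError(f"block length {block_len} not divisible by {sub_len}")
    df = trials.copy()
    df["sub_block"] = (df["trial_in_block"] - 1) // sub_len + 1
    out = df.groupby(
        ["subject_id", "group", "block", "sub_block"], observed=True
    )["rt_ms"].agg(mean_rt="mean", n_trials="size").reset_index()
    return out
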
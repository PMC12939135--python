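"""Synthetic trial-level reaction-time cohorts for the serial reaction time task.

Emulates the study design the analyses assume: two groups (motor execution,
ME, and motor imagery, MI) of ``n_per_group`` subjects each, 750 trials in
5 blocks of 150, stimuli drawn from the packaged context tree, and reaction
times built additively from

    rt = group baseline + subject intercept + block effect
         + within-block sub-block slope + event-type offset
         + (event x last-variable-event) interaction + trial noise,

censored to the response window (draws outside (0, ceiling) are redrawn, and
marked incorrect after 100 failures so no point mass accumulates at the
ceiling).  Incorrect responses (probability ``error_rate``) keep their RT —
the task waited for the correct key — and are excluded downstream, not here.

The default effect sizes qualitatively mirror the study's findings (MI
improves across blocks, ME only within blocks; MI shows larger event
differentiation and a crossed event-by-last-variable interaction); they are
demonstration values, not estimates from the participant data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .context_tree import (
    ContextTree,
    annotate_last_variable,
    default_tree,
    generate_sequence,
    label_events,
)

GROUPS = ("ME", "MI")
EVENTS = ("F1", "F2", "V2", "V3")
SUB_BLOCK_LEN = 50

COHORT_COLUMNS = [
    "subject_id", "group", "block", "trial_in_block",
    "stimulus", "event", "last_var", "rt_ms", "correct",
]

# documentation-only timing constants of the task (ms); RT is measured from
# stimulus end, so these never enter generation
ANTICIPATORY_WINDOW_MS = 500
STIMULUS_DURATION_MS = 220


class ConfigError(ValueError):
    pass


def _zeros_by_group(n_blocks: int) -> dict:
    return {g: [0.0] * n_blocks for g in GROUPS}


@dataclass
class SyntheticConfig:
    """Cohort design and planted effect sizes (all RT quantities in ms)."""

    n_per_group: int = 10
    n_blocks: int = 5
    block_len: int = 150
    groups: tuple[str, ...] = GROUPS
    baseline_ms: dict = field(default_factory=lambda: {"ME": 450.0, "MI": 900.0})
    # additive per-block shift, length n_blocks
    block_effect_ms: dict = field(default_factory=lambda: {
        "ME": [0.0, 0.0, 0.0, 0.0, 0.0],
        "MI": [0.0, -40.0, -80.0, -110.0, -130.0],
    })
    # additive slope per 50-trial sub-block step, one entry per block
    within_block_slope_ms: dict = field(default_factory=lambda: {
        "ME": [-8.0, -15.0, -5.0, 0.0, 0.0],
        "MI": [-25.0, -8.0, -4.0, 0.0, 0.0],
    })
    event_offset_ms: dict = field(default_factory=lambda: {
        "ME": {"F1": 0.0, "F2": 10.0, "V2": 40.0, "V3": 5.0},
        "MI": {"F1": 0.0, "F2": 5.0, "V2": 80.0, "V3": 20.0},
    })
    # event -> last_var -> offset; crossed in MI (repetition speeds repeats)
    lastvar_interaction_ms: dict = field(default_factory=lambda: {
        "ME": {"F1": {"V2": -15.0, "V3": 15.0}, "F2": {"V2": 15.0, "V3": -15.0}},
        "MI": {"V2": {"V2": -20.0, "V3": 20.0}, "V3": {"V2": 20.0, "V3": -20.0}},
    })
    subject_sd_ms: float = 50.0
    noise_sd_ms: float = 150.0
    noise_family: str = "lognormal"  # or "gaussian"
    error_rate: float = 0.001
    rt_ceiling_ms: float = 2000.0
    shared_sequence: bool = False
    seed: int = 12345

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.block_len % SUB_BLOCK_LEN != 0:
            raise ConfigError(f"block_len must be divisible by {SUB_BLOCK_LEN}")
        if not (0 <= self.error_rate < 1):
            raise ConfigError("error_rate must lie in [0, 1)")
        if self.rt_ceiling_ms <= 0:
            raise ConfigError("rt_ceiling_ms must be positive")
        if self.noise_family not in ("gaussian", "lognormal"):
            raise ConfigError(f"unknown noise_family {self.noise_family!r}")
        for g in self.groups:
            if self.baseline_ms[g] <= 0:
                raise ConfigError(f"baseline for {g} must be positive")
            for name in ("block_effect_ms", "within_block_slope_ms"):
                vec = getattr(self, name)[g]
                if len(vec) != self.n_blocks:
                    raise ConfigError(f"{name}[{g}] must have length n_blocks")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_len

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["groups"] = tuple(payload.get("groups", GROUPS))
        return cls(**payload)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config(seed: int = 12345) -> SyntheticConfig:
    """The study-shaped design (2 x 10 subjects, 5 x 150 trials, 2 s window)."""
    cfg = SyntheticConfig(seed=seed)
    cfg.validate()
    return cfg


def null_config(seed: int = 12345) -> SyntheticConfig:
    """Baseline + subject + trial noise only; every planted effect is zero."""
    cfg = default_config(seed=seed)
    cfg = replace(
        cfg,
        block_effect_ms=_zeros_by_group(cfg.n_blocks),
        within_block_slope_ms=_zeros_by_group(cfg.n_blocks),
        event_offset_ms={g: {e: 0.0 for e in EVENTS} for g in GROUPS},
        lastvar_interaction_ms={g: {} for g in GROUPS},
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------- simulation
def _standardised_noise(rng: np.random.Generator, n: int, family: str) -> np.ndarray:
    """Mean-0, SD-1 trial noise; lognormal keeps the right skew of real RTs."""
    if family == "gaussian":
        return rng.standard_normal(n)
    s = 0.6  # fixed lognormal shape: skewness ~ 2.2
    x = np.exp(s * rng.standard_normal(n))
    mean = np.exp(s * s / 2.0)
    sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    return (x - mean) / sd


def simulate_subject(
    config: SyntheticConfig,
    group: str,
    subject_seed,
    subject_id: str | None = None,
    tree: ContextTree | None = None,
    symbols: Sequence[int] | None = None,
) -> pd.DataFrame:
    """One subject's full session as a tidy trial table.

    ``symbols`` may supply a pre-generated stimulus sequence (shared-sequence
    designs); otherwise the sequence is drawn from the subject's own stream.
    """
    config.validate()
    if group not in config.groups:
        raise ConfigError(f"unknown group {group!r}")
    tree = tree or default_tree()
    ss = (subject_seed if isinstance(subject_seed, np.random.SeedSequence)
          else np.random.SeedSequence(subject_seed))
    seq_rng, rt_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    n = config.n_trials
    if symbols is None:
        symbols = generate_sequence(tree, n, rng=seq_rng)
    symbols = np.asarray(symbols, dtype=int)
    labels = np.asarray(label_events(tree, symbols))
    last_var = np.asarray(annotate_last_variable(labels))

    block = np.arange(n) // config.block_len + 1
    trial_in_block = np.arange(n) % config.block_len + 1
    sub_block = (trial_in_block - 1) // SUB_BLOCK_LEN  # 0-based

    g = group
    det = np.full(n, config.baseline_ms[g], dtype=float)
    det += rt_rng.normal(0.0, config.subject_sd_ms)
    det += np.asarray(config.block_effect_ms[g], dtype=float)[block - 1]
    det += np.asarray(config.within_block_slope_ms[g], dtype=float)[block - 1] * sub_block
    offsets = config.event_offset_ms.get(g, {})
    det += np.array([offsets.get(lab, 0.0) for lab in labels])
    inter = config.lastvar_interaction_ms.get(g, {})
    det += np.array([inter.get(lab, {}).get(lv, 0.0) for lab, lv in zip(labels, last_var)])

    rt = det + config.noise_sd_ms * _standardised_noise(rt_rng, n, config.noise_family)
    correct = np.ones(n, dtype=bool)
    # redraw censored trials; give up after 100 attempts and mark incorrect
    for _ in range(100):
        bad = (rt <= 0) | (rt >= config.rt_ceiling_ms)
        if not bad.any():
            break
        rt[bad] = det[bad] + config.noise_sd_ms * _standardised_noise(
            rt_rng, int(bad.sum()), config.noise_family
        )
    bad = (rt <= 0) | (rt >= config.rt_ceiling_ms)
    correct[bad] = False
    rt[bad] = np.clip(rt[bad], 1.0, config.rt_ceiling_ms)

    correct &= rt_rng.random(n) >= config.error_rate

    return pd.DataFrame({
        "subject_id": subject_id or f"{group}01",
        "group": group,
        "block": block,
        "trial_in_block": trial_in_block,
        "stimulus": symbols,
        "event": labels,
        "last_var": last_var,
        "rt_ms": rt,
        "correct": correct,
    })


def simulate_cohort(
    config: SyntheticConfig,
    tree: ContextTree | None = None,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full cohort: ``n_per_group`` subjects per group, seeds derived from ``config.seed``.

    ``groups`` restricts simulation to a subset (handy for within-group
    harnesses); subject seeds are derived identically either way, so the MI
    subjects of a restricted run match those of the full run.
    """
    config.validate()
    tree = tree or default_tree()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.groups) * config.n_per_group + 1)
    shared_symbols = None
    if config.shared_sequence:
        shared_symbols = generate_sequence(
            tree, config.n_trials, rng=np.random.default_rng(children[-1])
        )
    wanted = set(groups) if groups is not None else set(config.groups)
    frames = []
    k = 0
    for g in config.groups:
        for i in range(config.n_per_group):
            child = children[k]
            k += 1
            if g not in wanted:
                continue
            frames.append(simulate_subject(
                config, g, child, subject_id=f"{g}{i + 1:02d}",
                tree=tree, symbols=shared_symbols,
            ))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["config_hash"] = config.hash()
    out.attrs["seed"] = config.seed
    return out


# ---------------------------------------------------------------------- I/O
def write_cohort_csv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={
        "subject_id": str, "group": str, "event": str, "last_var": str,
        "block": int, "trial_in_block": int, "stimulus": int,
        "rt_ms": float, "correct": bool,
    })
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df[COHORT_COLUMNS]
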
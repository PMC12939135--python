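"""The reaction-time analysis battery.

Implements, from balanced-design sums of squares:

* two-way repeated-measures ANOVA (both factors within subjects), optionally
  on pooled average ranks of the cell means (the rank-transform, RT-1,
  robustification);
* two-way mixed (split-plot) ANOVA with one between-subjects factor;
* Mauchly's sphericity test and Greenhouse-Geisser df correction per
  within-subject effect;
* Bonferroni-corrected pairwise follow-ups (paired or two-sample t);
* per-subject sub-block slope regression with one-sample t-tests;
* a simulation harness for type-I error and power of the whole pipeline.

All ANOVA tables are tidy DataFrames with columns
``effect, F, df_num, df_den, p, eps_gg, p_gg, mauchly_W, mauchly_p,
sphericity_corrected, p_report`` where ``p_report`` applies the
Greenhouse-Geisser correction exactly when Mauchly's test rejects at 0.05
(and is testable), and equals the uncorrected p otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

from . import preprocessing, synthetic

log = logging.getLogger(__name__)

ANOVA_COLUMNS = [
    "effect", "F", "df_num", "df_den", "p", "eps_gg", "p_gg",
    "mauchly_W", "mauchly_p", "sphericity_corrected", "p_report",
]


class DesignError(ValueError):
    pass


# ------------------------------------------------------------------ ranking
def rank_transform(values) -> np.ndarray:
    """Pooled average ranks 1..N (ties averaged), shape-preserving."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values cannot be ranked")
    return sps.rankdata(arr.ravel()).reshape(arr.shape)


# -------------------------------------------------------------- sphericity
def _gg_epsilon(T: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from orthonormal-contrast scores T (n x d)."""
    S = np.cov(T, rowvar=False)
    S = np.atleast_2d(S)
    d = S.shape[0]
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    if tr2 <= 0:
        return 1.0
    eps = tr * tr / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


def _mauchly(T: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square p on contrast scores T (n x d).

    Returns (nan, nan) when the covariance is singular or n is too small to
    test (d >= n), in which case sphericity is reported untestable.
    """
    n, d = T.shape
    if d < 2 or d >= n:
        return float("nan"), float("nan")
    S = np.cov(T, rowvar=False)
    det = np.linalg.det(S)
    tr = np.trace(S)
    if det <= 0 or tr <= 0:
        return float("nan"), float("nan")
    W = det / (tr / d) ** d
    # chi-square approximation with the second-order term (as in ezANOVA)
    ddof = d * (d + 1) / 2.0 - 1.0
    k = d + 1
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1))
    w2 = ((d + 2.0) * (d - 1.0) * (d - 2.0) * (2.0 * d**3 + 6.0 * d**2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    chi2 = -(n - 1) * f * np.log(W)
    p1 = sps.chi2.sf(chi2, ddof)
    p2 = sps.chi2.sf(chi2, ddof + 4)
    return float(W), float(p1 + w2 * (p2 - p1))


def _clean_ss(ss_total: float, *ss_values: float) -> list[float]:
    """Clip negative rounding residue and zero out negligible sums of squares."""
    tol = 1e-12 * max(ss_total, 1.0)
    return [0.0 if s < tol else float(s) for s in ss_values]


def _effect_row(name, ss_eff, df_eff, ss_err, df_err, T=None) -> dict:
    """Assemble one ANOVA table row; T carries the effect's contrast scores."""
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = ms_eff / ms_err if ms_err > 0 else 0.0
    F = max(F, 0.0)
    p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else (1.0 if ss_eff == 0 else 0.0)
    row = {
        "effect": name, "F": float(F), "df_num": int(df_eff), "df_den": int(df_err),
        "p": p, "eps_gg": float("nan"), "p_gg": float("nan"),
        "mauchly_W": float("nan"), "mauchly_p": float("nan"),
        "sphericity_corrected": False, "p_report": p,
    }
    if T is not None and df_eff > 1:
        eps = _gg_epsilon(T)
        row["eps_gg"] = eps
        row["p_gg"] = float(sps.f.sf(F, eps * df_eff, eps * df_err)) if ms_err > 0 else p
        W, pw = _mauchly(T)
        row["mauchly_W"], row["mauchly_p"] = W, pw
        if np.isfinite(pw) and pw < 0.05:
            row["sphericity_corrected"] = True
            row["p_report"] = row["p_gg"]
    return row


# ---------------------------------------------------------- table -> arrays
def _pivot_complete(
    table: pd.DataFrame, subject: str, factors: Sequence[str], dv: str
) -> tuple[np.ndarray, list, list[list]]:
    """Pivot a cell-mean table to a dense (n_subjects x levels...) array.

    Subjects with any missing cell are dropped (complete-case) with a logged
    warning, mirroring standard repeated-measures practice.
    """
    piv = table.pivot_table(index=subject, columns=list(factors), values=dv,
                            aggfunc="mean", observed=True, dropna=False)
    incomplete = piv.index[piv.isna().any(axis=1)].tolist()
    if incomplete:
        log.warning("complete-case reduction: dropping subjects %s", incomplete)
        warnings.warn(f"dropping subjects with missing cells: {incomplete}",
                      stacklevel=3)
        piv = piv.drop(index=incomplete)
    if len(factors) == 1:
        levels = [list(piv.columns)]
    else:
        levels = [list(piv.columns.levels[i]) for i in range(len(factors))]
    shape = (len(piv),) + tuple(len(lv) for lv in levels)
    Y = piv.to_numpy(dtype=float).reshape(shape)
    return Y, list(piv.index), levels


# ------------------------------------------------- two-way repeated measures
def rm_anova2(
    table: pd.DataFrame,
    subject: str = "subject_id",
    within: Sequence[str] = ("block", "event"),
    dv: str = "mean_rt",
    use_ranks: bool = False,
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA (both factors within subjects).

    Classical subject-crossed decomposition: each within effect is tested
    against its interaction-with-subject error stratum.  With ``use_ranks``
    the decomposition is applied to the pooled average ranks of all
    subject-by-cell means entering the design.
    """
    w1, w2 = within
    Y, subjects, (lev1, lev2) = _pivot_complete(table, subject, [w1, w2], dv)
    n, a, b = Y.shape
    if n < 2 or a < 2 or b < 2:
        raise DesignError(f"need >=2 subjects and >=2 levels per factor, got {Y.shape}")
    if use_ranks:
        Y = rank_transform(Y)

    grand = Y.mean()
    mA = Y.mean(axis=(0, 2))            # a
    mB = Y.mean(axis=(0, 1))            # b
    mS = Y.mean(axis=(1, 2))            # n
    mAB = Y.mean(axis=0)                # a x b
    mAS = Y.mean(axis=2)                # n x a
    mBS = Y.mean(axis=1)                # n x b

    ss_A = n * b * np.sum((mA - grand) ** 2)
    ss_B = n * a * np.sum((mB - grand) ** 2)
    ss_S = a * b * np.sum((mS - grand) ** 2)
    ss_AB = n * np.sum((mAB - mA[:, None] - mB[None, :] + grand) ** 2)
    ss_AS = b * np.sum((mAS - mS[:, None] - mA[None, :] + grand) ** 2)
    ss_BS = a * np.sum((mBS - mS[:, None] - mB[None, :] + grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_ABS = ss_tot - ss_A - ss_B - ss_S - ss_AB - ss_AS - ss_BS
    ss_A, ss_B, ss_AB, ss_AS, ss_BS, ss_ABS = _clean_ss(
        ss_tot, ss_A, ss_B, ss_AB, ss_AS, ss_BS, ss_ABS
    )

    # contrast scores per effect for sphericity diagnostics
    Ca, Cb = helmert(a, full=False), helmert(b, full=False)
    T_A = Y.mean(axis=2) @ Ca.T
    T_B = Y.mean(axis=1) @ Cb.T
    T_AB = Y.reshape(n, a * b) @ np.kron(Ca, Cb).T

    rows = [
        _effect_row(w1, ss_A, a - 1, ss_AS, (a - 1) * (n - 1), T_A),
        _effect_row(w2, ss_B, b - 1, ss_BS, (b - 1) * (n - 1), T_B),
        _effect_row(f"{w1} * {w2}", ss_AB, (a - 1) * (b - 1),
                    ss_ABS, (a - 1) * (b - 1) * (n - 1), T_AB),
    ]
    out = pd.DataFrame(rows, columns=ANOVA_COLUMNS)
    out.attrs.update({"n_subjects": n, "subjects": subjects,
                      "levels": {w1: lev1, w2: lev2}, "use_ranks": use_ranks})
    return out


# ----------------------------------------------------------- split-plot mixed
def mixed_anova(
    table: pd.DataFrame,
    subject: str = "subject_id",
    between: str = "group",
    within: str = "event",
    dv: str = "mean_rt",
) -> pd.DataFrame:
    """Two-way mixed (split-plot) ANOVA: one between-, one within-subjects factor.

    The between effect is tested against subjects-within-groups; the within
    effect and the interaction against the within-subjects error stratum.
    Requires balanced groups (equal subjects per between level).
    """
    groups = table[[subject, between]].drop_duplicates()
    if groups[subject].duplicated().any():
        raise DesignError("a subject appears in more than one between level")
    Y, subjects, (levels_w,) = _pivot_complete(table, subject, [within], dv)
    gmap = dict(zip(groups[subject], groups[between]))
    glabels = np.asarray([gmap[s] for s in subjects])
    glevels = sorted(set(glabels))
    counts = [int((glabels == g).sum()) for g in glevels]
    if len(glevels) < 2:
        raise DesignError("need >= 2 between-subject levels")
    if len(set(counts)) != 1:
        raise DesignError(f"unbalanced groups {dict(zip(glevels, counts))}")
    N, w = Y.shape
    g = len(glevels)
    if w < 2 or min(counts) < 2:
        raise DesignError("need >= 2 within levels and >= 2 subjects per group")

    grand = Y.mean()
    mW = Y.mean(axis=0)                                  # w
    mS = Y.mean(axis=1)                                  # N
    mG = np.array([Y[glabels == gl].mean() for gl in glevels])
    cell = np.stack([Y[glabels == gl].mean(axis=0) for gl in glevels])  # g x w

    n_g = counts[0]
    ss_G = w * n_g * np.sum((mG - grand) ** 2)
    ss_SG = w * sum(
        np.sum((mS[glabels == gl] - mG[i]) ** 2) for i, gl in enumerate(glevels)
    )
    ss_W = N * np.sum((mW - grand) ** 2)
    ss_GW = n_g * np.sum((cell - mG[:, None] - mW[None, :] + grand) ** 2)
    ss_tot = np.sum((Y - grand) ** 2)
    ss_err = ss_tot - ss_G - ss_SG - ss_W - ss_GW
    ss_G, ss_SG, ss_W, ss_GW, ss_err = _clean_ss(
        ss_tot, ss_G, ss_SG, ss_W, ss_GW, ss_err
    )

    # pooled within-group contrast scores for sphericity
    Cw = helmert(w, full=False)
    T = np.concatenate([
        (Y[glabels == gl] - Y[glabels == gl].mean(axis=0)) for gl in glevels
    ]) @ Cw.T
    # _mauchly/_gg use np.cov with n-1; pooled centering costs g dfs, accept
    rows = [
        _effect_row(between, ss_G, g - 1, ss_SG, N - g),
        _effect_row(within, ss_W, w - 1, ss_err, (w - 1) * (N - g), T),
        _effect_row(f"{between} * {within}", ss_GW, (g - 1) * (w - 1),
                    ss_err, (w - 1) * (N - g), T),
    ]
    out = pd.DataFrame(rows, columns=ANOVA_COLUMNS)
    out.attrs.update({"n_subjects": N, "groups": dict(zip(glevels, counts)),
                      "levels": {within: levels_w}})
    return out


def lastvar_rm_anova(
    table: pd.DataFrame,
    subject: str = "subject_id",
    dv: str = "mean_rt",
    use_ranks: bool = False,
) -> pd.DataFrame:
    """Event x last-variable-event repeated-measures ANOVA (one group's table)."""
    return rm_anova2(table, subject=subject, within=("event", "last_var"),
                     dv=dv, use_ranks=use_ranks)


# ----------------------------------------------------------------- pairwise
def pairwise_bonferroni(
    table: pd.DataFrame,
    factor: str,
    subject: str = "subject_id",
    dv: str = "mean_rt",
    paired: bool = True,
    family: Sequence[tuple] | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise t-tests between levels of ``factor``.

    The family defaults to all unordered level pairs; adjusted p =
    min(1, m x raw p).  Significance tiers follow the 0.05 / 0.01 convention.
    A zero-variance paired difference is flagged (p undefined).
    """
    levels = sorted(table[factor].unique())
    pairs = list(family) if family is not None else list(combinations(levels, 2))
    m = len(pairs)
    if m == 0:
        raise DesignError("empty comparison family")
    rows = []
    for la, lb in pairs:
        xa = table[table[factor] == la].set_index(subject)[dv]
        xb = table[table[factor] == lb].set_index(subject)[dv]
        if paired:
            common = xa.index.intersection(xb.index)
            d = xa.loc[common].to_numpy() - xb.loc[common].to_numpy()
            if len(d) < 2 or np.allclose(d.std(ddof=1), 0):
                t, p, df = float("nan"), float("nan"), len(d) - 1
                flag = "zero-variance difference"
            else:
                res = sps.ttest_rel(xa.loc[common], xb.loc[common])
                t, p, df, flag = res.statistic, res.pvalue, len(d) - 1, ""
        else:
            res = sps.ttest_ind(xa, xb, equal_var=True)
            t, p, df, flag = res.statistic, res.pvalue, len(xa) + len(xb) - 2, ""
        p_adj = min(1.0, m * p) if np.isfinite(p) else float("nan")
        tier = "ns"
        if np.isfinite(p_adj):
            tier = "p<0.01" if p_adj < 0.01 else ("p<0.05" if p_adj < 0.05 else "ns")
        rows.append({"level_a": la, "level_b": lb, "t": float(t), "df": int(df),
                     "p_raw": float(p), "m": m, "p_bonf": float(p_adj),
                     "tier": tier, "note": flag})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- slopes
def subblock_slopes(sb_table: pd.DataFrame, dv: str = "mean_rt") -> pd.DataFrame:
    """Per-subject OLS slope of sub-block mean RT against sub-block index."""
    rows = []
    for (sid, grp, blk), cell in sb_table.groupby(
        ["subject_id", "group", "block"], observed=True
    ):
        x = cell["sub_block"].to_numpy(dtype=float)
        y = cell[dv].to_numpy(dtype=float)
        if len(x) < 2:
            raise DesignError(f"subject {sid} block {blk}: need >= 2 sub-block means")
        slope = np.polyfit(x, y, 1)[0]
        rows.append({"subject_id": sid, "group": grp, "block": blk,
                     "slope": float(slope)})
    return pd.DataFrame(rows)


def subblock_slope_test(
    sb_table: pd.DataFrame, group: str | None = None, block: int | None = None,
    dv: str = "mean_rt",
) -> pd.DataFrame:
    """One-sample two-sided t-test of per-subject slopes against zero.

    One row per (group, block) — or the single requested cell — with the mean
    slope, t, df = n_subjects - 1 and p.  Zero slope variance is flagged.
    """
    slopes = subblock_slopes(sb_table, dv=dv)
    if group is not None:
        slopes = slopes[slopes["group"] == group]
    if block is not None:
        slopes = slopes[slopes["block"] == block]
    if slopes.empty:
        raise DesignError("no slopes in the requested group/block")
    rows = []
    for (grp, blk), cell in slopes.groupby(["group", "block"], observed=True):
        vals = cell["slope"].to_numpy()
        n = len(vals)
        if np.allclose(vals.std(ddof=1) if n > 1 else 0.0, 0.0):
            t = p = float("nan")
            note = "zero slope variance"
        else:
            res = sps.ttest_1samp(vals, 0.0)
            t, p, note = float(res.statistic), float(res.pvalue), ""
        rows.append({"group": grp, "block": blk, "n": n,
                     "mean_slope": float(vals.mean()), "t": t, "df": n - 1,
                     "p": p, "note": note})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ harness
def _design_pvalues(design: str, trials: pd.DataFrame) -> dict[str, float]:
    """Run one named analysis design on a filtered trial table; p per effect."""
    if design.startswith("rm_ranks") or design.startswith("rm"):
        use_ranks = "ranks" in design
        group = design.split(":")[1] if ":" in design else "MI"
        sub = trials[trials["group"] == group]
        tab = preprocessing.cell_means(sub, ["block", "event"])
        res = rm_anova2(tab, use_ranks=use_ranks)
    elif design == "mixed":
        tab = preprocessing.cell_means(trials, ["event"])
        res = mixed_anova(tab)
    elif design.startswith("lastvar"):
        group = design.split(":")[1] if ":" in design else "MI"
        sub = trials[trials["group"] == group]
        tab = preprocessing.cell_means(sub, ["event", "last_var"])
        res = lastvar_rm_anova(tab)
    else:
        raise ValueError(f"unknown design {design!r}")
    return dict(zip(res["effect"], res["p_report"]))


def error_rate_harness(
    config: "synthetic.SyntheticConfig",
    design: str,
    reps: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    ci_level: float = 0.99,
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of a design over simulated cohorts.

    Simulates ``reps`` cohorts (seeds derived from ``seed``), runs ``design``
    (e.g. ``"rm_ranks:MI"``, ``"mixed"``, ``"lastvar:ME"``) on filtered
    trials, and reports per-effect rejection fractions with exact
    Clopper-Pearson confidence intervals.  Under a null configuration this
    measures type-I error; under planted effects, power.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if groups is None and (design.startswith("rm") or design.startswith("lastvar")):
        grp = design.split(":")[1] if ":" in design else "MI"
        groups = [grp]
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    counts: dict[str, int] = {}
    for child in root.spawn(reps):
        cfg = replace(config, seed=int(child.generate_state(1)[0] % (2 ** 31)))
        trials = synthetic.simulate_cohort(cfg, groups=groups)
        kept, _ = preprocessing.filter_trials(trials, cfg.rt_ceiling_ms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals = _design_pvalues(design, kept)
        for eff, p in pvals.items():
            counts[eff] = counts.get(eff, 0) + int(np.isfinite(p) and p < alpha)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for eff, k in counts.items():
        lo = sps.beta.ppf(lo_q, k, reps - k + 1) if k > 0 else 0.0
        hi = sps.beta.ppf(hi_q, k + 1, reps - k) if k < reps else 1.0
        rows.append({"effect": eff, "rejections": k, "reps": reps,
                     "rate": k / reps, "ci_low": float(lo), "ci_high": float(hi),
                     "alpha": alpha, "ci_level": ci_level})
    return pd.DataFrame(rows)
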
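"""Independent brute-force oracles used to verify ctsrt's statistics.

The ANOVA oracle computes sums of squares by incremental least-squares
projection on full dummy design matrices (model-comparison route), which is
algebraically independent of the cell-mean formulas used by the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def _dummies(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Full-rank-free one-hot encoding of the interaction of ``cols``."""
    key = df[cols[0]].astype(str)
    for c in cols[1:]:
        key = key + "|" + df[c].astype(str)
    return pd.get_dummies(key, dtype=float).to_numpy()


def _rss_and_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def anova_by_projection(
    df: pd.DataFrame, y_col: str, terms: list[list[str]]
) -> dict[str, tuple[float, int]]:
    """Sequential SS and df per term via nested model comparison.

    Balanced crossed designs are orthogonal, so the sequential decomposition
    is order-free and equals the classical ANOVA sums of squares.
    Returns {term_name: (SS, df)}.
    """
    y = df[y_col].to_numpy(dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rss_prev, rank_prev = _rss_and_rank(X, y)
    out: dict[str, tuple[float, int]] = {}
    for term in terms:
        X = np.hstack([X, _dummies(df, term)])
        rss, rank = _rss_and_rank(X, y)
        out[":".join(term)] = (rss_prev - rss, rank - rank_prev)
        rss_prev, rank_prev = rss, rank
    out["residual"] = (rss_prev, n - rank_prev)
    return out


def rm_anova2_oracle(df: pd.DataFrame, subject: str, w1: str, w2: str,
                     dv: str) -> pd.DataFrame:
    """Two-way within-subjects ANOVA by projection: effects tested against
    their subject-interaction strata; the three-way cell is the AB x S residual."""
    ss = anova_by_projection(
        df, dv,
        [[subject], [w1], [w2], [w1, w2], [subject, w1], [subject, w2]],
    )
    rows = []
    for eff, err in ((w1, f"{subject}:{w1}"), (w2, f"{subject}:{w2}"),
                     (f"{w1}:{w2}", "residual")):
        ss_e, df_e = ss[eff]
        ss_r, df_r = ss[err]
        F = (ss_e / df_e) / (ss_r / df_r)
        rows.append({"effect": eff, "F": F, "df_num": df_e, "df_den": df_r,
                     "p": sps.f.sf(F, df_e, df_r)})
    return pd.DataFrame(rows)


def mixed_anova_oracle(df: pd.DataFrame, subject: str, between: str,
                       within: str, dv: str) -> pd.DataFrame:
    """Split-plot ANOVA by projection: subjects nested in groups."""
    ss = anova_by_projection(
        df, dv, [[between], [subject], [within], [between, within]]
    )
    rows = []
    ss_g, df_g = ss[between]
    ss_sg, df_sg = ss[subject]      # subjects after groups = subjects within groups
    ss_w, df_w = ss[within]
    ss_gw, df_gw = ss[f"{between}:{within}"]
    ss_r, df_r = ss["residual"]
    for eff, (se, de), (sr, dr) in (
        (between, (ss_g, df_g), (ss_sg, df_sg)),
        (within, (ss_w, df_w), (ss_r, df_r)),
        (f"{between}:{within}", (ss_gw, df_gw), (ss_r, df_r)),
    ):
        F = (se / de) / (sr / dr)
        rows.append({"effect": eff, "F": F, "df_num": de, "df_den": dr,
                     "p": sps.f.sf(F, de, dr)})
    return pd.DataFrame(rows)


def one_sample_t_power(mean: float, sd: float, n: int, alpha: float = 0.05) -> float:
    """Exact two-sided power of the one-sample t-test via the noncentral t."""
    df = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    nc = mean / (sd / np.sqrt(n))
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def longest_suffix_match(contexts, history):
    """Brute-force longest-matching-suffix scan over a context set."""
    best = None
    h = tuple(history)
    for ctx in contexts:
        c = tuple(ctx)
        if len(c) <= len(h) and (len(c) == 0 or h[len(h) - len(c):] == c):
            if best is None or len(c) > len(best):
                best = c
    return best
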
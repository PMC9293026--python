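"""ICC(3,1) reliability, split-half consistency, and inversion effects.

The test-retest and internal-consistency analyses both reduce to the
two-way fixed-effects, single-measure, consistency intraclass
correlation (Shrout & Fleiss case 3,1):

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

with MS_R the between-subject mean square and MS_E the residual mean
square after removing the session (column) effect; k = 2 throughout
(two sessions, or two split halves). Confidence limits and the one-tailed
p-value (H1: ICC > 0) come from the F statistic MS_R/MS_E with
(n - 1, (n - 1)(k - 1)) degrees of freedom.

Interpretation bands follow the convention: below .40 poor, .40 to .59
fair, .60 to .75 good, above .75 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import TrialSet


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    band: str
    defined: bool = True


def icc_3_1(scores: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1) with 95% CI and one-tailed p for an n x k score matrix.

    Rows with any missing value are dropped pairwise; the retained n is
    reported. All-identical scores leave the ICC undefined
    (``defined=False``). Requires at least 3 complete rows.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D (subjects x sessions) matrix")
    scores = scores[~np.isnan(scores).any(axis=1)]
    n, k = scores.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete rows, got {n}")

    grand = scores.mean()
    row_means = scores.mean(axis=1)
    col_means = scores.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((scores - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if ms_r + ms_e == 0:
        return ICCResult(np.nan, np.nan, np.nan, np.nan, n, "undefined", defined=False)

    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)

    if ms_e == 0:
        return ICCResult(float(icc), float(icc), float(icc), 0.0, n, categorize_icc(icc))

    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_r / ms_e
    p = float(scipy.stats.f.sf(f_obs, df1, df2))
    f_l = f_obs / scipy.stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * scipy.stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_l - 1) / (f_l + k - 1)
    ci_high = (f_u - 1) / (f_u + k - 1)
    return ICCResult(
        float(icc), float(ci_low), float(ci_high), p, n, categorize_icc(icc)
    )


def categorize_icc(value: float) -> str:
    """Interpretation band: poor / fair / good / excellent."""
    if not np.isfinite(value):
        raise ValueError("ICC value must be finite")
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value <= 0.75:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# tables over trial counts


def score_matrix(
    features: pd.DataFrame, feature: str, n_trials, key_a, key_b, key_col: str = "session"
) -> tuple:
    """Pivot a feature table into the paired (n x 2) score matrix.

    ``features`` needs columns subject, ``key_col``, n_trials and the
    feature. ``n_trials`` of None selects the all-available rows (stored
    as n_trials = -1).
    """
    nt = -1 if n_trials is None else n_trials
    sub = features[features["n_trials"] == nt]
    piv = sub.pivot_table(
        index="subject", columns=key_col, values=feature, aggfunc="first", dropna=False
    )
    if key_a not in piv.columns or key_b not in piv.columns:
        return np.empty((0, 2)), []
    piv = piv[[key_a, key_b]].dropna()
    return piv.to_numpy(), list(piv.index)


def test_retest_table(
    features: pd.DataFrame,
    feature_names,
    grid,
    sessions=(0, 1),
    key_col: str = "session",
) -> pd.DataFrame:
    """ICC(3,1) per (feature, trial count) between two sessions (or halves).

    Missing subjects are dropped pairwise per cell, so each row carries
    its own retained n.
    """
    rows = []
    for feature in feature_names:
        if feature not in features.columns:
            continue
        for n_trials in grid:
            scores, _ = score_matrix(features, feature, n_trials, *sessions, key_col=key_col)
            row = {
                "feature": feature,
                "n_trials": "all" if n_trials is None else n_trials,
                "n_subjects": len(scores),
            }
            if len(scores) >= 3:
                res = icc_3_1(scores)
                row.update(
                    icc=res.icc,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    p=res.p_value,
                    band=res.band,
                )
            else:
                row.update(icc=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan, band="n/a")
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split-half internal consistency


def split_half(ts: TrialSet, n: int, seed: int = 0) -> tuple | None:
    """Draw ``n`` clean trials and split alternating draws into halves A/B.

    Trials are drawn at random without replacement; odd draw positions go
    to A, even to B (|A| = |B| = n/2). Returns ``None`` when fewer than
    ``n`` clean trials are available.
    """
    if n % 2:
        raise ValueError("split-half needs an even n")
    clean = ts.clean_indices()
    if len(clean) < n:
        return None
    rng = np.random.default_rng(seed)
    drawn = rng.choice(clean, n, replace=False)
    return drawn[0::2], drawn[1::2]


def internal_consistency(
    features_a: pd.DataFrame, features_b: pd.DataFrame, feature_names, grid
) -> pd.DataFrame:
    """ICC(3,1) between half-A and half-B features within a session."""
    both = pd.concat(
        [features_a.assign(half="A"), features_b.assign(half="B")], ignore_index=True
    )
    if both.empty:
        return pd.DataFrame()
    return test_retest_table(both, feature_names, grid, sessions=("A", "B"), key_col="half")


# ---------------------------------------------------------------------------
# inversion effects


def inversion_effect(
    features_upright: pd.DataFrame, features_inverted: pd.DataFrame, feature_names
) -> pd.DataFrame:
    """Upright minus inverted per subject/session/n_trials; missing propagates."""
    keys = ["subject", "session", "n_trials"]
    merged = features_upright.merge(
        features_inverted, on=keys, suffixes=("_up", "_inv"), how="outer"
    )
    out = merged[keys].copy()
    for f in feature_names:
        a, b = f"{f}_up", f"{f}_inv"
        out[f] = merged[a] - merged[b] if a in merged and b in merged else np.nan
    return out


def paired_t(x, y) -> dict:
    """Paired t-test (two-sided) from explicit sums.

    Returns t, df, p, and the per-condition means/SDs. Identical columns
    give t = 0, p = 1; a nonzero constant difference (zero variance)
    leaves the statistic undefined and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    d = x - y
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    out = {
        "n": n,
        "df": n - 1,
        "mean_x": float(x.mean()),
        "sd_x": float(x.std(ddof=1)),
        "mean_y": float(y.mean()),
        "sd_y": float(y.std(ddof=1)),
        "defined": bool(sd_d > 0 or mean_d == 0),
    }
    if sd_d == 0:
        if mean_d == 0:
            out.update(t=0.0, p=1.0)
        else:
            out.update(t=float("nan"), p=float("nan"))
        return out
    t = mean_d / (sd_d / np.sqrt(n))
    out.update(t=float(t), p=float(2 * scipy.stats.t.sf(abs(t), n - 1)))
    return out
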
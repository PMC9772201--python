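"""Choice-phase participant screening.

Three criteria, each computed on the full cohort in a single pass and
then combined:

* side bias — probability of choosing the right-hand item more than
  2 cohort SDs from the cohort mean;
* fast responding — trial RT under 300 ms on more than half of the
  responded trials;
* value sanity — a per-participant logistic regression of choose-right
  on Δvalue must have a positive and significant (Wald p < 0.05) slope,
  since a participant whose choices do not track their own ratings is
  uninterpretable in a value-based task.

The per-participant logistic is a hand-vectorized 2-parameter
Newton/IRLS fit so screening stays cheap inside large power
simulations; it is cross-checked against statsmodels in the test suite.
Perfect separation (a perfectly value-consistent chooser) is detected
and resolved by the data direction: such a participant is kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .choice import responded

__all__ = [
    "simple_logistic",
    "side_bias_filter",
    "fast_rt_filter",
    "value_sanity_filter",
    "screen",
]

_SEP_SLOPE = 15.0  # |slope| beyond this is treated as separation


def simple_logistic(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None, max_iter: int = 50):
    """Batched intercept+slope logistic regression by Newton/IRLS.

    x, y, w: (n_groups, n_trials); w masks padded trials. Returns a
    dict of arrays: slope, intercept, se_slope, p_slope (Wald,
    two-sided), separated, converged.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    w = np.ones_like(x) if w is None else np.atleast_2d(np.asarray(w, float))
    g = x.shape[0]
    b0 = np.zeros(g)
    b1 = np.zeros(g)
    active = np.ones(g, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x
        mu = expit(eta)
        wt = w * mu * (1 - mu)
        g0 = (w * (y - mu)).sum(axis=1)
        g1 = (w * (y - mu) * x).sum(axis=1)
        h00 = wt.sum(axis=1)
        h01 = (wt * x).sum(axis=1)
        h11 = (wt * x * x).sum(axis=1)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.nan_to_num(d0)
        d1 = np.nan_to_num(d1)
        step = np.clip(np.abs(np.stack([d0, d1])).max(axis=0), None, None)
        scale = np.where(step > 5.0, 5.0 / np.maximum(step, 1e-12), 1.0)
        b0 = b0 + active * scale * d0
        b1 = b1 + active * scale * d1
        moved = np.maximum(np.abs(d0), np.abs(d1))
        active = active & (moved > 1e-8) & (np.abs(b1) < _SEP_SLOPE * 2)
        if not active.any():
            break
    separated = np.abs(b1) >= _SEP_SLOPE
    converged = ~active | separated
    # Wald SE from the final information matrix
    eta = b0[:, None] + b1[:, None] * x
    mu = expit(eta)
    wt = w * mu * (1 - mu)
    h00 = wt.sum(axis=1)
    h01 = (wt * x).sum(axis=1)
    h11 = (wt * x * x).sum(axis=1)
    det = h00 * h11 - h01**2
    with np.errstate(invalid="ignore", divide="ignore"):
        se1 = np.sqrt(np.where(det > 0, h00 / det, np.nan))
        z = b1 / se1
    p = 2.0 * norm.sf(np.abs(z))
    return {
        "intercept": b0,
        "slope": b1,
        "se_slope": se1,
        "p_slope": p,
        "separated": separated,
        "converged": converged,
    }


def _per_participant(trials: pd.DataFrame):
    t = responded(trials)
    return t, t.groupby("participant_id", sort=True)


def side_bias_filter(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag participants whose P(choose right) is > 2 sample SDs from
    the cohort mean (strict inequality; SD 0 excludes nobody)."""
    t, g = _per_participant(trials)
    if t["participant_id"].nunique() < 3:
        raise ValueError("side-bias screening needs at least 3 participants")
    p_right = g.apply(lambda s: float((s["choice"] == "right").mean()), include_groups=False)
    mean, sd = p_right.mean(), p_right.std(ddof=1)
    excl = (p_right - mean).abs() > 2 * sd if sd > 0 else pd.Series(False, index=p_right.index)
    return pd.DataFrame({"p_right": p_right, "side_bias_excluded": excl})


def fast_rt_filter(trials: pd.DataFrame, threshold_ms: float = 300.0, fraction: float = 0.5) -> pd.DataFrame:
    """Flag participants with RT < threshold on more than ``fraction``
    of their responded trials (strictly more than)."""
    t, g = _per_participant(trials)
    frac_fast = g.apply(lambda s: float((s["rt_ms"] < threshold_ms).mean()), include_groups=False)
    return pd.DataFrame({"frac_fast": frac_fast, "fast_rt_excluded": frac_fast > fraction})


def value_sanity_filter(trials: pd.DataFrame, alpha: float = 0.05, min_trials: int = 10) -> pd.DataFrame:
    """Per-participant logistic regression of choose-right on Δvalue;
    excluded iff the slope is non-positive or non-significant.

    Perfect separation: the slope sign is taken from the data direction
    and p is treated as < alpha, so a perfectly value-consistent
    participant is kept. Non-convergence or too few trials excludes the
    participant (flagged)."""
    t, g = _per_participant(trials)
    sizes = g.size()
    pids = list(sizes.index)
    n_max = int(sizes.max())
    k = len(pids)
    x = np.zeros((k, n_max))
    y = np.zeros((k, n_max))
    w = np.zeros((k, n_max))
    for i, (pid, s) in enumerate(g):
        n = len(s)
        x[i, :n] = s["delta_value"].to_numpy(float)
        y[i, :n] = (s["choice"] == "right").to_numpy(float)
        w[i, :n] = 1.0
    fit = simple_logistic(x, y, w)
    slope = fit["slope"]
    p = fit["p_slope"]
    sep = fit["separated"]
    conv = fit["converged"]
    n_trials = sizes.reindex(pids).to_numpy()
    # separation: direction decides, p treated as < alpha
    p_eff = np.where(sep, 0.0, p)
    keep = (slope > 0) & (p_eff < alpha) & conv & (n_trials >= min_trials)
    return pd.DataFrame(
        {
            "dv_slope": slope,
            "dv_p": p,
            "dv_separated": sep,
            "dv_converged": conv,
            "n_responded": n_trials,
            "value_sanity_excluded": ~keep,
        },
        index=pd.Index(pids, name="participant_id"),
    )


def screen(trials: pd.DataFrame) -> pd.DataFrame:
    """Full screening report: all three criteria, computed on the full
    cohort in one pass, plus the combined ``kept`` flag."""
    side = side_bias_filter(trials)
    fast = fast_rt_filter(trials)
    value = value_sanity_filter(trials)
    report = side.join(fast, how="outer").join(value, how="outer")
    report["kept"] = ~(
        report["side_bias_excluded"].fillna(True)
        | report["fast_rt_excluded"].fillna(True)
        | report["value_sanity_excluded"].fillna(True)
    )
    report.index.name = "participant_id"
    return report


def kept_trials(trials: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Responded trials of the participants that survive screening."""
    kept = report.index[report["kept"]]
    return responded(trials[trials["participant_id"].isin(kept)])
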
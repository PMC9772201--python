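"""Continuous-recognition design and memorability scoring.

A recognition stream shows one item per trial; a small set of *targets*
repeats after a long delay (> 60 intervening trials) and is scored,
while *fillers* pad the gaps, some repeating after 1–7 trials as
attention probes. An item's memorability is its corrected recognition
(CR): hit rate minus false-alarm rate over the participants who saw it
as a target. Cross-participant consistency of the per-item scores is
quantified by repeated split-half Spearman correlations against a
label-shuffled permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._rng import substream

__all__ = [
    "StreamDesign",
    "ConsistencyResult",
    "build_stream",
    "build_streams",
    "validate_stream",
    "assignment_balance",
    "exclude_memory_participants",
    "score_memorability",
    "participant_item_scores",
    "split_half_consistency",
    "rank_consistency_curve",
]

logger = logging.getLogger(__name__)

ROLES = ("target_first", "target_repeat", "filler_first", "filler_repeat")


@dataclass(frozen=True)
class StreamDesign:
    """Constraints for one participant's recognition stream."""

    n_targets: int = 29
    n_fillers: int = 109
    min_target_gap: int = 61  # repeat_index - first_index >= this (i.e. > 60 trials)
    filler_gap_range: tuple[int, int] = (1, 7)
    filler_repeat_fraction: float = 0.5
    max_retries: int = 1000

    @property
    def n_filler_repeats(self) -> int:
        return int(round(self.filler_repeat_fraction * self.n_fillers))

    @property
    def n_trials(self) -> int:
        return 2 * self.n_targets + self.n_fillers + self.n_filler_repeats


class StreamConstructionError(RuntimeError):
    """Raised when no valid stream is found within the retry budget."""


def _place_pairs(
    free: np.ndarray, n_pairs: int, gap_lo: int, gap_hi: int | None, rng: np.random.Generator
) -> list[tuple[int, int]] | None:
    """Place n_pairs (first, repeat) slot pairs with repeat-first gap in
    [gap_lo, gap_hi] (gap_hi=None means unbounded). Mutates ``free``.
    Returns None on a dead end."""
    n = len(free)
    pairs = []
    for _ in range(n_pairs):
        idx = np.flatnonzero(free)
        rng.shuffle(idx)
        placed = False
        for f in idx:
            hi = n if gap_hi is None else min(n, f + gap_hi + 1)
            lo = f + gap_lo
            if lo >= n:
                continue
            cands = np.flatnonzero(free[lo:hi])
            if len(cands) == 0:
                continue
            r = lo + rng.choice(cands)
            free[f] = free[r] = False
            pairs.append((int(f), int(r)))
            placed = True
            break
        if not placed:
            return None
    return pairs


def build_stream(
    item_ids,
    design: StreamDesign = StreamDesign(),
    seed: int | np.random.Generator = 0,
    participant_id=0,
) -> pd.DataFrame:
    """Build one participant's stream satisfying the spacing constraints.

    Targets and fillers are drawn uniformly at random from ``item_ids``
    per participant. Construction is by rejection sampling: target
    first/repeat slot pairs are placed first (long gaps), then the
    short-gap filler repeats, then the remaining slots are filled with
    one-shot fillers; any dead end restarts the attempt, up to
    ``design.max_retries`` attempts.

    Returns a DataFrame (participant_id, trial_index, item_id, role).
    """
    item_ids = np.asarray(item_ids)
    d = design
    if d.n_targets + d.n_fillers > len(item_ids):
        raise ValueError("n_targets + n_fillers exceeds the item count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    chosen = rng.choice(item_ids, size=d.n_targets + d.n_fillers, replace=False)
    targets, fillers = chosen[: d.n_targets], chosen[d.n_targets :]
    repeating = rng.choice(fillers, size=d.n_filler_repeats, replace=False)
    repeating_set = set(repeating.tolist())
    once = np.array([f for f in fillers if f not in repeating_set])

    n = d.n_trials
    for _ in range(d.max_retries):
        free = np.ones(n, dtype=bool)
        tpairs = _place_pairs(free, d.n_targets, d.min_target_gap, None, rng)
        if tpairs is None:
            continue
        fpairs = _place_pairs(free, d.n_filler_repeats, d.filler_gap_range[0], d.filler_gap_range[1], rng)
        if fpairs is None:
            continue
        item = np.empty(n, dtype=item_ids.dtype)
        role = np.empty(n, dtype=object)
        for t, (f, r) in zip(targets, tpairs):
            item[f], role[f] = t, "target_first"
            item[r], role[r] = t, "target_repeat"
        for fl, (f, r) in zip(repeating, fpairs):
            item[f], role[f] = fl, "filler_first"
            item[r], role[r] = fl, "filler_repeat"
        rest = np.flatnonzero(free)
        assert len(rest) == len(once)
        perm = rng.permutation(len(once))
        item[rest] = once[perm]
        role[rest] = "filler_first"
        return pd.DataFrame(
            {
                "participant_id": participant_id,
                "trial_index": np.arange(n),
                "item_id": item,
                "role": role,
            }
        )
    raise StreamConstructionError(
        f"no valid stream found in {d.max_retries} attempts for design {d}"
    )


def build_streams(
    item_ids, n_participants: int, design: StreamDesign = StreamDesign(), seed: int = 0
) -> pd.DataFrame:
    """Independent streams for a cohort, concatenated long-format."""
    rng = substream(seed, "streams")
    return pd.concat(
        [build_stream(item_ids, design, rng, participant_id=p) for p in range(n_participants)],
        ignore_index=True,
    )


def validate_stream(stream: pd.DataFrame, design: StreamDesign = StreamDesign()) -> None:
    """Re-verify every stream invariant; raises ValueError on violation."""
    for pid, s in stream.groupby("participant_id"):
        s = s.sort_values("trial_index")
        if not np.array_equal(s["trial_index"].to_numpy(), np.arange(len(s))):
            raise ValueError(f"participant {pid}: trial_index not contiguous from 0")
        bad = set(s["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"participant {pid}: unknown roles {bad}")
        counts = s.groupby("item_id", sort=False).size()
        if (counts > 2).any():
            raise ValueError(f"participant {pid}: an item appears more than twice")
        pos = s.set_index("trial_index")
        by_item = s.groupby("item_id")
        n_targets = 0
        n_fillers = 0
        for item, grp in by_item:
            roles = sorted(grp["role"])
            idx = np.sort(grp["trial_index"].to_numpy())
            if roles == ["target_first", "target_repeat"]:
                n_targets += 1
                if idx[1] - idx[0] < design.min_target_gap:
                    raise ValueError(f"participant {pid}: target {item} gap {idx[1]-idx[0]} too short")
            elif roles == ["filler_first", "filler_repeat"]:
                n_fillers += 1
                gap = idx[1] - idx[0]
                lo, hi = design.filler_gap_range
                if not lo <= gap <= hi:
                    raise ValueError(f"participant {pid}: filler {item} gap {gap} outside [{lo},{hi}]")
            elif roles == ["filler_first"]:
                n_fillers += 1
            else:
                raise ValueError(f"participant {pid}: item {item} has inconsistent roles {roles}")
        if n_targets != design.n_targets:
            raise ValueError(f"participant {pid}: {n_targets} targets, expected {design.n_targets}")
        if n_fillers != design.n_fillers:
            raise ValueError(f"participant {pid}: {n_fillers} fillers, expected {design.n_fillers}")
        del pos


def assignment_balance(streams: pd.DataFrame, item_ids=None) -> pd.Series:
    """Per-item count of participants for whom the item was a target.

    The mean count equals n_participants * n_targets / n_items exactly
    when ``item_ids`` covers the full bank.
    """
    if streams.empty:
        raise ValueError("need at least one stream")
    t = streams[streams["role"] == "target_first"]
    counts = t.groupby("item_id")["participant_id"].nunique()
    if item_ids is None:
        item_ids = np.unique(streams["item_id"])
    return counts.reindex(item_ids, fill_value=0).rename("n_times_target")


def _check_alignment(log: pd.DataFrame) -> None:
    required = {"participant_id", "trial_index", "item_id", "role", "pressed"}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"recognition log missing columns: {sorted(missing)}")


def exclude_memory_participants(log: pd.DataFrame, min_hits: int = 3, min_cr: int = 3):
    """Memory-task screening: a participant is excluded iff they have
    fewer than ``min_hits`` hits (presses on target repeats) or fewer
    than ``min_cr`` correct rejections (no-press on any first
    presentation). Returns (kept_ids, excluded_ids)."""
    _check_alignment(log)
    is_hit = (log["role"] == "target_repeat") & log["pressed"]
    is_first = log["role"].isin(["target_first", "filler_first"])
    is_corr_rej = is_first & ~log["pressed"]
    g = log.assign(hit=is_hit, cr=is_corr_rej).groupby("participant_id")[["hit", "cr"]].sum()
    kept_mask = (g["hit"] >= min_hits) & (g["cr"] >= min_cr)
    kept = g.index[kept_mask].tolist()
    excluded = g.index[~kept_mask].tolist()
    return kept, excluded


def participant_item_scores(log: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-item CR contribution.

    For each (participant, item-as-target): hit indicator minus
    false-alarm indicator, in {-1, 0, 1}; NaN where the item was not
    that participant's target. This matrix is the input to the
    split-half consistency analysis.
    """
    _check_alignment(log)
    t = log[log["role"].isin(["target_first", "target_repeat"])]
    hit = (
        t[t["role"] == "target_repeat"]
        .pivot(index="participant_id", columns="item_id", values="pressed")
        .astype(float)
    )
    fa = (
        t[t["role"] == "target_first"]
        .pivot(index="participant_id", columns="item_id", values="pressed")
        .astype(float)
    )
    idx = hit.index.union(fa.index)
    cols = hit.columns.union(fa.columns)
    return hit.reindex(index=idx, columns=cols) - fa.reindex(index=idx, columns=cols)


def score_memorability(log: pd.DataFrame, item_ids=None) -> pd.DataFrame:
    """Per-item memorability table: hit rate, false-alarm rate and
    corrected recognition (CR = hit - fa), computed over the
    participants for whom the item was a target.

    Items that were never a target are flagged in
    ``result.attrs["missing_items"]`` and omitted, never silently
    scored as zero.
    """
    _check_alignment(log)
    t = log[log["role"].isin(["target_first", "target_repeat"])]
    hit = t[t["role"] == "target_repeat"].groupby("item_id")["pressed"].mean()
    fa = t[t["role"] == "target_first"].groupby("item_id")["pressed"].mean()
    n = t[t["role"] == "target_first"].groupby("item_id")["participant_id"].nunique()
    table = pd.DataFrame({"hit_rate": hit, "fa_rate": fa, "n_target_participants": n})
    table["cr"] = table["hit_rate"] - table["fa_rate"]
    table = table[["hit_rate", "fa_rate", "cr", "n_target_participants"]]
    missing: list = []
    if item_ids is not None:
        missing = [i for i in np.asarray(item_ids) if i not in table.index]
        if missing:
            logger.warning("items never assigned as target: %s", missing)
    table.index.name = "item_id"
    table = table.reset_index()
    table.attrs["missing_items"] = missing
    return table


# ---------------------------------------------------------------------------
# split-half consistency


@dataclass(frozen=True)
class ConsistencyResult:
    """Split-half consistency of per-item scores across participants."""

    mean_rho: float
    rhos: np.ndarray  # per-iteration observed Spearman rho
    null_rhos: np.ndarray  # permuted-chance distribution of mean rho
    p_value: float
    n_iterations: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.mean_rho <= 1.0:
            raise ValueError("mean_rho outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value outside (0, 1]")


def _half_masks(n_part: int, n_iter: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint halves for each iteration, as 0/1 matrices."""
    h1 = np.zeros((n_iter, n_part))
    for b in range(n_iter):
        perm = rng.permutation(n_part)
        h1[b, perm[: n_part // 2]] = 1.0
    h2 = 1.0 - h1
    return h1, h2


def _half_item_means(h: np.ndarray, x0: np.ndarray, m: np.ndarray) -> np.ndarray:
    """nanmean over the selected participants, per item: (B, I)."""
    sums = h @ x0
    counts = h @ m
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _spearman_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho with pairwise-complete item drop.

    Items unscored in either half of an iteration are dropped for that
    iteration (average ranks for ties, the standard treatment).
    """
    out = np.empty(len(a))
    valid = np.isfinite(a) & np.isfinite(b)
    full = valid.all(axis=1)
    if full.any():
        ra = rankdata(a[full], axis=1)
        rb = rankdata(b[full], axis=1)
        ra -= ra.mean(axis=1, keepdims=True)
        rb -= rb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[full] = np.where(denom > 0, (ra * rb).sum(axis=1) / denom, 0.0)
    for i in np.flatnonzero(~full):
        v = valid[i]
        if v.sum() < 3:
            out[i] = 0.0
            continue
        ra = rankdata(a[i, v])
        rb = rankdata(b[i, v])
        ra = ra - ra.mean()
        rb = rb - rb.mean()
        denom = np.sqrt((ra**2).sum() * (rb**2).sum())
        out[i] = (ra * rb).sum() / denom if denom > 0 else 0.0
    return out


def _iteration_rhos(
    x0: np.ndarray,
    m: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    chunk: int = 4096,
) -> np.ndarray:
    """Split-half rhos over fresh random halves."""
    n_part, n_items = x0.shape
    rhos = np.empty(n_iter)
    done = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        h1, h2 = _half_masks(n_part, b, rng)
        a = _half_item_means(h1, x0, m)
        c = _half_item_means(h2, x0, m)
        rhos[done : done + b] = _spearman_rows(a, c)
        done += b
    return rhos


def _scramble_rows(x0: np.ndarray, m: np.ndarray, rng: np.random.Generator):
    """Independently permute each participant's item labels (the
    randomization-null transformation: valid when, absent item signal,
    scores are exchangeable across items within participant)."""
    order = np.argsort(rng.random(x0.shape), axis=1)
    return np.take_along_axis(x0, order, axis=1), np.take_along_axis(m, order, axis=1)


def split_half_consistency(
    scores: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 0,
    n_null: int | None = None,
) -> ConsistencyResult:
    """Split-half consistency with a permutation null.

    Each iteration splits participants into two random disjoint halves,
    computes per-half item CR, and takes the Spearman rank correlation
    over items; ``mean_rho`` averages the iterations. The permuted-
    chance distribution repeats the entire ``n_iter``-iteration
    procedure on label-scrambled data: each null draw independently
    shuffles every participant's item labels (destroying any shared
    item signal while preserving participant-level structure and the
    target-assignment pattern), making the observed statistic the
    identity member of an exact randomization family, so
    p = (1 + #{null draws >= mean_rho}) / (n_null + 1) is calibrated
    (uniform under the no-signal null).

    ``scores``: participants x items matrix of per-participant item
    scores (NaN where the item was not the participant's target).
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 participants for split-half analysis")
    if n_null is None:
        n_null = n_iter
    x = scores.to_numpy(float)
    m = np.isfinite(x).astype(float)
    x0 = np.where(np.isfinite(x), x, 0.0)
    rng = substream(seed, "split_half")

    rhos = _iteration_rhos(x0, m, n_iter, rng)
    mean_rho = float(rhos.mean())
    null_means = np.empty(n_null)
    for j in range(n_null):
        xs, ms = _scramble_rows(x0, m, rng)
        null_means[j] = _iteration_rhos(xs, ms, n_iter, rng).mean()
    p = (1.0 + np.sum(null_means >= mean_rho)) / (n_null + 1.0)
    return ConsistencyResult(
        mean_rho=mean_rho,
        rhos=rhos,
        null_rhos=null_means,
        p_value=float(p),
        n_iterations=n_iter,
    )


def rank_consistency_curve(scores: pd.DataFrame, n_iter: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Plot-ready split-half curve: items ranked by group-1 CR, with the
    group-1, group-2 and label-shuffled (chance) mean scores at each
    rank, averaged over iterations."""
    x = scores.to_numpy(float)
    m = np.isfinite(x).astype(float)
    x0 = np.where(np.isfinite(x), x, 0.0)
    n_part, n_items = x.shape
    rng = substream(seed, "rank_curve")
    g1 = np.zeros(n_items)
    g2 = np.zeros(n_items)
    null = np.zeros(n_items)
    h1, h2 = _half_masks(n_part, n_iter, rng)
    a = _half_item_means(h1, x0, m)
    c = _half_item_means(h2, x0, m)
    for b in range(n_iter):
        order = np.argsort(-np.where(np.isfinite(a[b]), a[b], -np.inf), kind="stable")
        g1 += np.nan_to_num(a[b, order])
        g2 += np.nan_to_num(c[b, order])
        null += np.nan_to_num(c[b, rng.permutation(n_items)][order])
    return pd.DataFrame(
        {
            "rank": np.arange(1, n_items + 1),
            "group1_mean": g1 / n_iter,
            "group2_mean": g2 / n_iter,
            "null_mean": null / n_iter,
        }
    )
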
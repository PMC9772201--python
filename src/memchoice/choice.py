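"""Choice-trial construction from subjective-value ratings.

Each participant rates every item on a 0–10 slider; ratings are
z-scored within participant, items are ranked by value, and two pair
sets are formed: *close* pairs of adjacent ranks (rank 2k-1 vs 2k) and
*far* pairs half the ranking apart (rank k vs k + n/2), so every item
appears exactly twice, once per pair type. Trials carry the signed,
right-minus-left covariates Δvalue and Δmem (memorability z-scored once
across items and shared by all participants), their absolute values,
and SumMem, the pair's summed memorability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "zscore_ratings",
    "rank_items",
    "build_choice_pairs",
    "zscore_memorability",
    "assemble_choice_trials",
    "median_split",
    "responded",
]


def zscore_ratings(table: pd.DataFrame) -> pd.DataFrame:
    """Within-participant z-scores of ratings (sample SD, n-1).

    Zero-variance participants get z = 0 and a ``zero_variance`` flag
    (candidates for downstream exclusion). Idempotent on already
    z-scored data.
    """
    if not {"participant_id", "item_id", "rating"} <= set(table.columns):
        raise ValueError("ratings table needs participant_id, item_id, rating")
    out = table.copy()
    g = out.groupby("participant_id")["rating"]
    mean = g.transform("mean")
    sd = g.transform(lambda s: s.std(ddof=1))
    flagged = sd.fillna(0.0) == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (out["rating"] - mean) / sd
    out["z_value"] = np.where(flagged, 0.0, z)
    out["zero_variance"] = flagged
    return out


def rank_items(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Per-participant value ranking, 1 = highest value.

    The order is a strict total order: rating ties are broken uniformly
    at random with a participant-scoped substream, reproducibly under
    ``seed``.
    """
    col = "z_value" if "z_value" in table.columns else "rating"
    frames = []
    for pid, grp in table.groupby("participant_id"):
        rng = substream(seed, f"rank/{pid}")
        jitter = rng.random(len(grp))
        order = np.lexsort((jitter, -grp[col].to_numpy(float)))
        ranks = np.empty(len(grp), dtype=int)
        ranks[order] = np.arange(1, len(grp) + 1)
        frames.append(grp.assign(value_rank=ranks))
    return pd.concat(frames).sort_index()


def build_choice_pairs(ranking: pd.DataFrame, far_offset: int | None = None) -> pd.DataFrame:
    """Close + far pairs from one participant's (or many participants')
    value ranking.

    Close pairs join adjacent ranks (2k-1, 2k); far pairs join rank k
    with rank k + far_offset (default n/2, the unique disjoint
    half-split). For n items this yields n unique pairs, n/2 per type,
    with every item appearing exactly twice.
    """
    frames = []
    for pid, grp in ranking.groupby("participant_id"):
        n = len(grp)
        if n % 2 != 0:
            raise ValueError(f"participant {pid}: n_items must be even, got {n}")
        off = n // 2 if far_offset is None else far_offset
        if off != n // 2:
            # arbitrary offsets cannot keep every item's degree at 2 in
            # a disjoint pairing unless off == n/2; allowed but checked
            if n % (2 * off) != 0:
                raise ValueError(f"far_offset {off} incompatible with n_items {n}")
        by_rank = grp.sort_values("value_rank")["item_id"].to_numpy()
        close_lo = by_rank[0::2]
        close_hi = by_rank[1::2]
        if off == n // 2:
            far_lo = by_rank[:off]
            far_hi = by_rank[off:]
        else:
            far_lo, far_hi = [], []
            for block in range(0, n, 2 * off):
                far_lo.extend(by_rank[block : block + off])
                far_hi.extend(by_rank[block + off : block + 2 * off])
            far_lo, far_hi = np.asarray(far_lo), np.asarray(far_hi)
        pairs = pd.DataFrame(
            {
                "participant_id": pid,
                "item_hi": np.concatenate([close_lo, far_lo]),  # better rank = higher value
                "item_lo": np.concatenate([close_hi, far_hi]),
                "pair_type": ["close"] * (n // 2) + ["far"] * (n // 2),
            }
        )
        rank_of = grp.set_index("item_id")["value_rank"]
        pairs["rank_distance"] = (
            rank_of.reindex(pairs["item_lo"]).to_numpy() - rank_of.reindex(pairs["item_hi"]).to_numpy()
        )
        frames.append(pairs)
    return pd.concat(frames, ignore_index=True)


def zscore_memorability(mem_table: pd.DataFrame) -> pd.Series:
    """Memorability (CR) z-scored once across items; shared by all
    participants. Sample SD (n-1)."""
    cr = mem_table.set_index("item_id")["cr"].astype(float)
    sd = cr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("memorability scores have zero variance; cannot z-score")
    return ((cr - cr.mean()) / sd).rename("z_mem")


def assemble_choice_trials(
    pairs: pd.DataFrame,
    z_values: pd.DataFrame,
    z_mem: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """One trial per pair: shuffled order, random left/right placement,
    and the Δ/|Δ|/Sum covariates.

    delta_value = z_value(right) - z_value(left) (within-participant
    z-scores); delta_mem likewise with the across-item memorability
    z-scores; sum_mem = z_mem(right) + z_mem(left).
    """
    missing = set(pd.unique(pairs[["item_lo", "item_hi"]].to_numpy().ravel())) - set(z_mem.index)
    if missing:
        raise ValueError(f"memorability missing for items: {sorted(missing)[:5]}")
    zv = z_values.set_index(["participant_id", "item_id"])["z_value"]
    frames = []
    for pid, grp in pairs.groupby("participant_id"):
        rng = substream(seed, f"trials/{pid}")
        grp = grp.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
        right_is_hi = rng.random(len(grp)) < 0.5
        right = np.where(right_is_hi, grp["item_hi"], grp["item_lo"])
        left = np.where(right_is_hi, grp["item_lo"], grp["item_hi"])
        zr = zv.reindex(pd.MultiIndex.from_arrays([np.repeat(pid, len(grp)), right])).to_numpy()
        zl = zv.reindex(pd.MultiIndex.from_arrays([np.repeat(pid, len(grp)), left])).to_numpy()
        mr = z_mem.reindex(right).to_numpy()
        ml = z_mem.reindex(left).to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "trial_index": np.arange(len(grp)),
                    "left_item": left,
                    "right_item": right,
                    "pair_type": grp["pair_type"].to_numpy(),
                    "delta_value": zr - zl,
                    "delta_mem": mr - ml,
                    "abs_delta_value": np.abs(zr - zl),
                    "abs_delta_mem": np.abs(mr - ml),
                    "sum_mem": mr + ml,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def responded(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials with a response (choice != 'none')."""
    if "choice" not in trials.columns:
        return trials
    return trials[trials["choice"] != "none"]


def median_split(trials: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Low half of responded trials by the pooled median of ``variable``.

    Trials strictly below the pooled median are taken; ties at the
    median are then assigned to the low half in stable trial order until
    the halves are as equal as possible.
    """
    if variable not in ("abs_delta_mem", "abs_delta_value"):
        raise ValueError("variable must be abs_delta_mem or abs_delta_value")
    t = responded(trials)
    if len(t) < 2:
        raise ValueError("need at least 2 responded trials")
    v = t[variable].to_numpy(float)
    med = float(np.median(v))
    below = v < med
    target = len(t) // 2
    take = below.copy()
    deficit = target - int(below.sum())
    if deficit > 0:
        at = np.flatnonzero(v == med)[:deficit]
        take[at] = True
    return t.iloc[np.flatnonzero(take)]
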
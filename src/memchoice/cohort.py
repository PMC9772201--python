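"""Synthetic cohort generator.

Emulates a two-part behavioural study on food-item memorability and
value-based choice: (1) a continuous-recognition "memory game" from which
per-item memorability is scored, and (2) a rating + two-alternative
forced-choice task from which value effects on choice are estimated.
Items carry two latent traits — a hit propensity ``theta_mem`` and a
false-alarm propensity ``phi_fa`` on the logit scale, plus a population
mean subjective value ``mu_value`` on the 0–10 rating scale — coupled
through a Gaussian copula so the memorability/value correlation is a
single tunable parameter.

All randomness flows from one root seed through named substreams
("items", "recognition", "ratings", "choices"), so any stage can be
regenerated independently and identical configs give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from ._rng import substream

__all__ = [
    "ItemBank",
    "CohortConfig",
    "LogisticChoiceParams",
    "make_item_bank",
    "simulate_recognition",
    "simulate_ratings",
    "simulate_choices",
]

# Pearson attenuation of corr(z, 10*Phi(w)) relative to corr(z, w) for a
# bivariate normal (z, w): corr = rho * sqrt(3/pi). The latent copula
# correlation is pre-corrected by the inverse factor.
_PHI_ATTENUATION = float(np.sqrt(3.0 / np.pi))


@dataclass(frozen=True)
class LogisticChoiceParams:
    """Generative twin of the fixed effects in the choice mixed model.

    ``beta_mem = 0`` is the null world: memorability has no causal effect
    on choice. The ``sd_*`` fields add by-subject heterogeneity (random
    intercepts/slopes) so fitted mixed models face a realistic random
    structure. RT is lognormal with log-mean decreasing in |Δvalue|.
    """

    beta0: float = 0.0
    beta_value: float = float(np.log(3.6))
    beta_mem: float = 0.0
    sd_beta0: float = 0.3
    sd_beta_value: float = 0.5
    sd_beta_mem: float = 0.0
    rt_log_mean: float = 0.0  # log seconds at |delta_value| = 0
    rt_value_slope: float = -0.04  # on log RT per z-unit |delta_value|
    rt_log_sd: float = 0.4
    rt_sd_subject: float = 0.15  # by-subject SD of the log-RT intercept
    rt_sd_value_slope: float = 0.02  # by-subject SD of the |delta_value| RT slope

    def __post_init__(self) -> None:
        for name in ("beta0", "beta_value", "beta_mem"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale configuration for the synthetic cohort.

    Defaults mirror the study design this package emulates: 138 items,
    199 recognition participants each seeing 29 targets and 109 fillers,
    and 44 choice participants rating all items and completing 138
    choice trials.
    """

    n_items: int = 138
    n_mem_participants: int = 199
    n_choice_participants: int = 44
    mem_value_corr: float = 0.15
    rating_noise_sd: float = 2.0
    modality: str = "image"
    # item latent distributions (logit scale)
    theta_loc: float = 0.4
    theta_scale: float = 0.35
    phi_loc: float = -2.0
    phi_scale: float = 0.3
    # recognition participant effects (logit scale)
    alpha_sd: float = 0.5
    gamma_sd: float = 0.5
    # recognition stream design
    n_targets: int = 29
    n_fillers: int = 109
    min_target_gap: int = 61
    filler_repeat_fraction: float = 0.5
    choice_params: LogisticChoiceParams = field(default_factory=LogisticChoiceParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_items, self.n_mem_participants, self.n_choice_participants) < 2:
            raise ValueError("all cohort counts must be >= 2")
        if not -1.0 <= self.mem_value_corr <= 1.0:
            raise ValueError("mem_value_corr must lie in [-1, 1]")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        if self.modality not in ("image", "word"):
            raise ValueError("modality must be 'image' or 'word'")


@dataclass(frozen=True)
class ItemBank:
    """Per-item latent ground truth behind memorability and value."""

    table: pd.DataFrame  # item_id, name, modality, theta_mem, phi_fa, mu_value

    def __post_init__(self) -> None:
        t = self.table
        required = {"item_id", "name", "modality", "theta_mem", "phi_fa", "mu_value"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"ItemBank table missing columns: {sorted(missing)}")
        if t["item_id"].duplicated().any():
            raise ValueError("item_ids must be unique")
        if not np.all(np.isfinite(t[["theta_mem", "phi_fa"]].to_numpy(float))):
            raise ValueError("theta_mem and phi_fa must be finite")
        mu = t["mu_value"].to_numpy(float)
        if np.any(mu < 0) or np.any(mu > 10):
            raise ValueError("mu_value must lie in [0, 10]")

    @property
    def item_ids(self) -> np.ndarray:
        return self.table["item_id"].to_numpy()

    @property
    def n_items(self) -> int:
        return len(self.table)


def make_item_bank(config: CohortConfig) -> ItemBank:
    """Draw an item bank whose theta_mem/mu_value correlation matches
    ``config.mem_value_corr`` (Gaussian copula, attenuation-corrected)."""
    if config.n_items < 4:
        raise ValueError("need n_items >= 4")
    rng = substream(config.seed, "items")
    rho = config.mem_value_corr / _PHI_ATTENUATION
    rho = float(np.clip(rho, -1.0, 1.0))
    z = rng.standard_normal((config.n_items, 2))
    z_mem = z[:, 0]
    z_val = rho * z_mem + np.sqrt(max(0.0, 1.0 - rho**2)) * z[:, 1]
    theta = config.theta_loc + config.theta_scale * z_mem
    phi = config.phi_loc + config.phi_scale * rng.standard_normal(config.n_items)
    mu_value = 10.0 * ndtr(z_val)
    table = pd.DataFrame(
        {
            "item_id": np.arange(config.n_items),
            "name": [f"{config.modality}_{i:03d}" for i in range(config.n_items)],
            "modality": config.modality,
            "theta_mem": theta,
            "phi_fa": phi,
            "mu_value": mu_value,
        }
    )
    return ItemBank(table)


def simulate_recognition(
    bank: ItemBank,
    streams: pd.DataFrame,
    config: CohortConfig,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate key presses for continuous-recognition streams.

    ``streams`` is the long-format design (participant_id, trial_index,
    item_id, role). On any repeat, press probability is
    ``expit(alpha_p + theta_mem_i)``; on any first presentation it is
    ``expit(gamma_p + phi_fa_i)``, with participant effects
    ``alpha_p ~ N(0, alpha_sd)`` and ``gamma_p ~ N(0, gamma_sd)``.

    Returns the stream with a boolean ``pressed`` column appended.
    """
    if rng is None:
        rng = substream(config.seed, "recognition")
    known = pd.Index(bank.item_ids)
    unknown = pd.Index(streams["item_id"].unique()).difference(known)
    if len(unknown) > 0:
        raise ValueError(f"stream references unknown item_ids: {list(unknown)[:5]}")

    out = streams.copy()
    participants = out["participant_id"].unique()
    alpha = pd.Series(rng.normal(0.0, config.alpha_sd, len(participants)), index=participants)
    gamma = pd.Series(rng.normal(0.0, config.gamma_sd, len(participants)), index=participants)

    theta = bank.table.set_index("item_id")["theta_mem"]
    phi = bank.table.set_index("item_id")["phi_fa"]
    is_repeat = out["role"].isin(["target_repeat", "filler_repeat"]).to_numpy()
    item = out["item_id"].to_numpy()
    pid = out["participant_id"].to_numpy()
    logit = np.where(
        is_repeat,
        alpha.reindex(pid).to_numpy() + theta.reindex(item).to_numpy(),
        gamma.reindex(pid).to_numpy() + phi.reindex(item).to_numpy(),
    )
    out["pressed"] = rng.random(len(out)) < expit(logit)
    return out


def simulate_ratings(
    bank: ItemBank,
    n_participants: int,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Slider ratings: ``clip(mu_value + N(0, noise_sd), 0, 10)``.

    Continuous values are retained (no integer rounding), matching a
    0–10 slider response. Returns (participant_id, item_id, rating).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "ratings")
    mu = bank.table["mu_value"].to_numpy()
    n_items = len(mu)
    noise = rng.normal(0.0, noise_sd, (n_participants, n_items)) if noise_sd > 0 else 0.0
    ratings = np.broadcast_to(np.clip(mu[None, :] + noise, 0.0, 10.0), (n_participants, n_items))
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_participants), n_items),
            "item_id": np.tile(bank.item_ids, n_participants),
            "rating": np.asarray(ratings).ravel(),
        }
    )


def simulate_choices(
    trials: pd.DataFrame,
    params,
    seed: int | np.random.Generator,
    *,
    deadline_ms: float = 3000.0,
) -> pd.DataFrame:
    """Fill in ``choice`` and ``rt_ms`` on choice-trial skeletons.

    ``params`` selects the backend: :class:`LogisticChoiceParams` draws
    Bernoulli choices from ``expit(b0 + b_v*Δvalue + b_m*Δmem)`` (with
    by-subject random coefficients) and lognormal RTs whose mean falls
    with |Δvalue|; :class:`memchoice.ddm.DDMParams` simulates first
    passages of a drift-diffusion process with
    ``v = v0 + v_val*Δvalue + v_mem*Δmem (+ v_int*Δvalue*Δmem)``.
    RTs exceeding the 3 s response deadline become no-response trials
    (choice = "none", rt_ms = NaN).
    """
    for col in ("participant_id", "delta_value", "delta_mem"):
        if col not in trials.columns:
            raise ValueError(f"trials missing required covariate column '{col}'")
    rng = seed if isinstance(seed, np.random.Generator) else substream(int(seed), "choices")
    out = trials.copy()
    dv = out["delta_value"].to_numpy(float)
    dm = out["delta_mem"].to_numpy(float)

    if isinstance(params, LogisticChoiceParams):
        pid = out["participant_id"].to_numpy()
        participants = pd.unique(pid)
        b0 = pd.Series(params.beta0 + rng.normal(0, params.sd_beta0, len(participants)), index=participants)
        bv = pd.Series(
            params.beta_value + rng.normal(0, params.sd_beta_value, len(participants)), index=participants
        )
        bm = pd.Series(
            params.beta_mem + rng.normal(0, params.sd_beta_mem, len(participants)), index=participants
        )
        eta = b0.reindex(pid).to_numpy() + bv.reindex(pid).to_numpy() * dv + bm.reindex(pid).to_numpy() * dm
        chose_right = rng.random(len(out)) < expit(eta)
        r0 = pd.Series(
            params.rt_log_mean + rng.normal(0, params.rt_sd_subject, len(participants)), index=participants
        )
        rs = pd.Series(
            params.rt_value_slope + rng.normal(0, params.rt_sd_value_slope, len(participants)),
            index=participants,
        )
        log_rt = rng.normal(
            r0.reindex(pid).to_numpy() + rs.reindex(pid).to_numpy() * np.abs(dv), params.rt_log_sd
        )
        rt_ms = 1000.0 * np.exp(log_rt)
    else:
        from .ddm import DDMParams, simulate_ddm  # local import avoids cycle

        if not isinstance(params, DDMParams):
            raise TypeError("params must be LogisticChoiceParams or DDMParams")
        covariates = pd.DataFrame({"delta_value": dv, "delta_mem": dm})
        chose_right, rt_s = simulate_ddm(params, covariates, len(out), rng=rng)
        rt_ms = 1000.0 * rt_s

    no_resp = ~np.isfinite(rt_ms) | (rt_ms > deadline_ms)
    choice = np.where(chose_right, "right", "left")
    choice = np.where(no_resp, "none", choice)
    out["choice"] = choice
    out["rt_ms"] = np.where(no_resp, np.nan, rt_ms)
    return out


def null_world(params: LogisticChoiceParams | None = None) -> LogisticChoiceParams:
    """Choice generator with no memorability effect (beta_mem = 0)."""
    base = params or LogisticChoiceParams()
    return replace(base, beta_mem=0.0, sd_beta_mem=0.0)


def simulate_choice_cohort(
    bank: ItemBank,
    z_mem: pd.Series,
    n_participants: int,
    params: LogisticChoiceParams,
    rng: np.random.Generator,
    rating_noise_sd: float = 2.0,
    deadline_ms: float = 3000.0,
) -> pd.DataFrame:
    """Vectorized end-to-end choice cohort: ratings -> within-participant
    z-scores -> value ranking -> close/far pairing -> randomized sides ->
    logistic choices + lognormal RTs.

    Numerically equivalent to chaining ``simulate_ratings`` with the
    :mod:`memchoice.choice` constructors and ``simulate_choices`` (the
    test suite checks the agreement), but runs as pure array code so
    power simulations at hundreds of participants stay cheap. Requires
    an even item count and the logistic choice backend.
    """
    n_items = bank.n_items
    if n_items % 2 != 0:
        raise ValueError("n_items must be even")
    mu = bank.table["mu_value"].to_numpy()
    zm = z_mem.reindex(bank.item_ids).to_numpy(float)
    if np.any(~np.isfinite(zm)):
        raise ValueError("z_mem missing for some items in the bank")

    ratings = np.clip(mu[None, :] + rng.normal(0, rating_noise_sd, (n_participants, n_items)), 0, 10)
    z = (ratings - ratings.mean(axis=1, keepdims=True)) / ratings.std(axis=1, ddof=1, keepdims=True)
    order = np.argsort(-z, axis=1, kind="stable")  # item index by value rank

    half = n_items // 2
    hi = np.concatenate([order[:, 0::2], order[:, :half]], axis=1)  # higher-valued of each pair
    lo = np.concatenate([order[:, 1::2], order[:, half:]], axis=1)
    pair_type = np.array(["close"] * half + ["far"] * half)

    right_is_hi = rng.random(hi.shape) < 0.5
    right = np.where(right_is_hi, hi, lo)
    left = np.where(right_is_hi, lo, hi)
    rows = np.arange(n_participants)[:, None]
    dv = z[rows, right] - z[rows, left]
    dm = zm[right] - zm[left]
    sm = zm[right] + zm[left]

    b0 = params.beta0 + rng.normal(0, params.sd_beta0, n_participants)[:, None]
    bv = params.beta_value + rng.normal(0, params.sd_beta_value, n_participants)[:, None]
    bm = params.beta_mem + rng.normal(0, params.sd_beta_mem, n_participants)[:, None]
    chose_right = rng.random(dv.shape) < expit(b0 + bv * dv + bm * dm)
    r0 = params.rt_log_mean + rng.normal(0, params.rt_sd_subject, n_participants)[:, None]
    rs = params.rt_value_slope + rng.normal(0, params.rt_sd_value_slope, n_participants)[:, None]
    log_rt = rng.normal(r0 + rs * np.abs(dv), params.rt_log_sd)
    rt_ms = 1000.0 * np.exp(log_rt)
    no_resp = rt_ms > deadline_ms

    n_pairs = n_items
    out = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_participants), n_pairs),
            "trial_index": np.tile(np.arange(n_pairs), n_participants),
            "left_item": bank.item_ids[left].ravel(),
            "right_item": bank.item_ids[right].ravel(),
            "pair_type": np.tile(pair_type, n_participants),
            "delta_value": dv.ravel(),
            "delta_mem": dm.ravel(),
            "abs_delta_value": np.abs(dv).ravel(),
            "abs_delta_mem": np.abs(dm).ravel(),
            "sum_mem": sm.ravel(),
            "choice": np.where(no_resp.ravel(), "none", np.where(chose_right.ravel(), "right", "left")),
            "rt_ms": np.where(no_resp.ravel(), np.nan, rt_ms.ravel()),
        }
    )
    return out
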
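"""Conditional mixed-model inference for choice and reaction time.

The focal questions are framed as repeated-measures mixed-effects
regressions on the choice trials of the screened sample:

* choice models — logistic regressions of "chose the higher-valued
  item" on |Δvalue| (on the low-|Δmem| half of trials) and of "chose
  the more memorable item" on |Δmem| (on the low-|Δvalue| half), each
  with by-subject random intercepts and slopes; effects are reported as
  odds ratios with Wald 95% CIs and likelihood-ratio p-values;
* RT models — linear mixed models on log RT with the same random
  structure (via statsmodels MixedLM, ML);
* a simulation-based power analysis that replays the entire synthetic
  pipeline (ratings -> pairing -> choices -> screening -> median split
  -> mixed logistic LRT) at a grid of sample sizes;
* item-level Pearson/Spearman correlations and the binned trial
  summaries behind the figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import glmm
from ._rng import substream
from .choice import median_split, responded
from .cohort import CohortConfig, ItemBank, LogisticChoiceParams, simulate_choice_cohort
from .screening import kept_trials, screen

__all__ = [
    "ModelSpec",
    "ModelFit",
    "PowerCurve",
    "PowerTemplate",
    "build_design",
    "default_power_template",
    "fit_mixed_logistic",
    "fit_mixed_linear",
    "power_simulation",
    "item_level_correlations",
    "representativeness_scores",
    "binned_summary",
]

logger = logging.getLogger(__name__)

RESPONSES = ("chose_higher_value", "chose_more_memorable", "chose_right", "log_rt")
COVARIATES = ("abs_delta_value", "abs_delta_mem", "delta_value", "delta_mem", "sum_mem")


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, with which random structure."""

    response: str
    fixed_effects: tuple[str, ...]
    random_slopes: tuple[str, ...] | None = None  # default: all fixed effects
    trial_filter: str | None = None  # None, "low_abs_delta_mem", "low_abs_delta_value"
    rt_transform: str = "log"  # "log" (natural log of seconds) or "logit_scaled"

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        slopes = self.fixed_effects if self.random_slopes is None else self.random_slopes
        extra = set(slopes) - set(self.fixed_effects)
        if extra:
            raise ValueError(f"random slopes without matching fixed effects: {sorted(extra)}")

    @property
    def slopes(self) -> tuple[str, ...]:
        return self.fixed_effects if self.random_slopes is None else self.random_slopes


@dataclass
class ModelFit:
    """Coefficients, intervals, odds ratios and LRT p-values."""

    kind: str  # "logistic" or "linear"
    spec: ModelSpec
    table: pd.DataFrame  # term, estimate, se, ci_low, ci_high[, or, or_low, or_high], lrt_p
    loglik: float
    n_trials: int
    n_participants: int
    converged: bool
    notes: dict = field(default_factory=dict)

    def coef(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]


def _column(trials: pd.DataFrame, name: str) -> np.ndarray:
    """A covariate column, allowing 'a:b' interactions."""
    if ":" in name:
        a, b = name.split(":", 1)
        return _column(trials, a) * _column(trials, b)
    if name not in trials.columns:
        raise ValueError(f"trials missing covariate {name!r}")
    return trials[name].to_numpy(float)


def build_design(trials: pd.DataFrame, spec: ModelSpec):
    """Response vector, fixed/random design matrices and group labels.

    Tie trials (exactly equal value or memorability) are dropped for
    the chose-higher/more-memorable responses, since the response is
    undefined there; the count is recorded.
    """
    t = responded(trials)
    if spec.trial_filter == "low_abs_delta_mem":
        t = median_split(t, "abs_delta_mem")
    elif spec.trial_filter == "low_abs_delta_value":
        t = median_split(t, "abs_delta_value")
    elif spec.trial_filter is not None:
        raise ValueError(f"unknown trial_filter {spec.trial_filter!r}")

    n_ties = 0
    if spec.response == "chose_right":
        y = (t["choice"] == "right").to_numpy(float)
    elif spec.response in ("chose_higher_value", "chose_more_memorable"):
        delta = t["delta_value"] if spec.response == "chose_higher_value" else t["delta_mem"]
        ties = delta == 0
        n_ties = int(ties.sum())
        if n_ties:
            logger.info("dropping %d exact-tie trials for %s", n_ties, spec.response)
        t = t[~ties]
        delta = delta[~ties]
        right = t["choice"] == "right"
        y = np.where(delta > 0, right, ~right).astype(float)
    else:  # log_rt
        rt_s = t["rt_ms"].to_numpy(float) / 1000.0
        if spec.rt_transform == "log":
            y = np.log(rt_s)
        elif spec.rt_transform == "logit_scaled":
            # logit of RT rescaled into (0, 1) by the 3 s deadline
            frac = np.clip(rt_s / 3.0, 1e-4, 1 - 1e-4)
            y = np.log(frac / (1 - frac))
        else:
            raise ValueError(f"unknown rt_transform {spec.rt_transform!r}")

    X = np.column_stack([np.ones(len(t))] + [_column(t, c) for c in spec.fixed_effects])
    Z = np.column_stack([np.ones(len(t))] + [_column(t, c) for c in spec.slopes])
    names = ["intercept"] + list(spec.fixed_effects)
    return y, X, Z, t["participant_id"].to_numpy(), names, t, n_ties


def fit_mixed_logistic(trials: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Laplace-ML mixed logistic fit with per-effect LRT p-values.

    The LRT refits the model without the focal fixed effect while
    retaining the full random structure.
    """
    y, X, Z, groups, names, t, n_ties = build_design(trials, spec)
    full = glmm.fit_mixed_logit(y, X, Z, groups, fixed_names=names)
    zc = stats.norm.ppf(0.975)
    rows = []
    for j, name in enumerate(names):
        row = {
            "term": name,
            "estimate": full.beta[j],
            "se": full.se[j],
            "ci_low": full.beta[j] - zc * full.se[j],
            "ci_high": full.beta[j] + zc * full.se[j],
        }
        row["or"] = float(np.exp(row["estimate"]))
        row["or_low"] = float(np.exp(row["ci_low"]))
        row["or_high"] = float(np.exp(row["ci_high"]))
        if name != "intercept":
            keep = [k for k in range(X.shape[1]) if k != j]
            reduced = glmm.fit_mixed_logit(
                y, X[:, keep], Z, groups, fixed_names=[names[k] for k in keep]
            )
            row["lrt_p"] = glmm.lrt(full, reduced)
        else:
            row["lrt_p"] = np.nan
        rows.append(row)
    notes = {"n_tie_trials_dropped": n_ties}
    if full.fallback:
        notes["fallback"] = full.fallback
    return ModelFit(
        kind="logistic",
        spec=spec,
        table=pd.DataFrame(rows),
        loglik=full.loglik,
        n_trials=len(y),
        n_participants=int(pd.unique(groups).size),
        converged=full.converged,
        notes=notes,
    )


def fit_mixed_linear(trials: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Linear mixed model on transformed RT (statsmodels MixedLM, ML)."""
    if spec.response != "log_rt":
        raise ValueError("fit_mixed_linear expects the log_rt response")
    y, X, Z, groups, names, t, _ = build_design(trials, spec)
    if np.std(y) < 1e-12:
        return ModelFit(
            kind="linear",
            spec=spec,
            table=pd.DataFrame({"term": names}),
            loglik=np.nan,
            n_trials=len(y),
            n_participants=int(pd.unique(groups).size),
            converged=False,
            notes={"degenerate": "zero response variance"},
        )

    def _fit(exog):
        model = sm.MixedLM(y, exog, groups=groups, exog_re=Z)
        with np.errstate(all="ignore"):
            return model.fit(reml=False, method="lbfgs", maxiter=200, disp=False)

    full = _fit(X)
    zc = stats.norm.ppf(0.975)
    rows = []
    for j, name in enumerate(names):
        b, se = full.fe_params[j], full.bse_fe[j]
        row = {
            "term": name,
            "estimate": float(b),
            "se": float(se),
            "ci_low": float(b - zc * se),
            "ci_high": float(b + zc * se),
        }
        if name != "intercept":
            keep = [k for k in range(X.shape[1]) if k != j]
            red = _fit(X[:, keep])
            stat = max(0.0, 2.0 * (full.llf - red.llf))
            row["lrt_p"] = float(stats.chi2.sf(stat, 1))
        else:
            row["lrt_p"] = np.nan
        rows.append(row)
    return ModelFit(
        kind="linear",
        spec=spec,
        table=pd.DataFrame(rows),
        loglik=float(full.llf),
        n_trials=len(y),
        n_participants=int(pd.unique(groups).size),
        converged=bool(full.converged),
        notes={},
    )


# ---------------------------------------------------------------------------
# power simulation


@dataclass(frozen=True)
class PowerTemplate:
    """The generative pipeline a power simulation replays.

    ``bank`` and ``z_mem`` are held fixed across replicates — the item
    set and its memorability scores are measured once in the emulated
    study — while ratings, choices and participants are redrawn.
    """

    bank: ItemBank
    z_mem: pd.Series
    params: LogisticChoiceParams = field(default_factory=LogisticChoiceParams)
    rating_noise_sd: float = 2.0
    focal_spec: ModelSpec = field(
        default_factory=lambda: ModelSpec(
            response="chose_more_memorable",
            fixed_effects=("abs_delta_mem",),
            trial_filter="low_abs_delta_value",
        )
    )


def default_power_template(config: CohortConfig | None = None, seed: int = 0) -> PowerTemplate:
    """Template at study-default conditions: one item bank and one
    memorability measurement (from the latent hit/false-alarm
    propensities' expected corrected recognition), then the standard
    choice pipeline."""
    from scipy.special import expit

    from .cohort import make_item_bank

    cfg = config or CohortConfig(seed=seed)
    bank = make_item_bank(cfg)
    # expected CR over the participant-effect distribution, by quadrature
    nodes, weights = np.polynomial.hermite_e.hermegauss(31)
    w = weights / weights.sum()
    theta = bank.table["theta_mem"].to_numpy()
    phi = bank.table["phi_fa"].to_numpy()
    hit = (w[:, None] * expit(cfg.alpha_sd * nodes[:, None] + theta[None, :])).sum(axis=0)
    fa = (w[:, None] * expit(cfg.gamma_sd * nodes[:, None] + phi[None, :])).sum(axis=0)
    cr = hit - fa
    z = (cr - cr.mean()) / cr.std(ddof=1)
    z_mem = pd.Series(z, index=pd.Index(bank.item_ids, name="item_id"), name="z_mem")
    return PowerTemplate(bank=bank, z_mem=z_mem, params=cfg.choice_params, rating_noise_sd=cfg.rating_noise_sd)


@dataclass
class PowerCurve:
    """Rejection proportion of the focal LRT across sample sizes."""

    table: pd.DataFrame  # n, power, se, n_sims, n_failed
    alpha: float
    effect_or: float

    @property
    def max_power(self) -> float:
        return float(self.table["power"].max())


def _one_power_replicate(template: PowerTemplate, n: int, effect_or: float, rng):
    params = replace(
        template.params, beta_mem=float(np.log(effect_or)), sd_beta_mem=template.params.sd_beta_mem
    )
    trials = simulate_choice_cohort(
        template.bank, template.z_mem, n, params, rng, template.rating_noise_sd
    )
    report = screen(trials)
    t = kept_trials(trials, report)
    if t["participant_id"].nunique() < 2:
        raise RuntimeError("screening left fewer than 2 participants")
    spec = template.focal_spec
    y, X, Z, groups, names, _, _ = build_design(t, spec)
    full = glmm.fit_mixed_logit(y, X, Z, groups, fixed_names=names)
    reduced = glmm.fit_mixed_logit(y, X[:, [0]], Z, groups, fixed_names=["intercept"])
    return glmm.lrt(full, reduced), float(full.beta[-1])


def power_simulation(
    effect_or: float,
    n_grid=(44, 100, 250, 500),
    n_sims: int = 100,
    alpha: float = 0.05,
    template: PowerTemplate | None = None,
    seed: int = 0,
    alternative: str = "greater",
) -> PowerCurve:
    """Simulation-based power of the focal median-split |Δmem| test.

    For each sample size n: simulate the full pipeline with the focal
    odds ratio injected (per z-unit of the signed Δmem), screen, median
    split, fit the mixed logistic and LRT-test the focal effect; power
    is the rejection proportion (binomial SE reported). Replicates that
    fail at any stage are counted and logged, never silently dropped.

    ``alternative`` defines what counts as a detection: "greater" (the
    default) counts LRT-significant fits whose focal coefficient is
    positive — the probability of claiming the hypothesized
    more-memorable-items-are-chosen effect, which is the quantity a
    directional post-hoc power analysis reports; "less" mirrors it;
    "two-sided" counts any significant fit (used for calibration).
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater, less or two-sided")
    if template is None:
        template = default_power_template(seed=seed)
    rows = []
    for n in n_grid:
        rejections = 0
        successes = 0
        failed = 0
        for s in range(n_sims):
            rng = substream(seed, f"power/{n}/{s}")
            try:
                p, coef = _one_power_replicate(template, int(n), effect_or, rng)
            except Exception as exc:  # failed replicate: logged, counted
                logger.warning("power replicate n=%d sim=%d failed: %s", n, s, exc)
                failed += 1
                continue
            successes += 1
            hit = p < alpha
            if alternative == "greater":
                hit = hit and coef > 0
            elif alternative == "less":
                hit = hit and coef < 0
            rejections += hit
        power = rejections / successes if successes else np.nan
        se = np.sqrt(power * (1 - power) / successes) if successes else np.nan
        rows.append({"n": int(n), "power": power, "se": se, "n_sims": n_sims, "n_failed": failed})
    return PowerCurve(table=pd.DataFrame(rows), alpha=alpha, effect_or=effect_or)


# ---------------------------------------------------------------------------
# item-level correlations and figure tables


def item_level_correlations(
    mem_table: pd.DataFrame,
    mean_values: pd.Series,
    representativeness: pd.Series | None = None,
    external_predictions: pd.Series | None = None,
    spearman: bool = False,
) -> pd.DataFrame:
    """Pearson correlations (r, df = n-2, two-sided p) between per-item
    memorability and the other per-item quantities, aligned on item."""
    cr = mem_table.set_index("item_id")["cr"]
    columns = {"mean_value": mean_values}
    if representativeness is not None:
        columns["representativeness"] = representativeness
    if external_predictions is not None:
        columns["external_prediction"] = external_predictions
    rows = []
    for name, series in columns.items():
        aligned = pd.concat([cr.rename("cr"), series.rename(name)], axis=1, join="inner").dropna()
        if len(aligned) != len(cr) or len(aligned) != len(series.dropna()):
            if len(aligned) < 3:
                raise ValueError(f"item vectors for {name} share too few items")
        r, p = stats.pearsonr(aligned["cr"], aligned[name])
        row = {"pair": f"cr~{name}", "pearson_r": float(r), "df": len(aligned) - 2, "p": float(p)}
        if spearman:
            rho, sp = stats.spearmanr(aligned["cr"], aligned[name])
            row["spearman_rho"], row["spearman_p"] = float(rho), float(sp)
        rows.append(row)
    # representativeness ~ value correlation is also of interest
    if representativeness is not None:
        aligned = pd.concat(
            [mean_values.rename("v"), representativeness.rename("rep")], axis=1, join="inner"
        ).dropna()
        r, p = stats.pearsonr(aligned["v"], aligned["rep"])
        rows.append(
            {"pair": "mean_value~representativeness", "pearson_r": float(r), "df": len(aligned) - 2, "p": float(p)}
        )
    return pd.DataFrame(rows)


def representativeness_scores(ratings: pd.DataFrame) -> pd.Series:
    """Per-item mean of within-participant z-scored ratings (0–10
    scale in, standardized out). Constant raters contribute zeros and
    are flagged by :func:`memchoice.choice.zscore_ratings`."""
    from .choice import zscore_ratings

    z = zscore_ratings(ratings)
    return z.groupby("item_id")["z_value"].mean().rename("representativeness")


def binned_summary(trials: pd.DataFrame, x: str, y: str, n_bins: int = 5) -> pd.DataFrame:
    """Equal-count bins of x (pooled quantiles); within each bin the
    mean of y is taken within participant first, then across
    participants, with the SEM across participants."""
    t = responded(trials)
    if len(t) < n_bins:
        raise ValueError("fewer trials than bins")
    xv = t[x].to_numpy(float)
    # equal-count bins via rank
    order = stats.rankdata(xv, method="ordinal") - 1
    bins = (order * n_bins // len(t)).astype(int)
    if y == "chose_higher_value":
        delta = t["delta_value"]
        keep = delta != 0
        yv = np.where(delta[keep] > 0, t["choice"][keep] == "right", t["choice"][keep] == "left").astype(float)
        t2 = t[keep].assign(_y=yv, _bin=bins[keep.to_numpy()])
    elif y == "chose_more_memorable":
        delta = t["delta_mem"]
        keep = delta != 0
        yv = np.where(delta[keep] > 0, t["choice"][keep] == "right", t["choice"][keep] == "left").astype(float)
        t2 = t[keep].assign(_y=yv, _bin=bins[keep.to_numpy()])
    elif y == "rt_ms":
        t2 = t.assign(_y=t["rt_ms"], _bin=bins)
    else:
        t2 = t.assign(_y=t[y], _bin=bins)
    per_part = t2.groupby(["_bin", "participant_id"])["_y"].mean()
    x_mean = t2.groupby("_bin")[x].mean()
    out = per_part.groupby("_bin").agg(["mean", "sem", "count"]).rename(
        columns={"mean": "y_mean", "sem": "y_sem", "count": "n_participants"}
    )
    out[x + "_mean"] = x_mean
    out.index.name = "bin"
    return out.reset_index()
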
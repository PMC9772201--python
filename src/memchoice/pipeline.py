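"""End-to-end orchestration: simulate -> score -> design -> screen ->
infer (-> ddm), with provenance and a human-readable summary.

Every stage draws from a named substream of one root seed and writes
its inputs/outputs under the bundle directory, so identical configs
and seeds produce byte-identical bundles and any stage can be re-run
in isolation from the written artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import choice, cohort, inference, io, memory, screening
from ._rng import child_seed

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable pipeline configuration."""

    cohort: cohort.CohortConfig = field(default_factory=cohort.CohortConfig)
    seed: int = 0
    out_dir: str = "memchoice_out"
    run_consistency: bool = True
    consistency_iters: int = 200
    run_choice_models: bool = True
    run_rt_models: bool = True
    run_bayes: bool = False
    bayes_widths: tuple[float, ...] = (0.5, 1.0)
    run_power: bool = False
    power_effect_or: float = 0.97
    power_grid: tuple[int, ...] = (44, 100, 250, 500)
    power_sims: int = 100
    run_ddm: bool = False
    ddm_min_trials: int = 80

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ccfg = raw.pop("cohort", {})
        if "choice_params" in ccfg:
            ccfg["choice_params"] = cohort.LogisticChoiceParams(**ccfg["choice_params"])
        for key in ("bayes_widths", "power_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort.CohortConfig(**ccfg), **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a dict of the key results and
    writes the full bundle (CSV/JSON + summary.txt) to config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config.cohort, seed=config.seed)
    # hash the scientific configuration only, not the output location
    results: dict = {"config_hash": io.config_hash(dataclasses.replace(config, out_dir=""))}
    summary: list[str] = [f"memchoice pipeline (seed={config.seed}, config {results['config_hash']})"]

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                return fn()
            except Exception as exc:
                raise StageError(name, exc) from exc

        return deco

    # --- simulate items + recognition ---
    @stage("simulate_items")
    def bank():
        b = cohort.make_item_bank(cfg)
        io.write_table(b.table, out / "items.csv", config.seed, cfg)
        return b

    design = memory.StreamDesign(
        n_targets=cfg.n_targets,
        n_fillers=cfg.n_fillers,
        min_target_gap=cfg.min_target_gap,
        filler_repeat_fraction=cfg.filler_repeat_fraction,
    )

    @stage("simulate_recognition")
    def recog_log():
        streams = memory.build_streams(
            bank.item_ids, cfg.n_mem_participants, design, seed=child_seed(config.seed, "streams")
        )
        log = cohort.simulate_recognition(bank, streams, cfg)
        io.write_table(log, out / "recognition_log.csv", config.seed, cfg)
        return log

    # --- score memorability ---
    @stage("score_memory")
    def mem_result():
        kept, excluded = memory.exclude_memory_participants(recog_log)
        log = recog_log[recog_log["participant_id"].isin(kept)]
        table = memory.score_memorability(log, item_ids=bank.item_ids)
        io.write_table(table, out / "memorability.csv", config.seed, cfg)
        summary.append(
            f"memory task: {len(kept)} kept / {len(excluded)} excluded; "
            f"CR median {table['cr'].median():.2f}, range [{table['cr'].min():.2f}, {table['cr'].max():.2f}]"
        )
        balance = memory.assignment_balance(recog_log, bank.item_ids)
        summary.append(f"mean per-item target count {balance.mean():.1f}")
        return {"table": table, "log": log, "kept": kept, "excluded": excluded}

    if config.run_consistency:

        @stage("consistency")
        def consistency():
            scores = memory.participant_item_scores(mem_result["log"])
            res = memory.split_half_consistency(
                scores, n_iter=config.consistency_iters, seed=child_seed(config.seed, "consistency")
            )
            io.consistency_to_json(res, out / "consistency.json")
            curve = memory.rank_consistency_curve(
                scores, n_iter=config.consistency_iters, seed=child_seed(config.seed, "consistency")
            )
            io.write_table(curve, out / "consistency_curve.csv", config.seed, cfg)
            summary.append(f"split-half consistency: mean rho {res.mean_rho:.2f}, p {res.p_value:.3g}")
            return res

        results["consistency"] = consistency

    # --- choice design + simulated choices ---
    @stage("design_choice")
    def trials():
        ratings = cohort.simulate_ratings(
            bank, cfg.n_choice_participants, cfg.rating_noise_sd, child_seed(config.seed, "ratings")
        )
        io.write_table(ratings, out / "ratings.csv", config.seed, cfg)
        z = choice.zscore_ratings(ratings)
        ranking = choice.rank_items(z, seed=child_seed(config.seed, "ranks"))
        pairs = choice.build_choice_pairs(ranking)
        z_mem = choice.zscore_memorability(mem_result["table"])
        skeleton = choice.assemble_choice_trials(pairs, z, z_mem, seed=child_seed(config.seed, "sides"))
        t = cohort.simulate_choices(skeleton, cfg.choice_params, child_seed(config.seed, "choices"))
        io.write_table(t[io.TRIAL_COLUMNS], out / "trials.csv", config.seed, cfg)
        return t

    # --- screening ---
    @stage("screen")
    def screened():
        report = screening.screen(trials)
        io.write_table(report.reset_index(), out / "screening.csv", config.seed, cfg)
        n = len(report)
        counts = {
            "side_bias": int(report["side_bias_excluded"].sum()),
            "fast_rt": int(report["fast_rt_excluded"].sum()),
            "value_sanity": int(report["value_sanity_excluded"].sum()),
            "kept": int(report["kept"].sum()),
        }
        io.dump_json(counts, out / "screening_summary.json")
        summary.append(
            f"screening: {counts['kept']}/{n} kept ({counts['side_bias']} side-bias, "
            f"{counts['fast_rt']} fast-RT, {counts['value_sanity']} value-sanity)"
        )
        return screening.kept_trials(trials, report)

    results["n_kept_participants"] = int(screened["participant_id"].nunique())

    # --- inference ---
    if config.run_choice_models:

        @stage("infer_choice")
        def choice_fits():
            fits = {}
            value_spec = inference.ModelSpec(
                response="chose_higher_value",
                fixed_effects=("abs_delta_value",),
                trial_filter="low_abs_delta_mem",
            )
            mem_spec = inference.ModelSpec(
                response="chose_more_memorable",
                fixed_effects=("abs_delta_mem",),
                trial_filter="low_abs_delta_value",
            )
            for name, spec in (("value_choice", value_spec), ("mem_choice", mem_spec)):
                fit = inference.fit_mixed_logistic(screened, spec)
                io.model_fit_to_json(fit, out / f"fit_{name}.json")
                fits[name] = fit
                focal = fit.table.iloc[-1]
                summary.append(
                    f"{name}: OR {focal['or']:.2f} (95% CI {focal['or_low']:.2f}-{focal['or_high']:.2f}), "
                    f"LRT p {focal['lrt_p']:.3g} [{fit.n_trials} trials]"
                )
            return fits

        results["choice_fits"] = choice_fits

    if config.run_rt_models:

        @stage("infer_rt")
        def rt_fits():
            fits = {}
            for name, cov, filt in (
                ("rt_value", "abs_delta_value", "low_abs_delta_mem"),
                ("rt_mem", "abs_delta_mem", "low_abs_delta_value"),
            ):
                spec = inference.ModelSpec(response="log_rt", fixed_effects=(cov,), trial_filter=filt)
                fit = inference.fit_mixed_linear(screened, spec)
                io.model_fit_to_json(fit, out / f"fit_{name}.json")
                fits[name] = fit
                focal = fit.table.iloc[-1]
                summary.append(
                    f"{name}: beta {focal['estimate']:.3f} (95% CI {focal['ci_low']:.3f} to "
                    f"{focal['ci_high']:.3f}), LRT p {focal['lrt_p']:.3g}"
                )
            return fits

        results["rt_fits"] = rt_fits

    if config.run_bayes:

        @stage("infer_bayes")
        def bayes_table():
            from .bayes import bf_prior_sensitivity

            spec = inference.ModelSpec(
                response="chose_more_memorable",
                fixed_effects=("abs_delta_mem",),
                trial_filter="low_abs_delta_value",
            )
            table = bf_prior_sensitivity(
                screened, spec, widths=config.bayes_widths, seed=child_seed(config.seed, "bayes")
            )
            io.write_table(table, out / "bf_sensitivity.csv", config.seed, cfg)
            summary.append("BF01 by prior width: " + ", ".join(f"{w:.2g}->{b:.3g}" for w, b in zip(table["prior_width"], table["bf01"])))
            return table

        results["bayes"] = bayes_table

    if config.run_power:

        @stage("power")
        def power_curve():
            template = inference.default_power_template(cfg, seed=config.seed)
            curve = inference.power_simulation(
                config.power_effect_or,
                n_grid=config.power_grid,
                n_sims=config.power_sims,
                template=template,
                seed=child_seed(config.seed, "power"),
            )
            io.write_table(curve.table, out / "power_curve.csv", config.seed, cfg)
            summary.append(f"power (OR={config.power_effect_or}): max {100*curve.max_power:.1f}% over n {list(config.power_grid)}")
            return curve

        results["power"] = power_curve

    if config.run_ddm:

        @stage("ddm")
        def ddm_fit():
            from .ddm import fit_ddm_regression

            fit = fit_ddm_regression(screened, min_trials=config.ddm_min_trials)
            io.write_table(fit.per_participant, out / "ddm_participants.csv", config.seed, cfg)
            io.dump_json(fit.group, out / "ddm_group.json")
            if len(fit.group):
                sig = fit.group[fit.group["significant"] == True]["param"].tolist()  # noqa: E712
                summary.append(f"ddm: credible weights {sig or 'none'}")
            return fit

        results["ddm"] = ddm_fit

    # --- correlations + figure tables ---
    @stage("correlations")
    def correlations():
        ratings = pd.read_csv(out / "ratings.csv")
        mean_vals = ratings.groupby("item_id")["rating"].mean()
        table = inference.item_level_correlations(mem_result["table"], mean_vals)
        io.write_table(table, out / "item_correlations.csv", config.seed, cfg)
        row = table.iloc[0]
        summary.append(f"memorability~value: r({int(row['df'])}) = {row['pearson_r']:.2f}, p = {row['p']:.2g}")
        return table

    results["correlations"] = correlations

    @stage("figure_tables")
    def figures():
        for name, x, y, filt in (
            ("value_choice", "abs_delta_value", "chose_higher_value", "abs_delta_mem"),
            ("mem_choice", "abs_delta_mem", "chose_more_memorable", "abs_delta_value"),
            ("value_rt", "abs_delta_value", "rt_ms", "abs_delta_mem"),
            ("mem_rt", "abs_delta_mem", "rt_ms", "abs_delta_value"),
        ):
            sub = choice.median_split(screened, filt)
            io.write_table(inference.binned_summary(sub, x, y), out / f"bins_{name}.csv", config.seed, cfg)

    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    results["summary"] = "\n".join(summary)
    return results
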
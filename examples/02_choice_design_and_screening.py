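"""Design the value-based choice task and screen participants.

Each participant rates all items on a 0-10 slider; items are ranked by
value and paired into 69 close (adjacent-rank) and 69 far (half-split)
pairs; trials carry the right-minus-left covariates Δvalue and Δmem.
Simulated choices are then screened with the three exclusion criteria:
side bias, fast responding, and a per-participant Δvalue sanity
regression.
"""

import memchoice as mc
from memchoice import choice, cohort, inference, memory, screening
from memchoice._rng import child_seed

SEED = 11
config = mc.CohortConfig(seed=SEED)
bank = mc.make_item_bank(config)

# memorability scores measured once (here: a simulated recognition cohort)
streams = memory.build_streams(bank.item_ids, 60, seed=SEED)
log = cohort.simulate_recognition(bank, streams, config)
mem_table = memory.score_memorability(log, item_ids=bank.item_ids)
z_mem = choice.zscore_memorability(mem_table)

ratings = cohort.simulate_ratings(bank, config.n_choice_participants, config.rating_noise_sd, SEED)
z = choice.zscore_ratings(ratings)
ranking = choice.rank_items(z, seed=child_seed(SEED, "ranks"))
pairs = choice.build_choice_pairs(ranking)
n_per = len(pairs) // pairs.participant_id.nunique()
print(f"{n_per} pairs per participant; close pairs have rank distance "
      f"{pairs[pairs.pair_type == 'close'].rank_distance.unique()}, far "
      f"{pairs[pairs.pair_type == 'far'].rank_distance.unique()}")

trials = choice.assemble_choice_trials(pairs, z, z_mem, seed=child_seed(SEED, "sides"))
trials = cohort.simulate_choices(trials, config.choice_params, child_seed(SEED, "choices"))
print(f"{len(trials)} trials; {(trials.choice == 'none').sum()} hit the 3 s deadline (no response)")

report = screening.screen(trials)
print(
    f"\nscreening: {int(report.kept.sum())}/{len(report)} kept "
    f"({int(report.side_bias_excluded.sum())} side-bias, "
    f"{int(report.fast_rt_excluded.sum())} fast-RT, "
    f"{int(report.value_sanity_excluded.sum())} value-sanity)"
)

kept = screening.kept_trials(trials, report)
low_mem = choice.median_split(kept, "abs_delta_mem")
print(f"\nmedian split on |Δmem|: {len(low_mem)} of {len(kept)} responded trials in the low half")
print("these trials isolate the value effect: memorability is matched, value varies")
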
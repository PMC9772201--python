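"""Post-hoc power: could the |Δmem| effect realistically be detected?

Replays the full pipeline (ratings -> pairing -> choices -> screening ->
median split -> mixed-logistic LRT) at several sample sizes, injecting
the small observed effect (odds ratio 0.97 per z-unit of Δmem), and
counts detections of the hypothesized positive memorability effect.
Replicate counts are reduced here to keep the example quick.
"""

import memchoice as mc
from memchoice import inference

template = inference.default_power_template(mc.CohortConfig(seed=0))
curve = inference.power_simulation(
    effect_or=0.97,
    n_grid=(44, 100),
    n_sims=25,
    template=template,
    seed=5,
)
print(curve.table.to_string(index=False))
print(
    "\npower stays in the low single digits: an effect of OR 0.97 in the wrong"
    "\n(negative) direction essentially never produces the hypothesized positive"
    "\nfinding, no matter the sample size - the null result is not a power problem."
)
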
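"""Decompose choices and RTs with a drift-diffusion regression.

Generates choice/RT data from a diffusion process whose drift depends
on Δvalue only, then fits per-participant DDM regressions and tests
each drift/start-point weight at the group level. The value weight
should be detected; the memorability weight should not.
"""

import numpy as np
import pandas as pd

from memchoice import ddm

true = ddm.DDMParams(a=1.8, t0=0.3, v0=0.1, v_val=1.5, v_mem=0.0, v_int=0.0)
rng = np.random.default_rng(42)

rows = []
for pid in range(12):
    cov = pd.DataFrame({"delta_value": rng.normal(0, 1, 138), "delta_mem": rng.normal(0, 1, 138)})
    chose_right, rt = ddm.simulate_ddm(true, cov, 138, dt=1e-3, rng=rng)
    ok = np.isfinite(rt) & (rt <= 3.0)
    rows.append(
        pd.DataFrame(
            {
                "participant_id": pid,
                "delta_value": cov.delta_value,
                "delta_mem": cov.delta_mem,
                "choice": np.where(ok, np.where(chose_right, "right", "left"), "none"),
                "rt_ms": np.where(ok, rt * 1000, np.nan),
            }
        )
    )
trials = pd.concat(rows, ignore_index=True)

fit = ddm.fit_ddm_regression(trials, v_covariates=("delta_value", "delta_mem"), z_covariates=())
print("group-level tests of the drift regression weights:")
print(fit.group.to_string(index=False))
print(
    "\nv_delta_value is credibly positive (value speeds evidence accumulation toward"
    "\nthe higher-valued side); v_delta_mem is indistinguishable from zero, matching"
    "\nthe generating model in which memorability plays no role in the decision."
)
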
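"""Why a global optimizer: LM from random starting points often fails.

Draws 100 initial parameter vectors uniformly from the standard bound box
and runs Levenberg-Marquardt from each.  The nonrectangular hyperbola is
the classic failure case — its curvature parameter confines valid
parameter vectors to a slab of the box.
"""

import numpy as np

import lightresponse as lr

rng = np.random.default_rng(5)
m = lr.get_model("nonrectangular")
truth = (0.75, 0.06, 18.0, 0.9)
a_net = m.predict(truth, lr.DEFAULT_GRID) + rng.normal(0.0, 0.3, lr.DEFAULT_GRID.size)
curve = lr.LightResponseDataset("demo", "1", lr.DEFAULT_GRID, a_net)

for name in lr.MODEL_NAMES:
    sweep = lr.initial_value_sweep(curve, name, n_trials=100, seed=9)
    ok = sweep.n_trials - sweep.n_failed
    print(f"{name:22s} {sweep.n_failed:3d}/100 failed, best R^2 of successes: "
          f"{sweep.best_r2:.4f}")

de = lr.fit(curve, "nonrectangular", "de", seed=9)
print(f"\nDE from the same box:  never fails, R^2 = {de.metrics.r_squared:.4f}")
print("Each failed LM run is a start from which the damped Gauss-Newton")
print("iteration hit an invalid region, a singular system, or the")
print("iteration cap — exactly the initial-value sensitivity DE removes.")
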
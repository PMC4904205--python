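"""Fit all four light-response models to one curve and rank them by AIC.

No initial parameter values are supplied anywhere: Differential Evolution
searches each model's standard bound box directly.
"""

import numpy as np

import lightresponse as lr

# a typical noisy A-Q curve, generated here so the script is self-contained
m = lr.get_model("nonrectangular")
truth = (0.7, 0.055, 21.0, 1.1)  # theta, a, Amax, Rd
rng = np.random.default_rng(7)
a_net = m.predict(truth, lr.DEFAULT_GRID) + rng.normal(0.0, 0.3, lr.DEFAULT_GRID.size)
curve = lr.LightResponseDataset("demo_species", "1", lr.DEFAULT_GRID, a_net)

fits = []
for name in lr.MODEL_NAMES:
    res = lr.fit(curve, name, method="de", seed=1)
    fits.append(res)
    params = ", ".join(f"{k}={v:.4g}" for k, v in res.param_dict.items())
    print(f"{name:22s} R^2={res.metrics.r_squared:.4f} AIC={res.metrics.aic:8.2f}  {params}")

ranked = lr.rank_models(fits)
print(f"\nbest model by AIC: {ranked[0].model}")
print("R^2 close to 1 means the model explains nearly all variance in the")
print("curve; lower AIC balances that fit quality against parameter count.")
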
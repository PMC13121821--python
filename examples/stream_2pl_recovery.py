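"""Stream simulated 2PL responses through the averaged Newton recursion.

Simulates a 20-item test, feeds 5,000 examinees one at a time to the
TASNA engine, and prints how the pooled item-parameter RMSE falls as the
stream lengthens, plus the final estimates and standard errors for a few
items.  The RMSE pools discrimination (a) and difficulty (b) errors; it
should drop to roughly 0.1 by n=2,500 under these conditions.
"""

import numpy as np

from irtstream import EstimatorConfig, SimulationConfig, generate_dataset
from irtstream.simulate import pooled_item_rmse, stream_fit

sim = SimulationConfig(N=5000, J=20, Q=1, a_low=0.5, a_high=2.0, K_fit=11)
data = generate_dataset(sim, seed=1)

fit = stream_fit(
    data.responses,
    EstimatorConfig.tasna(),  # gamma=0.65, log-weighted averaging, K=11
    template=data.params,
    checkpoints=(500, 1000, 2500, 5000),
)

print("pooled item RMSE along the stream:")
for rec in fit.records:
    print(f"  n={rec.n:5d}  rmse={pooled_item_rmse(rec.beta_avg, data.params):.4f}")

ses = fit.estimator.standard_errors()
truth = data.params.beta_matrix()
est = fit.estimator.beta_avg
print("\nfirst three items (slope-intercept scale), estimate (SE) vs truth:")
for j in range(3):
    print(
        f"  item {j + 1}: a = {est[j, 0]:.3f} ({ses[j, 0]:.3f}) vs {truth[j, 0]:.3f}"
        f" | d = {est[j, 1]:.3f} ({ses[j, 1]:.3f}) vs {truth[j, 1]:.3f}"
    )

print(
    "\nEAP ability of the final examinee:",
    np.round(fit.eap[-1], 3),
    "(true theta %.3f)" % data.thetas[-1, 0],
)
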
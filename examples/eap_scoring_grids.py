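"""EAP ability scoring and the choice of scoring grid.

After a 20-item test an examinee's ability posterior is narrow (sd near
0.3), so the placement of quadrature nodes matters for scoring precision.
The Gauss-Hermite grid used during item estimation quantizes the EAP at
K=21; the equally spaced density-weighted scoring grid resolves it to a
few 1e-5 of a dense reference.
"""

import numpy as np

from irtstream import ResponseVector, build_quadrature_grid, eap_ability
from irtstream.model import ItemParamSet

rng = np.random.default_rng(7)
beta = np.hstack([rng.uniform(0.5, 2.0, (20, 1)), rng.standard_normal((20, 1))])
params = ItemParamSet.from_arrays(beta)

dense = build_quadrature_grid(401, 1, rule="rectangle", lim=6.0)
gh21 = build_quadrature_grid(21, 1)  # estimation-style Gauss-Hermite
rect21 = build_quadrature_grid(21, 1, rule="rectangle")  # scoring grid

y = ResponseVector(rng.integers(0, 2, 20))
ref = eap_ability(y, params, dense)[0]
print(f"dense-reference EAP:        {ref:+.6f}")
print(f"K=21 Gauss-Hermite EAP:     {eap_ability(y, params, gh21)[0]:+.6f}")
print(f"K=21 scoring-grid EAP:      {eap_ability(y, params, rect21)[0]:+.6f}")
print("\nThe scoring grid's uniform 0.4 spacing over [-4, 4] tracks the")
print("reference to ~1e-5; same-size Gauss-Hermite placement is ~1e-3 off.")
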
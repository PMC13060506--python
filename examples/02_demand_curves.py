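"""Fit an exponentiated demand curve to a purchase-task response set and
report observed and derived demand metrics."""

import numpy as np

from eftrial import (DemandObservationSet, fit_exponentiated, fitted_pmax,
                     observed_metrics, shared_k_span)
from eftrial.demand import DEFAULT_PRICES

# A plausible response pattern: heavy consumption at free drinks, declining
# with price, with one overconsumption response (capped to 50).
raw = (60, 20, 15, 12, 10, 9, 8, 7, 5, 4, 3, 1, 0)
obs = DemandObservationSet(DEFAULT_PRICES, raw).capped()
print("capped quantities:", obs.quantities)

intensity, omax, pmax = observed_metrics(obs)
print(f"observed: intensity={intensity} drinks, "
      f"Omax=${omax:.2f}, Pmax=${pmax:.2f}")

k = shared_k_span([obs.quantities])  # shared span; here one set defines it
fit = fit_exponentiated(obs, k)
print(f"fitted:  Q0={fit.Q0:.2f} drinks, alpha={fit.alpha:.5f} "
      f"(ln alpha {fit.ln_alpha:.2f}), k span={k:.3f}")
print(f"fitted Pmax (unit-elasticity price) = ${fitted_pmax(fit):.2f}")
# alpha is the elasticity rate: larger alpha means consumption collapses
# faster with price; Omax/Pmax describe the peak of the expenditure curve.
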
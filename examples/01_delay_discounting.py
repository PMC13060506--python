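"""Run the adjusting-amount task against a known hyperbolic decision maker
and recover the discount rate from the resulting indifference points."""

import math

from eftrial import (TitrationSchedule, fit_hyperbolic, johnson_bickel_screen,
                     run_titration, simulated_chooser)

schedule = TitrationSchedule()  # $1000 larger-later, 7 delays, 6 trials each

true_ln_k = math.log(0.01)
chooser = simulated_chooser(true_ln_k, temperature=0.0)  # noiseless responder

curve = run_titration(chooser, schedule)
print("delay (days) -> indifference point ($):")
for d, v in zip(curve.delays_days, curve.values):
    print(f"  {d:>7.0f}     {v:8.2f}")

c1, c2 = johnson_bickel_screen(curve, schedule.ll_amount)
fit = fit_hyperbolic(curve, schedule=schedule)
print(f"\nsystematic: criterion1={c1}, criterion2={c2}")
print(f"estimated ln(k) = {fit.ln_k:.4f}   (true {true_ln_k:.4f})")
print(f"titration resolution = ${schedule.resolution:.4f}")
# The indifference points fall as V = A/(1+kD); the fit recovers ln(k) to
# within the quantization the 6-trial titration imposes (~0.03 here).
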
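"""Single-cell action potential of the plateau surrogate myocyte.

Integrates the surrogate ventricular model (Mitchell-Schaeffer-type gate
kinetics with a phenomenological calcium transient) at one point, stimulated
once, and prints the AP landmarks.  Writes the trace as CSV.
"""

import numpy as np
from scipy.integrate import solve_ivp

from gsmono import PlateauParameters, surrogate_ventricular_model
from gsmono.io import write_probe_csv

p = PlateauParameters()
model = surrogate_ventricular_model(p)


def rhs(t, s):
    V, y = np.array([s[0]]), s[1:][None, :]
    dV = -model.current(V, y)[0] / p.cm
    if 1.0 <= t < 3.0:                       # 2 ms suprathreshold stimulus
        dV += 0.15 / p.cm
    return np.concatenate([[dV], model.rhs(V, y)[0]])


sol = solve_ivp(rhs, (0, 900), [model.rest_potential, *model.initial_state],
                max_step=0.25, rtol=1e-8, atol=1e-10, dense_output=True)
t = np.linspace(0, 900, 3600)
V, h, ca = sol.sol(t)

up = t[np.argmax(V > 0.0)]
apd90 = t[V > model.rest_potential + 11.0]
print(f"resting potential: {model.rest_potential:.0f} mV")
print(f"peak potential:    {V.max():.1f} mV  (upstroke crosses 0 mV at "
      f"t={up:.1f} ms)")
print(f"APD90:             {apd90[-1] - apd90[0]:.0f} ms")
print(f"calcium transient: {ca.min():.2f} -> {ca.max():.2f} uM, "
      f"peak at t={t[np.argmax(ca)]:.0f} ms")
write_probe_csv("single_cell_ap.csv", t, V[:, None],
                {"gate": h[:, None], "calcium": ca[:, None]},
                probe_names=["cell"])
print("trace written to single_cell_ap.csv (t, V, gate, calcium)")
# The morphology is the textbook ventricular AP: fast upstroke, long
# plateau, repolarization, and a calcium pulse that lags the upstroke by a
# few tens of ms -- the excitation-contraction coupling proxy.
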
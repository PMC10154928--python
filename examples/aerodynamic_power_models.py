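"""Predict mechanical flight power for the study bat with both models.

Builds the 8.9 g study morphology, evaluates the fixed-wing (Pennycuick-
style) and quasi-steady flapping power curves over 3-10 m/s and prints the
characteristic speeds: U_mp (minimum power) and U_mr (maximum range, the
cost-of-transport optimum).
"""

import numpy as np

from flightpower import (
    Environment,
    STUDY_MORPHOLOGY,
    flap_model_power,
    maximum_range_speed,
    minimum_power_speed,
    pennycuick_power,
)

env = Environment()
bat = STUDY_MORPHOLOGY

print(f"morphology: {bat.body_mass * 1000:.1f} g, span {bat.wing_span} m, "
      f"area {bat.wing_area} m^2, {bat.wingbeat_freq} Hz")
print(f"{'U (m/s)':>8} {'fixed-wing P (W)':>17} {'flapping P (W)':>15}")
for u in np.arange(3.0, 10.5, 1.0):
    p_fixed = pennycuick_power(bat, env, u).total
    p_flap, flags = flap_model_power(bat, env, u)
    mark = " *" if flags.any_flag else ""
    print(f"{u:8.1f} {p_fixed:17.4f} {p_flap.total:15.4f}{mark}")
print("(* = outside the flapping model's validity envelope)\n")

for name, curve in (
        ("fixed-wing", lambda u: pennycuick_power(bat, env, u).total),
        ("flapping  ", lambda u: flap_model_power(bat, env, u)[0].total)):
    u_mp = minimum_power_speed(curve)
    u_mr = maximum_range_speed(curve)
    print(f"{name}: U_mp = {u_mp:.1f} m/s, U_mr = {u_mr:.1f} m/s")

print("\nU_mp is where flight is cheapest per unit time; U_mr (always higher)")
print("is where it is cheapest per unit distance.")
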
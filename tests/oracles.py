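"""Independent reference implementations used only to check the package.

The dynamic-model oracle is a literal, scalar, hour-by-hour transcription of
the two-step chill kinetics, kept deliberately naive (math module, explicit
loop, no vectorization) so it shares nothing with the production code path.
"""

import math


def chill_portions_oracle(
    temps_c,
    slp: float = 1.6,
    tetmlt: float = 277.0,
    a0: float = 139500.0,
    a1: float = 2.567e18,
    e0: float = 4153.5,
    e1: float = 12888.8,
):
    """Cumulative chill portions after each hour of ``temps_c`` (degC)."""
    carry = 0.0
    portions = 0.0
    cumulative = []
    for tc in temps_c:
        tk = tc + 273.0
        ftmprt = slp * tetmlt * (tk - tetmlt) / tk
        sr = math.exp(ftmprt)
        xi = sr / (1.0 + sr)
        xs = (a0 / a1) * math.exp(-(e0 - e1) / tk)
        ak1 = a1 * math.exp(-e1 / tk)
        inter_e = xs - (xs - carry) * math.exp(-ak1)
        if inter_e >= 1.0:
            delt = xi * inter_e
            carry = inter_e - delt
        else:
            delt = 0.0
            carry = inter_e
        portions += delt
        cumulative.append(portions)
    return cumulative


def gdh_oracle(tc, t_base=4.0, t_optimal=25.0, t_critical=36.0, f=1.0):
    """Closed-form ASYMCUR hourly response at one temperature."""
    if tc < t_base or tc > t_critical:
        return 0.0
    if tc <= t_optimal:
        return f * (t_optimal - t_base) / 2.0 * (
            1.0 + math.cos(math.pi + math.pi * (tc - t_base) / (t_optimal - t_base))
        )
    return f * (t_optimal - t_base) * (
        1.0 + math.cos(math.pi / 2.0 + math.pi / 2.0 * (tc - t_optimal) / (t_critical - t_optimal))
    )
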
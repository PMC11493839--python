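"""Independent numerical oracles used by the test suite.

The ODE oracle integrates the four-state absorption/disposition system with
an adaptive stiff solver, fully independently of the closed-form solution
under test.
"""

import numpy as np
from scipy.integrate import solve_ivp

from equipopk.structural_pk import PKParameters, Regimen, micro_constants


def ode_profile(p: PKParameters, regimen: Regimen, times: np.ndarray) -> np.ndarray:
    """Concentration profile by adaptive-step numerical integration."""
    m = micro_constants(p)
    infusions = []
    bolus: dict[float, list[float]] = {}
    for e in regimen.events:
        d = e.base_amount
        if e.route == "PO":
            bolus.setdefault(e.time, [0.0, 0.0])[0] += p.F * d
        elif e.infusion_duration and e.infusion_duration > 0:
            infusions.append((e.time, e.time + e.infusion_duration,
                              d / e.infusion_duration))
        else:
            bolus.setdefault(e.time, [0.0, 0.0])[1] += d

    def rhs(t, x):
        gut, a1, a2, a3 = x
        rate = sum(r for (t0, t1, r) in infusions if t0 <= t < t1)
        return [
            -m.ka * gut,
            m.ka * gut - (m.k10 + m.k12 + m.k13) * a1
            + m.k21 * a2 + m.k31 * a3 + rate,
            m.k12 * a1 - m.k21 * a2,
            m.k13 * a1 - m.k31 * a3,
        ]

    times = np.asarray(times, dtype=float)
    breakpoints = sorted(
        set(times.tolist())
        | set(bolus)
        | {t for window in infusions for t in window[:2]}
    )
    x = np.zeros(4)
    tcur = 0.0
    values = {}
    for tb in breakpoints:
        if tb > tcur:
            sol = solve_ivp(rhs, (tcur, tb), x, method="LSODA",
                            rtol=1e-11, atol=1e-13)
            x = sol.y[:, -1]
            tcur = tb
        if tb in bolus:
            x = x + np.array([bolus[tb][0], bolus[tb][1], 0.0, 0.0])
        values[tb] = x[1] / p.V1
    return np.array([values[t] for t in times])


def random_parameters(rng: np.random.Generator) -> PKParameters:
    """A random, physiologically plausible parameter draw for property tests."""
    return PKParameters(
        V1=rng.uniform(0.2, 1.2),
        V2=rng.uniform(0.2, 2.0),
        V3=rng.uniform(1.0, 6.0),
        CL=rng.uniform(0.1, 1.0),
        CL2=rng.uniform(0.5, 5.0),
        CL3=rng.uniform(0.5, 5.0),
        Kabs=rng.uniform(0.3, 3.0),
        F=rng.uniform(0.1, 0.9),
    )
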
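"""Closed-form-checkable dual-topology FEP: 1-D harmonic alchemy.

Both endpoint Hamiltonians are harmonic wells over the same coordinate,
U_A = k_A x^2 / 2 and U_B = k_B x^2 / 2, mixed linearly so window w has
spring constant k(lambda_w) = lambda_w k_A + (1 - lambda_w) k_B.  Each
window is sampled from its exact Boltzmann (Gaussian) distribution, so the
estimator's statistical behavior is isolated from integrator error.  The
exact answer is dF = (kT/2) ln(k_B / k_A).
"""

from __future__ import annotations

import numpy as np

from .sampling import FEPEstimate, fep_estimate, mixed_hamiltonian


def lambda_schedule(n_windows: int, direction: str = "forward"):
    """Lambda ladder, lambda = 1 (state A) to 0 (state B) or reversed."""
    if n_windows < 2:
        raise ValueError("need at least two lambda windows")
    lams = np.linspace(1.0, 0.0, n_windows)
    return lams if direction == "forward" else lams[::-1]


def harmonic_alchemy_fep(k_a: float, k_b: float, kT: float,
                         n_windows: int = 11, n_samples: int = 100000,
                         direction: str = "forward", seed: int = 0) -> FEPEstimate:
    """FEP estimate for the alchemical k_a -> k_b harmonic transformation."""
    rng = np.random.default_rng(seed)
    lams = lambda_schedule(n_windows, direction)
    ks = np.array([mixed_hamiltonian(l, k_a, k_b) for l in lams])
    windows = []
    for w in range(n_windows - 1):
        x = rng.standard_normal(n_samples) * np.sqrt(kT / ks[w])
        dU = 0.5 * (ks[w + 1] - ks[w]) * x * x
        windows.append(dU)
    return fep_estimate(windows, kT, direction=direction)


def exact_harmonic_dF(k_a: float, k_b: float, kT: float) -> float:
    return 0.5 * kT * float(np.log(k_b / k_a))
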
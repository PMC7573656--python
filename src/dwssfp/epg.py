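"""Exact configuration-state (extended-phase-graph) steady state for SSFP.

Independent reference implementation used to validate the closed-form
model in :mod:`dwssfp.signals`: the full linear steady state of the SSFP
partition recursion is solved with inter-pulse relaxation and diffusion
operators, truncated at a configurable harmonic order.  At D = 0 it matches
the classical Freeman-Hill SSFP echo to machine precision; with diffusion
it converges as the truncation order grows (states of winding order k
attenuate like exp(-k^2 q^2 D TR)).

This solver is deliberately simple and dense; it is a correctness oracle,
not a fitting engine.
"""

from __future__ import annotations

import numpy as np

from .signals import SequenceParams, TissueParams

__all__ = ["epg_ss_signal", "classical_ssfp_echo"]


def _epg_core(alpha_deg, T1_s, T2_s, TR_s, q_invmm, delta_s, D, K):
    a = np.deg2rad(alpha_deg)
    c2 = np.cos(a / 2.0) ** 2
    s2 = np.sin(a / 2.0) ** 2
    sa, ca = np.sin(a), np.cos(a)
    E1 = np.exp(-TR_s / T1_s)
    E2 = np.exp(-TR_s / T2_s)
    m2 = (2.0 * np.pi * q_invmm) ** 2

    def att_transverse(k):
        # winding ramps k -> k+1 during the gradient (duration delta),
        # then stays at k+1 for the rest of the TR
        b = m2 * (delta_s * (k * k + k + 1.0 / 3.0) + (TR_s - delta_s) * (k + 1) ** 2)
        return np.exp(-D * b)

    def att_longitudinal(k):
        return np.exp(-D * m2 * TR_s * k * k)

    nu = 2 * K + 1
    N = nu + K + 1
    iu = lambda k: k + K
    iz = lambda k: nu + k
    A = np.zeros((N, N))
    rhs = np.zeros(N)
    # steady state of: u_k <- E2 * att(k-1) * [c2 u_{k-1} - s2 u_{1-k} + sa Z_{|k-1|}]
    for k in range(-K, K + 1):
        row = iu(k)
        A[row, row] += 1.0
        f = E2 * att_transverse(k - 1)
        if -K <= k - 1 <= K:
            A[row, iu(k - 1)] -= f * c2
        if -K <= 1 - k <= K:
            A[row, iu(1 - k)] += f * s2
        if abs(k - 1) <= K:
            A[row, iz(abs(k - 1))] -= f * sa
    # Z_k <- E1 * att_l(k) * [ca Z_k - sa/2 (u_k + u_{-k})] + (1-E1) delta_k0
    for k in range(0, K + 1):
        row = iz(k)
        az = E1 * att_longitudinal(k)
        A[row, row] += 1.0 - az * ca
        A[row, iu(k)] += az * sa / 2.0
        A[row, iu(-k)] += az * sa / 2.0
        if k == 0:
            rhs[row] = 1.0 - E1
    x = np.linalg.solve(A, rhs)
    return abs(x[iu(0)])  # rephased pre-pulse echo state


def epg_ss_signal(
    alpha_actual: float,
    tissue: TissueParams,
    seq: SequenceParams,
    D: float,
    *,
    q: float | None = None,
    order: int = 60,
) -> float:
    """Exact steady-state DW-SSFP echo (fraction of S0) at one setting."""
    if not 0 < alpha_actual <= 180:
        raise ValueError("actual flip angle must be in (0, 180] degrees")
    if D < 0:
        raise ValueError("D must be non-negative")
    q_cm = seq.q if q is None else q
    return float(
        _epg_core(
            alpha_actual,
            tissue.T1 * 1e-3,
            tissue.T2 * 1e-3,
            seq.TR * 1e-3,
            q_cm / 10.0,
            seq.delta * 1e-3,
            D,
            order,
        )
    )


def classical_ssfp_echo(alpha_deg: float, T1_ms: float, T2_ms: float, TR_ms: float) -> float:
    """Non-diffusion-weighted SSFP echo (Freeman-Hill partition solution)."""
    a = np.deg2rad(alpha_deg)
    E1 = np.exp(-TR_ms / T1_ms)
    E2 = np.exp(-TR_ms / T2_ms)
    ca = np.cos(a)
    p = 1.0 - E1 * ca - E2 * E2 * (E1 - ca)
    q = E2 * (1.0 - E1) * (1.0 + ca)
    r = np.sqrt(p * p - q * q)
    return float(abs(np.tan(a / 2.0) * (1.0 - (1.0 - E1 * ca) * (1.0 - E2 * E2) / r)))
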
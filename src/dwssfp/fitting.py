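"""Voxelwise estimation from DW-SSFP series.

The estimation chain mirrors the dual-flip quantification pipeline:

1. :func:`fit_tensor` -- nonlinear tensor fit of the steady-state forward
   model (with noise floor) to one flip angle's series, or to both flips
   simultaneously with a *shared* set of eigenvectors and per-flip
   eigenvalue triplets.  T1, T2, B1 and the noise floor enter as fixed
   voxelwise parameters; eigenvalue ordering L1 > L2 > L3 > 0 is built
   into the parameterisation.
2. :func:`fit_gamma_eigenvalues` -- for each eigenvector, the pair of
   per-flip eigenvalues is explained by a gamma distribution of
   diffusivities (Dm_i, Ds_i) through a three-term regularised objective:
   the two flips' simulated apparent eigenvalues must match the fitted
   ones, and the prior ``lambda * ||Dm_i - L_i(alpha_high)||^2`` anchors
   the mean to the higher-SNR high-flip estimate (lambda defaults to 1).
3. :func:`map_eigenvalues_to_beff` -- the per-eigenvector gamma parameters
   are converted to eigenvalues at one common effective b-value (default
   4000 s/mm^2), removing the flip-angle/B1 dependence.

:func:`fit_ballsticks` provides the orientation (ball & sticks) model with
shared stick geometry and per-flip diffusivities, and
:func:`posterior_pdd_samples` / :func:`pdd_dispersion` quantify angular
uncertainty of the principal diffusion direction from Markov-chain samples
around the fitted optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .signals import (
    DEFAULT_CLOSURE_DEPTH,
    SequenceParams,
    TissueParams,
    _buxton_core,
    noise_floor_signal,
)
from .gamma import _gamma_batch_raw, adc_at_beff, GammaDiffusivity, buxton_gamma_signal
from .phantom import DirectionSet

__all__ = [
    "FLAG_OK",
    "FLAG_LOW_SIGNAL",
    "FLAG_NO_CONVERGENCE",
    "FLAG_ORDERING",
    "FLAG_OUT_OF_BOUNDS",
    "TensorFitResult",
    "DualFlipTensorFit",
    "EigenGammaFit",
    "BallSticksFitResult",
    "OrientationSamples",
    "fit_tensor",
    "apparent_diffusivity_at_flip",
    "fit_gamma_eigenvalues",
    "map_eigenvalues_to_beff",
    "fit_ballsticks",
    "posterior_pdd_samples",
    "pdd_dispersion",
    "fractional_anisotropy",
    "mean_diffusivity",
]

FLAG_OK = 0
FLAG_LOW_SIGNAL = 1
FLAG_NO_CONVERGENCE = 2
FLAG_ORDERING = 4
FLAG_OUT_OF_BOUNDS = 8

#: Diffusivity box constraint (mm^2/s) for voxel fits; with the
#: mean-signal-over-floor exclusion this suppresses spurious estimates in
#: very low signal regions.
D_BOUNDS = (1e-6, 3e-3)

_D_SCALE = 1e-4  # typical diffusivity, used to condition residuals


def _bux_raw(alpha_deg, T1_ms, T2_ms, TR_ms, q_cm, delta_ms, D, depth=DEFAULT_CLOSURE_DEPTH):
    return _buxton_core(
        np.asarray(alpha_deg, float),
        np.asarray(T1_ms, float) * 1e-3,
        np.asarray(T2_ms, float) * 1e-3,
        TR_ms * 1e-3,
        q_cm / 10.0,
        delta_ms * 1e-3,
        np.asarray(D, float),
        depth,
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1.0 - p))


def _eigenvalues_from_params(a, b, c):
    """Strictly ordered positive eigenvalues: L1 = e^a, L2 = L1*sig(b),
    L3 = L2*sig(c)."""
    L1 = np.exp(a)
    L2 = L1 * _sigmoid(b)
    L3 = L2 * _sigmoid(c)
    return np.array([L1, L2, L3])


def _params_from_eigenvalues(L):
    L1, L2, L3 = L
    a = np.log(L1)
    b = _logit(L2 / L1)
    c = _logit(L3 / L2)
    return a, b, c


def fractional_anisotropy(L):
    """FA from eigenvalue triplets (last axis of length 3)."""
    L = np.asarray(L, float)
    m = L.mean(axis=-1, keepdims=True)
    num = ((L - m) ** 2).sum(axis=-1)
    den = (L**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def mean_diffusivity(L):
    return np.asarray(L, float).mean(axis=-1)


# ---------------------------------------------------------------------------
# Tensor fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DualFlipTensorFit:
    """Single-voxel dual-flip tensor estimate: shared eigenvector columns,
    per-flip ordered eigenvalues and signal scales."""

    V: np.ndarray  # (3, 3), columns V1, V2, V3
    L_low: tuple[float, float, float]
    L_high: tuple[float, float, float]
    S0_low: float
    S0_high: float


@dataclass
class TensorFitResult:
    """Volume-level tensor fit output.

    ``L[flip]`` holds (..., 3) eigenvalues; ``V`` the shared (or
    single-flip) eigenvector columns (..., 3, 3); ``flags`` the bitwise QC
    flags; ``fitted`` marks the voxels that were attempted.
    """

    mode: str
    flips: tuple[float, ...]
    L: dict[float, np.ndarray]
    V: np.ndarray
    S0: dict[float, np.ndarray]
    flags: np.ndarray
    residual: np.ndarray
    fitted: np.ndarray

    def at(self, idx) -> DualFlipTensorFit:
        lo, hi = min(self.flips), max(self.flips)
        return DualFlipTensorFit(
            V=self.V[idx],
            L_low=tuple(self.L[lo][idx]),
            L_high=tuple(self.L[hi][idx]),
            S0_low=float(self.S0[lo][idx]),
            S0_high=float(self.S0[hi][idx]),
        )


def _effective_q(dirs: DirectionSet, spoiler_as_q0: bool) -> np.ndarray:
    q = dirs.q.copy()
    if spoiler_as_q0 and len(q):
        qmax = q.max()
        q[q < qmax] = 0.0
    return q


def _init_tensor_voxel(data, dirs_m, q_eff, alpha, T1, T2, seq, Snf, depth):
    """Log-linear initialisation: S0 from the non-DW volumes, per-volume
    apparent diffusivities by inverting the scalar attenuation on a grid,
    then a linear 6-component tensor fit."""
    qmax = q_eff.max()
    dw = q_eff == qmax
    s_nd = np.sqrt(np.maximum(np.mean(data[~dw]) ** 2 - Snf**2, 1e-20)) if np.any(~dw) else np.nan
    f_nd = _bux_raw(alpha, T1, T2, seq.TR, 0.0, seq.delta, 1e-4, depth)
    S0 = s_nd / max(f_nd, 1e-12) if np.isfinite(s_nd) else data.max() / max(f_nd, 1e-12)
    S0 = max(S0, 1e-9)
    Dgrid = np.geomspace(D_BOUNDS[0], D_BOUNDS[1], 64)
    att_grid = _bux_raw(alpha, T1, T2, seq.TR, qmax, seq.delta, Dgrid, depth) / f_nd
    s_dw = np.sqrt(np.maximum(data[dw] ** 2 - Snf**2, 1e-20))
    ratio = np.clip(s_dw / (S0 * f_nd), att_grid.min(), att_grid.max())
    # att_grid decreases with D
    D_est = np.interp(-ratio, -att_grid, Dgrid)
    g = dirs_m[dw]
    M = np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    )
    t, *_ = np.linalg.lstsq(M, D_est, rcond=None)
    T = np.array([[t[0], t[3], t[4]], [t[3], t[1], t[5]], [t[4], t[5], t[2]]])
    w, Vm = np.linalg.eigh(T)
    order = np.argsort(w)[::-1]
    L = np.clip(w[order], D_BOUNDS[0], D_BOUNDS[1])
    # enforce strict ordering
    L[1] = min(L[1], 0.95 * L[0])
    L[2] = min(L[2], 0.95 * L[1])
    L = np.maximum(L, D_BOUNDS[0] * np.array([4.0, 2.0, 1.0]))
    V = Vm[:, order]
    if np.linalg.det(V) < 0:
        V[:, 2] *= -1
    rot = Rotation.from_matrix(V).as_rotvec()
    return S0, L, rot


class _TensorProblem:
    """Residuals of the (dual-)flip tensor model for one voxel."""

    def __init__(self, data_by_flip, dirs, sequences, T1, T2, B1, Snf,
                 spoiler_as_q0=True, depth=DEFAULT_CLOSURE_DEPTH):
        self.flips = sorted(data_by_flip)
        self.data = np.concatenate([data_by_flip[f] for f in self.flips])
        self.dirs = dirs
        self.seqs = sequences
        self.T1, self.T2, self.B1, self.Snf = T1, T2, B1, Snf
        self.depth = depth
        self.q_eff = _effective_q(dirs, spoiler_as_q0)
        self.n_flips = len(self.flips)
        self.nvol = len(dirs)

    @property
    def n_params(self):
        return self.n_flips * 4 + 3  # lnS0 + 3 eigvals per flip, shared rotvec

    def unpack(self, p):
        lnS0 = p[: self.n_flips]
        rot = p[self.n_flips : self.n_flips + 3]
        eig = p[self.n_flips + 3 :].reshape(self.n_flips, 3)
        return lnS0, rot, eig

    def model(self, p):
        lnS0, rot, eig = self.unpack(p)
        R = Rotation.from_rotvec(rot).as_matrix()
        cos2 = (self.dirs.vectors @ R) ** 2  # (nvol, 3)
        out = np.empty(self.n_flips * self.nvol)
        for i, f in enumerate(self.flips):
            L = _eigenvalues_from_params(*eig[i])
            Dg = cos2 @ L
            seq = self.seqs[f]
            alpha = self.B1 * f
            S = np.empty(self.nvol)
            for qv in np.unique(self.q_eff):
                sel = self.q_eff == qv
                S[sel] = _bux_raw(
                    alpha, self.T1, self.T2, seq.TR, qv, seq.delta, Dg[sel], self.depth
                )
            out[i * self.nvol : (i + 1) * self.nvol] = np.exp(lnS0[i]) * S
        return noise_floor_signal(out, self.Snf)

    def residual(self, p):
        return self.model(p) - self.data

    def init(self):
        # seed from the highest flip (best SNR at low B1)
        f_hi = self.flips[-1]
        data_hi = self.data[(self.n_flips - 1) * self.nvol :]
        S0, L, rot = _init_tensor_voxel(
            data_hi, self.dirs.vectors, self.q_eff, self.B1 * f_hi,
            self.T1, self.T2, self.seqs[f_hi], self.Snf, self.depth
        )
        a, b, c = _params_from_eigenvalues(L)
        p = np.empty(self.n_params)
        p[: self.n_flips] = np.log(S0)
        p[self.n_flips : self.n_flips + 3] = rot
        for i in range(self.n_flips):
            p[self.n_flips + 3 + 3 * i : self.n_flips + 6 + 3 * i] = (a, b, c)
        return p

    def pdd(self, p):
        _, rot, _ = self.unpack(p)
        return Rotation.from_rotvec(rot).as_matrix()[:, 0]


def fit_tensor(
    volumes: dict[float, np.ndarray],
    dirs: DirectionSet,
    maps: dict,
    sequences: dict[float, SequenceParams],
    mode: str = "dual",
    *,
    voxels: np.ndarray | None = None,
    spoiler_as_q0: bool = True,
    exclude_snf_factor: float = 2.0,
    depth: int = DEFAULT_CLOSURE_DEPTH,
    max_nfev: int = 2000,
) -> TensorFitResult:
    """Voxelwise (dual-)flip tensor fit.

    Parameters
    ----------
    volumes : dict
        ``{nominal_flip: 4-D array}``; one entry in single mode, two in
        dual mode (same direction set for both).
    dirs : DirectionSet
        Directions and q-values shared by every flip.
    maps : dict
        ``T1``, ``T2``, ``B1`` volumes (ms / relative); optional ``mask``;
        optional ``Snf`` (scalar or volume) noise floor.
    mode : {"single", "dual"}
        Dual mode estimates one shared eigenvector set and per-flip
        eigenvalue triplets.

    Voxels whose mean signal is below ``exclude_snf_factor * Snf`` are
    flagged :data:`FLAG_LOW_SIGNAL` and skipped; optimiser failures are
    flagged :data:`FLAG_NO_CONVERGENCE`, not raised.
    """
    if mode not in ("single", "dual"):
        raise ValueError("mode must be 'single' or 'dual'")
    flips = sorted(volumes)
    if mode == "single" and len(flips) != 1:
        raise ValueError("single mode expects exactly one flip's volumes")
    if mode == "dual" and len(flips) != 2:
        raise ValueError("dual mode expects exactly two flips' volumes")
    nvol = len(dirs)
    for f in flips:
        if volumes[f].shape[-1] != nvol:
            raise ValueError(f"flip {f}: volume count != direction count")
    n_min = 7 if mode == "single" else 10
    if len(flips) * nvol < n_min:
        raise ValueError(
            f"{mode} tensor fit needs >= {n_min} volumes, got {len(flips) * nvol}"
        )
    shape = volumes[flips[0]].shape[:-1]
    mask = np.asarray(maps.get("mask", np.ones(shape, bool)), bool)
    if voxels is None:
        voxels = mask
    voxels = voxels & mask
    snf_map = np.broadcast_to(np.asarray(maps.get("Snf", 0.0), float), shape)

    L = {f: np.zeros(shape + (3,)) for f in flips}
    V = np.zeros(shape + (3, 3))
    S0 = {f: np.zeros(shape) for f in flips}
    flags = np.zeros(shape, np.uint8)
    resid = np.full(shape, np.nan)

    for idx in zip(*np.nonzero(voxels)):
        data = {f: volumes[f][idx] for f in flips}
        snf = float(snf_map[idx])
        if snf > 0 and np.mean([d.mean() for d in data.values()]) < exclude_snf_factor * snf:
            flags[idx] |= FLAG_LOW_SIGNAL
            continue
        prob = _TensorProblem(
            data, dirs, sequences,
            float(maps["T1"][idx]), float(maps["T2"][idx]), float(maps["B1"][idx]),
            snf, spoiler_as_q0, depth,
        )
        p0 = prob.init()
        try:
            sol = least_squares(prob.residual, p0, method="lm", max_nfev=max_nfev)
        except Exception:
            flags[idx] |= FLAG_NO_CONVERGENCE
            continue
        if not sol.success:
            flags[idx] |= FLAG_NO_CONVERGENCE
        lnS0, rot, eig = prob.unpack(sol.x)
        R = Rotation.from_rotvec(rot).as_matrix()
        V[idx] = R
        for i, f in enumerate(flips):
            Li = _eigenvalues_from_params(*eig[i])
            L[f][idx] = Li
            S0[f][idx] = np.exp(lnS0[i])
            if np.any(Li < D_BOUNDS[0]) or np.any(Li > D_BOUNDS[1]):
                flags[idx] |= FLAG_OUT_OF_BOUNDS
        resid[idx] = np.sqrt(np.mean(sol.fun**2))
    return TensorFitResult(
        mode=mode, flips=tuple(flips), L=L, V=V, S0=S0,
        flags=flags, residual=resid, fitted=voxels,
    )


# ---------------------------------------------------------------------------
# Apparent diffusivity and the eigenvalue-gamma fit
# ---------------------------------------------------------------------------

def apparent_diffusivity_at_flip(
    gamma: GammaDiffusivity,
    alpha_actual: float,
    tissue: TissueParams,
    seq: SequenceParams,
    *,
    q: float | None = None,
    depth: int = DEFAULT_CLOSURE_DEPTH,
) -> float:
    """The single diffusivity whose steady-state attenuation matches the
    gamma system's at this flip angle (the simulated eigenvalue L_sim).

    Because the q = 0 signal carries no diffusion weighting, matching the
    attenuation ratio S(q)/S(0) and matching the raw q-weighted signal at a
    shared S0 are the same criterion.  Root-finding is by bisection on the
    monotone scalar model; raises if the equivalent diffusivity falls
    outside (0, 10 Dm].
    """
    q_cm = seq.q if q is None else q
    target = buxton_gamma_signal(alpha_actual, tissue, seq, gamma, q=q_cm, depth=depth)
    if gamma.degenerate:
        return gamma.Dm

    def f(D):
        return float(
            _bux_raw(alpha_actual, tissue.T1, tissue.T2, seq.TR, q_cm, seq.delta, D, depth)
        ) - target

    lo, hi = 1e-12, 10.0 * gamma.Dm
    if f(hi) > 0:
        raise ValueError(
            f"no matching diffusivity in (0, 10*Dm] for Dm={gamma.Dm}, Ds={gamma.Ds}"
        )
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _apparent_d_batch(Dm, Ds, alpha, T1, T2, seq: SequenceParams, q_cm, nodes, depth):
    """Vectorised L_sim: bisection of the scalar model onto the
    gamma-averaged signal, element-wise."""
    target = _gamma_batch_raw(alpha, Dm, Ds, T1, T2, seq.TR, q_cm, seq.delta, nodes, depth)
    lo = np.full(np.shape(target), np.log(1e-9))
    hi = np.full(np.shape(target), np.log(3e-2))
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        val = _bux_raw(alpha, T1, T2, seq.TR, q_cm, seq.delta, np.exp(mid), depth)
        above = val > target  # signal too high -> need more diffusivity
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return np.exp(0.5 * (lo + hi))


@dataclass
class EigenGammaFit:
    """Per-eigenvector gamma parameters (maps shaped (..., 3))."""

    Dm: np.ndarray
    Ds: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    lambda_reg: float


def fit_gamma_eigenvalues(
    L_low,
    L_high,
    alpha_low,
    alpha_high,
    tissue,
    seq_low: SequenceParams,
    seq_high: SequenceParams | None = None,
    lambda_reg: float = 1.0,
    *,
    nodes: int = 32,
    depth: int = DEFAULT_CLOSURE_DEPTH,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> EigenGammaFit:
    """Regularised gamma fit along each eigenvector (vectorised LM).

    For eigenvector i the objective is::

        || L_sim(alpha_low; Dm_i, Ds_i)  - L_exp_low_i  ||^2
      + || L_sim(alpha_high; Dm_i, Ds_i) - L_exp_high_i ||^2
      + lambda * || Dm_i - L_exp_high_i ||^2

    where L_sim is the apparent single diffusivity implied by the
    gamma-averaged steady-state signal at that (voxelwise, B1-scaled) flip
    angle.  A Levenberg-Marquardt iteration in (ln Dm, ln Ds) runs
    vectorised over all voxels and eigenvectors; initialisation uses
    ``Dm = L_exp_high`` (consistent with the prior) and
    ``Ds = sqrt(|L_high - L_low| * Dm)``.
    """
    L_low = np.asarray(L_low, float)
    L_high = np.asarray(L_high, float)
    if L_low.shape != L_high.shape or L_low.shape[-1] != 3:
        raise ValueError("L_low and L_high must both be (..., 3)")
    base_shape = L_low.shape[:-1]
    if seq_high is None:
        seq_high = seq_low
    if isinstance(tissue, TissueParams):
        T1 = np.broadcast_to(tissue.T1, base_shape)
        T2 = np.broadcast_to(tissue.T2, base_shape)
    else:
        T1 = np.broadcast_to(np.asarray(tissue["T1"], float), base_shape)
        T2 = np.broadcast_to(np.asarray(tissue["T2"], float), base_shape)
    a_lo = np.broadcast_to(np.asarray(alpha_low, float), base_shape)
    a_hi = np.broadcast_to(np.asarray(alpha_high, float), base_shape)

    # flatten voxels x eigenvectors
    rep = lambda x: np.repeat(np.ravel(x), 3)
    Ll = L_low.reshape(-1)
    Lh = L_high.reshape(-1)
    al, ah = rep(a_lo), rep(a_hi)
    t1, t2 = rep(T1), rep(T2)
    n = Ll.size
    valid = (Ll > 0) & (Lh > 0)

    u = np.log(np.maximum(Lh, 1e-9))  # ln Dm
    ds0 = np.sqrt(np.abs(Lh - Ll) * np.maximum(Lh, 1e-9))
    v = np.log(np.clip(ds0, 1e-7, 2e-3))  # ln Ds
    sqrt_lam = np.sqrt(lambda_reg)

    def residuals(u, v):
        Dm = np.exp(u)
        Ds = np.exp(v)
        Ls_lo = _apparent_d_batch(Dm, Ds, al, t1, t2, seq_low, seq_low.q, nodes, depth)
        Ls_hi = _apparent_d_batch(Dm, Ds, ah, t1, t2, seq_high, seq_high.q, nodes, depth)
        return np.stack(
            [(Ls_lo - Ll) / _D_SCALE, (Ls_hi - Lh) / _D_SCALE,
             sqrt_lam * (Dm - Lh) / _D_SCALE]
        )  # (3, n)

    r = residuals(u, v)
    cost = (r**2).sum(axis=0)
    mu = np.full(n, 1e-3)
    h = 1e-4
    converged = np.zeros(n, bool)
    for _ in range(max_iter):
        active = valid & ~converged
        if not np.any(active):
            break
        Ju = (residuals(u + h, v) - r) / h
        Jv = (residuals(u, v + h) - r) / h
        A11 = (Ju * Ju).sum(axis=0) + mu
        A12 = (Ju * Jv).sum(axis=0)
        A22 = (Jv * Jv).sum(axis=0) + mu
        g1 = (Ju * r).sum(axis=0)
        g2 = (Jv * r).sum(axis=0)
        det = A11 * A22 - A12**2
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        du = -(A22 * g1 - A12 * g2) / det
        dv = -(-A12 * g1 + A11 * g2) / det
        du = np.clip(du, -1.0, 1.0)
        dv = np.clip(dv, -2.0, 2.0)
        u_new = np.clip(u + np.where(active, du, 0.0), np.log(1e-7), np.log(5e-3))
        v_new = np.clip(v + np.where(active, dv, 0.0), np.log(1e-8), np.log(5e-3))
        r_new = residuals(u_new, v_new)
        cost_new = (r_new**2).sum(axis=0)
        better = (cost_new < cost) & active
        u = np.where(better, u_new, u)
        v = np.where(better, v_new, v)
        r = np.where(better, r_new, r)
        improved = cost - cost_new
        cost = np.where(better, cost_new, cost)
        mu = np.where(better, mu * 0.3, mu * 4.0)
        mu = np.clip(mu, 1e-10, 1e8)
        converged |= valid & (
            (better & (improved < tol * (cost + 1e-30))) | (mu >= 1e8)
        )
    out_shape = base_shape + (3,)
    return EigenGammaFit(
        Dm=np.exp(u).reshape(out_shape),
        Ds=np.exp(v).reshape(out_shape),
        residual=np.sqrt(cost).reshape(out_shape),
        converged=(converged | ~valid).reshape(out_shape) if n else np.zeros(out_shape, bool),
        lambda_reg=lambda_reg,
    )


def map_eigenvalues_to_beff(eigfit: EigenGammaFit, beff_target: float = 4000.0):
    """Eigenvalue maps at one common effective b-value.

    ``L_i(beff) = ADC(beff; Dm_i, Ds_i)`` per eigenvector.  Voxels whose
    mapped eigenvalues violate L1 > L2 > L3 are flagged (not reordered, to
    keep the eigenvalue-eigenvector pairing intact).

    Returns ``(L_beff, flags)``.
    """
    if beff_target <= 0:
        raise ValueError("beff_target must be positive")
    Dm = np.asarray(eigfit.Dm, float)
    Ds = np.asarray(eigfit.Ds, float)
    k2 = np.where(Ds > 0, (Dm / np.where(Ds > 0, Ds, 1.0)) ** 2, np.inf)
    x = beff_target * Ds**2 / Dm
    with np.errstate(invalid="ignore", over="ignore"):
        L = np.where(
            (Ds <= 1e-7 * Dm) | (x < 1e-12),
            Dm,
            k2 * np.log1p(x) / beff_target,
        )
    flags = np.zeros(Dm.shape[:-1], np.uint8)
    bad = ~((L[..., 0] > L[..., 1]) & (L[..., 1] > L[..., 2]))
    flags[bad] |= FLAG_ORDERING
    return L, flags


# ---------------------------------------------------------------------------
# Ball & sticks
# ---------------------------------------------------------------------------

@dataclass
class BallSticksFitResult:
    mode: str
    flips: tuple[float, ...]
    fractions: np.ndarray  # (..., n_sticks), sorted descending
    sticks: np.ndarray  # (..., n_sticks, 3)
    d: dict[float, np.ndarray]
    S0: dict[float, np.ndarray]
    flags: np.ndarray
    residual: np.ndarray
    fitted: np.ndarray


class _BallSticksProblem:
    """Residuals of the (dual-)flip ball & sticks model for one voxel.

    Parameter vector: per-flip ln S0, per-flip ln d, then per stick
    (theta, phi, z) with stick-breaking fractions f_1 = sig(z_1),
    f_2 = (1 - f_1) sig(z_2), ...
    """

    def __init__(self, data_by_flip, dirs, sequences, T1, T2, B1, Snf, n_sticks,
                 spoiler_as_q0=True, depth=DEFAULT_CLOSURE_DEPTH):
        self.flips = sorted(data_by_flip)
        self.data = np.concatenate([data_by_flip[f] for f in self.flips])
        self.dirs = dirs
        self.seqs = sequences
        self.T1, self.T2, self.B1, self.Snf = T1, T2, B1, Snf
        self.n_sticks = n_sticks
        self.depth = depth
        self.q_eff = _effective_q(dirs, spoiler_as_q0)
        self.n_flips = len(self.flips)
        self.nvol = len(dirs)

    @property
    def n_params(self):
        return 2 * self.n_flips + 3 * self.n_sticks

    def unpack(self, p):
        lnS0 = p[: self.n_flips]
        lnd = p[self.n_flips : 2 * self.n_flips]
        sticks = p[2 * self.n_flips :].reshape(self.n_sticks, 3)
        return lnS0, lnd, sticks

    @staticmethod
    def stick_vectors(sticks):
        th, ph = sticks[:, 0], sticks[:, 1]
        return np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )

    @staticmethod
    def fractions(sticks):
        rem = 1.0
        f = np.empty(len(sticks))
        for j in range(len(sticks)):
            f[j] = rem * _sigmoid(sticks[j, 2])
            rem -= f[j]
        return f

    def model(self, p):
        lnS0, lnd, sticks = self.unpack(p)
        v = self.stick_vectors(sticks)
        f = self.fractions(sticks)
        proj2 = (self.dirs.vectors @ v.T) ** 2  # (nvol, n_sticks)
        out = np.empty(self.n_flips * self.nvol)
        for i, fl in enumerate(self.flips):
            seq = self.seqs[fl]
            d = np.exp(lnd[i])
            alpha = self.B1 * fl
            S = np.zeros(self.nvol)
            for qv in np.unique(self.q_eff):
                sel = self.q_eff == qv
                ball = _bux_raw(alpha, self.T1, self.T2, seq.TR, qv, seq.delta, d, self.depth)
                S[sel] = (1.0 - f.sum()) * ball
                for j in range(self.n_sticks):
                    S[sel] += f[j] * _bux_raw(
                        alpha, self.T1, self.T2, seq.TR, qv, seq.delta,
                        d * proj2[sel, j], self.depth,
                    )
            out[i * self.nvol : (i + 1) * self.nvol] = np.exp(lnS0[i]) * S
        return noise_floor_signal(out, self.Snf)

    def residual(self, p):
        return self.model(p) - self.data

    def init(self, rng):
        f_hi = self.flips[-1]
        data_hi = self.data[(self.n_flips - 1) * self.nvol :]
        qmax = self.q_eff.max()
        dw = self.q_eff == qmax
        nd_mean = data_hi[~dw].mean() if np.any(~dw) else data_hi.max()
        f_nd = _bux_raw(self.B1 * f_hi, self.T1, self.T2, self.seqs[f_hi].TR, 0.0,
                        self.seqs[f_hi].delta, 1e-4, self.depth)
        S0 = max(nd_mean / max(float(f_nd), 1e-12), 1e-9)
        # strongest attenuation ~ fibre direction
        v0 = self.dirs.vectors[dw][np.argmin(data_hi[dw])]
        p = np.empty(self.n_params)
        p[: self.n_flips] = np.log(S0)
        p[self.n_flips : 2 * self.n_flips] = np.log(1e-4)
        for j in range(self.n_sticks):
            if j == 0:
                v = v0
            else:
                v = rng.normal(size=3)
            v = v / np.linalg.norm(v)
            th = np.arccos(np.clip(v[2], -1, 1))
            ph = np.arctan2(v[1], v[0])
            p[2 * self.n_flips + 3 * j : 2 * self.n_flips + 3 * j + 3] = (
                th, ph, _logit(0.5 / self.n_sticks)
            )
        return p

    def pdd(self, p):
        _, _, sticks = self.unpack(p)
        f = self.fractions(sticks)
        v = self.stick_vectors(sticks)
        return v[np.argmax(f)]


def fit_ballsticks(
    volumes: dict[float, np.ndarray],
    dirs: DirectionSet,
    maps: dict,
    sequences: dict[float, SequenceParams],
    n_sticks: int = 1,
    mode: str = "dual",
    *,
    voxels: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 42,
    spoiler_as_q0: bool = True,
    exclude_snf_factor: float = 2.0,
    depth: int = DEFAULT_CLOSURE_DEPTH,
    max_nfev: int = 1500,
) -> BallSticksFitResult:
    """Voxelwise ball & sticks fit with shared orientations/fractions and
    per-flip diffusivities (dual mode).  Multi-start LM mitigates local
    minima; sticks are sorted by fraction to resolve label switching."""
    if n_sticks not in (1, 2, 3):
        raise ValueError("n_sticks must be 1, 2 or 3")
    if mode not in ("single", "dual"):
        raise ValueError("mode must be 'single' or 'dual'")
    flips = sorted(volumes)
    if (mode == "single") != (len(flips) == 1):
        raise ValueError(f"{mode} mode expects {'one' if mode == 'single' else 'two'} flips")
    nvol = len(dirs)
    n_params = 2 * len(flips) + 3 * n_sticks
    if len(flips) * nvol < n_params + 1:
        raise ValueError("under-determined ball & sticks fit")
    shape = volumes[flips[0]].shape[:-1]
    mask = np.asarray(maps.get("mask", np.ones(shape, bool)), bool)
    if voxels is None:
        voxels = mask
    voxels = voxels & mask
    snf_map = np.broadcast_to(np.asarray(maps.get("Snf", 0.0), float), shape)
    rng = np.random.default_rng(seed)

    fr = np.zeros(shape + (n_sticks,))
    st = np.zeros(shape + (n_sticks, 3))
    d = {f: np.zeros(shape) for f in flips}
    S0 = {f: np.zeros(shape) for f in flips}
    flags = np.zeros(shape, np.uint8)
    resid = np.full(shape, np.nan)

    for idx in zip(*np.nonzero(voxels)):
        data = {f: volumes[f][idx] for f in flips}
        snf = float(snf_map[idx])
        if snf > 0 and np.mean([dd.mean() for dd in data.values()]) < exclude_snf_factor * snf:
            flags[idx] |= FLAG_LOW_SIGNAL
            continue
        prob = _BallSticksProblem(
            data, dirs, sequences,
            float(maps["T1"][idx]), float(maps["T2"][idx]), float(maps["B1"][idx]),
            snf, n_sticks, spoiler_as_q0, depth,
        )
        best = None
        for _ in range(n_starts):
            p0 = prob.init(rng)
            try:
                sol = least_squares(prob.residual, p0, method="lm", max_nfev=max_nfev)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            flags[idx] |= FLAG_NO_CONVERGENCE
            continue
        lnS0, lnd, sticks = prob.unpack(best.x)
        f_v = prob.fractions(sticks)
        v = prob.stick_vectors(sticks)
        order = np.argsort(f_v)[::-1]
        fr[idx] = f_v[order]
        st[idx] = v[order]
        for i, fl in enumerate(flips):
            d[fl][idx] = np.exp(lnd[i])
            S0[fl][idx] = np.exp(lnS0[i])
        resid[idx] = np.sqrt(np.mean(best.fun**2))
    return BallSticksFitResult(
        mode=mode, flips=tuple(flips), fractions=fr, sticks=st, d=d, S0=S0,
        flags=flags, residual=resid, fitted=voxels,
    )


# ---------------------------------------------------------------------------
# Orientation posterior and dispersion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationSamples:
    """Posterior draws of the principal diffusion direction (antipodally
    symmetric: v and -v are the same orientation)."""

    vectors: np.ndarray  # (n, 3) unit vectors
    acceptance_rate: float = np.nan
    warn: bool = False

    def __post_init__(self):
        v = np.asarray(self.vectors, float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise ValueError("vectors must be a non-empty (n, 3) array")
        if not np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-6):
            raise ValueError("orientation samples must be unit vectors")
        object.__setattr__(self, "vectors", v)

    def __len__(self):
        return self.vectors.shape[0]


def posterior_pdd_samples(
    volumes: dict[float, np.ndarray],
    dirs: DirectionSet,
    maps: dict,
    sequences: dict[float, SequenceParams],
    voxel: tuple,
    model: str = "tensor",
    mode: str = "dual",
    n_samples: int = 500,
    seed: int = 0,
    *,
    n_sticks: int = 1,
    spoiler_as_q0: bool = True,
    depth: int = DEFAULT_CLOSURE_DEPTH,
    target_acceptance: float = 0.3,
) -> OrientationSamples:
    """Posterior orientation samples for one voxel.

    A point fit initialises a random-walk Metropolis chain under the
    Gaussian likelihood of the same forward model (noise variance set from
    the point fit's residuals).  The step size adapts toward
    ``target_acceptance`` during the first half of ``2 * n_samples``
    iterations (discarded as burn-in); the PDD (tensor V1 or largest-
    fraction stick) of the second half is returned, sign-aligned to the
    point estimate.  Fixed seeds give bit-identical chains.  An acceptance
    rate outside [0.1, 0.9] after adaptation sets ``warn``.
    """
    flips = sorted(volumes)
    data = {f: volumes[f][voxel] for f in flips}
    args = (
        data, dirs, sequences,
        float(maps["T1"][voxel]), float(maps["T2"][voxel]), float(maps["B1"][voxel]),
        float(np.broadcast_to(np.asarray(maps.get("Snf", 0.0), float),
                              volumes[flips[0]].shape[:-1])[voxel]),
    )
    rng = np.random.default_rng(seed)
    if model == "tensor":
        prob = _TensorProblem(*args, spoiler_as_q0=spoiler_as_q0, depth=depth)
        p0 = prob.init()
    elif model == "ballsticks":
        prob = _BallSticksProblem(*args[:7], n_sticks, spoiler_as_q0, depth)
        p0 = prob.init(rng)
    else:
        raise ValueError("model must be 'tensor' or 'ballsticks'")
    sol = least_squares(prob.residual, p0, method="lm", max_nfev=2000)
    p_hat = sol.x
    nres = sol.fun.size
    dof = max(nres - p_hat.size, 1)
    sigma2 = max(2.0 * sol.cost / dof, 1e-30)

    def loglike(p):
        # extreme proposals can overflow the forward model; treat them as
        # zero-probability rather than propagating warnings/NaNs
        with np.errstate(all="ignore"):
            r = prob.residual(p)
        if not np.all(np.isfinite(r)):
            return -np.inf
        return -0.5 * float(r @ r) / sigma2

    v_ref = prob.pdd(p_hat)
    scale = 0.02 * (np.abs(p_hat) + 0.05)
    c = 1.0
    n_iter = 2 * n_samples
    burn = n_iter // 2
    ll = loglike(p_hat)
    p = p_hat.copy()
    acc_window = 0
    accepted_post = 0
    out = np.empty((n_iter - burn, 3))
    for it in range(n_iter):
        prop = p + c * scale * rng.normal(size=p.size)
        ll_prop = loglike(prop)
        if np.log(rng.uniform()) < ll_prop - ll:
            p, ll = prop, ll_prop
            acc_window += 1
            if it >= burn:
                accepted_post += 1
        if it < burn and (it + 1) % 25 == 0:
            rate = acc_window / 25.0
            c *= 1.25 if rate > target_acceptance + 0.05 else 1.0
            c /= 1.25 if rate < target_acceptance - 0.05 else 1.0
            acc_window = 0
        if it >= burn:
            v = prob.pdd(p)
            if v @ v_ref < 0:
                v = -v
            out[it - burn] = v
    rate = accepted_post / max(n_iter - burn, 1)
    return OrientationSamples(
        vectors=out, acceptance_rate=rate, warn=not (0.1 <= rate <= 0.9)
    )


def pdd_dispersion(samples: OrientationSamples | np.ndarray) -> float:
    """Angular uncertainty in [0, 1]: one minus the principal eigenvalue of
    the mean dyadic tensor mean(v v^T).  0 for perfectly aligned
    (or antipodal) samples, 2/3 for uniform orientations; invariant to
    permutation and to flipping any sample's sign."""
    v = samples.vectors if isinstance(samples, OrientationSamples) else np.asarray(samples, float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise ValueError("need at least two 3-vectors")
    dyad = np.einsum("ni,nj->ij", v, v) / v.shape[0]
    w = np.linalg.eigvalsh(dyad)
    return float(1.0 - w[-1])
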
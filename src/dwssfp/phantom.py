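"""Digital DW-SSFP phantoms: the test bed for every fitting stage.

No scanner data ships with this package; instead a brain-like digital
phantom provides co-registered B1 / T1 / T2 / mask volumes, voxelwise
ground-truth diffusion (gamma-distributed diffusivities along tensor
eigenvectors, or ball & sticks), and simulated dual-flip DW-SSFP series
with Rician noise.  The defaults emulate the fixed post-mortem regime the
sequence is used in: T1 = 500 ms, T2 = 30 ms, mean diffusivity near
1e-4 mm^2/s, a transmit field that decays smoothly from 1.0 at the centre
of the sample to 0.3 at its edge, and an acquisition of 120 diffusion
directions (q = 300 cm^-1) plus six spoiled "non-DW" volumes
(q = 20 cm^-1) per nominal flip angle (24 and 94 degrees).

Restriction (non-Gaussianity) is encoded by the per-eigenvector standard
deviations ``Ds_i``; the default ``Ds_i = 0.5 * Dm_i`` gives a gamma shape
parameter of 4, strong enough that the two flip angles see clearly
different apparent diffusivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .signals import SequenceParams, TissueParams, buxton_signal
from .gamma import buxton_gamma_signal_batch

__all__ = [
    "DirectionSet",
    "PhantomVolumeSet",
    "Region",
    "make_b1_map",
    "make_ellipsoid_mask",
    "make_tensor_phantom",
    "make_ballsticks_phantom",
    "simulate_acquisition",
    "generate_directions",
    "subset_directions",
    "protocol_directions",
    "electrostatic_energy",
    "default_sequences",
    "white_matter_region",
]

DEFAULT_DM = (1.7e-4, 0.8e-4, 0.5e-4)  # mm^2/s, MD = 1e-4
DEFAULT_DS_RATIO = 0.5
DEFAULT_T1_MS = 500.0
DEFAULT_T2_MS = 30.0
DEFAULT_FLIPS = (24.0, 94.0)


# ---------------------------------------------------------------------------
# Direction schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionSet:
    """Per-volume gradient directions, q-values and flip labels."""

    vectors: np.ndarray  # (N, 3) unit vectors
    q: np.ndarray  # (N,) cm^-1
    flip: np.ndarray | None = None  # (N,) nominal flip per volume, optional

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        qv = np.asarray(self.q, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or qv.shape != (v.shape[0],):
            raise ValueError("vectors must be (N,3) with matching q of length N")
        if not np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-6):
            raise ValueError("direction vectors must be unit norm")
        if np.any(qv < 0):
            raise ValueError("q-values must be non-negative")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "q", qv)
        if self.flip is not None:
            f = np.asarray(self.flip, dtype=float)
            if f.shape != (v.shape[0],):
                raise ValueError("flip labels must match the number of volumes")
            object.__setattr__(self, "flip", f)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_dw(self) -> int:
        return int(np.sum(self.q == np.max(self.q))) if len(self) else 0


def _pair_energy(v: np.ndarray) -> np.ndarray:
    """Per-vector electrostatic energy with antipodal symmetry (1/r on both
    v_j and -v_j); diagonal excluded."""
    d1 = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
    d2 = np.linalg.norm(v[:, None, :] + v[None, :, :], axis=-1)
    np.fill_diagonal(d1, np.inf)
    np.fill_diagonal(d2, np.inf)
    return (1.0 / d1 + 1.0 / d2).sum(axis=1)


def electrostatic_energy(vectors: np.ndarray) -> float:
    """Total antipodally-symmetric Coulomb energy of a direction scheme."""
    return float(_pair_energy(np.asarray(vectors, float)).sum() / 2.0)


def generate_directions(n: int, seed: int = 0, *, iters: int = 2000) -> DirectionSet:
    """Approximately uniform antipodally-symmetric directions by
    electrostatic-repulsion minimisation (projected gradient descent from a
    seeded random start; deterministic under the seed)."""
    if n < 6:
        raise ValueError("at least 6 directions are required")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.05
    energy = electrostatic_energy(v)
    for _ in range(iters):
        diff = v[:, None, :] - v[None, :, :]
        summ = v[:, None, :] + v[None, :, :]
        d1 = np.linalg.norm(diff, axis=-1)
        d2 = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        # force = -grad E; E = sum 1/d
        f = (diff / d1[..., None] ** 3).sum(axis=1) + (summ / d2[..., None] ** 3).sum(axis=1)
        vn = v + step * f
        vn /= np.linalg.norm(vn, axis=1, keepdims=True)
        en = electrostatic_energy(vn)
        if en < energy:
            v, energy = vn, en
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-9:
                break
    return DirectionSet(v, np.zeros(n))


def subset_directions(dirs: DirectionSet, m: int) -> DirectionSet:
    """Greedy electrostatic subset: repeatedly drop the most crowded vector
    until ``m`` remain (deterministic)."""
    n = len(dirs)
    if not 6 <= m <= n:
        raise ValueError("require 6 <= m <= n")
    keep = np.ones(n, dtype=bool)
    v = dirs.vectors
    for _ in range(n - m):
        idx = np.flatnonzero(keep)
        e = _pair_energy(v[idx])
        keep[idx[np.argmax(e)]] = False
    flip = dirs.flip[keep] if dirs.flip is not None else None
    return DirectionSet(v[keep], dirs.q[keep], flip)


def protocol_directions(
    n_dw: int = 120,
    n_nondw: int = 6,
    q_dw: float = 300.0,
    q_spoiler: float = 20.0,
    seed: int = 0,
) -> DirectionSet:
    """The per-flip acquisition scheme: ``n_dw`` DW directions at ``q_dw``
    plus ``n_nondw`` spoiled non-DW volumes along (1,1,1)/sqrt(3)."""
    dw = generate_directions(n_dw, seed=seed)
    spoiler = np.tile(np.ones(3) / np.sqrt(3.0), (n_nondw, 1))
    vectors = np.vstack([spoiler, dw.vectors])
    q = np.concatenate([np.full(n_nondw, q_spoiler), np.full(n_dw, q_dw)])
    return DirectionSet(vectors, q)


def default_sequences(
    flips: Sequence[float] = DEFAULT_FLIPS,
    TR: float = 30.0,
    G: float = 52.0,
    delta: float = 13.56,
) -> dict[float, SequenceParams]:
    """Protocol sequence parameters per nominal flip angle."""
    return {
        float(a): SequenceParams(TR=TR, alpha_nominal=float(a), delta=delta, G=G)
        for a in flips
    }


# ---------------------------------------------------------------------------
# Geometry and ground truth
# ---------------------------------------------------------------------------

def make_ellipsoid_mask(shape, semiaxes_frac=(0.45, 0.45, 0.45)) -> np.ndarray:
    shape = tuple(shape)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = [(s - 1) / 2.0 for s in shape]
    r2 = sum(
        ((g - ci) / (fi * si)) ** 2
        for g, ci, fi, si in zip(grids, c, semiaxes_frac, shape)
    )
    return r2 <= 1.0


def _normalized_radius(shape, semiaxes_frac=(0.45, 0.45, 0.45)) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = [(s - 1) / 2.0 for s in shape]
    r2 = sum(
        ((g - ci) / (fi * si)) ** 2
        for g, ci, fi, si in zip(grids, c, semiaxes_frac, shape)
    )
    return np.sqrt(r2)


def make_b1_map(
    shape,
    center_value: float = 1.0,
    edge_value: float = 0.3,
    profile: str = "cosine",
    semiaxes_frac=(0.45, 0.45, 0.45),
) -> np.ndarray:
    """Smooth radially decaying transmit field: ``center_value`` at the
    centroid falling monotonically to ``edge_value`` at the mask boundary
    (clamped outside)."""
    if not 0 < edge_value < center_value:
        raise ValueError("require 0 < edge_value < center_value")
    r = np.clip(_normalized_radius(shape, semiaxes_frac), 0.0, 1.0)
    if profile == "cosine":
        w = np.cos(0.5 * np.pi * r)
    elif profile == "quadratic":
        w = 1.0 - r**2
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return edge_value + (center_value - edge_value) * w


@dataclass(frozen=True)
class Region:
    """One homogeneous phantom region.

    ``selector`` maps the volume shape to a boolean mask; ``pdd`` orients
    the principal eigenvector ("x"/"y"/"z" or a unit 3-vector); "radial"
    points V1 away from the volume centre.
    """

    name: str
    selector: Callable[[tuple], np.ndarray]
    Dm: tuple[float, float, float] = DEFAULT_DM
    Ds: tuple[float, float, float] | None = None  # default DEFAULT_DS_RATIO * Dm
    pdd: str | tuple[float, float, float] = "x"


def _default_regions() -> list[Region]:
    def lower(shape):
        m = np.zeros(shape, bool)
        m[..., : shape[2] // 2] = True
        return m

    def upper(shape):
        m = np.zeros(shape, bool)
        m[..., shape[2] // 2:] = True
        return m

    return [
        Region("wm_x", lower, pdd="x"),
        Region("wm_y", upper, pdd="y"),
    ]


def _frame_from_pdd(pdd, shape):
    """Per-voxel eigenvector frames (..., 3, 3), columns V1, V2, V3."""
    basis = {"x": np.eye(3), "y": np.eye(3)[:, [1, 0, 2]], "z": np.eye(3)[:, [2, 0, 1]]}
    if isinstance(pdd, str) and pdd in basis:
        return np.broadcast_to(basis[pdd], shape + (3, 3)).copy()
    if isinstance(pdd, str) and pdd == "radial":
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        c = [(s - 1) / 2.0 for s in shape]
        v1 = np.stack([g - ci for g, ci in zip(grids, c)], axis=-1)
        nrm = np.linalg.norm(v1, axis=-1, keepdims=True)
        v1 = np.where(nrm > 1e-9, v1 / np.where(nrm == 0, 1, nrm), [1.0, 0.0, 0.0])
        # complete a right-handed frame
        helper = np.where(np.abs(v1[..., [0]]) < 0.9, [1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
        v2 = np.cross(v1, helper)
        v2 /= np.linalg.norm(v2, axis=-1, keepdims=True)
        v3 = np.cross(v1, v2)
        return np.stack([v1, v2, v3], axis=-1)
    v1 = np.asarray(pdd, dtype=float)
    v1 = v1 / np.linalg.norm(v1)
    helper = np.array([1.0, 0.0, 0.0]) if abs(v1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v2 = np.cross(v1, helper)
    v2 /= np.linalg.norm(v2)
    v3 = np.cross(v1, v2)
    V = np.stack([v1, v2, v3], axis=-1)
    return np.broadcast_to(V, shape + (3, 3)).copy()


def white_matter_region(phantom: "PhantomVolumeSet", radius_frac: float = 0.8) -> np.ndarray:
    """Interior "white-matter-like" evaluation mask.

    White matter occupies the interior of a brain sample; the outermost
    shell of the phantom plays the role of cortex/rind (where the very low
    transmit field makes the low-flip acquisition unreliable, mirroring the
    low-signal constraint applied to real data).  The default keeps voxels
    within 80% of the mask radius.
    """
    r = _normalized_radius(phantom.shape)
    return phantom.mask & (r <= radius_frac)


@dataclass
class PhantomVolumeSet:
    """Co-registered synthetic maps plus voxelwise ground truth."""

    shape: tuple
    voxel_size_mm: float
    mask: np.ndarray
    B1: np.ndarray
    T1: np.ndarray  # ms
    T2: np.ndarray  # ms
    S0: np.ndarray
    kind: str = "tensor"  # or "ballsticks"
    Dm: np.ndarray | None = None  # (..., 3) per-eigenvector means
    Ds: np.ndarray | None = None  # (..., 3) per-eigenvector stds
    V: np.ndarray | None = None  # (..., 3, 3) eigenvector columns
    # ball & sticks truth
    fractions: np.ndarray | None = None  # (..., n_sticks)
    sticks: np.ndarray | None = None  # (..., n_sticks, 3)
    d_low: np.ndarray | None = None
    d_high: np.ndarray | None = None
    region_labels: np.ndarray | None = None
    region_names: tuple = ()
    seed: int | None = None


def make_tensor_phantom(
    shape=(32, 32, 32),
    regions: Sequence[Region] | None = None,
    *,
    voxel_size_mm: float = 0.85,
    T1: float = DEFAULT_T1_MS,
    T2: float = DEFAULT_T2_MS,
    S0: float = 1.0,
    b1_center: float = 1.0,
    b1_edge: float = 0.3,
) -> PhantomVolumeSet:
    """Tensor-with-gamma-eigenvalue-distributions phantom.

    Ground-truth maps carry the *specified* region parameters exactly (no
    sampling), so recovery errors measured against them are purely the
    pipeline's.  Overlapping regions raise.
    """
    shape = tuple(shape)
    mask = make_ellipsoid_mask(shape)
    b1 = make_b1_map(shape, b1_center, b1_edge)
    if regions is None:
        regions = _default_regions()
    Dm = np.zeros(shape + (3,))
    Ds = np.zeros(shape + (3,))
    V = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    labels = np.full(shape, -1, dtype=np.int16)
    claimed = np.zeros(shape, bool)
    for ridx, reg in enumerate(regions):
        sel = np.asarray(reg.selector(shape), bool) & mask
        if np.any(sel & claimed):
            raise ValueError(f"region {reg.name!r} overlaps a previous region")
        claimed |= sel
        dm = np.asarray(reg.Dm, float)
        if not (dm[0] > dm[1] > dm[2] > 0):
            raise ValueError(f"region {reg.name!r}: Dm must satisfy L1 > L2 > L3 > 0")
        ds = np.asarray(reg.Ds, float) if reg.Ds is not None else DEFAULT_DS_RATIO * dm
        Dm[sel] = dm
        Ds[sel] = ds
        V[sel] = _frame_from_pdd(reg.pdd, shape)[sel]
        labels[sel] = ridx
    return PhantomVolumeSet(
        shape=shape,
        voxel_size_mm=voxel_size_mm,
        mask=mask & claimed,
        B1=b1,
        T1=np.full(shape, T1),
        T2=np.full(shape, T2),
        S0=np.full(shape, S0),
        kind="tensor",
        Dm=Dm,
        Ds=Ds,
        V=V,
        region_labels=labels,
        region_names=tuple(r.name for r in regions),
    )


def make_ballsticks_phantom(
    shape=(16, 16, 16),
    *,
    fractions=(0.5,),
    stick_axes=((1.0, 0.0, 0.0),),
    d_low: float = 0.8e-4,
    d_high: float = 1.2e-4,
    voxel_size_mm: float = 0.85,
    T1: float = DEFAULT_T1_MS,
    T2: float = DEFAULT_T2_MS,
    S0: float = 1.0,
) -> PhantomVolumeSet:
    """Uniform ball & sticks phantom (``d_high > d_low`` emulates the
    restriction-driven rise of apparent diffusivity with flip angle)."""
    shape = tuple(shape)
    mask = make_ellipsoid_mask(shape)
    f = np.asarray(fractions, float)
    sticks = np.asarray(stick_axes, float)
    sticks = sticks / np.linalg.norm(sticks, axis=-1, keepdims=True)
    if f.sum() > 1:
        raise ValueError("fractions must sum to <= 1")
    return PhantomVolumeSet(
        shape=shape,
        voxel_size_mm=voxel_size_mm,
        mask=mask,
        B1=make_b1_map(shape),
        T1=np.full(shape, T1),
        T2=np.full(shape, T2),
        S0=np.full(shape, S0),
        kind="ballsticks",
        fractions=np.broadcast_to(f, shape + f.shape).copy(),
        sticks=np.broadcast_to(sticks, shape + sticks.shape).copy(),
        d_low=np.full(shape, d_low),
        d_high=np.full(shape, d_high),
        region_labels=mask.astype(np.int16) - 1,
        region_names=("bs",),
    )


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------

def _projected_gamma(phantom: PhantomVolumeSet, g: np.ndarray, vox: np.ndarray):
    """Projected mean/std of the diffusivity distribution along ``g`` for
    the masked voxels ``vox`` (tuple of index arrays)."""
    V = phantom.V[vox]  # (n, 3, 3)
    cos2 = np.einsum("nij,j->ni", np.swapaxes(V, 1, 2), g) ** 2  # (n, 3)
    Dm_g = np.einsum("ni,ni->n", cos2, phantom.Dm[vox])
    Ds_g = np.einsum("ni,ni->n", cos2, phantom.Ds[vox])
    return Dm_g, Ds_g


def simulate_acquisition(
    phantom: PhantomVolumeSet,
    dirs: DirectionSet,
    sequences: dict[float, SequenceParams] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    quad_nodes: int = 48,
) -> dict[float, np.ndarray]:
    """Simulate the dual-flip DW-SSFP series.

    For each nominal flip angle the voxelwise actual flip is
    ``B1 * nominal``; each volume's signal is the gamma-averaged
    steady-state signal at the direction-projected (Dm, Ds) (tensor
    phantoms) or the ball & sticks signal with the per-flip diffusivity
    (ball & sticks phantoms).  Non-DW volumes are simulated at their true
    spoiler q.  Rician noise adds two-channel Gaussian noise of width
    ``noise_sigma`` and takes the magnitude; the same ``seed`` gives
    bit-identical output.

    Returns ``{nominal_flip: 4-D array (x, y, z, volume)}``.
    """
    if sequences is None:
        sequences = default_sequences()
    shapes = {phantom.mask.shape, phantom.B1.shape}
    if len(shapes) != 1:
        raise ValueError("phantom volumes have mismatched shapes")
    rng = np.random.default_rng(seed)
    vox = np.nonzero(phantom.mask)
    n_vox = vox[0].size
    T1 = float(np.median(phantom.T1[vox]))
    T2 = float(np.median(phantom.T2[vox]))
    tissue = TissueParams(T1=T1, T2=T2)
    out: dict[float, np.ndarray] = {}
    for nominal, seq in sequences.items():
        alpha = phantom.B1[vox] * nominal
        data = np.zeros(phantom.shape + (len(dirs),), dtype=float)
        for vol in range(len(dirs)):
            g = dirs.vectors[vol]
            qv = float(dirs.q[vol])
            if phantom.kind == "tensor":
                Dm_g, Ds_g = _projected_gamma(phantom, g, vox)
                S = buxton_gamma_signal_batch(
                    alpha, Dm_g, Ds_g, tissue, seq, q=qv, nodes=quad_nodes
                )
            elif phantom.kind == "ballsticks":
                d = (phantom.d_low if nominal == min(sequences) else phantom.d_high)[vox]
                f = phantom.fractions[vox]  # (n, ns)
                sticks = phantom.sticks[vox]  # (n, ns, 3)
                proj2 = np.einsum("nsj,j->ns", sticks, g) ** 2
                S = (1.0 - f.sum(axis=1)) * buxton_signal(alpha, tissue, seq, d, q=qv)
                for s in range(f.shape[1]):
                    S = S + f[:, s] * buxton_signal(
                        alpha, tissue, seq, d * proj2[:, s], q=qv
                    )
            else:
                raise ValueError(f"unknown phantom kind {phantom.kind!r}")
            data[vox + (vol,)] = S * phantom.S0[vox]
        if noise_sigma > 0:
            n_r = rng.normal(0.0, noise_sigma, size=data.shape)
            n_i = rng.normal(0.0, noise_sigma, size=data.shape)
            data = np.hypot(data + n_r, n_i)
        out[float(nominal)] = data
    return out
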
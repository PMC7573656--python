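"""Readers/writers and study configuration.

Volumes are NIfTI-1 (via nibabel); direction tables are whitespace text
with four columns (unit vector x, y, z and q in cm^-1, one row per
volume); study and phantom configurations are YAML; every output directory
gets a JSON sidecar recording the package version, seed and a hash of the
configuration that produced it.

Direction vectors are interpreted in image-axis coordinates (the
convention of the direction-table ecosystem the maps are consumed in).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .phantom import DirectionSet, PhantomVolumeSet
from .signals import SequenceParams

logger = logging.getLogger("dwssfp")

__all__ = [
    "StudyBundle",
    "load_study",
    "write_outputs",
    "read_direction_table",
    "write_direction_table",
    "save_phantom_study",
]


def read_direction_table(path) -> DirectionSet:
    """Whitespace table: unit vector (3 cols) + q in cm^-1, one row per
    volume.  Non-unit rows raise with the offending row number."""
    arr = np.atleast_2d(np.loadtxt(path))
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(f"{path}: direction table must have 4 columns (vx vy vz q)")
    v = arr[:, :3]
    norms = np.linalg.norm(v, axis=1)
    bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-3)
    if bad.size:
        raise ValueError(
            f"{path}: non-unit direction vector at row {bad[0] + 1} "
            f"(|v| = {norms[bad[0]]:.6f})"
        )
    return DirectionSet(v / norms[:, None], arr[:, 3])


def write_direction_table(path, dirs: DirectionSet) -> None:
    arr = np.column_stack([dirs.vectors, dirs.q])
    np.savetxt(path, arr, fmt=["%+.10f", "%+.10f", "%+.10f", "%10.4f"])


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_vol(path, name):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{name} volume not found: {p}")
    img = nib.load(str(p))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


@dataclass
class StudyBundle:
    """Validated in-memory study: per-flip series, fixed maps, directions,
    sequence parameters and fitting options."""

    volumes: dict[float, np.ndarray]
    maps: dict[str, np.ndarray]
    dirs: DirectionSet
    sequences: dict[float, SequenceParams]
    options: dict
    affine: np.ndarray
    config: dict = field(repr=False, default_factory=dict)


def load_study(config_path) -> StudyBundle:
    """Load and validate a study configuration.

    The YAML layout::

        flips:
          24: {volumes: dw_24.nii.gz, TR: 30, delta: 13.56, q: 300}
          94: {volumes: dw_94.nii.gz, TR: 30, delta: 13.56, q: 300}
        maps: {B1: b1.nii.gz, T1: t1.nii.gz, T2: t2.nii.gz, mask: mask.nii.gz}
        directions: dirs.txt
        options: {lambda_reg: 1.0, beff_target: 4000, seed: 42, Snf: 0.0}

    All volumes must share grid and affine (tolerance 1e-4); per-flip
    volume counts must match the direction table; B1 zeros inside the mask
    are excluded from the mask with a logged count.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent

    def respath(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    dirs = read_direction_table(respath(cfg["directions"]))

    volumes: dict[float, np.ndarray] = {}
    sequences: dict[float, SequenceParams] = {}
    affine = None
    shape = None
    for flip, spec in cfg["flips"].items():
        flip = float(flip)
        data, aff = _load_vol(respath(spec["volumes"]), f"flip {flip}")
        if data.ndim != 4:
            raise ValueError(f"flip {flip}: expected a 4-D series")
        if data.shape[-1] != len(dirs):
            raise ValueError(
                f"flip {flip}: {data.shape[-1]} volumes but "
                f"{len(dirs)} rows in the direction table"
            )
        if affine is None:
            affine, shape = aff, data.shape[:-1]
        else:
            if data.shape[:-1] != shape:
                raise ValueError(f"flip {flip}: grid {data.shape[:-1]} != {shape}")
            if np.max(np.abs(aff - affine)) > 1e-4:
                raise ValueError(f"flip {flip}: affine mismatch beyond 1e-4")
        volumes[flip] = data
        sequences[flip] = SequenceParams(
            TR=float(spec["TR"]),
            alpha_nominal=flip,
            delta=float(spec["delta"]),
            q=float(spec["q"]) if "q" in spec else None,
            G=float(spec["G"]) if "G" in spec else None,
            q_spoiler=float(spec.get("q_spoiler", 20.0)),
        )

    maps: dict[str, np.ndarray] = {}
    for name, path in cfg["maps"].items():
        data, aff = _load_vol(respath(path), name)
        if data.shape != shape:
            raise ValueError(f"map {name}: grid {data.shape} != {shape}")
        if np.max(np.abs(aff - affine)) > 1e-4:
            raise ValueError(f"map {name}: affine mismatch beyond 1e-4")
        maps[name] = data
    if "mask" in maps:
        maps["mask"] = maps["mask"] > 0.5
    else:
        maps["mask"] = np.ones(shape, bool)
    if "B1" in maps:
        zero_b1 = maps["mask"] & (maps["B1"] <= 0)
        if np.any(zero_b1):
            logger.warning(
                "excluding %d voxels with B1 <= 0 inside the mask", zero_b1.sum()
            )
            maps["mask"] = maps["mask"] & ~zero_b1

    options = dict(cfg.get("options", {}))
    logger.info(
        "study loaded: grid %s, %d flips, %d volumes/flip, B1 range [%.2f, %.2f]",
        shape, len(volumes), len(dirs),
        float(np.min(maps["B1"][maps["mask"]])) if "B1" in maps else np.nan,
        float(np.max(maps["B1"][maps["mask"]])) if "B1" in maps else np.nan,
    )
    return StudyBundle(
        volumes=volumes, maps=maps, dirs=dirs, sequences=sequences,
        options=options, affine=affine, config=cfg,
    )


def write_outputs(results: dict[str, np.ndarray], out_dir, affine=None, meta: dict | None = None):
    """Write result maps as float32 NIfTI plus a JSON sidecar.

    Keys become file names (``<key>.nii.gz``).  FA maps (keys containing
    "FA") are checked to lie in [0, 1].  The sidecar records package
    version and the caller's metadata (seed, configuration hash...).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    written = []
    for name, arr in results.items():
        arr = np.asarray(arr)
        if "FA" in name and arr.size:
            vals = arr[np.isfinite(arr)]
            if vals.size and (vals.min() < -1e-6 or vals.max() > 1 + 1e-6):
                raise ValueError(f"{name}: FA values outside [0, 1]")
        img = nib.Nifti1Image(arr.astype(np.float32), affine)
        path = out_dir / f"{name}.nii.gz"
        nib.save(img, str(path))
        written.append(path.name)
    sidecar = {"version": __version__, "files": written}
    if meta:
        sidecar.update(meta)
        if "config" in meta and isinstance(meta["config"], dict):
            sidecar["config_hash"] = _config_hash(meta.pop("config"))
            sidecar.pop("config", None)
    with open(out_dir / "sidecar.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)
    logger.info("wrote %d maps to %s", len(written), out_dir)
    return out_dir / "sidecar.json"


def save_phantom_study(
    phantom: PhantomVolumeSet,
    dirs: DirectionSet,
    volumes: dict[float, np.ndarray],
    sequences: dict[float, SequenceParams],
    out_dir,
    *,
    seed: int,
    noise_sigma: float,
    options: dict | None = None,
) -> Path:
    """Write a simulated study (volumes, maps, directions, ground truth)
    plus a ``study.yaml`` that :func:`load_study` can read back."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([phantom.voxel_size_mm] * 3 + [1.0])
    write_direction_table(out_dir / "directions.txt", dirs)
    cfg: dict = {"flips": {}, "maps": {}, "directions": "directions.txt"}
    for flip, data in volumes.items():
        name = f"dwssfp_flip{int(round(flip))}.nii.gz"
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(out_dir / name))
        seq = sequences[flip]
        cfg["flips"][float(flip)] = {
            "volumes": name, "TR": seq.TR, "delta": seq.delta,
            "q": seq.q, "q_spoiler": seq.q_spoiler,
        }
    for key, arr in (("B1", phantom.B1), ("T1", phantom.T1), ("T2", phantom.T2),
                     ("mask", phantom.mask.astype(np.float32))):
        name = f"{key}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), affine), str(out_dir / name))
        cfg["maps"][key] = name
    snf = noise_sigma * np.sqrt(np.pi / 2.0)
    cfg["options"] = {"seed": seed, "noise_sigma": noise_sigma, "Snf": float(snf),
                      **(options or {})}
    truth = {}
    if phantom.kind == "tensor":
        truth = {"truth_Dm": phantom.Dm, "truth_Ds": phantom.Ds,
                 "truth_V": phantom.V.reshape(phantom.shape + (9,))}
    for name, arr in truth.items():
        nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), affine),
                 str(out_dir / f"{name}.nii.gz"))
    with open(out_dir / "study.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out_dir / "study.yaml"
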
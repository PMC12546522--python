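"""Textured 3-D image volumes with controllable heterogeneity."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..fields import LabeledImageVolume
from .truth import SyntheticTruth

__all__ = ["make_texture_image"]


def _pattern_array(pattern: dict, shape, spacing, rng) -> np.ndarray:
    kind = pattern.get("kind", "constant")
    if kind == "constant":
        return np.full(shape, float(pattern.get("value", 1.0)))
    if kind == "axis_gradient":
        axis = int(pattern.get("axis", 0))
        lo = float(pattern.get("low", 0.0))
        hi = float(pattern.get("high", 1.0))
        n = shape[axis]
        ramp = np.linspace(lo, hi, n)
        view = [1, 1, 1]
        view[axis] = n
        return np.broadcast_to(ramp.reshape(view), shape).copy()
    if kind == "checkerboard":
        levels = pattern.get("levels", (0.0, 1.0))
        period = int(pattern.get("period", 1))
        idx = np.indices(shape) // period
        parity = idx.sum(axis=0) % 2
        return np.where(parity == 0, float(levels[0]), float(levels[1]))
    if kind == "gaussian_random_field":
        corr = float(pattern["correlation_length"])
        var = float(pattern.get("variance", 1.0))
        mean = float(pattern.get("mean", 0.0))
        white = rng.standard_normal(shape)
        sigmas = [max(corr / s, 1e-9) for s in spacing]
        smooth = gaussian_filter(white, sigmas, mode="wrap")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        return mean + np.sqrt(var) * smooth
    raise ValueError(f"unknown pattern kind {kind!r}")


def _build_mask(spec, shape) -> np.ndarray:
    if spec is None or spec == "all":
        return np.ones(shape, dtype=bool)
    if isinstance(spec, np.ndarray):
        m = np.asarray(spec, dtype=bool)
        if m.shape != tuple(shape):
            raise ValueError("mask array shape mismatch")
        return m
    # slice-box spec: [[lo, hi], [lo, hi], [lo, hi]] half-open per axis
    mask = np.zeros(shape, dtype=bool)
    (i0, i1), (j0, j1), (k0, k1) = spec
    if i1 > shape[0] or j1 > shape[1] or k1 > shape[2] or min(i0, j0, k0) < 0:
        raise ValueError("mask box exceeds image bounds")
    mask[i0:i1, j0:j1, k0:k1] = True
    return mask


def make_texture_image(
    shape: tuple[int, int, int],
    pattern: dict,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    mask_spec: dict | None = None,
    seed: int | None = None,
) -> tuple[LabeledImageVolume, SyntheticTruth]:
    """Generate a deterministic textured volume with named ROI masks.

    ``pattern`` kinds: constant, axis_gradient, checkerboard,
    gaussian_random_field (periodic smoothing of white noise, rescaled to
    the requested variance).  ``mask_spec`` maps ROI name -> "all", a
    boolean array, or an axis-aligned box [[lo,hi],[lo,hi],[lo,hi]].
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 1 for s in shape):
        raise ValueError("every image dimension must be >= 1")
    rng = np.random.default_rng(seed)
    voxels = _pattern_array(pattern, shape, spacing, rng)

    if mask_spec is None:
        mask_spec = {"roi": "all"}
    masks = {name: _build_mask(spec, shape) for name, spec in mask_spec.items()}
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")

    image = LabeledImageVolume(voxels, spacing, masks)

    targets: dict = {"pattern": dict(pattern)}
    if pattern.get("kind", "constant") == "constant":
        c = float(pattern.get("value", 1.0))
        stats = {}
        for name, m in masks.items():
            n = int(m.sum())
            stats[name] = {
                "mean": c,
                "minimum": c,
                "rms": abs(c),
                "energy": n * c * c,
                "total_energy": n * c * c * image.voxel_volume,
                "n_voxels": n,
            }
        targets["first_order"] = stats
    truth = SyntheticTruth(
        generator="make_texture_image",
        parameters={"shape": shape, "spacing": tuple(spacing)},
        seed=seed,
        targets=targets,
    )
    return image, truth
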
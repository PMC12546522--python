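"""Assemble the full supported feature vector per ROI."""

from __future__ import annotations

import numpy as np

from ..fields import LabeledImageVolume
from .discretize import discretize
from .firstorder import first_order
from .glcm import glcm_features
from .glrlm import glrlm_features
from .glszm import glszm_features
from .gldm import gldm_features
from .ngtdm import ngtdm_features

__all__ = ["FEATURE_NAMES", "extract_feature_vector", "DEFAULT_CONFIG"]

#: Names exactly as reported downstream; family prefixes identify texture
#: matrices, bare names are first-order or GLCM scalars.
FEATURE_NAMES = (
    "Mean", "Minimum", "RMS", "Energy", "Total Energy",
    "Contrast", "CP", "CS", "GLCM.DA", "GLCM.DV",
    "GLRLM.GLN", "GLRLM.RLN", "GLRLM.HGLRE", "GLRLM.SRHGLE", "GLRLM.LRHGLE",
    "GLSZM.SZN", "GLSZM.GLN", "GLSZM.GLV", "GLSZM.HGLZE", "GLSZM.SAHGLE",
    "GLDM.DN", "GLDM.DNN", "GLDM.GLN", "GLDM.HGLE", "GLDM.SDHGLE",
    "NGTDM.Coarseness", "NGTDM.Complexity", "NGTDM.Strength",
)

DEFAULT_CONFIG = {
    "policy": "fixed_bin_count",
    "n_bins": 32,
    "bin_width": None,
    "gldm_alpha": 0,
    "glcm_distance": 1,
    "intensity_shift": 0.0,
}


def extract_feature_vector(
    image: LabeledImageVolume,
    roi_names=("wall_free_of_IST", "wall_next_to_IST"),
    config: dict | None = None,
) -> dict[str, dict[str, float]]:
    """One named feature dict per ROI, plus extraction metadata.

    Returns ``{roi: {feature: value, ...}, ..., "_metadata": {...}}``.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)

    out: dict[str, dict[str, float]] = {}
    for roi in roi_names:
        mask = image.mask(roi)  # raises on missing/empty ROI
        disc = discretize(
            image,
            roi,
            policy=cfg["policy"],
            n_bins=cfg["n_bins"],
            bin_width=cfg["bin_width"],
        )
        features: dict[str, float] = {}
        features.update(
            first_order(
                image.voxels[mask], image.voxel_volume, shift=cfg["intensity_shift"]
            )
        )
        glcm = glcm_features(disc, distance=cfg["glcm_distance"])
        glcm.pop("degenerate", None)
        features.update(glcm)
        features.update(glrlm_features(disc))
        features.update(glszm_features(disc))
        features.update(gldm_features(disc, alpha=cfg["gldm_alpha"]))
        features.update(ngtdm_features(disc))

        missing = set(FEATURE_NAMES) - set(features)
        if missing:  # pragma: no cover - internal consistency
            raise RuntimeError(f"feature set incomplete: {sorted(missing)}")
        bad = {k: v for k, v in features.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite features for ROI {roi!r}: {sorted(bad)}")
        out[roi] = {name: features[name] for name in FEATURE_NAMES}
    out["_metadata"] = dict(cfg)
    return out
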
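"""End-to-end reproducible demo pipeline on synthetic inputs.

Each synthetic case draws a latent severity in [0, 1] that monotonically
drives sac size, WSS reversal fraction, vortex-blob size/count/motion, and
image heterogeneity, so the downstream correlation screen has planted
monotone feature-parameter associations to find.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import correlation_screen
from .io.vtk import write_polydata
from .morphology import compute_morphology
from .radiomics import extract_feature_vector
from .synthetic import (
    VortexBlob,
    make_pulsatile_wss_series,
    make_sphere_surface,
    make_tet_ball,
    make_texture_image,
    make_vortex_velocity_series,
)
from .vortex import analyze_vortex_series
from .wss import compute_wall_metrics

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "config_hash"]

ALL_STAGES = ("morphology", "wss", "vortex", "radiomics", "correlate")

DEFAULT_CONFIG = {
    "n_cases": 8,
    "seed": 0,
    "phases": 20,
    "stages": list(ALL_STAGES),
    "surface_subdivisions": 2,
    "ball_radius": 1.0,
    "ball_edge": 0.12,
    "image_shape": [12, 12, 6],
    "wss_weighting": "area",
    "vortex_criterion": "Q",
    # 1e-3 * omega^2 for the demo blobs (omega = 6): far below the core
    # plateau, far above interpolation-roundoff speckle
    "vortex_threshold": 0.036,
    "vortex_min_cells": 32,
    "radiomics": {"policy": "fixed_bin_count", "n_bins": 16},
    "rho_threshold": 0.7,
    "alpha": 0.05,
    "correlation_mode": "abs",
}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def _merge_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in config.items():
            if isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    bad = set(cfg["stages"]) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    return cfg


def _feature_column(roi: str, feature: str) -> str:
    prefix = {"wall_free_of_IST": "free", "wall_next_to_IST": "adj"}[roi]
    return f"{prefix}.{feature}"


def _case_row(k: int, cfg: dict, ball, run_dir: Path) -> dict:
    """Simulate one case and compute every requested stage's metrics."""
    rng = np.random.default_rng([cfg["seed"], k])
    severity = float(rng.uniform(0.05, 0.95))
    stages = cfg["stages"]
    row: dict = {"case_id": f"case_{k:03d}", "severity": severity}
    row["subgroup"] = "saccular" if k % 5 < 2 else "fusiform"

    sphere = make_sphere_surface(
        radius=1.0 + severity, subdivisions=cfg["surface_subdivisions"]
    )

    if "morphology" in stages:
        r = 1.0 + severity
        morph = compute_morphology(
            sphere,
            neck_point=(0.0, 0.0, -r),
            neck_normal=(0.0, 0.0, 1.0),
            inflow_direction=(0.0, 0.0, 1.0),
            parent_diameter=1.0 + 0.2 * severity,
        )
        row.update({f"morph.{k2}": v for k2, v in morph.as_dict().items()})

    if "wss" in stages:
        field, _ = make_pulsatile_wss_series(
            sphere,
            magnitude_profile={"kind": "pulsatile", "base": 2.0, "amplitude": 0.8},
            reversal_fraction=0.45 * severity,
            phases=cfg["phases"],
            seed=int(rng.integers(2**31)),
        )
        metrics = compute_wall_metrics(field, weighting=cfg["wss_weighting"])
        for name in ("avg_osi", "avg_ecap", "avg_rrt", "avg_tawss", "max_tawss"):
            row[f"wss.{name}"] = metrics.summary[name]
        if k == 0:
            write_polydata(
                run_dir / "case_000_wall_metrics.vtk",
                sphere,
                point_data={
                    "TAWSS": metrics.tawss,
                    "OSI": metrics.osi,
                    "ECAP": np.nan_to_num(metrics.ecap),
                    "RRT": np.nan_to_num(metrics.rrt),
                },
            )

    if "vortex" in stages:
        n_blobs = 1 + int(severity * 2.999)
        sigma = 0.2 + 0.14 * severity
        anchors = np.array(
            [[0.0, 0.0, 0.0], [0.55, 0.0, 0.2], [-0.5, 0.3, -0.2]]
        )
        P = cfg["phases"]
        blobs = []
        for b in range(n_blobs):
            wobble = 0.15 * severity
            t = np.arange(P) / P
            path = anchors[b] + wobble * np.stack(
                [np.cos(2 * np.pi * t + b), np.sin(2 * np.pi * t + b), 0 * t], axis=1
            )
            blobs.append(VortexBlob(center=path, sigma=sigma, omega=6.0))
        vfield, _ = make_vortex_velocity_series(ball, blobs, phases=P)
        summary = analyze_vortex_series(
            vfield,
            criterion=cfg["vortex_criterion"],
            threshold=cfg["vortex_threshold"],
            min_cells=cfg["vortex_min_cells"],
        )
        row["vortex.vv_mean"] = summary.vv_mean
        row["vortex.noc_mean"] = float(summary.noc.mean())
        row["vortex.noc_std"] = summary.noc_std
        row["vortex.dvo_mean"] = summary.dvo_mean

    if "radiomics" in stages:
        nx, ny, nz = cfg["image_shape"]
        image, _ = make_texture_image(
            (nx, ny, nz),
            pattern={
                "kind": "gaussian_random_field",
                "correlation_length": 3.0 - 2.5 * severity,
                "variance": 1.0 + 3.0 * severity,
                "mean": 10.0 * (1.0 + severity),
            },
            mask_spec={
                "wall_free_of_IST": [[0, nx // 2], [0, ny], [0, nz]],
                "wall_next_to_IST": [[nx // 2, nx], [0, ny], [0, nz]],
            },
            seed=int(rng.integers(2**31)),
        )
        vectors = extract_feature_vector(image, config=cfg["radiomics"])
        for roi in ("wall_free_of_IST", "wall_next_to_IST"):
            for name, value in vectors[roi].items():
                row[_feature_column(roi, name)] = value
    return row


def run_pipeline(config: dict | None, out_dir) -> Path:
    """Execute the selected stages and write cohort, screen, and manifest.

    Reruns of the same config produce byte-identical outputs.
    """
    cfg = _merge_config(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    ball = (
        make_tet_ball(cfg["ball_radius"], cfg["ball_edge"])
        if "vortex" in cfg["stages"]
        else None
    )
    rows = []
    for k in range(cfg["n_cases"]):
        try:
            rows.append(_case_row(k, cfg, ball, run_dir))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in case {k}: {exc}") from exc
    cohort = pd.DataFrame(rows)
    cohort.to_csv(run_dir / "cohort.csv", index=False, float_format="%.17g")

    outputs = ["cohort.csv"]
    if "correlate" in cfg["stages"]:
        categories = {}
        for cat in ("morph", "wss", "vortex"):
            cols = [c for c in cohort.columns if c.startswith(cat + ".")]
            if cols:
                categories[cat] = cols
        features = [
            c for c in cohort.columns if c.startswith(("free.", "adj."))
        ]
        if not categories or not features:
            raise RuntimeError(
                "correlate stage requires at least one parameter stage and radiomics"
            )
        screen = correlation_screen(
            cohort,
            features=features,
            categories=categories,
            rho_threshold=cfg["rho_threshold"],
            alpha=cfg["alpha"],
            mode=cfg["correlation_mode"],
        )
        screen.table.to_csv(
            run_dir / "correlations.csv", index=False, float_format="%.17g"
        )
        _write_strong_report(screen, run_dir / "strong_pairs.md")
        outputs += ["correlations.csv", "strong_pairs.md"]

    manifest = {
        "tool": "aneuhemo",
        "version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "outputs": sorted(outputs),
        "n_cases": cfg["n_cases"],
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return run_dir


def _write_strong_report(screen, path: Path) -> None:
    lines = [
        "# Strong correlation pairs",
        "",
        f"Rule: {'|rho|' if screen.mode == 'abs' else 'rho'} > "
        f"{screen.rho_threshold} and p < {screen.alpha}",
        "",
    ]
    strong = screen.strong_pairs()
    for (subgroup, category), sub in strong.groupby(["subgroup", "category"]):
        lines.append(f"## {subgroup} / {category}")
        lines.append("")
        lines.append("| feature | parameter | rho | p | n |")
        lines.append("|---|---|---|---|---|")
        for _, r in sub.iterrows():
            lines.append(
                f"| {r.feature} | {r.parameter} | {r.rho:.2f} | {r.p:.2g} | {r.n} |"
            )
        lines.append("")
    if strong.empty:
        lines.append("No strong pairs found.")
    path.write_text("\n".join(lines) + "\n")
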
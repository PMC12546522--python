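"""Cohort tables with planted rank correlations via a Gaussian copula.

For a bivariate normal with Pearson correlation r the population Spearman
correlation is (6/pi) * asin(r/2); inverting, r = 2 sin(pi * rho_s / 6)
plants an exact population Spearman rho_s.  Monotone link functions on
either margin leave ranks (hence Spearman) untouched.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .truth import SyntheticTruth

__all__ = ["make_coupled_cohort", "spearman_to_pearson"]

_LINKS = {
    "linear": lambda z: z,
    "exp": np.exp,
    "cubic": lambda z: z**3,
}


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal whose Spearman is ``rho_s``."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _rho_for(spec, subgroup: str) -> float:
    rho = spec[subgroup] if isinstance(spec, dict) else spec
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("planted rho must be in [-1, 1]")
    return rho


def make_coupled_cohort(
    n_cases: int,
    link: str = "linear",
    planted_rho=0.8,
    noise_sd: float = 0.0,
    seed: int | None = None,
    subgroup_sizes: tuple[int, int] | None = None,
    pairs: dict | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a cohort with planted feature-parameter rank correlations.

    Parameters
    ----------
    planted_rho : float or {"saccular": rho, "fusiform": rho}
        Target Spearman correlation, optionally per subgroup.
    subgroup_sizes : (n_saccular, n_fusiform); defaults to a 40/60 split.
    pairs : mapping (feature_name, parameter_name) -> rho spec; defaults to
        a single ("feature", "parameter") pair using ``planted_rho``.
    noise_sd : additive Gaussian noise on the feature column; the planted
        correlation is exact only at 0.
    """
    if n_cases < 5:
        raise ValueError("n_cases must be >= 5")
    if link not in _LINKS and not callable(link):
        raise ValueError(f"unknown link {link!r}")
    link_fn = _LINKS.get(link, link)
    rng = np.random.default_rng(seed)

    if subgroup_sizes is None:
        n_sac = int(round(0.4 * n_cases))
        subgroup_sizes = (n_sac, n_cases - n_sac)
    if sum(subgroup_sizes) != n_cases:
        raise ValueError("subgroup sizes must sum to n_cases")
    labels = np.array(
        ["saccular"] * subgroup_sizes[0] + ["fusiform"] * subgroup_sizes[1]
    )

    if pairs is None:
        pairs = {("feature", "parameter"): planted_rho}

    data = {"case_id": [f"case_{i:03d}" for i in range(n_cases)], "subgroup": labels}
    truth_pairs = {}
    for (feat, param), rho_spec in pairs.items():
        feat_col = np.empty(n_cases)
        param_col = np.empty(n_cases)
        planted = {}
        for subgroup in ("saccular", "fusiform"):
            sel = labels == subgroup
            m = int(sel.sum())
            rho = _rho_for(rho_spec, subgroup)
            r = spearman_to_pearson(rho)
            z = rng.standard_normal((m, 2))
            z2 = r * z[:, 0] + math.sqrt(max(0.0, 1.0 - r * r)) * z[:, 1]
            feat_col[sel] = z[:, 0] + noise_sd * rng.standard_normal(m)
            param_col[sel] = link_fn(z2)
            planted[subgroup] = rho
        data[feat] = feat_col
        data[param] = param_col
        truth_pairs[f"{feat}|{param}"] = planted

    table = pd.DataFrame(data)
    truth = SyntheticTruth(
        generator="make_coupled_cohort",
        parameters={
            "n_cases": n_cases,
            "link": link if isinstance(link, str) else "callable",
            "noise_sd": noise_sd,
            "subgroup_sizes": tuple(subgroup_sizes),
        },
        seed=seed,
        targets={"planted_rho": truth_pairs},
    )
    return table, truth
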
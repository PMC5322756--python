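"""Synthetic feeding tables for exercising the fitting layer in isolation.

Counts are drawn from a negative binomial whose mean follows Real's
functional response with known habitat scalings, so parameter recovery can
be checked against ground truth without running the individual-based
simulator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .frfit import ScalingSpec, _design_matrix

__all__ = ["make_synthetic_feeding_table", "default_design"]


def default_design(
    areas: Sequence[float] = (0.04, 0.16, 0.64, 1.44, 2.56),
    refuges: Sequence[float] = (0.05, 0.25, 0.45, 0.65),
    exponents: Sequence[int] = tuple(range(0, 14, 2)),
    reps: int = 5,
) -> pd.DataFrame:
    """A factorial (area, refuge, prey count) design table, counts 2^k."""
    rows = [
        {
            "area_m2": a,
            "refuge_fraction": r,
            "prey_count": 2**k,
            "density_per_m2": 2**k / a,
            "rep": rep,
        }
        for a in areas
        for r in refuges
        for k in exponents
        for rep in range(reps)
    ]
    return pd.DataFrame(rows)


def make_synthetic_feeding_table(
    true_params: dict[str, float],
    design: pd.DataFrame,
    k: float,
    seed: int = 0,
    spec: ScalingSpec | None = None,
    ln_fmax: float = 1.902,
) -> pd.DataFrame:
    """Draw negative-binomial feeding counts at a design's habitat points.

    Parameters
    ----------
    true_params
        Generating coefficients keyed by parameter name (``ln_C_N0``,
        ``a_N0``, ``b_N0``, ``gamma_N0``, ``ln_C_h``, ``a_h``, ``b_h``,
        ``gamma_h``); parameters absent from ``spec`` are ignored.
    design
        Table with ``area_m2``, ``refuge_fraction`` and ``density_per_m2``
        (or ``prey_count`` from which density is derived).
    k
        Negative-binomial dispersion (variance ``mu + mu**2/k``); very large
        values approach Poisson noise.
    spec
        Scaling structure used to build the predictors; defaults to the
        structure implied by which names appear in ``true_params``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    design = design.copy().reset_index(drop=True)
    if "density_per_m2" not in design:
        design["density_per_m2"] = design["prey_count"] / design["area_m2"]
    if spec is None:
        spec = ScalingSpec(
            include_a_n0="a_N0" in true_params,
            include_b_n0="b_N0" in true_params,
            include_gamma_n0="gamma_N0" in true_params,
            include_a_h="a_h" in true_params,
            include_b_h="b_h" in true_params,
            include_gamma_h="gamma_h" in true_params,
        )
    area = design["area_m2"].to_numpy()
    refuge = design["refuge_fraction"].to_numpy()
    X_n0 = _design_matrix(
        area, refuge, spec.area_form_n0, spec.refuge_form_n0,
        spec.include_a_n0, spec.include_b_n0, spec.include_gamma_n0,
    )
    X_h = _design_matrix(
        area, refuge, spec.area_form_h, spec.refuge_form_h,
        spec.include_a_h, spec.include_b_h, spec.include_gamma_h,
    )
    beta_n0 = [true_params.get("ln_C_N0", 0.0)]
    if spec.include_a_n0:
        beta_n0.append(true_params.get("a_N0", 0.0))
    if spec.include_b_n0:
        beta_n0.append(true_params.get("b_N0", 0.0))
    if spec.include_gamma_n0:
        beta_n0.append(true_params.get("gamma_N0", 0.0))
    beta_h = [true_params.get("ln_C_h", 0.0)]
    if spec.include_a_h:
        beta_h.append(true_params.get("a_h", 0.0))
    if spec.include_b_h:
        beta_h.append(true_params.get("b_h", 0.0))
    if spec.include_gamma_h:
        beta_h.append(true_params.get("gamma_h", 0.0))

    n0 = np.exp(X_n0 @ np.asarray(beta_n0))
    h = np.exp(X_h @ np.asarray(beta_h))
    N = design["density_per_m2"].to_numpy()
    fmax = true_params.get("fmax", np.exp(true_params.get("ln_fmax", ln_fmax)))
    with np.errstate(over="ignore"):
        mu = fmax * N**h / (n0**h + N**h)

    # NB as gamma-Poisson mixture keeps the (mu, k) parametrization exact
    rng = np.random.default_rng(seed)
    lam = rng.gamma(shape=k, scale=mu / k)
    counts = rng.poisson(lam)
    out = design.copy()
    out["eaten"] = counts
    return out
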
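"""Fitting Real's functional response with habitat-dependent parameters.

The feeding rate of one predator at prey density ``N`` follows Real's
(Hill-type) functional response::

    f(N) = f_max * N**h / (N0**h + N**h)

with maximum feeding rate ``f_max`` [prey/h], half-saturation density ``N0``
[prey/m^2] and Hill exponent ``h`` (h = 1: hyperbolic type II; h > 1:
sigmoid type III).  ``f_max`` is a physiological ceiling and is estimated
first from replicated non-spatial maximum-feeding trials by an
intercept-only Poisson GLM; it then enters the functional-response fit as a
fixed constant.

``N0`` and ``h`` may depend on patch size ``A`` [m^2] and refuge
availability ``R`` (proportion) through ln-linear predictors,

    ln(N0) = ln(C_N0) + a_N0 * tA(A) + b_N0 * tR(R) + gamma_N0 * tA(A)*tR(R)
    ln(h)  = ln(C_h)  + a_h  * tA(A) + b_h  * tR(R) + gamma_h  * tA(A)*tR(R)

where each covariate enters either as a logarithm ("power" form, a power law
on the natural scale) or untransformed ("exponential" form).  The default
forms are a power law in patch size and an exponential in refuge for N0,
and power laws in both for h.  Counts are fitted by maximum likelihood with
negative-binomial errors (variance mu + mu^2/k); the dispersion k is
estimated jointly on the log scale.

Model selection enumerates the 25 admissible on/off combinations of the
slope terms (an interaction may only be present together with both main
effects) and ranks them by BIC; a 16-model "form screen" instead crosses the
power/exponential forms over the full (all-terms) models.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import gammaln
import statsmodels.api as sm
from statsmodels.tools import numdiff

__all__ = [
    "ScalingSpec",
    "ScalingEstimate",
    "FunctionalResponseModel",
    "FunctionalResponseResult",
    "FitError",
    "real_fr",
    "fit_max_feeding",
    "nb_loglik",
    "fit_scaling_model",
    "predict_N0_h",
    "hill_test",
    "select_model",
    "form_screen",
    "enumerate_scaling_specs",
    "enumerate_form_specs",
]

logger = logging.getLogger(__name__)

_BAD = 1e12  # optimizer-safe sentinel for non-finite likelihoods


class FitError(RuntimeError):
    """Raised when a maximum-likelihood fit cannot be completed."""


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

_FORMS = ("power", "exponential")


@dataclass(frozen=True)
class ScalingSpec:
    """Which habitat terms enter the ln-linear predictors, and on what scale.

    ``include_*`` flags switch the patch-size slope (``a``), refuge slope
    (``b``) and their interaction (``gamma``) on or off for each response;
    an interaction may only be included together with both main effects.
    ``*_form`` chooses the covariate scale: ``"power"`` enters the logarithm
    of the covariate (a power law on the natural scale), ``"exponential"``
    enters it untransformed.
    """

    include_a_n0: bool = True
    include_b_n0: bool = True
    include_gamma_n0: bool = True
    include_a_h: bool = True
    include_b_h: bool = True
    include_gamma_h: bool = True
    area_form_n0: str = "power"
    refuge_form_n0: str = "exponential"
    area_form_h: str = "power"
    refuge_form_h: str = "power"

    def __post_init__(self) -> None:
        if self.include_gamma_n0 and not (self.include_a_n0 and self.include_b_n0):
            raise ValueError("gamma_N0 requires both a_N0 and b_N0")
        if self.include_gamma_h and not (self.include_a_h and self.include_b_h):
            raise ValueError("gamma_h requires both a_h and b_h")
        for f in (self.area_form_n0, self.refuge_form_n0, self.area_form_h, self.refuge_form_h):
            if f not in _FORMS:
                raise ValueError(f"unknown form {f!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["ln_C_N0"]
        if self.include_a_n0:
            names.append("a_N0")
        if self.include_b_n0:
            names.append("b_N0")
        if self.include_gamma_n0:
            names.append("gamma_N0")
        names.append("ln_C_h")
        if self.include_a_h:
            names.append("a_h")
        if self.include_b_h:
            names.append("b_h")
        if self.include_gamma_h:
            names.append("gamma_h")
        names.append("ln_k")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _transform(values: np.ndarray, form: str, what: str) -> np.ndarray:
    if form == "power":
        if np.any(values <= 0):
            raise ValueError(f"{what} must be > 0 when it enters as a power law (log scale)")
        return np.log(values)
    return np.asarray(values, dtype=float)


def _design_matrix(
    area: np.ndarray,
    refuge: np.ndarray,
    area_form: str,
    refuge_form: str,
    inc_a: bool,
    inc_b: bool,
    inc_g: bool,
) -> np.ndarray:
    cols = [np.ones_like(np.asarray(area, dtype=float))]
    ta = tr = None
    if inc_a or inc_g:
        ta = _transform(np.asarray(area, dtype=float), area_form, "patch size")
    if inc_b or inc_g:
        tr = _transform(np.asarray(refuge, dtype=float), refuge_form, "refuge availability")
    if inc_a:
        cols.append(ta)
    if inc_b:
        cols.append(tr)
    if inc_g:
        cols.append(ta * tr)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def real_fr(N, fmax: float, N0: float, h: float):
    """Real's functional response ``f_max * N**h / (N0**h + N**h)``.

    At ``N == N0`` the feeding rate is exactly ``f_max / 2`` for any Hill
    exponent.  Evaluated on the log scale to stay finite at extreme
    densities.
    """
    if fmax <= 0:
        raise ValueError("fmax must be > 0")
    if N0 <= 0 or h <= 0:
        raise ValueError("N0 and h must be > 0")
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("N must be > 0")
    ln_f = np.log(fmax) + h * np.log(N) - np.logaddexp(h * np.log(N0), h * np.log(N))
    out = np.exp(ln_f)
    return float(out) if out.ndim == 0 else out


def fit_max_feeding(counts: Sequence[int]) -> tuple[float, float, float]:
    """Intercept-only Poisson GLM (log link) for the maximum feeding rate.

    Returns ``(ln_fmax, se, p_value)``.  The closed form of this model is
    ``ln_fmax = ln(mean)`` with ``se = 1/sqrt(sum(counts))``; the GLM route
    additionally provides the Wald p-value.
    """
    y = np.asarray(counts, dtype=float)
    if y.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if not np.any(y > 0):
        raise FitError("all-zero counts: the log-link intercept is degenerate")
    with warnings.catch_warnings():
        # constant replicate counts trip a spurious separation warning
        warnings.simplefilter("ignore")
        res = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Poisson()).fit()
    return float(res.params[0]), float(res.bse[0]), float(res.pvalues[0])


#: Dispersion ceiling: beyond this the NB is numerically indistinguishable
#: from its Poisson limit and gammaln differences lose precision.
_LN_K_MAX = 16.0


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    """Negative-binomial log pmf in the ecological (mu, k) parametrization.

    Variance is ``mu + mu**2 / k``; ``k -> inf`` recovers the Poisson.
    ``-k*log(k/(k+mu))`` is evaluated via ``log1p`` so the Poisson limit is
    approached stably.
    """
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1.0)
        - k * np.log1p(mu / k)
        + y * (np.log(mu) - np.log(k + mu))
    )


# ---------------------------------------------------------------------------
# the model object
# ---------------------------------------------------------------------------

class FunctionalResponseModel:
    """Negative-binomial MLE of Real's functional response on trial data.

    Parameters
    ----------
    data
        Trial table with columns ``area_m2``, ``refuge_fraction``,
        ``density_per_m2`` (or ``density``) and ``eaten``.
    ln_fmax
        Log maximum feeding rate, fixed at the Poisson-GLM estimate from the
        non-spatial maximum-feeding trials (not re-estimated here).
    spec
        Which habitat scalings of ``N0`` and ``h`` to estimate; defaults to
        the full model (both slopes and the interaction on both responses).

    Examples
    --------
    >>> model = FunctionalResponseModel(trials, ln_fmax=1.9,
    ...                                 spec=ScalingSpec(include_gamma_n0=False,
    ...                                                  include_a_h=False,
    ...                                                  include_b_h=False,
    ...                                                  include_gamma_h=False))
    >>> res = model.fit()
    >>> res.predict_n0_h(1.0, 0.35)          # doctest: +SKIP
    """

    def __init__(
        self,
        data: pd.DataFrame,
        ln_fmax: float,
        spec: ScalingSpec | None = None,
    ) -> None:
        self.spec = spec if spec is not None else ScalingSpec()
        self.ln_fmax = float(ln_fmax)
        density_col = "density_per_m2" if "density_per_m2" in data else "density"
        required = {"area_m2", "refuge_fraction", density_col, "eaten"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        if not len(data):
            raise ValueError("data must be non-empty")
        self.data = data.reset_index(drop=True)
        self.endog = np.asarray(self.data["eaten"], dtype=float)
        if np.any(self.endog < 0):
            raise ValueError("eaten counts must be >= 0")
        self.density = np.asarray(self.data[density_col], dtype=float)
        if np.any(self.density <= 0):
            raise ValueError("densities must be > 0")
        self._ln_density = np.log(self.density)
        s = self.spec
        self._X_n0 = _design_matrix(
            self.data["area_m2"].to_numpy(), self.data["refuge_fraction"].to_numpy(),
            s.area_form_n0, s.refuge_form_n0,
            s.include_a_n0, s.include_b_n0, s.include_gamma_n0,
        )
        self._X_h = _design_matrix(
            self.data["area_m2"].to_numpy(), self.data["refuge_fraction"].to_numpy(),
            s.area_form_h, s.refuge_form_h,
            s.include_a_h, s.include_b_h, s.include_gamma_h,
        )

    # -- parameter bookkeeping ---------------------------------------------

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.spec.param_names

    @property
    def n_obs(self) -> int:
        return self.endog.size

    def _split(self, params: np.ndarray):
        n_n0 = self._X_n0.shape[1]
        n_h = self._X_h.shape[1]
        if params.size != n_n0 + n_h + 1:
            raise ValueError(
                f"expected {n_n0 + n_h + 1} parameters for spec {self.spec}, got {params.size}"
            )
        return params[:n_n0], params[n_n0:n_n0 + n_h], params[-1]

    def _ln_mean(self, params: np.ndarray) -> np.ndarray:
        beta_n0, beta_h, _ = self._split(params)
        ln_n0 = self._X_n0 @ beta_n0
        h = np.exp(self._X_h @ beta_h)
        return self.ln_fmax + h * self._ln_density - np.logaddexp(
            h * ln_n0, h * self._ln_density
        )

    def loglike(self, params) -> float:
        """Summed negative-binomial log likelihood at ``params``."""
        params = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(params)):
            return -np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            ln_mu = self._ln_mean(params)
            # cap the dispersion at its numerically safe Poisson-limit value;
            # feeding counts with no overdispersion drive ln(k) to +inf
            k = np.exp(min(float(self._split(params)[2]), _LN_K_MAX))
            ll = _nb_logpmf(self.endog, np.exp(ln_mu), k)
        total = float(np.sum(ll))
        return total if np.isfinite(total) else -np.inf

    # -- fitting -----------------------------------------------------------

    def _start_grid(self) -> list[np.ndarray]:
        starts = []
        q = np.quantile(self._ln_density, [0.3, 0.5, 0.7])
        for ln_c_n0 in q:
            for ln_c_h in (0.0, 0.35):
                p = np.zeros(self.spec.n_params)
                p[0] = ln_c_n0
                p[self._X_n0.shape[1]] = ln_c_h
                p[-1] = 1.0  # ln k
                starts.append(p)
        return starts

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 5000,
    ) -> "FunctionalResponseResult":
        """Maximize the likelihood (multi-start Nelder-Mead + BFGS polish).

        Standard errors come from the observed information matrix (numerical
        Hessian of the negative log likelihood at the optimum).
        """
        def objective(p):
            ll = self.loglike(p)
            return -ll if np.isfinite(ll) else _BAD

        starts = [np.asarray(start_params, dtype=float)] if start_params is not None \
            else self._start_grid()
        # cheap exploratory simplex from every start, full refinement from
        # the best basin only
        best = None
        for p0 in starts:
            probe = scipy.optimize.minimize(
                objective, p0, method="Nelder-Mead",
                options={"maxiter": 300, "fatol": 1e-6},
            )
            if best is None or probe.fun < best.fun:
                best = probe
        if best is not None and best.fun < _BAD:
            refined = scipy.optimize.minimize(
                objective, best.x, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
            )
            if refined.fun <= best.fun:
                best = refined
        if best is None or best.fun >= _BAD:
            raise FitError(
                f"no start converged to a finite likelihood (spec={self.spec}, "
                f"n={self.n_obs})"
            )
        polish = scipy.optimize.minimize(
            objective, best.x, method="BFGS",
            options={"maxiter": maxiter, "gtol": 1e-8},
        )
        if np.isfinite(polish.fun) and polish.fun <= best.fun:
            best = polish
        params = np.asarray(best.x, dtype=float)
        llf = -float(best.fun)

        # at the Poisson limit the surface is flat in ln(k): pin the
        # dispersion at its cap and take the information over the rest
        at_cap = params[-1] >= _LN_K_MAX
        if at_cap:
            params[-1] = _LN_K_MAX
        bse = np.full(params.size, np.nan)
        cov = np.full((params.size, params.size), np.nan)
        if at_cap:
            free = params[:-1]
            def sub_objective(p):
                return objective(np.append(p, _LN_K_MAX))
            hess_fn, hess_args = sub_objective, free
        else:
            hess_fn, hess_args = objective, params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = numdiff.approx_hess(hess_args, hess_fn)
        try:
            sub_cov = np.linalg.inv(hess)
            diag = np.diag(sub_cov)
            sub_bse = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
            m = hess.shape[0]
            cov[:m, :m] = sub_cov
            bse[:m] = sub_bse
        except np.linalg.LinAlgError:
            logger.warning("singular observed information; SEs unavailable")
        return FunctionalResponseResult(
            model=self, params=params, bse=bse, llf=llf, cov_params=cov,
        )


@dataclass
class FunctionalResponseResult:
    """MLE estimates of a habitat-dependent functional response.

    Carries the point estimates, Wald standard errors from the observed
    information, the log likelihood and BIC, and prediction helpers.
    """

    model: FunctionalResponseModel
    params: np.ndarray
    bse: np.ndarray
    llf: float
    cov_params: np.ndarray

    @property
    def spec(self) -> ScalingSpec:
        return self.model.spec

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.model.param_names

    @property
    def n_obs(self) -> int:
        return self.model.n_obs

    @property
    def ln_fmax(self) -> float:
        return self.model.ln_fmax

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.params.size * np.log(self.n_obs)

    @property
    def dispersion(self) -> float:
        """Negative-binomial size parameter k (variance = mu + mu^2/k)."""
        return float(np.exp(self.params[-1]))

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.params)))

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * scipy.stats.norm.sf(np.abs(self.zvalues))

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]

    def se(self, name: str) -> float:
        return float(self.bse[self.param_names.index(name)])

    def predict_n0_h(self, area_m2, refuge_fraction) -> tuple:
        """Half-saturation density and Hill exponent at a habitat point."""
        return _predict_n0_h(self.spec, self.params, area_m2, refuge_fraction)

    def predict(self, N, area_m2, refuge_fraction):
        """Expected feeding rate at density N in a given habitat."""
        n0, h = self.predict_n0_h(area_m2, refuge_fraction)
        return real_fr(N, float(np.exp(self.ln_fmax)), float(n0), float(h))

    def hill_test(self) -> tuple[float, float]:
        """Hill exponent and Wald p-value of ln(C_h) against 0 (i.e. h = 1)."""
        i = self.param_names.index("ln_C_h")
        se = self.bse[i]
        if not np.isfinite(se):
            raise FitError("no standard error available for ln_C_h")
        z = self.params[i] / se
        p = float(2.0 * scipy.stats.norm.sf(abs(z)))
        return float(np.exp(self.params[i])), p

    def summary(self) -> str:
        lines = [
            "Functional response fit (negative-binomial MLE)",
            "=" * 58,
            f"n_obs: {self.n_obs}    logLik: {self.llf:.3f}    BIC: {self.bic:.3f}",
            f"fixed ln(f_max): {self.ln_fmax:.4f}   dispersion k: {self.dispersion:.3f}",
            f"forms: N0 ~ {self.spec.area_form_n0}(A) x {self.spec.refuge_form_n0}(R), "
            f"h ~ {self.spec.area_form_h}(A) x {self.spec.refuge_form_h}(R)",
            "-" * 58,
            f"{'term':<12}{'estimate':>12}{'s.e.':>10}{'z':>9}{'p':>11}",
        ]
        for name, est, se, z, p in zip(
            self.param_names, self.params, self.bse, self.zvalues, self.pvalues
        ):
            lines.append(f"{name:<12}{est:>12.4f}{se:>10.4f}{z:>9.2f}{p:>11.3g}")
        lines.append("=" * 58)
        return "\n".join(lines)


def _predict_n0_h(spec: ScalingSpec, params: np.ndarray, area_m2, refuge_fraction):
    """Evaluate the fitted ln-linear predictors at habitat points."""
    area = np.atleast_1d(np.asarray(area_m2, dtype=float))
    refuge = np.atleast_1d(np.asarray(refuge_fraction, dtype=float))
    area, refuge = np.broadcast_arrays(area, refuge)
    X_n0 = _design_matrix(
        area, refuge, spec.area_form_n0, spec.refuge_form_n0,
        spec.include_a_n0, spec.include_b_n0, spec.include_gamma_n0,
    )
    X_h = _design_matrix(
        area, refuge, spec.area_form_h, spec.refuge_form_h,
        spec.include_a_h, spec.include_b_h, spec.include_gamma_h,
    )
    params = np.asarray(params, dtype=float)
    n_n0 = X_n0.shape[1]
    n0 = np.exp(X_n0 @ params[:n_n0])
    h = np.exp(X_h @ params[n_n0:n_n0 + X_h.shape[1]])
    if np.isscalar(area_m2) and np.isscalar(refuge_fraction):
        return float(n0[0]), float(h[0])
    return n0, h


@dataclass(frozen=True)
class ScalingEstimate:
    """A fitted habitat scaling detached from its data (e.g. loaded from
    JSON); enough to drive predictions and the population-dynamics layer."""

    spec: ScalingSpec
    params: tuple
    ln_fmax: float

    def predict_n0_h(self, area_m2, refuge_fraction):
        return _predict_n0_h(self.spec, np.asarray(self.params), area_m2, refuge_fraction)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names, map(float, self.params)))

    @classmethod
    def from_result(cls, res: "FunctionalResponseResult") -> "ScalingEstimate":
        return cls(spec=res.spec, params=tuple(map(float, res.params)), ln_fmax=res.ln_fmax)

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingEstimate":
        return cls(
            spec=ScalingSpec(**d["spec"]),
            params=tuple(d["params"]),
            ln_fmax=float(d["ln_fmax"]),
        )

    def to_dict(self) -> dict:
        import dataclasses

        return {
            "spec": dataclasses.asdict(self.spec),
            "params": list(self.params),
            "param_names": list(self.spec.param_names),
            "ln_fmax": self.ln_fmax,
        }


# ---------------------------------------------------------------------------
# module-level operation wrappers
# ---------------------------------------------------------------------------

def nb_loglik(params, spec: ScalingSpec, data: pd.DataFrame, ln_fmax_fixed: float) -> float:
    """Negative-binomial log likelihood of a parameter vector on trial data."""
    return FunctionalResponseModel(data, ln_fmax_fixed, spec).loglike(params)


def fit_scaling_model(
    data: pd.DataFrame,
    spec: ScalingSpec,
    ln_fmax_fixed: float,
    **fit_kwargs,
) -> FunctionalResponseResult:
    """Fit one habitat-scaling structure by maximum likelihood."""
    return FunctionalResponseModel(data, ln_fmax_fixed, spec).fit(**fit_kwargs)


def predict_N0_h(area_m2, refuge_fraction, fit: FunctionalResponseResult):
    """Half-saturation density and Hill exponent implied by a fit."""
    return fit.predict_n0_h(area_m2, refuge_fraction)


def hill_test(fit: FunctionalResponseResult) -> tuple[float, float]:
    """Hill exponent and its Wald test against h = 1 (ln C_h against 0)."""
    return fit.hill_test()


# ---------------------------------------------------------------------------
# enumeration and selection
# ---------------------------------------------------------------------------

_TERM_SETS = (
    (False, False, False),
    (True, False, False),
    (False, True, False),
    (True, True, False),
    (True, True, True),
)


def enumerate_scaling_specs(base: ScalingSpec | None = None) -> list[ScalingSpec]:
    """The 25 admissible on/off combinations of the habitat slope terms.

    Five term sets per response ({}, {a}, {b}, {a, b}, {a, b, gamma}) crossed
    over the N0 and h predictors; the covariate forms are inherited from
    ``base``.
    """
    if base is None:
        base = ScalingSpec()
    specs = []
    for (a0_, b0_, g0_), (ah, bh, gh) in itertools.product(_TERM_SETS, _TERM_SETS):
        specs.append(
            replace(
                base,
                include_a_n0=a0_, include_b_n0=b0_, include_gamma_n0=g0_,
                include_a_h=ah, include_b_h=bh, include_gamma_h=gh,
            )
        )
    return specs


def enumerate_form_specs() -> list[ScalingSpec]:
    """The 16 full models crossing power/exponential forms on A and R."""
    specs = []
    for fa0, fr0, fah, frh in itertools.product(_FORMS, _FORMS, _FORMS, _FORMS):
        specs.append(
            ScalingSpec(
                include_a_n0=True, include_b_n0=True, include_gamma_n0=True,
                include_a_h=True, include_b_h=True, include_gamma_h=True,
                area_form_n0=fa0, refuge_form_n0=fr0,
                area_form_h=fah, refuge_form_h=frh,
            )
        )
    return specs


def _fits_table(fits: list[tuple[ScalingSpec, FunctionalResponseResult | None]]) -> pd.DataFrame:
    rows = []
    for spec, res in fits:
        row: dict = {
            "include_a_n0": spec.include_a_n0,
            "include_b_n0": spec.include_b_n0,
            "include_gamma_n0": spec.include_gamma_n0,
            "include_a_h": spec.include_a_h,
            "include_b_h": spec.include_b_h,
            "include_gamma_h": spec.include_gamma_h,
            "area_form_n0": spec.area_form_n0,
            "refuge_form_n0": spec.refuge_form_n0,
            "area_form_h": spec.area_form_h,
            "refuge_form_h": spec.refuge_form_h,
            "n_params": spec.n_params,
        }
        if res is not None:
            row.update(llf=res.llf, bic=res.bic)
            for name, est, se in zip(res.param_names, res.params, res.bse):
                row[name] = est
                row[f"se_{name}"] = se
        else:
            row.update(llf=np.nan, bic=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    order = table["bic"].rank(method="first")
    table["rank"] = order
    return table


def select_model(
    data: pd.DataFrame,
    ln_fmax_fixed: float,
    base: ScalingSpec | None = None,
    **fit_kwargs,
) -> tuple[FunctionalResponseResult, pd.DataFrame]:
    """BIC selection over the 25 habitat-scaling term combinations.

    Returns the minimum-BIC fit (ties broken toward fewer parameters) and
    the full candidate table.  Candidates whose optimisation fails are
    excluded with a warning.
    """
    fits: list[tuple[ScalingSpec, FunctionalResponseResult | None]] = []
    results: list[FunctionalResponseResult] = []
    for spec in enumerate_scaling_specs(base):
        try:
            res = fit_scaling_model(data, spec, ln_fmax_fixed, **fit_kwargs)
        except FitError as err:
            warnings.warn(f"candidate {spec} excluded: {err}")
            fits.append((spec, None))
            continue
        fits.append((spec, res))
        results.append(res)
    if not results:
        raise FitError("every candidate model failed to fit")
    best = min(results, key=lambda r: (round(r.bic, 9), r.params.size))
    return best, _fits_table(fits)


def form_screen(
    data: pd.DataFrame,
    ln_fmax_fixed: float,
    **fit_kwargs,
) -> pd.DataFrame:
    """BIC comparison of the 16 full models with power/exponential forms.

    Each candidate keeps all slope and interaction terms and varies only
    whether patch size and refuge enter the N0 and h predictors as power
    laws (log scale) or exponentials (natural scale).
    """
    fits: list[tuple[ScalingSpec, FunctionalResponseResult | None]] = []
    for spec in enumerate_form_specs():
        try:
            res = fit_scaling_model(data, spec, ln_fmax_fixed, **fit_kwargs)
        except FitError as err:
            warnings.warn(f"form candidate {spec} excluded: {err}")
            res = None
        fits.append((spec, res))
    return _fits_table(fits)
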
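"""Mechanistic diffusion trap-catch models for MRR recapture-distance data.

Three time-integrated diffusion models describe the expected per-trap
recapture percentage P(r) at distance r from the release point:

``simple``
    P(r) = A' r^{-1/2} e^{-r/B} — diffusion with constant disappearance;
    the r^{-1/2} factor is the two-dimensional dilution effect.
``heterogeneous``
    P(r) = A1' r^{-1/2} e^{-r/B1} + A2' r^{-1/2} e^{-r/B2} — the sum of
    two diffusion components for short- and long-distance disperser
    subpopulations (B1 < B2 enforced).
``mixed_equal``
    P(r) = A' r^{-1/2} e^{-r/B} + C' — diffusion plus a distance-
    independent constant, a flat-tail null for long-distance dispersers.

Fitting maximizes a Gaussian likelihood on the ring x release per-trap
percentages, with the residual standard deviation optionally depending on
the fitted mean: sd_i = sigma (``none``), sigma * exp(delta_v * mu_i)
(``exponential``), or sigma * |mu_i|^delta_v (``power``).  These variance
functions absorb the strong heteroscedasticity of recapture rates, which
vary over orders of magnitude between the inner and outer rings.

A' is measured in percent * m^{1/2} (per-trap percentage of flyers), B in
meters, C' in percent per trap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import RingSummary

__all__ = [
    "DiffusionParams",
    "DiffusionTrapCatchModel",
    "DiffusionFitResults",
    "eval_model",
    "fit_diffusion",
    "compare_models",
]

MODEL_KINDS = ("simple", "heterogeneous", "mixed_equal")
VARIANCE_KINDS = ("none", "exponential", "power")

#: admissible range for the variance coefficient delta_v.  Recapture-rate
#: spread grows with the mean (inner rings are noisier on the percent
#: scale), so sd must be non-decreasing in the fitted mean; the caps keep
#: the likelihood bounded on small or degenerate datasets.
VAR_COEF_BOUNDS = {"exponential": (0.0, 500.0), "power": (0.0, 5.0)}

#: upper bound on the dispersal scales B (m).  A scale orders of magnitude
#: beyond the outermost ring is indistinguishable from a flat tail and
#: only produces absurd extrapolations; 1,000 km is far outside any
#: biologically meaningful flight range.
B_MAX_M = 1e6

#: parameter names per model kind, in reporting order
PARAM_NAMES = {
    "simple": ("A_prime", "B"),
    "heterogeneous": ("A1_prime", "B1", "A2_prime", "B2"),
    "mixed_equal": ("A_prime", "B", "C_prime"),
}


@dataclass(frozen=True)
class DiffusionParams:
    """Mean-function parameters for one trap-catch model."""

    kind: str
    A_prime: float | None = None
    B: float | None = None
    A1_prime: float | None = None
    B1: float | None = None
    A2_prime: float | None = None
    B2: float | None = None
    C_prime: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        missing = [n for n in PARAM_NAMES[self.kind] if getattr(self, n) is None]
        if missing:
            raise ValueError(f"{self.kind} model requires parameters {missing}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES[self.kind]], float)

    @classmethod
    def from_array(cls, kind: str, values: Sequence[float]) -> "DiffusionParams":
        return cls(kind=kind, **dict(zip(PARAM_NAMES[kind], map(float, values))))

    def ordered(self) -> "DiffusionParams":
        """Return with components relabelled so that B1 < B2 (heterogeneous)."""
        if self.kind == "heterogeneous" and self.B1 > self.B2:
            return replace(
                self, A1_prime=self.A2_prime, B1=self.B2, A2_prime=self.A1_prime, B2=self.B1
            )
        return self


def eval_model(params: DiffusionParams, r) -> np.ndarray | float:
    """Expected per-trap recapture percentage at distance(s) r (m), r > 0."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("distances must be > 0")
    k = params.kind
    if k == "simple":
        out = params.A_prime * r_arr**-0.5 * np.exp(-r_arr / params.B)
    elif k == "heterogeneous":
        out = params.A1_prime * r_arr**-0.5 * np.exp(-r_arr / params.B1) + (
            params.A2_prime * r_arr**-0.5 * np.exp(-r_arr / params.B2)
        )
    else:  # mixed_equal
        out = params.A_prime * r_arr**-0.5 * np.exp(-r_arr / params.B) + params.C_prime
    return out if out.ndim else float(out)


def _mean_gradient(params: DiffusionParams, r: np.ndarray) -> np.ndarray:
    """Analytic gradient of the mean function w.r.t. the natural parameters.

    Shape (len(r), n_params), columns in PARAM_NAMES order.
    """
    k = params.kind
    if k == "simple":
        basis = r**-0.5 * np.exp(-r / params.B)
        return np.column_stack([basis, params.A_prime * basis * r / params.B**2])
    if k == "heterogeneous":
        b1 = r**-0.5 * np.exp(-r / params.B1)
        b2 = r**-0.5 * np.exp(-r / params.B2)
        return np.column_stack(
            [b1, params.A1_prime * b1 * r / params.B1**2, b2, params.A2_prime * b2 * r / params.B2**2]
        )
    basis = r**-0.5 * np.exp(-r / params.B)
    return np.column_stack(
        [basis, params.A_prime * basis * r / params.B**2, np.ones_like(r)]
    )


class DiffusionFitError(RuntimeError):
    """Raised on non-convergence; carries the best incumbent fit."""

    def __init__(self, message: str, incumbent: "DiffusionFitResults | None" = None):
        super().__init__(message)
        self.incumbent = incumbent


class DiffusionTrapCatchModel:
    """Gaussian ML fit of a diffusion trap-catch curve to ring-level data.

    Parameters
    ----------
    distance : array-like
        Ring distances r_i (m), one per observation (ring x release).
    pr_percent : array-like
        Per-trap recapture percentage of flyers at each distance.
    kind : {"simple", "heterogeneous", "mixed_equal"}
    variance : {"none", "exponential", "power"}
        Residual variance function of the fitted mean.
    """

    def __init__(self, distance, pr_percent, kind: str = "simple", variance: str = "none"):
        self.r = np.asarray(distance, dtype=float)
        self.y = np.asarray(pr_percent, dtype=float)
        if self.r.shape != self.y.shape or self.r.ndim != 1:
            raise ValueError("distance and pr_percent must be matching 1-d arrays")
        if np.any(self.r <= 0):
            raise ValueError("distances must be > 0")
        if kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        if variance not in VARIANCE_KINDS:
            raise ValueError(f"variance must be one of {VARIANCE_KINDS}")
        self.kind = kind
        self.variance = variance
        self.n_mean_params = len(PARAM_NAMES[kind])
        self.n_var_coef = 0 if variance == "none" else 1
        # k for AIC: mean params + variance coefficient + sigma
        self.k_params = self.n_mean_params + self.n_var_coef + 1
        if len(self.y) < self.n_mean_params + 1:
            raise ValueError(
                f"need at least {self.n_mean_params + 1} observations for a "
                f"{kind} fit, got {len(self.y)}"
            )
        if not np.any(self.y > 0):
            raise ValueError("all-zero response: nothing to fit")

    @classmethod
    def from_ring_summaries(
        cls, rows: Sequence[RingSummary], kind: str = "simple", variance: str = "none"
    ) -> "DiffusionTrapCatchModel":
        return cls(
            [row.ring_m for row in rows],
            [row.pr_percent for row in rows],
            kind=kind,
            variance=variance,
        )

    # -- internal parameterization: log of positive mean params, free var coef

    def _unpack(self, psi: np.ndarray) -> tuple[DiffusionParams, float]:
        theta = np.exp(psi[: self.n_mean_params])
        params = DiffusionParams.from_array(self.kind, theta)
        var_coef = float(psi[self.n_mean_params]) if self.n_var_coef else 0.0
        return params, var_coef

    def _sd_factors(self, mu: np.ndarray, var_coef: float) -> np.ndarray:
        if self.variance == "none":
            return np.ones_like(mu)
        if self.variance == "exponential":
            return np.exp(var_coef * mu)
        return np.abs(mu) ** var_coef

    def _profile_loglik(self, psi: np.ndarray) -> float:
        """Log-likelihood with sigma profiled out analytically."""
        params, var_coef = self._unpack(psi)
        if self.n_var_coef:
            lo, hi = VAR_COEF_BOUNDS[self.variance]
            if not lo <= var_coef <= hi:
                return -np.inf
        for name in PARAM_NAMES[self.kind]:
            if name.startswith("B") and getattr(params, name) > B_MAX_M:
                return -np.inf
        mu = eval_model(params, self.r)
        g = self._sd_factors(mu, var_coef)
        if not np.all(np.isfinite(g)) or np.any(g <= 0):
            return -np.inf
        z = (self.y - mu) / g
        s2 = float(np.mean(z**2))
        if s2 <= 0 or not np.isfinite(s2):
            return -np.inf
        n = len(self.y)
        return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0) - float(np.sum(np.log(g)))

    def loglik(self, params: DiffusionParams, sigma: float, var_coef: float = 0.0) -> float:
        """Full Gaussian log-likelihood at explicit parameter values."""
        mu = eval_model(params, self.r)
        sd = sigma * self._sd_factors(mu, var_coef)
        return float(np.sum(stats.norm.logpdf(self.y, loc=mu, scale=sd)))

    # -- initialization -----------------------------------------------------

    def _simple_init(self, r: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """Linearized fit: ln(y r^{1/2}) = ln A' - r/B on positive rows."""
        pos = y > 0
        r_p, y_p = r[pos], y[pos]
        if len(r_p) >= 2 and np.ptp(r_p) > 0:
            coef = np.polyfit(r_p, np.log(y_p * np.sqrt(r_p)), 1)
            slope, intercept = coef[0], coef[1]
            A0 = float(np.exp(intercept))
            B0 = float(-1.0 / slope) if slope < 0 else float(np.mean(r_p))
        else:
            A0 = float(y_p[0] * np.sqrt(r_p[0]) * np.e)
            B0 = float(r_p[0])
        return max(A0, 1e-8), max(B0, 1.0)

    def _initial_psi(self, init: DiffusionParams | None) -> np.ndarray:
        if init is not None:
            theta = np.log(np.maximum(init.as_array(), 1e-12))
        elif self.kind == "simple":
            A0, B0 = self._simple_init(self.r, self.y)
            theta = np.log([A0, B0])
        elif self.kind == "heterogeneous":
            rings = np.unique(self.r)
            inner = np.isin(self.r, rings[:3]) if len(rings) > 3 else slice(None)
            A0, B0 = self._simple_init(self.r[inner], self.y[inner])
            B2_0 = 20.0 * B0
            r_out = rings[-1]
            out_rows = self.r == r_out
            resid = np.mean(self.y[out_rows]) - np.mean(
                A0 * r_out**-0.5 * np.exp(-r_out / B0)
            )
            A2_0 = max(resid, 1e-6) * np.sqrt(r_out) * np.exp(r_out / B2_0)
            theta = np.log([A0, B0, max(A2_0, 1e-8), B2_0])
        else:  # mixed_equal
            rings = np.unique(self.r)
            outer = np.isin(self.r, rings[-2:]) if len(rings) > 2 else slice(None)
            C0 = max(float(np.mean(self.y[outer])), 1e-8)
            inner = np.isin(self.r, rings[:-2]) if len(rings) > 2 else slice(None)
            A0, B0 = self._simple_init(self.r[inner], self.y[inner])
            theta = np.log([A0, B0, C0])
        if self.n_var_coef:
            theta = np.append(theta, 0.5)
        return theta

    def _embedded_simple_starts(self) -> list[np.ndarray]:
        """Starts that embed the one-component curve in a nesting model.

        Guards the nesting inequalities: a heterogeneous or mixed_equal
        fit must never end below the simple fit it contains, so the
        simple solution (with a vanishing second component) is always
        among the starting points.
        """
        if self.kind == "simple":
            return []
        A0, B0 = self._simple_init(self.r, self.y)
        if self.kind == "heterogeneous":
            theta = np.log([A0, B0, 1e-10, 20.0 * B0])
        else:
            theta = np.log([A0, B0, 1e-10])
        if self.n_var_coef:
            theta = np.append(theta, 0.5)
        return [theta]

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        init: DiffusionParams | None = None,
        n_restarts: int = 5,
        seed: int = 0,
        jitter_scale: float = 0.5,
    ) -> "DiffusionFitResults":
        """Maximize the likelihood from a deterministic start plus jittered
        restarts; polish the best optimum to high precision."""
        psi0 = self._initial_psi(init)
        rng = np.random.default_rng(seed)
        starts = [psi0] + self._embedded_simple_starts() + [
            psi0 + rng.normal(scale=jitter_scale, size=psi0.shape) for _ in range(n_restarts)
        ]
        best_psi, best_ll = None, -np.inf
        for s in starts:
            with np.errstate(all="ignore"):
                try:
                    res = optimize.minimize(
                        lambda p: -self._profile_loglik(p), s, method="Nelder-Mead",
                        options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-11},
                    )
                except (FloatingPointError, ValueError):
                    continue
            ll = self._profile_loglik(res.x)
            if np.isfinite(ll) and ll > best_ll:
                best_ll, best_psi = ll, res.x
        if best_psi is None:
            raise DiffusionFitError("no start converged to a finite likelihood")
        # high-precision polish of the winning mode only
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                lambda p: -self._profile_loglik(p), best_psi, method="Nelder-Mead",
                options={"maxiter": 8000, "xatol": 1e-12, "fatol": 1e-14},
            )
        if self._profile_loglik(res.x) >= best_ll:
            best_psi, best_ll = res.x, self._profile_loglik(res.x)
        best_psi = self._newton_polish(best_psi)
        return self._build_results(best_psi)

    def _newton_polish(self, psi: np.ndarray, max_steps: int = 8) -> np.ndarray:
        """Drive the score toward zero with damped Newton steps."""
        ll = self._profile_loglik(psi)
        gmax = np.max(np.abs(self._score(psi)))
        for _ in range(max_steps):
            if gmax < 1e-9:
                break
            grad = self._score(psi)
            H = _numeric_hessian(self._profile_loglik, psi, rel_step=1e-5)
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                break
            improved = False
            # near the optimum the likelihood change sits below float
            # resolution, so accept on score reduction with a tiny
            # tolerance on the likelihood itself
            for damp in (1.0, 0.5, 0.25, 0.1):
                cand = psi + damp * step
                ll_c = self._profile_loglik(cand)
                if not np.isfinite(ll_c) or ll_c < ll - 1e-8 * max(1.0, abs(ll)):
                    continue
                g_c = np.max(np.abs(self._score(cand)))
                if g_c < gmax:
                    psi, ll, gmax, improved = cand, max(ll, ll_c), g_c, True
                    break
            if not improved:
                break
        return psi

    def _build_results(self, psi: np.ndarray) -> "DiffusionFitResults":
        params, var_coef = self._unpack(psi)
        mu = eval_model(params, self.r)
        g = self._sd_factors(mu, var_coef)
        sigma = float(np.sqrt(np.mean(((self.y - mu) / g) ** 2)))
        ll = self.loglik(params, sigma, var_coef)
        aic = -2.0 * ll + 2.0 * self.k_params

        grad = self._score(psi)
        cov, cov_ok = self._covariance(params, sigma, var_coef)
        ordered = params.ordered()
        if ordered is not params and cov_ok:
            cov = self._permute_cov(cov)
        return DiffusionFitResults(
            model=self,
            params=ordered,
            sigma=sigma,
            variance_coef=var_coef if self.n_var_coef else None,
            loglik=ll,
            aic=aic,
            covariance=cov,
            score_sup=float(np.max(np.abs(grad))),
        )

    def _permute_cov(self, cov: np.ndarray) -> np.ndarray:
        """Swap mixture-component blocks after B1/B2 relabelling."""
        perm = np.arange(cov.shape[0])
        perm[[0, 1, 2, 3]] = [2, 3, 0, 1]
        return cov[np.ix_(perm, perm)]

    def _score(self, psi: np.ndarray, h: float = 1e-6) -> np.ndarray:
        grad = np.zeros_like(psi)
        for j in range(len(psi)):
            e = np.zeros_like(psi)
            e[j] = h
            grad[j] = (self._profile_loglik(psi + e) - self._profile_loglik(psi - e)) / (2 * h)
        return grad

    def _full_natural_loglik(self, phi: np.ndarray) -> float:
        """Log-likelihood as a function of all natural-scale parameters
        (mean params, variance coefficient if any, sigma)."""
        theta = phi[: self.n_mean_params]
        if np.any(theta <= 0):
            return -np.inf
        params = DiffusionParams.from_array(self.kind, theta)
        var_coef = float(phi[self.n_mean_params]) if self.n_var_coef else 0.0
        sigma = float(phi[-1])
        if sigma <= 0:
            return -np.inf
        return self.loglik(params, sigma, var_coef)

    def _covariance(
        self, params: DiffusionParams, sigma: float, var_coef: float
    ) -> tuple[np.ndarray, bool]:
        """Observed-information covariance on the natural parameter scale."""
        phi = params.as_array()
        if self.n_var_coef:
            phi = np.append(phi, var_coef)
        phi = np.append(phi, sigma)
        H = _numeric_hessian(self._full_natural_loglik, phi)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.full((len(phi), len(phi)), np.nan), False
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            return cov, False
        return cov, True


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


@dataclass
class DiffusionFitResults:
    """Estimates, uncertainty and fit diagnostics for one trap-catch model.

    ``covariance`` rows/columns are ordered (mean params..., variance
    coefficient if any, sigma), on the natural parameter scale; Wald
    confidence intervals are symmetric and may cross zero.
    """

    model: DiffusionTrapCatchModel
    params: DiffusionParams
    sigma: float
    variance_coef: float | None
    loglik: float
    aic: float
    covariance: np.ndarray
    score_sup: float
    akaike_weight: float | None = None

    @property
    def kind(self) -> str:
        return self.params.kind

    @property
    def variance_kind(self) -> str:
        return self.model.variance

    @property
    def k_params(self) -> int:
        return self.model.k_params

    @property
    def param_names(self) -> tuple[str, ...]:
        names = PARAM_NAMES[self.kind]
        extra = ("variance_coef",) if self.variance_coef is not None else ()
        return names + extra + ("sigma",)

    @property
    def estimates(self) -> np.ndarray:
        vals = list(self.params.as_array())
        if self.variance_coef is not None:
            vals.append(self.variance_coef)
        vals.append(self.sigma)
        return np.array(vals)

    @property
    def bse(self) -> np.ndarray:
        d = np.diag(self.covariance)
        return np.sqrt(np.where(d >= 0, d, np.nan))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        est, se = self.estimates, self.bse
        return np.column_stack([est - z * se, est + z * se])

    def predict(self, r) -> np.ndarray | float:
        return eval_model(self.params, r)

    def predict_band(self, grid) -> pd.DataFrame:
        """Delta-method 95% band around the mean curve.

        Var(P_r) = g' Sigma g with g the gradient of the mean function at
        the estimates; band half-width 1.96 * sqrt(Var), symmetric and
        allowed to cross zero.
        """
        grid = np.asarray(grid, dtype=float)
        if np.any(grid <= 0):
            raise ValueError("grid distances must be > 0")
        npar = self.model.n_mean_params
        sub = self.covariance[:npar, :npar]
        if not np.all(np.isfinite(sub)):
            raise ValueError("singular or undefined covariance; cannot form band")
        G = _mean_gradient(self.params, grid)
        var = np.einsum("ij,jk,ik->i", G, sub, G)
        var = np.maximum(var, 0.0)
        mean = eval_model(self.params, grid)
        half = 1.96 * np.sqrt(var)
        return pd.DataFrame(
            {"r_m": grid, "mean": mean, "lower": mean - half, "upper": mean + half}
        )

    def summary(self) -> str:
        lines = [
            f"Diffusion trap-catch model: {self.kind} / variance {self.variance_kind}",
            f"n obs = {len(self.model.y)}, k = {self.k_params}, "
            f"loglik = {self.loglik:.4f}, AIC = {self.aic:.2f}",
        ]
        if self.akaike_weight is not None:
            lines.append(f"Akaike weight = {self.akaike_weight:.3f}")
        ci = self.conf_int()
        lines.append(f"{'param':>14} {'estimate':>12} {'se':>11} {'ci_low':>11} {'ci_high':>11}")
        for name, est, se, (lo, hi) in zip(self.param_names, self.estimates, self.bse, ci):
            lines.append(f"{name:>14} {est:>12.5g} {se:>11.4g} {lo:>11.4g} {hi:>11.4g}")
        lines.append(f"max |score| at optimum = {self.score_sup:.2e}")
        return "\n".join(lines)

    def plot(self, ax=None, grid=None):
        """Data, fitted curve and delta-method band on a log-distance axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if grid is None:
            grid = np.geomspace(self.model.r.min(), self.model.r.max(), 200)
        band = self.predict_band(grid)
        ax.scatter(self.model.r, self.model.y, s=12, color="k", zorder=3)
        ax.plot(band["r_m"], band["mean"], color="C0")
        ax.fill_between(band["r_m"], band["lower"], band["upper"], alpha=0.25, color="C0")
        ax.set_xscale("log")
        ax.set_xlabel("distance from release point (m)")
        ax.set_ylabel("recapture (% of flyers per trap)")
        ax.set_title(f"{self.kind} / {self.variance_kind}")
        return ax

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "variance": self.variance_kind,
            "estimates": dict(zip(self.param_names, map(float, self.estimates))),
            "se": dict(zip(self.param_names, map(float, self.bse))),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "akaike_weight": None if self.akaike_weight is None else float(self.akaike_weight),
        }


def fit_diffusion(
    rows: Sequence[RingSummary] | pd.DataFrame,
    kind: str = "simple",
    variance: str = "none",
    init: DiffusionParams | None = None,
    **fit_kw,
) -> DiffusionFitResults:
    """Convenience wrapper: build the model from ring summaries and fit."""
    if isinstance(rows, pd.DataFrame):
        model = DiffusionTrapCatchModel(
            rows["ring_m"].to_numpy(), rows["pr_percent"].to_numpy(), kind, variance
        )
    else:
        model = DiffusionTrapCatchModel.from_ring_summaries(rows, kind, variance)
    return model.fit(init=init, **fit_kw)


#: nesting structure for likelihood-ratio tests (nested, full)
NESTED_PAIRS = (("simple", "heterogeneous"), ("simple", "mixed_equal"))


def compare_models(fits: Sequence[DiffusionFitResults]) -> pd.DataFrame:
    """Akaike weights across fits of the same data, plus LRTs for nested pairs.

    Weights are w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) with
    Delta_i = AIC_i - min AIC.  Likelihood-ratio tests are reported for
    simple-within-heterogeneous and simple-within-mixed_equal at matching
    variance function, with df = difference in parameter counts.

    Mutates each fit's ``akaike_weight`` in place and returns the table.
    """
    if not fits:
        raise ValueError("need at least one fit")
    ref_y, ref_r = fits[0].model.y, fits[0].model.r
    for f in fits[1:]:
        if not (np.array_equal(f.model.y, ref_y) and np.array_equal(f.model.r, ref_r)):
            raise ValueError("all fits must share identical data")

    aic = np.array([f.aic for f in fits])
    delta = aic - aic.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    for f, wi in zip(fits, w):
        f.akaike_weight = float(wi)

    rows = []
    order = np.argsort(aic, kind="stable")
    for i in order:
        f = fits[i]
        lrt_stat = lrt_df = lrt_p = np.nan
        nested_vs = ""
        for nested_kind, full_kind in NESTED_PAIRS:
            if f.kind != full_kind:
                continue
            for g in fits:
                if g.kind == nested_kind and g.variance_kind == f.variance_kind:
                    lrt_stat = 2.0 * (f.loglik - g.loglik)
                    lrt_df = f.k_params - g.k_params
                    lrt_p = float(stats.chi2.sf(max(lrt_stat, 0.0), lrt_df)) if lrt_df > 0 else np.nan
                    if lrt_stat == 0.0:
                        lrt_p = 1.0
                    nested_vs = f"{nested_kind}/{g.variance_kind}"
        rows.append(
            {
                "kind": f.kind,
                "variance": f.variance_kind,
                "k": f.k_params,
                "loglik": f.loglik,
                "aic": f.aic,
                "delta_aic": float(delta[i]),
                "akaike_weight": f.akaike_weight,
                "lrt_vs": nested_vs,
                "lrt_stat": lrt_stat,
                "lrt_df": lrt_df,
                "lrt_p": lrt_p,
            }
        )
    return pd.DataFrame(rows)
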
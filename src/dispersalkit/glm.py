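"""Phenomenological density-distance analysis of ring-level recaptures.

Recapture counts summed over the traps of each ring are modelled with a
Poisson log-link regression on log distance, sex, and their interaction,
with log(number of traps) as an offset denoting sampling intensity.
Candidate term sets are compared by AIC, and prediction bands are formed
on the linear predictor (width 2 x 1.96 x SE) then back-transformed, so
the bounds are strictly positive.

Flight-experienced and flight-naive releases are analysed separately;
this module operates on whatever rows it is given and does not pool
groups itself.

Natural logarithms are used for the distance covariate.  Sex uses
treatment coding with female as the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import RingSummary

__all__ = [
    "TERM_SETS",
    "glm_frame_from_ring_summaries",
    "RecaptureGLM",
    "GlmFit",
    "fit_poisson_loglink",
    "select_by_aic",
    "predict_with_ci",
]

VALID_TERMS = ("intercept", "log_distance", "sex", "interaction")

#: the candidate models compared in the analysis
TERM_SETS = {
    "full": ("intercept", "log_distance", "sex", "interaction"),
    "distance_sex": ("intercept", "log_distance", "sex"),
    "distance_only": ("intercept", "log_distance"),
    "sex_only": ("intercept", "sex"),
    "intercept_only": ("intercept",),
}


def glm_frame_from_ring_summaries(rows: Sequence[RingSummary]) -> pd.DataFrame:
    """Expand ring summaries into per-sex GLM rows.

    Each ring x release contributes one row per sex with the sexed
    recapture count; the trap count is carried as the exposure.
    """
    recs = []
    for row in rows:
        for sex, count in (("F", row.n_female), ("M", row.n_male)):
            recs.append(
                {
                    "release_id": row.release_id,
                    "distance": float(row.ring_m),
                    "sex": sex,
                    "count": count,
                    "n_traps": row.n_traps,
                }
            )
    return pd.DataFrame(recs)


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(data))], ["intercept"]
    if "log_distance" in terms:
        cols.append(np.log(data["distance"].to_numpy(float)))
        names.append("log_distance")
    if "sex" in terms:
        cols.append((data["sex"].to_numpy() == "M").astype(float))
        names.append("sex[M]")
    if "interaction" in terms:
        cols.append(
            np.log(data["distance"].to_numpy(float))
            * (data["sex"].to_numpy() == "M").astype(float)
        )
        names.append("log_distance:sex[M]")
    return np.column_stack(cols), names


@dataclass
class GlmFit:
    """Fitted Poisson log-link model for ring-level recapture counts."""

    terms: tuple[str, ...]
    coef_names: list[str]
    coefficients: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    loglik: float
    aic: float
    df_model: int
    converged: bool
    offset_name: str = "log(n_traps)"
    _data_key: tuple = field(default=(), repr=False)

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.coef_names, map(float, self.coefficients)))

    def summary(self) -> str:
        lines = [
            f"Poisson log-link GLM, offset = {self.offset_name}",
            f"terms: {' + '.join(self.terms)}",
            f"loglik = {self.loglik:.4f}, AIC = {self.aic:.2f}, df_model = {self.df_model}",
            f"{'term':>22} {'estimate':>10} {'se':>9} {'z':>8}",
        ]
        for name, b, s in zip(self.coef_names, self.coefficients, self.bse):
            z = b / s if s > 0 else np.inf
            lines.append(f"{name:>22} {b:>10.4f} {s:>9.4f} {z:>8.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": {n: float(c) for n, c in self.coef.items()},
            "se": dict(zip(self.coef_names, map(float, self.bse))),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
        }


class RecaptureGLM:
    """Model object for the Poisson density-distance regression.

    Parameters
    ----------
    data : DataFrame
        Rows with columns ``count`` (non-negative integer recaptures),
        ``n_traps`` (exposure), ``distance`` (m, > 0 when a distance term
        is used), and ``sex`` ("M"/"F", required for sex terms).
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)
        counts = self.data["count"].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        if np.all(counts == 0):
            raise ValueError("all-zero response: model is not identifiable")

    @classmethod
    def from_ring_summaries(cls, rows: Sequence[RingSummary]) -> "RecaptureGLM":
        return cls(glm_frame_from_ring_summaries(rows))

    def fit(self, terms: tuple[str, ...] = TERM_SETS["full"]) -> GlmFit:
        terms = tuple(terms)
        unknown = set(terms) - set(VALID_TERMS)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}; valid: {VALID_TERMS}")
        if "interaction" in terms and not {"log_distance", "sex"} <= set(terms):
            raise ValueError("interaction requires both log_distance and sex terms")
        needs_distance = "log_distance" in terms
        if needs_distance and np.any(self.data["distance"].to_numpy(float) <= 0):
            raise ValueError("distances must be > 0")

        X, names = _design_matrix(self.data, terms)
        offset = np.log(self.data["n_traps"].to_numpy(float))
        model = sm.GLM(
            self.data["count"].to_numpy(float), X, family=sm.families.Poisson(), offset=offset
        )
        res = model.fit(maxiter=100, tol=1e-10)
        if not res.converged:
            raise RuntimeError(
                f"IRLS failed to converge in {res.fit_history['iteration']} iterations"
            )
        k = X.shape[1]
        return GlmFit(
            terms=terms,
            coef_names=names,
            coefficients=np.asarray(res.params),
            bse=np.asarray(res.bse),
            cov_params=np.asarray(res.cov_params()),
            loglik=float(res.llf),
            aic=float(-2.0 * res.llf + 2.0 * k),
            df_model=k - 1,
            converged=True,
            _data_key=_data_key(self.data),
        )

    def fit_all(self, term_sets: dict[str, tuple[str, ...]] | None = None) -> dict[str, GlmFit]:
        """Fit every candidate term set that the data can support."""
        term_sets = term_sets or TERM_SETS
        has_sex = "sex" in self.data.columns and self.data["sex"].nunique() > 1
        out = {}
        for name, terms in term_sets.items():
            if ("sex" in terms or "interaction" in terms) and not has_sex:
                continue
            out[name] = self.fit(terms)
        return out


def _data_key(data: pd.DataFrame) -> tuple:
    return (
        tuple(data["count"].tolist()),
        tuple(data["n_traps"].tolist()),
        tuple(data.get("distance", pd.Series(dtype=float)).tolist()),
        tuple(data.get("sex", pd.Series(dtype=str)).tolist()),
    )


def fit_poisson_loglink(data: pd.DataFrame, terms: tuple[str, ...]) -> GlmFit:
    """Fit one Poisson log-link model with a log trap-count offset."""
    return RecaptureGLM(data).fit(terms)


def select_by_aic(fits: Sequence[GlmFit]) -> list[GlmFit]:
    """Rank fits of the same data by ascending AIC.

    Ties break toward fewer parameters, then lexically on the term set.
    """
    if not fits:
        raise ValueError("need at least one fit")
    keys = {f._data_key for f in fits}
    if len(keys) > 1:
        raise ValueError("fits were made on differing data; AIC is not comparable")
    return sorted(fits, key=lambda f: (f.aic, f.df_model + 1, f.terms))


def predict_with_ci(fit: GlmFit, grid, sex: str = "F") -> pd.DataFrame:
    """Back-transformed 95% prediction band over a distance grid.

    The band is computed on the linear predictor (mean +/- 1.96 SE, i.e.
    width 2 x 1.96 x SE) and exponentiated, so lower < mean < upper and
    all three are strictly positive.  The prediction is the expected
    count per single trap (offset term zero).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid distances must be > 0")
    frame = pd.DataFrame({"distance": grid, "sex": sex})
    X, names = _design_matrix(frame, fit.terms)
    if names != fit.coef_names:
        raise ValueError("fit coefficients do not match the requested design")
    eta = X @ fit.coefficients
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_params, X))
    return pd.DataFrame(
        {
            "distance": grid,
            "mean": np.exp(eta),
            "lower": np.exp(eta - 1.96 * se),
            "upper": np.exp(eta + 1.96 * se),
        }
    )
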
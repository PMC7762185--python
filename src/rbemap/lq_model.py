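"""Poisson maximum-likelihood fitting of the linear-quadratic survival model.

The LQ model writes clonogenic survival after dose D as

    SF(D) = exp(-alpha * D - beta * D**2),   alpha [1/Gy] >= 0, beta [1/Gy^2] >= 0,

so the colony count of a well seeded with N cells at plating efficiency PE
is Poisson with mean ``N * PE * SF(D)``.  Fitting maximises the Poisson
log-likelihood directly (log link, offset log(N*PE)) under box constraints
alpha, beta >= 0.  The covariance of the estimates is the inverse observed
information at the optimum, restricted to the free parameters: a parameter
pinned at the zero boundary is flagged and its variance reported as
unavailable (Wald variance is invalid on a boundary).

Nested fits are compared with an analysis-of-deviance F approximation: the
drop in Poisson deviance from pooling two datasets under shared (alpha,
beta), scaled by degrees of freedom, referred to the F distribution.  This
plays the role the extra sum-of-squares F test plays for least-squares fits
while keeping every fit in one Poisson framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

_BOUNDARY_TOL = 1e-8


class LQFitError(RuntimeError):
    """Raised when an LQ fit cannot be computed or does not converge."""


@dataclass
class LQFit:
    """A fitted linear-quadratic survival curve.

    ``covariance`` is a 2x2 matrix over (alpha, beta); rows/columns of a
    boundary-pinned parameter are NaN.  ``max_dose_covered`` optionally
    records the highest dose with a survival point above the limit of
    detection, used downstream to mark extrapolated isosurvival doses.
    """

    alpha: float
    beta: float
    covariance: np.ndarray
    pe: float
    cells_seeded: int
    log_likelihood: float
    deviance: float
    n_points: int
    alpha_at_boundary: bool = False
    beta_at_boundary: bool = False
    converged: bool = True
    ion: Optional[str] = None
    y_d: Optional[float] = None
    let_d: Optional[float] = None
    column_index: Optional[int] = None
    max_dose_covered: Optional[float] = None

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (2, 2):
            raise LQFitError("covariance must be 2x2 over (alpha, beta)")
        if self.alpha < 0 or self.beta < 0:
            raise LQFitError("alpha and beta must be non-negative")
        finite = ~np.isnan(self.covariance)
        if finite.any():
            sub = self.covariance[np.ix_(finite.all(axis=1), finite.all(axis=0))]
            if sub.size and np.linalg.eigvalsh(sub).min() < -1e-8 * max(
                1.0, float(np.abs(sub).max())
            ):
                raise LQFitError("covariance not positive semidefinite")

    @property
    def boundary_flags(self) -> tuple[bool, bool]:
        return (self.alpha_at_boundary, self.beta_at_boundary)

    def predict_sf(self, dose) -> float:
        return predict_sf(self, dose)

    def dose_at_sf(self, sf_level: float) -> float:
        return dose_at_sf(self, sf_level)

    def to_dict(self) -> dict:
        return {
            "alpha_per_Gy": self.alpha,
            "beta_per_Gy2": self.beta,
            "covariance": self.covariance.tolist(),
            "pe": self.pe,
            "cells_seeded": self.cells_seeded,
            "log_likelihood": self.log_likelihood,
            "deviance": self.deviance,
            "n_points": self.n_points,
            "alpha_at_boundary": self.alpha_at_boundary,
            "beta_at_boundary": self.beta_at_boundary,
            "ion": self.ion,
            "y_d": self.y_d,
            "let_d": self.let_d,
            "column": self.column_index,
            "max_dose_covered": self.max_dose_covered,
        }


@dataclass(frozen=True)
class FitComparison:
    """Analysis-of-deviance comparison of separate vs pooled LQ fits."""

    statistic: float
    p_value: float
    df_num: int
    df_den: int
    pooled_fit: LQFit
    separate_fits: tuple[LQFit, ...]


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _poisson_nll_and_grad(theta, doses, counts, offsets):
    """Negative Poisson log-likelihood (dropping log n! terms) and gradient.

    mu_i = offset_i * exp(-alpha d_i - beta d_i^2).
    """
    alpha, beta = theta
    log_mu = np.log(offsets) - alpha * doses - beta * doses**2
    mu = np.exp(log_mu)
    nll = float(np.sum(mu - counts * log_mu))
    resid = counts - mu
    grad = np.array([np.sum(resid * doses), np.sum(resid * doses**2)])
    return nll, grad


def _poisson_deviance(counts, mu):
    counts = np.asarray(counts, dtype=float)
    term = np.where(counts > 0, counts * np.log(np.where(counts > 0, counts, 1) / mu), 0.0)
    return float(2.0 * np.sum(term - (counts - mu)))


def _information_matrix(theta, doses, offsets):
    """Observed (= expected, canonical link) information over (alpha, beta)."""
    alpha, beta = theta
    mu = offsets * np.exp(-alpha * doses - beta * doses**2)
    return np.array(
        [
            [np.sum(mu * doses**2), np.sum(mu * doses**3)],
            [np.sum(mu * doses**3), np.sum(mu * doses**4)],
        ]
    )


def _minimize_nll(x0, doses, counts, offsets, bounds):
    """Bounded L-BFGS-B with a projected-gradient convergence check.

    The tight ftol can trip the optimizer's line search at machine
    precision ("ABNORMAL"); the fit is still accepted when the projected
    gradient at the solution is negligible.
    """
    res = optimize.minimize(
        _poisson_nll_and_grad,
        x0,
        args=(doses, counts, offsets),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    if not res.success:
        _, grad = _poisson_nll_and_grad(res.x, doses, counts, offsets)
        proj = np.array(
            [
                0.0 if (x <= lo + 1e-12 and g > 0) or (hi is not None and x >= hi - 1e-12 and g < 0) else g
                for x, g, (lo, hi) in zip(res.x, grad, bounds)
            ]
        )
        scale = 1.0 + abs(float(res.fun)) + float(np.abs(counts).sum())
        if np.abs(proj).max() > 1e-5 * scale:
            raise LQFitError(f"LQ optimizer did not converge: {res.message}")
    return res


def _initial_alpha(doses, counts, offsets):
    """Log-linear slope of mean survival vs dose, clipped to be non-negative."""
    d = np.asarray(doses, dtype=float)
    sf = np.clip(counts / offsets, 1e-6, None)
    pos = d > 0
    if not pos.any():
        return 0.1
    # through-origin least squares of -log SF on dose
    num = np.sum(d[pos] * (-np.log(sf[pos])))
    den = np.sum(d[pos] ** 2)
    return max(num / den, 0.0) if den > 0 else 0.1


def fit_lq_poisson(
    doses: Sequence[float],
    counts: Sequence[int],
    cells_seeded: int,
    pe: float,
    fix_beta_zero: bool = False,
    fix_alpha_zero: bool = False,
    **metadata,
) -> LQFit:
    """Fit alpha, beta >= 0 by Poisson maximum likelihood on per-well counts.

    Parameters
    ----------
    doses, counts
        Per-well dose (Gy) and colony count, aligned.  Dose-0 wells are
        allowed but not required: the plating efficiency enters as a fixed
        offset, following the normalise-then-fit sequence of the assay.
    cells_seeded, pe
        Seeding density and pooled plating efficiency fixing the offset
        ``cells_seeded * pe`` (PE uncertainty is not propagated).
    fix_beta_zero, fix_alpha_zero
        Constrain a component to zero (pure-alpha or pure-beta fit).
    metadata
        Optional ``ion``, ``y_d``, ``let_d``, ``column_index``,
        ``max_dose_covered`` carried on the returned :class:`LQFit`.
    """
    doses = np.asarray(doses, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if doses.shape != counts.shape or doses.ndim != 1 or doses.size == 0:
        raise LQFitError("doses and counts must be equal-length 1-D sequences")
    # fractional "counts" are accepted so noiseless expected counts can be
    # fitted exactly; real data are integers
    if (counts < 0).any() or not np.isfinite(counts).all():
        raise LQFitError("counts must be non-negative and finite")
    if counts.sum() == 0:
        raise LQFitError("all counts are zero: no information on survival")
    if not 0 < pe <= 1:
        raise LQFitError(f"plating efficiency {pe} outside (0, 1]")
    if np.unique(doses[doses > 0]).size < 1:
        raise LQFitError("need at least one positive dose level")
    offsets = np.full_like(doses, float(cells_seeded) * pe)

    x0 = np.array(
        [
            0.0 if fix_alpha_zero else _initial_alpha(doses, counts, offsets),
            0.0 if fix_beta_zero else 0.01,
        ]
    )
    bounds = [
        (0.0, 0.0) if fix_alpha_zero else (0.0, None),
        (0.0, 0.0) if fix_beta_zero else (0.0, None),
    ]
    res = _minimize_nll(x0, doses, counts, offsets, bounds)
    alpha, beta = (max(v, 0.0) for v in res.x)
    alpha_pinned = fix_alpha_zero or alpha < _BOUNDARY_TOL
    beta_pinned = fix_beta_zero or beta < _BOUNDARY_TOL
    if alpha_pinned:
        alpha = 0.0
    if beta_pinned:
        beta = 0.0

    info = _information_matrix((alpha, beta), doses, offsets)
    cov = np.full((2, 2), np.nan)
    free = [i for i, pinned in enumerate((alpha_pinned, beta_pinned)) if not pinned]
    if free:
        sub = info[np.ix_(free, free)]
        try:
            sub_inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError as exc:
            raise LQFitError(f"information matrix singular: {exc}") from exc
        for a, i in enumerate(free):
            for b, j in enumerate(free):
                cov[i, j] = sub_inv[a, b]

    mu = offsets * np.exp(-alpha * doses - beta * doses**2)
    log_mu = np.log(mu)
    loglik = float(np.sum(counts * log_mu - mu))
    return LQFit(
        alpha=alpha,
        beta=beta,
        covariance=cov,
        pe=pe,
        cells_seeded=cells_seeded,
        log_likelihood=loglik,
        deviance=_poisson_deviance(counts, mu),
        n_points=int(doses.size),
        alpha_at_boundary=bool(alpha_pinned),
        beta_at_boundary=bool(beta_pinned),
        **metadata,
    )


# ---------------------------------------------------------------------------
# curve evaluation and inversion
# ---------------------------------------------------------------------------


def predict_sf(fit: LQFit, dose):
    """Surviving fraction exp(-alpha D - beta D^2) at dose D >= 0 Gy."""
    d = np.asarray(dose, dtype=float)
    if (d < 0).any():
        raise ValueError("dose must be non-negative")
    out = np.exp(-fit.alpha * d - fit.beta * d**2)
    return float(out) if np.isscalar(dose) or d.ndim == 0 else out


def dose_at_sf(fit: LQFit, sf_level: float) -> float:
    """Isosurvival dose: the positive root of alpha D + beta D^2 = -ln(sf).

    Closed forms: -ln(sf)/alpha when beta = 0, sqrt(-ln(sf)/beta) when
    alpha = 0; otherwise the stable quadratic root
    ``2L / (alpha + sqrt(alpha^2 + 4 beta L))`` with L = -ln(sf).
    """
    if not 0 < sf_level < 1:
        raise ValueError(f"sf_level must be in (0, 1), got {sf_level}")
    L = -math.log(sf_level)
    a, b = fit.alpha, fit.beta
    if a == 0 and b == 0:
        raise LQFitError("flat curve (alpha = beta = 0): isosurvival dose undefined")
    if b == 0:
        return L / a
    if a == 0:
        return math.sqrt(L / b)
    return 2.0 * L / (a + math.sqrt(a * a + 4.0 * b * L))


# ---------------------------------------------------------------------------
# nested-model comparison
# ---------------------------------------------------------------------------


def _n_free(fit: LQFit) -> int:
    return 2 - sum(fit.boundary_flags)


def compare_fits(
    dataset_a: tuple[Sequence[float], Sequence[int], int, float],
    dataset_b: tuple[Sequence[float], Sequence[int], int, float],
) -> FitComparison:
    """Do two clonogenic datasets share one LQ curve?

    Each dataset is ``(doses, counts, cells_seeded, pe)``.  Separate fits
    and a pooled fit (shared alpha, beta; each dataset keeps its own
    offset) are compared by the scaled drop in Poisson deviance,

        F = [(D_pooled - D_separate) / df_num] / [D_separate / df_den],

    referred to F(df_num, df_den).  df_num counts the extra free parameters
    of the separate model, df_den the residual degrees of freedom.
    """
    fits = []
    arrays = []
    for ds in (dataset_a, dataset_b):
        doses, counts, cells_seeded, pe = ds
        fits.append(fit_lq_poisson(doses, counts, cells_seeded, pe))
        arrays.append(
            (
                np.asarray(doses, dtype=float),
                np.asarray(counts, dtype=float),
                np.full(len(doses), float(cells_seeded) * pe),
            )
        )
    doses = np.concatenate([a[0] for a in arrays])
    counts = np.concatenate([a[1] for a in arrays])
    offsets = np.concatenate([a[2] for a in arrays])

    x0 = np.array([_initial_alpha(doses, counts, offsets), 0.01])
    res = _minimize_nll(x0, doses, counts, offsets, [(0.0, None), (0.0, None)])
    alpha_p, beta_p = (max(v, 0.0) for v in res.x)
    mu_p = offsets * np.exp(-alpha_p * doses - beta_p * doses**2)
    dev_pooled = _poisson_deviance(counts, mu_p)
    pooled = LQFit(
        alpha=alpha_p,
        beta=beta_p,
        covariance=np.linalg.inv(_information_matrix((alpha_p, beta_p), doses, offsets)),
        pe=float("nan"),
        cells_seeded=0,
        log_likelihood=float(np.sum(counts * np.log(mu_p) - mu_p)),
        deviance=dev_pooled,
        n_points=int(doses.size),
    )

    dev_sep = sum(f.deviance for f in fits)
    df_num = max(sum(_n_free(f) for f in fits) - _n_free(pooled), 1)
    df_den = int(doses.size) - sum(_n_free(f) for f in fits)
    if df_den <= 0:
        raise LQFitError("not enough points for a nested comparison")
    extra = max(dev_pooled - dev_sep, 0.0)
    if dev_sep <= 0:
        statistic = 0.0 if extra == 0 else float("inf")
    else:
        statistic = (extra / df_num) / (dev_sep / df_den)
    p_value = float(stats.f.sf(statistic, df_num, df_den)) if np.isfinite(statistic) else 0.0
    return FitComparison(
        statistic=float(statistic),
        p_value=p_value,
        df_num=df_num,
        df_den=df_den,
        pooled_fit=pooled,
        separate_fits=tuple(fits),
    )
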
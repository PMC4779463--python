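"""Phenomenological adaptation laws fitted to the mechanistic pipeline.

Across loading scenarios, the remodelled trabecula's reorientation and
cross-section change correlate with the initial beam strain drivers:

    dphi = a K_eps^3 + b K_eps                      (odd cubic reorientation)
    R_A  = (i K_eps + sign(eps_a) j) eps_a + k_mean (cross-section law)

The first is an odd-restricted third-order polynomial in the bending
preponderance K_eps; the second composes per-angle linear fits of R_A
against the axial strain eps_a, whose slopes are themselves linear in K_eps
within the tension and compression subdomains, and whose intercepts are
pooled to a single mean.  Strains are dimensionless (e.g. 1.25e-3), which
makes j of order 1e3.

The two laws are exposed as scikit-learn style estimators
(:class:`ReorientationLaw`, :class:`SectionLaw`) plus thin function
wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "fit_linear",
    "ReorientationLaw",
    "SectionLaw",
    "PhenomLaw",
    "fit_reorientation_law",
    "fit_section_law",
    "predict_adaptation",
    "FIT_DOMAIN",
    "QUASI_LINEAR_DOMAIN",
    "in_domain",
]

#: Load-angle fit domain for the cross-section and cubic reorientation laws
#: (near-horizontal angles excluded): [0, 6pi/16] union [10pi/16, pi].
FIT_DOMAIN = ((0.0, 6 * np.pi / 16), (10 * np.pi / 16, np.pi))
#: Stricter domain on which dphi(K_eps) is quasi-linear.
QUASI_LINEAR_DOMAIN = ((0.0, 5 * np.pi / 16), (11 * np.pi / 16, np.pi))


def in_domain(theta, domain=FIT_DOMAIN) -> np.ndarray:
    """Boolean mask of angles inside a union-of-intervals fit domain."""
    theta = np.atleast_1d(np.asarray(theta, float))
    tol = 1e-9
    out = np.zeros(theta.shape, dtype=bool)
    for lo, hi in domain:
        out |= (theta >= lo - tol) & (theta <= hi + tol)
    return out


def fit_linear(x, y) -> tuple[float, float, float]:
    """Ordinary least squares line fit.

    Returns (slope, intercept, R^2) with R^2 = 1 - SS_res / SS_tot.
    Requires at least 3 points and non-degenerate x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(res.slope), float(res.intercept), r2


def _r2(y, pred) -> float:
    ss_res = float(np.sum((np.asarray(y) - np.asarray(pred)) ** 2))
    ss_tot = float(np.sum((np.asarray(y) - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)


class ReorientationLaw(RegressorMixin, BaseEstimator):
    """Cubic reorientation law dphi(K_eps), odd-restricted by default.

    Parameters
    ----------
    odd_only : bool, default True
        Restrict the polynomial basis to {x, x^3}, enforcing the exact
        antisymmetry expected of mirror-image loading scenarios.  The full
        cubic (including even terms) is always fitted alongside and kept in
        ``full_coef_`` for diagnostics.

    Attributes
    ----------
    a_, b_ : coefficients of dphi = a K^3 + b K.
    full_coef_ : full cubic coefficients, highest power first (numpy
        polyval order).
    r2_ : coefficient of determination of the (odd or full) fit used.
    """

    def __init__(self, odd_only: bool = True):
        self.odd_only = odd_only

    def fit(self, X, y):
        x = np.asarray(X, float).reshape(-1)
        y = np.asarray(y, float).reshape(-1)
        n_min = 2 if self.odd_only else 4
        if x.size < n_min:
            raise ValueError(f"need at least {n_min} points, got {x.size}")
        # full cubic, always available for diagnostics
        if x.size >= 4:
            self.full_coef_ = np.polyfit(x, y, 3)
        else:
            self.full_coef_ = None
        basis = np.column_stack([x**3, x])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        self.a_, self.b_ = float(coef[0]), float(coef[1])
        if self.odd_only:
            self.r2_ = _r2(y, self.predict(x))
        else:
            self.r2_ = _r2(y, np.polyval(self.full_coef_, x))
        return self

    def predict(self, X):
        x = np.asarray(X, float)
        if self.odd_only:
            return self.a_ * x**3 + self.b_ * x
        return np.polyval(self.full_coef_, x)


class SectionLaw(RegressorMixin, BaseEstimator):
    """Cross-section law R_A(eps_a, K_eps) composed from per-angle fits.

    ``fit`` expects X with columns (theta, eps_a, K_eps) and y = R_A, with
    at least 3 load amplitudes per angle.  Per-angle ordinary least squares
    of R_A against eps_a give a slope and intercept per angle; the slopes
    are regressed linearly on K_eps separately in the tension (theta < pi/2)
    and compression (theta > pi/2) subdomains, excluding the K_eps = 0
    discontinuity; intercepts are pooled into ``k_mean_``.

    Attributes
    ----------
    i_, j_ : slope-law coefficients, slope = i K_eps + sign(eps_a) j.
    k_mean_ : pooled intercept.
    per_angle_ : dict theta -> (slope, intercept, r2, K_eps).
    slope_fit_r2_ : dict subdomain -> R^2 of the slope-vs-K_eps fit.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have columns (theta, eps_a, K_eps)")
        theta, eps_a, k_eps = X.T
        self.per_angle_ = {}
        for th in np.unique(theta):
            sel = theta == th
            if sel.sum() < 3:
                raise ValueError(
                    f"angle {th:.4f} has {int(sel.sum())} amplitudes; need >= 3"
                )
            slope, intercept, r2 = fit_linear(eps_a[sel], y[sel])
            self.per_angle_[float(th)] = (slope, intercept, r2, float(k_eps[sel].mean()))
        self.k_mean_ = float(np.mean([v[1] for v in self.per_angle_.values()]))

        self.slope_fit_r2_ = {}
        coeffs = {}
        for name, sign, cond in (
            ("tension", 1.0, lambda th: th < np.pi / 2),
            ("compression", -1.0, lambda th: th > np.pi / 2),
        ):
            pts = [
                (v[3], v[0])
                for th, v in self.per_angle_.items()
                if cond(th) and abs(v[3]) > 1e-12
            ]
            if len(pts) < 2:
                raise ValueError(f"{name} subdomain has fewer than 2 angles")
            kk = np.array([p[0] for p in pts])
            ss = np.array([p[1] for p in pts])
            if len(pts) >= 3:
                i_c, j_c, r2 = fit_linear(kk, ss)
            else:
                i_c = float((ss[1] - ss[0]) / (kk[1] - kk[0]))
                j_c = float(ss[0] - i_c * kk[0])
                r2 = 1.0
            self.slope_fit_r2_[name] = r2
            coeffs[name] = (i_c, sign * j_c)  # slope = i K + sign(eps_a) j
        self.i_ = float(np.mean([coeffs[n][0] for n in coeffs]))
        self.j_ = float(np.mean([coeffs[n][1] for n in coeffs]))
        pred = self.predict(np.column_stack([eps_a, k_eps]))
        self.r2_ = _r2(y, pred)
        return self

    def predict(self, X):
        """R_A for X with columns (eps_a, K_eps)."""
        X = np.asarray(X, float)
        eps_a = X[:, 0]
        k_eps = X[:, 1]
        return (self.i_ * k_eps + np.sign(eps_a) * self.j_) * eps_a + self.k_mean_


@dataclass(frozen=True)
class PhenomLaw:
    """Fitted phenomenological adaptation law coefficients.

    ``a, b``: odd-cubic reorientation; ``i, j, k_mean``: cross-section law;
    ``full_cubic``: unconstrained cubic coefficients (diagnostics);
    ``r2``: per-fit coefficients of determination.
    """

    a: float
    b: float
    i: float
    j: float
    k_mean: float
    full_cubic: tuple[float, ...] | None = None
    r2: dict = field(default_factory=dict)


def fit_reorientation_law(k_eps, dphi, odd_only: bool = True) -> ReorientationLaw:
    """Least-squares cubic dphi(K_eps); odd-restricted basis by default."""
    return ReorientationLaw(odd_only=odd_only).fit(k_eps, dphi)


def fit_section_law(theta, eps_a, k_eps, r_a) -> SectionLaw:
    """Compose the cross-section law from per-angle linear fits."""
    return SectionLaw().fit(np.column_stack([theta, eps_a, k_eps]), r_a)


def predict_adaptation(
    eps_a: float, k_eps: float, law: PhenomLaw
) -> tuple[float, float | None]:
    """Forward evaluation of the fitted laws.

    Returns (dphi, R_A); R_A is None when eps_a == 0 (the sign in the
    cross-section law is undefined there).
    """
    dphi = law.a * k_eps**3 + law.b * k_eps
    if eps_a == 0:
        return dphi, None
    r_a = (law.i * k_eps + np.sign(eps_a) * law.j) * eps_a + law.k_mean
    return dphi, float(r_a)
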
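"""Two-stage mixed-model association scan.

Stage one fits the polygenic model

    y_i = mu + sum_j beta_j c_ji + G_i + e_i,
    Var(G) = sigma_G^2 * Phi,   Var(e) = sigma_e^2 * I,

by maximum likelihood, where Phi is a kinship matrix estimated from the
entries' scan genotypes.  Stage two runs, per marker, the score test on the
polygenic residuals:

    T = ((G - E[G])' V^-1 y*)^2 / ((G - E[G])' V^-1 (G - E[G]))  ~  chi^2_1,

with G the dosage vector, E[G] its mean, V the fitted covariance and y* the
phenotype residuals adjusted for the fixed effects (y - mu - X beta); the
polygenic family structure enters through V^-1, which is what adjusts the
residuals for population structure.  (Subtracting the polygenic BLUP G_hat
from y* instead would destroy the test: a trait driven by a single marker
projects onto a marker-based kinship exactly like a fully heritable
polygenic trait, so G_hat absorbs the signal itself.)
Markers carrying simulated QTL effects are excluded from the scan (a causal
locus is normally not itself on the array); detection must come from linked
markers.

The fit uses one eigendecomposition of Phi and a bounded scalar search over
the heritability ratio sigma_G^2 / (sigma_G^2 + sigma_e^2); the profile
likelihood in the total variance is closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KinshipMatrix",
    "PolygenicFit",
    "ScanResult",
    "fit_polygenic",
    "kinship_from_genotypes",
    "scan",
    "score_test",
]

_JITTER = 1e-6
_RATIO_TOL = 1e-8


@dataclass
class KinshipMatrix:
    """Symmetric entry-by-entry relationship matrix Phi."""

    values: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.values, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kinship must be square")
        if not np.all(np.isfinite(k)):
            raise ValueError("kinship must be finite")
        self.values = (k + k.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def kinship_from_genotypes(scan_genotypes: np.ndarray, method: str = "freq") -> KinshipMatrix:
    """Kinship from shared alleles at all markers.

    ``method='freq'`` (default) is the frequency-weighted allele-sharing
    estimator: K_ij = 0.5 * mean_m (g_im - 2p_m)(g_jm - 2p_m) / (2 p_m (1-p_m))
    over polymorphic markers, which is ~0.5 on the diagonal for a non-inbred
    individual and ~0 between unrelated ones.  ``method='ibs'`` is plain
    identity-by-state sharing (fraction of shared allele copies).
    """
    g = np.asarray(scan_genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need a 2-D dosage matrix with >= 2 entries")
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("all markers are monomorphic; kinship undefined")
    if method == "freq":
        z = (g[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
        k = 0.5 * (z @ z.T) / np.count_nonzero(poly)
    elif method == "ibs":
        # plain identity-by-state: mean fraction of shared allele copies,
        # 1 - |g_i - g_j| / 2 per marker
        gp = g[:, poly]
        n = gp.shape[0]
        k = np.empty((n, n))
        for i in range(n):
            k[i] = 1.0 - np.abs(gp - gp[i]).mean(axis=1) / 2.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return KinshipMatrix(k)


@dataclass
class PolygenicFit:
    """ML estimates of the polygenic model and its fitted covariance."""

    mu: float
    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    residuals: np.ndarray  # y* = y - (mu + X beta): fixed-effect residuals
    polygenic_residuals: np.ndarray  # e_hat = y* - G_hat (family-adjusted)
    v_inv: np.ndarray
    log_likelihood: float
    heritability_ratio: float


def fit_polygenic(
    phenotypes: np.ndarray,
    kinship: KinshipMatrix,
    covariates: np.ndarray | None = None,
) -> PolygenicFit:
    """Maximum-likelihood fit of the polygenic model.

    The covariance is parametrized as V = tau^2 (h K + (1-h) I) with the
    heritability ratio h in [0, 1); h is found by bounded scalar search on the
    profile log-likelihood, with mu/beta profiled out by GLS and tau^2 in
    closed form.
    """
    y = np.asarray(phenotypes, dtype=float)
    n = y.size
    if kinship.n != n:
        raise ValueError("phenotype count != kinship dimension")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    if np.var(y) == 0:
        raise ValueError("zero phenotypic variance; nothing to fit")
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )

    k = kinship.values
    s, u = np.linalg.eigh(k)
    if s[0] < 0:
        k = k + np.eye(n) * (_JITTER * float(np.trace(k)) / n - s[0])
        s, u = np.linalg.eigh(k)
    ys = u.T @ y
    xs = u.T @ x

    def profile(h: float) -> tuple[float, np.ndarray, float]:
        d = h * s + (1 - h)
        w = 1.0 / d
        xtwx = xs.T @ (xs * w[:, None])
        xtwy = xs.T @ (ys * w)
        beta = np.linalg.solve(xtwx, xtwy)
        r = ys - xs @ beta
        tau2 = float(np.sum(r * r * w) / n)
        nll = 0.5 * (n * np.log(2 * np.pi * tau2) + np.sum(np.log(d)) + n)
        return nll, beta, tau2

    res = optimize.minimize_scalar(
        lambda h: profile(h)[0],
        bounds=(0.0, 1.0 - 1e-6),
        method="bounded",
        options={"xatol": _RATIO_TOL},
    )
    h = float(res.x)
    nll, beta, tau2 = profile(h)
    sigma_g2 = tau2 * h
    sigma_e2 = tau2 * (1 - h)
    d = tau2 * (h * s + (1 - h))
    v_inv = (u / d) @ u.T
    r = y - x @ beta
    # e_hat = r - G_hat = sigma_e^2 V^-1 r  (since V - sigma_g^2 K = sigma_e^2 I)
    return PolygenicFit(
        mu=float(beta[0]),
        beta=beta[1:].copy(),
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        residuals=r,
        polygenic_residuals=sigma_e2 * (v_inv @ r),
        v_inv=v_inv,
        log_likelihood=float(-nll),
        heritability_ratio=h,
    )


def score_test(marker_dosages: np.ndarray, fit: PolygenicFit) -> tuple[float, float]:
    """Score statistic and chi^2_1 p-value for one marker.

    Returns ``(nan, nan)`` for an untestable (constant-dosage) marker.
    """
    g = np.asarray(marker_dosages, dtype=float)
    if g.size != fit.residuals.size:
        raise ValueError("dosage vector length != entry count")
    gc = g - g.mean()
    vg = fit.v_inv @ gc
    den = float(gc @ vg)
    if den <= 0:
        return float("nan"), float("nan")
    num = float(gc @ (fit.v_inv @ fit.residuals)) ** 2
    stat = num / den
    return stat, float(stats.chi2.sf(stat, df=1))


@dataclass
class ScanResult:
    """Per-marker score statistics; masked markers carry NaN."""

    statistic: np.ndarray
    p_value: np.ndarray
    excluded: np.ndarray  # bool mask of markers excluded a priori (QTL loci)

    @property
    def tested(self) -> np.ndarray:
        """Markers that actually received a statistic."""
        return ~np.isnan(self.p_value)

    def neglog10_p(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return -np.log10(self.p_value)


def scan(
    scan_genotypes: np.ndarray,
    fit: PolygenicFit,
    exclude_markers: np.ndarray | list[int] | None = None,
) -> ScanResult:
    """Score-test every non-excluded, non-constant marker.

    ``scan_genotypes`` is the (n_entries, M) dosage matrix; the whole scan is
    vectorized through two matrix products with V^-1.
    """
    g = np.asarray(scan_genotypes, dtype=float)
    n, m = g.shape
    excluded = np.zeros(m, dtype=bool)
    if exclude_markers is not None:
        excluded[np.asarray(exclude_markers, dtype=int)] = True

    gc = g - g.mean(axis=0)
    a = fit.v_inv @ fit.residuals
    num = (gc.T @ a) ** 2
    den = np.einsum("nm,nm->m", gc, fit.v_inv @ gc)

    stat = np.full(m, np.nan)
    p = np.full(m, np.nan)
    testable = (den > 0) & ~excluded
    stat[testable] = num[testable] / den[testable]
    p[testable] = stats.chi2.sf(stat[testable], df=1)
    return ScanResult(statistic=stat, p_value=p, excluded=excluded)
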
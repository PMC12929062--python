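"""Kinship construction and the mixed-linear-model engine shared by GWAS,
eGWAS, TWAS and multi-kernel prediction.

The single-marker model is

    y = X beta + m a + g + e,   g ~ N(0, K sigma_g^2),  e ~ N(0, I sigma_e^2)

with K either the VanRaden genomic relationship matrix (ZZ' / 2 sum p(1-p))
or a feature-derived kinship MM'/c with c the mean diagonal of MM'. The null
model is fitted once per trait by eigen-rotated REML (1-D search over the
variance ratio); the per-marker scan then keeps the rotation and variance
ratio fixed ("population parameters previously determined") and computes the
Wald statistic W = a_hat^2 / var(a_hat), referred to chi^2 with 1 df. The
residual scale entering var(a_hat) is re-estimated per marker from the GLS
residuals (at the fixed ratio), so in the K = I limit W reduces exactly to
the squared OLS t statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla, optimize, stats

from .io_formats import FeatureMatrix, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "MLMNullFit",
    "AssociationResult",
    "MultiKernelFit",
    "vanraden_grm",
    "feature_kinship",
    "reml_null_fit",
    "p3d_wald_scan",
    "fit_multikernel",
    "grm_principal_components",
]

_EIG_TOL = 1e-8


class KinshipError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    genotype_ids: list
    K: np.ndarray
    kind: str  # "vanraden" or "feature"
    scaling_constant: float

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.genotype_ids)
        if self.K.shape != (n, n):
            raise KinshipError("kinship must be square over genotype_ids")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise KinshipError("kinship not symmetric")
        if self.scaling_constant <= 0:
            raise KinshipError("scaling constant must be positive")
        w = np.linalg.eigvalsh(self.K)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise KinshipError(f"kinship not PSD (min eigenvalue {w.min():.3g})")

    @property
    def n(self) -> int:
        return len(self.genotype_ids)

    def align(self, genotype_ids: list) -> "KinshipMatrix":
        index = {g: i for i, g in enumerate(self.genotype_ids)}
        rows = np.array([index[g] for g in genotype_ids])
        return KinshipMatrix(
            genotype_ids=list(genotype_ids),
            K=self.K[np.ix_(rows, rows)],
            kind=self.kind,
            scaling_constant=self.scaling_constant,
        )


def vanraden_grm(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from minor-allele counts."""
    codes = G.codes
    if np.isnan(codes).any():
        raise KinshipError("missing codes; impute before kinship construction")
    p = codes.mean(axis=0) / 2.0
    poly = codes.std(axis=0) > 0
    if poly.sum() < 2:
        raise KinshipError("need at least two polymorphic markers")
    Z = codes[:, poly] - 2.0 * p[poly]
    c = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    K = (Z @ Z.T) / c
    return KinshipMatrix(list(G.sample_ids), K, "vanraden", c)


def feature_kinship(M: FeatureMatrix | pd.DataFrame) -> KinshipMatrix:
    """Feature-derived kinship MM'/c from column-standardized features
    (population sd); c is the mean diagonal of MM', so mean(diag(K)) = 1."""
    if isinstance(M, FeatureMatrix):
        ids, values = M.ids, M.values
    else:
        ids, values = [str(i) for i in M.index], M.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
    if keep.sum() < 2:
        raise KinshipError("fewer than two informative features")
    Z = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]
    MMt = Z @ Z.T
    c = float(np.mean(np.diag(MMt)))
    return KinshipMatrix(list(ids), MMt / c, "feature", c)


def grm_principal_components(K: KinshipMatrix, n_components: int) -> np.ndarray:
    """Leading eigenvectors of the kinship, usable as 'Q' covariates."""
    if n_components == 0:
        return np.zeros((K.n, 0))
    w, U = np.linalg.eigh(K.K)
    order = np.argsort(w)[::-1][:n_components]
    return U[:, order] * np.sqrt(np.maximum(w[order], 0.0))


# ---------------------------------------------------------------------------
# null model


@dataclass
class MLMNullFit:
    """Eigen-rotated REML null fit, cached for the P3D scan."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    lam: float  # sigma_g2 / sigma_e2
    eigvals: np.ndarray
    ystar: np.ndarray  # U' y
    Xstar: np.ndarray  # U' X
    U: np.ndarray
    loglik: float
    genotype_ids: list | None = None

    @property
    def n(self) -> int:
        return len(self.ystar)


def _reml_crit_rotated(lam: float, ystar, Xstar, d):
    """-2 profiled restricted ll (up to constant) at variance ratio lam."""
    n, p = Xstar.shape
    w = 1.0 / (lam * d + 1.0)
    Xw = Xstar * w[:, None]
    XtWX = Xstar.T @ Xw
    XtWy = Xw.T @ ystar
    try:
        cB = np.linalg.cholesky(XtWX)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ystar - Xstar @ beta
    rss = float(resid @ (w * resid))
    df = n - p
    crit = (
        df * np.log(max(rss, 1e-300) / df)
        + float(np.log(lam * d + 1.0).sum())
        + 2.0 * float(np.log(np.diag(cB)).sum())
    )
    return crit, beta, rss / df


def reml_null_fit(y: np.ndarray, X: np.ndarray, K: KinshipMatrix,
                  genotype_ids: list | None = None,
                  eig: tuple | None = None) -> MLMNullFit:
    """EMMA-style REML: eigendecompose K once, 1-D search over the log
    variance ratio on a grid followed by Brent refinement.

    ``eig = (d, U)`` may supply a precomputed eigendecomposition of K so
    that scans over many traits sharing one kinship reuse the rotation.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if X.shape[0] != len(y) or K.n != len(y):
        raise ValueError("dimension mismatch between y, X and K")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")

    if eig is None:
        d, U = np.linalg.eigh(K.K)
        d = np.maximum(d, 0.0)
    else:
        d, U = eig
    ystar = U.T @ y
    Xstar = U.T @ X

    grid = np.concatenate([[0.0], np.logspace(-5, 5, 41)])
    crits = np.array([_reml_crit_rotated(l, ystar, Xstar, d)[0] for l in grid])
    i = int(np.argmin(crits))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if i == 0:
        lam = 0.0
    else:
        res = optimize.minimize_scalar(
            lambda t: _reml_crit_rotated(np.exp(t), ystar, Xstar, d)[0],
            bounds=(np.log(max(lo, 1e-8)), np.log(max(hi, 1e-7))),
            method="bounded", options={"xatol": 1e-6},
        )
        lam = float(np.exp(res.x))
        if _reml_crit_rotated(0.0, ystar, Xstar, d)[0] <= res.fun:
            lam = 0.0
    crit, beta, sigma_e2 = _reml_crit_rotated(lam, ystar, Xstar, d)
    sigma_e2 = max(sigma_e2, 1e-8 * max(float(np.var(y)), 1e-300))
    df = len(y) - X.shape[1]
    loglik = -0.5 * (crit + df * (1.0 + np.log(2.0 * np.pi)))
    return MLMNullFit(
        sigma_g2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        beta=beta,
        lam=lam,
        eigvals=d,
        ystar=ystar,
        Xstar=Xstar,
        U=U,
        loglik=loglik,
        genotype_ids=list(genotype_ids) if genotype_ids is not None else None,
    )


# ---------------------------------------------------------------------------
# P3D scan


@dataclass
class AssociationResult:
    feature_id: str
    effect: float
    se: float
    wald: float
    p: float
    p_adj: float = float("nan")
    constant: bool = False


def p3d_wald_scan(nullfit: MLMNullFit, features: np.ndarray,
                  feature_ids: list | None = None,
                  rotated_features: np.ndarray | None = None) -> pd.DataFrame:
    """Wald scan over explanatory columns with variance ratio and rotation
    fixed at the null estimates.

    Partitioned weighted regression: covariates are projected out of the
    rotated trait and each rotated feature under the P3D weights; the marker
    effect, its variance (with per-marker residual scale) and the chi^2_1
    p-value follow in closed form, vectorized over features.
    """
    n, p = nullfit.Xstar.shape
    if rotated_features is not None:
        Mstar = np.asarray(rotated_features, dtype=float)
    else:
        M = np.asarray(features, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        if M.shape[0] != n:
            raise ValueError("feature rows must match trait length")
        Mstar = nullfit.U.T @ M
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(Mstar.shape[1])]

    w = 1.0 / (nullfit.lam * nullfit.eigvals + 1.0)
    Xs, ys = nullfit.Xstar, nullfit.ystar

    Xw = Xs * w[:, None]
    XtWX = Xs.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)
    # project X out of y and of every feature (weighted)
    beta_y = XtWX_inv @ (Xw.T @ ys)
    ry = ys - Xs @ beta_y
    B = XtWX_inv @ (Xw.T @ Mstar)
    RM = Mstar - Xs @ B

    mm = np.einsum("ij,i,ij->j", RM, w, RM)
    my = RM.T @ (w * ry)
    rss_y = float(ry @ (w * ry))

    const = mm <= 1e-12 * max(mm.max(initial=0.0), 1.0)
    mm_safe = np.where(const, 1.0, mm)
    effect = np.where(const, 0.0, my / mm_safe)
    rss = np.maximum(rss_y - effect * my, 1e-300)
    df = n - p - 1
    if df < 1:
        raise ValueError("no residual degrees of freedom for the scan")
    sigma2 = rss / df
    var_a = sigma2 / mm_safe
    wald = np.where(const, 0.0, effect**2 / var_a)
    pvals = np.where(const, 1.0, stats.chi2.sf(wald, df=1))
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "effect": effect,
            "se": np.sqrt(var_a),
            "wald": wald,
            "p": np.clip(pvals, np.nextafter(0, 1), 1.0),
            "constant": const,
        }
    )


# ---------------------------------------------------------------------------
# multi-kernel mixed model


@dataclass
class MultiKernelFit:
    kernel_names: list
    sigma2: np.ndarray  # per-kernel variances
    sigma_e2: float
    mu: float
    y: np.ndarray = field(repr=False)
    V_list: list = field(repr=False)
    loglik: float = float("nan")
    method: str = "reml"

    def predict(self, train_idx: np.ndarray, test_idx: np.ndarray,
                kernels_full: list[np.ndarray] | None = None) -> np.ndarray:
        """BLUP prediction of held-out genotypes via cross-covariance.

        When the fit was done on training rows only, ``kernels_full`` must
        supply the full-panel kernel matrices (same order as kernel_names).
        """
        Ks = kernels_full if kernels_full is not None else self.V_list
        n_tr = len(train_idx)
        Vtr = np.full((n_tr, n_tr), 0.0)
        for s2, K in zip(self.sigma2, Ks):
            Vtr += s2 * K[np.ix_(train_idx, train_idx)]
        Vtr[np.diag_indices_from(Vtr)] += self.sigma_e2
        resid = self.y - self.mu
        alpha = np.linalg.solve(Vtr, resid)
        out = np.full(len(test_idx), self.mu)
        for s2, K in zip(self.sigma2, Ks):
            out += s2 * (K[np.ix_(test_idx, train_idx)] @ alpha)
        return out


def _multikernel_reml(y, V_list):
    n = len(y)
    k = len(V_list)
    X = np.ones((n, 1))
    if k == 1:
        K = KinshipMatrix(["_%d" % i for i in range(n)], V_list[0], "feature",
                          max(float(np.mean(np.diag(V_list[0]))), 1e-12))
        nf = reml_null_fit(y, X, K)
        return np.array([nf.sigma_g2]), nf.sigma_e2, float(nf.beta[0]), nf.loglik

    yty = float(y @ y)

    def crit(theta):
        g = np.exp(np.clip(theta, -30, 30))
        H = np.eye(n)
        for gi, V in zip(g, V_list):
            H += gi * V
        try:
            cH = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_H = 2.0 * np.log(np.diag(cH)).sum()
        Hy = sla.cho_solve((cH, True), y)
        HX = sla.cho_solve((cH, True), X)
        XtHX = (X.T @ HX).item()
        beta = (X.T @ Hy).item() / XtHX
        resid = y - beta
        yPy = float(resid @ sla.cho_solve((cH, True), resid))
        df = n - 1
        return df * np.log(max(yPy, 1e-300) / df) + logdet_H + np.log(XtHX)

    best = None
    for start in (np.zeros(k), np.full(k, -2.0)):
        res = optimize.minimize(crit, start, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300 * k})
        if best is None or res.fun < best.fun:
            best = res
    g = np.exp(np.clip(best.x, -30, 30))
    g[g < 1e-7] = 0.0

    H = np.eye(n)
    for gi, V in zip(g, V_list):
        H += gi * V
    cH = np.linalg.cholesky(H)
    Hy = sla.cho_solve((cH, True), y)
    HX = sla.cho_solve((cH, True), X)
    XtHX = (X.T @ HX).item()
    mu = (X.T @ Hy).item() / XtHX
    resid = y - mu
    yPy = float(resid @ sla.cho_solve((cH, True), resid))
    df = n - 1
    sigma_e2 = max(yPy / df, 1e-12)
    crit_val = df * np.log(yPy / df) + 2.0 * np.log(np.diag(cH)).sum() + np.log(XtHX)
    loglik = -0.5 * (crit_val + df * (1.0 + np.log(2.0 * np.pi)))
    return g * sigma_e2, sigma_e2, mu, loglik


def _multikernel_gibbs(y, V_list, n_iter, burn_in, seed, df0=4.0):
    """Gibbs sampler for the multi-kernel model in each kernel's eigenbasis.

    Scaled-inverse-chi^2 priors on all variances (df0, scale anchored at the
    sample variance split across components); random effects are sampled in
    the eigenbasis of their kernel, where the conditional precision is
    diagonal. Posterior means over the kept iterations are returned.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    k = len(V_list)
    eig = []
    for V in V_list:
        d, Q = np.linalg.eigh(V)
        keep = d > _EIG_TOL * d.max()
        eig.append((d[keep], Q[:, keep]))
    vy = float(np.var(y))
    s0 = vy / (k + 1)
    sigma2 = np.full(k, s0)
    sigma_e2 = s0
    mu = float(y.mean())
    u = [np.zeros(n) for _ in range(k)]
    z = [np.zeros(len(d)) for d, _ in eig]
    keep_s2 = np.zeros((n_iter - burn_in, k))
    keep_se = np.zeros(n_iter - burn_in)
    keep_mu = np.zeros(n_iter - burn_in)
    for it in range(n_iter):
        for j in range(k):
            d, Q = eig[j]
            resid = y - mu - sum(u[l] for l in range(k) if l != j)
            rhs = Q.T @ resid / sigma_e2
            prec = 1.0 / (d * sigma2[j]) + 1.0 / sigma_e2
            mean = rhs / prec
            z[j] = mean + rng.standard_normal(len(d)) / np.sqrt(prec)
            u[j] = Q @ z[j]
            ss = float(z[j] @ (z[j] / d))
            dfj = df0 + len(d)
            sigma2[j] = (df0 * s0 + ss) / rng.chisquare(dfj)
        resid = y - sum(u)
        mu = float(resid.mean() + rng.standard_normal() * np.sqrt(sigma_e2 / n))
        e = resid - mu
        sigma_e2 = (df0 * s0 + float(e @ e)) / rng.chisquare(df0 + n)
        if it >= burn_in:
            keep_s2[it - burn_in] = sigma2
            keep_se[it - burn_in] = sigma_e2
            keep_mu[it - burn_in] = mu
    return keep_s2.mean(axis=0), float(keep_se.mean()), float(keep_mu.mean())


def fit_multikernel(y: np.ndarray, kernels: list[KinshipMatrix] | dict,
                    method: str = "reml", n_iter: int = 5000, burn_in: int = 1000,
                    seed: int = 0) -> MultiKernelFit:
    """Variance components and BLUP machinery for y = 1 mu + sum_i m_i + e
    with m_i ~ N(0, V_i sigma_i^2)."""
    if isinstance(kernels, dict):
        names = list(kernels.keys())
        klist = [kernels[n] for n in names]
    else:
        klist = list(kernels)
        names = [getattr(K, "kind", f"k{i}") + f"_{i}" for i, K in enumerate(klist)]
    if not 1 <= len(klist) <= 4:
        raise ValueError("need between 1 and 4 kernels")
    y = np.asarray(y, dtype=float)
    n = len(y)
    V_list = []
    for K in klist:
        V = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        if V.shape != (n, n):
            raise ValueError("kernel dimensions do not match the trait")
        V_list.append(V)
    if method == "reml":
        sigma2, sigma_e2, mu, loglik = _multikernel_reml(y, V_list)
    elif method == "gibbs":
        sigma2, sigma_e2, mu = _multikernel_gibbs(y, V_list, n_iter, burn_in, seed)
        loglik = float("nan")
    else:
        raise ValueError(f"unknown method {method!r}")
    return MultiKernelFit(
        kernel_names=names, sigma2=np.asarray(sigma2, dtype=float),
        sigma_e2=float(sigma_e2), mu=float(mu), y=y, V_list=V_list,
        loglik=loglik, method=method,
    )
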
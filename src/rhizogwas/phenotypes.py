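"""ASV filtering/normalization, plot-level variance components, broad-sense
heritability, BLUEs and rank-normal transformation.

The field model is

    y_ijk = mu + g_i + r_j + b_jk + e_ijk

with genotype (g), replicate (r), block-within-replicate (b) and residual (e)
effects; all random for variance estimation, genotype fixed for BLUEs.
Broad-sense heritability on a genotype-mean basis is

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / R)

with R the number of replicates. Restricted maximum likelihood is computed by
profiling the residual scale out of the restricted likelihood and optimizing
the variance ratios with Nelder-Mead; the linear algebra runs in the
random-effect dimension (Woodbury identities), so fits scale with the number
of genotypes rather than the number of plots squared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import FeatureMatrix, PlotPhenotype, SchemaError

__all__ = [
    "VarianceComponents",
    "HeritabilityResult",
    "filter_asv_table",
    "normalize_asv_abundance",
    "fit_plot_lmm",
    "estimate_h2",
    "compute_blues",
    "qqnorm_transform",
    "heritability_screen",
]

_VAR_FLOOR = 1e-12


class FitError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_r2: float
    sigma_b2: float
    sigma_e2: float
    mu: float
    n_reps: int
    loglik: float = float("nan")

    def __post_init__(self):
        for name in ("sigma_g2", "sigma_r2", "sigma_b2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be strictly positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class HeritabilityResult:
    feature_id: str
    H2: float
    blues: pd.Series
    environment: str


# ---------------------------------------------------------------------------
# ASV table handling


def filter_asv_table(counts: pd.DataFrame, min_total_reads: int = 10_000,
                     min_prevalence: float = 0.8) -> pd.DataFrame:
    """Keep ASVs with a total read count >= ``min_total_reads`` that are
    detected (count > 0) in at least ``ceil(min_prevalence * n_samples)``
    samples. The sample set is unchanged."""
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError(f"min_prevalence must be in [0, 1], got {min_prevalence}")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("negative counts")
    need = math.ceil(min_prevalence * counts.shape[0])
    total_ok = values.sum(axis=0) >= min_total_reads
    prevalence_ok = (values > 0).sum(axis=0) >= need
    return counts.loc[:, total_ok & prevalence_ok]


def normalize_asv_abundance(counts: pd.DataFrame, pseudocount: float = 1e-6) -> FeatureMatrix:
    """Per-sample relative abundance followed by a log transform,
    log(count / library_size + pseudocount), to damp compositional bias."""
    values = counts.to_numpy(dtype=float)
    rowsum = values.sum(axis=1)
    if (rowsum <= 0).any():
        bad = [str(counts.index[i]) for i in np.flatnonzero(rowsum <= 0)[:5]]
        raise ValueError(f"sample(s) with zero total reads: {bad}")
    rel = values / rowsum[:, None]
    return FeatureMatrix(
        ids=[str(i) for i in counts.index],
        feature_ids=[str(c) for c in counts.columns],
        values=np.log(rel + pseudocount),
        feature_kind="asv_abundance",
    )


# ---------------------------------------------------------------------------
# restricted likelihood in the random-effect dimension


def _incidence(levels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(levels)
    Z = np.zeros((len(codes), codes.max() + 1))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


class _RemlWorkspace:
    """Cross-products for profiled REML of y = X beta + sum_c Z_c u_c + e."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z_list: list[np.ndarray]):
        self.n, self.p = X.shape
        if self.n - self.p < 1:
            raise FitError("no residual degrees of freedom")
        self.sizes = [Z.shape[1] for Z in Z_list]
        Z = np.hstack(Z_list) if Z_list else np.zeros((self.n, 0))
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _expand(self, gammas: np.ndarray) -> np.ndarray:
        return np.repeat(gammas, self.sizes)

    def profile(self, gammas: np.ndarray):
        """Return (-2 * profiled restricted ll up to a constant, beta, sigma_e2)."""
        g = self._expand(np.maximum(gammas, 0.0))
        q = len(g)
        s = np.sqrt(g)
        A = np.eye(q) + (s[:, None] * self.ZtZ) * s[None, :]
        try:
            cA = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet_A = 2.0 * np.log(np.diag(cA)).sum()
        SX = s[:, None] * self.ZtX
        Sy = s * self.Zty
        WX = np.linalg.solve(cA, SX)
        Wy = np.linalg.solve(cA, Sy)
        XtHX = self.XtX - WX.T @ WX
        XtHy = self.Xty - WX.T @ Wy
        yHy = self.yty - Wy @ Wy
        try:
            cB = np.linalg.cholesky(XtHX)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        logdet_B = 2.0 * np.log(np.diag(cB)).sum()
        beta = np.linalg.solve(XtHX, XtHy)
        yPy = max(yHy - XtHy @ beta, _VAR_FLOOR)
        df = self.n - self.p
        crit = df * np.log(yPy / df) + logdet_A + logdet_B
        return crit, beta, yPy / df

    def restricted_loglik(self, gammas: np.ndarray) -> float:
        crit, _, _ = self.profile(gammas)
        df = self.n - self.p
        return -0.5 * (crit + df * (1.0 + np.log(2.0 * np.pi)))


def _reml_optimize(ws: _RemlWorkspace, k: int):
    """Nelder-Mead over log variance ratios, with a boundary-aware multistart."""
    if k == 0:
        crit, beta, s2 = ws.profile(np.zeros(0))
        return np.zeros(0), beta, s2, -0.5 * crit
    best = None
    for start in (np.zeros(k), np.full(k, -3.0)):
        res = optimize.minimize(
            lambda th: ws.profile(np.exp(np.clip(th, -30, 30)))[0],
            start, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200 * k},
        )
        if best is None or res.fun < best.fun:
            best = res
    gammas = np.exp(np.clip(best.x, -30, 30))
    gammas[gammas < 1e-7] = 0.0
    crit, beta, sigma_e2 = ws.profile(gammas)
    df = ws.n - ws.p
    loglik = -0.5 * (crit + df * (1.0 + np.log(2.0 * np.pi)))
    return gammas, beta, sigma_e2, loglik


def _design(sub: pd.DataFrame):
    y = sub["value"].to_numpy(dtype=float)
    Zg = _incidence(sub["genotype"].astype(str))
    Zr = _incidence(sub["replicate"].astype(str))
    block_key = sub["replicate"].astype(str) + "//" + sub["block"].astype(str)
    Zb = _incidence(block_key)
    return y, Zg, Zr, Zb


def fit_plot_lmm(trait: PlotPhenotype | pd.DataFrame, environment: str) -> VarianceComponents:
    """REML variance components of the plot model within one environment."""
    sub = trait.environment(environment) if isinstance(trait, PlotPhenotype) else trait
    if len(sub) < 2:
        raise FitError("need at least two observations")
    if sub["genotype"].nunique() < 2:
        raise FitError("need at least two genotypes")
    y, Zg, Zr, Zb = _design(sub)
    n_reps = Zr.shape[1]
    X = np.ones((len(y), 1))
    if float(np.var(y)) < _VAR_FLOOR:
        return VarianceComponents(0.0, 0.0, 0.0, _VAR_FLOOR, float(y.mean()), n_reps, 0.0)
    ws = _RemlWorkspace(y, X, [Zg, Zr, Zb])
    gammas, beta, sigma_e2, loglik = _reml_optimize(ws, 3)
    return VarianceComponents(
        sigma_g2=float(gammas[0] * sigma_e2),
        sigma_r2=float(gammas[1] * sigma_e2),
        sigma_b2=float(gammas[2] * sigma_e2),
        sigma_e2=float(max(sigma_e2, _VAR_FLOOR)),
        mu=float(beta[0]),
        n_reps=n_reps,
        loglik=loglik,
    )


def estimate_h2(vc: VarianceComponents) -> float:
    """Broad-sense heritability on a genotype-mean basis."""
    if vc.n_reps <= 0:
        raise ValueError("number of replications must be positive")
    denom = vc.sigma_g2 + vc.sigma_e2 / vc.n_reps
    return 0.0 if denom <= 0 else float(vc.sigma_g2 / denom)


def compute_blues(trait: PlotPhenotype | pd.DataFrame, environment: str) -> pd.Series:
    """Per-genotype BLUEs: genotype fixed, replicate and block random,
    generalized least squares under the REML-fitted covariance."""
    sub = trait.environment(environment) if isinstance(trait, PlotPhenotype) else trait
    counts = sub.groupby("genotype").size()
    empty = counts[counts == 0]
    if len(empty):
        warnings.warn(f"genotypes without observations excluded: {list(empty.index)}")
    y, _, Zr, Zb = _design(sub)
    genotypes, codes = np.unique(sub["genotype"].astype(str).to_numpy(), return_inverse=True)
    X = np.zeros((len(y), len(genotypes)))
    X[np.arange(len(y)), codes] = 1.0
    ws = _RemlWorkspace(y, X, [Zr, Zb])
    _, beta, _, _ = _reml_optimize(ws, 2)
    return pd.Series(beta, index=genotypes, name="blue")


def qqnorm_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal scores with the Blom offset
    (r - 3/8)/(n + 1/4); ties get the average score of their rank span."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant vector cannot be rank-normalized")
    n = len(x)
    # average normal score over each tie span, not the score of the average rank
    order_scores = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    ranks = stats.rankdata(x, method="average")
    out = np.empty(n)
    for value in np.unique(x):
        mask = x == value
        r = ranks[mask][0]
        span = np.arange(r - (mask.sum() - 1) / 2, r + (mask.sum() - 1) / 2 + 1).astype(int)
        out[mask] = order_scores[span - 1].mean()
    return out


# ---------------------------------------------------------------------------
# screening driver


def heritability_screen(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    environment: str,
    min_total_reads: int = 10_000,
    min_prevalence: float = 0.8,
    h2_cutoff: float = 0.15,
    pseudocount: float = 1e-6,
) -> tuple[pd.DataFrame, FeatureMatrix]:
    """Filter, normalize and screen ASVs for heritability within one environment.

    ``sample_meta`` maps sample ids (index) to genotype/environment/replicate/
    block columns. Returns the per-ASV (H2, retained) table and the BLUE
    matrix of ASVs passing the H2 cutoff.
    """
    need = {"genotype", "environment", "replicate", "block"}
    if not need.issubset(sample_meta.columns):
        raise SchemaError(f"sample metadata needs columns {sorted(need)}")
    env_samples = sample_meta[sample_meta["environment"] == environment].index
    counts_env = counts.loc[counts.index.intersection(env_samples)]
    filtered = filter_asv_table(counts_env, min_total_reads, min_prevalence)
    if filtered.shape[1] == 0:
        raise ValueError("no ASV passed the abundance/prevalence filter")
    log_abund = normalize_asv_abundance(filtered, pseudocount)
    meta = sample_meta.loc[log_abund.ids]

    rows, blue_cols = [], {}
    for j, asv in enumerate(log_abund.feature_ids):
        plot = pd.DataFrame(
            {
                "genotype": meta["genotype"].to_numpy(),
                "environment": environment,
                "replicate": meta["replicate"].to_numpy(),
                "block": meta["block"].to_numpy(),
                "value": log_abund.values[:, j],
            }
        )
        vc = fit_plot_lmm(plot, environment)
        h2 = estimate_h2(vc)
        keep = h2 > h2_cutoff
        rows.append({"feature_id": asv, "H2": h2, "retained": keep})
        if keep:
            blue_cols[asv] = compute_blues(plot, environment)
    table = pd.DataFrame(rows)
    if not blue_cols:
        raise ValueError("no ASV passed the heritability screen")
    blues = pd.DataFrame(blue_cols)
    fm = FeatureMatrix(
        ids=[str(i) for i in blues.index],
        feature_ids=list(blues.columns),
        values=blues.to_numpy(),
        feature_kind="asv_abundance",
    )
    return table, fm
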
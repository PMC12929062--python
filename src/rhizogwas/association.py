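"""Study-level drivers: marker filters, multiple-testing adjustment and the
GWAS / eGWAS / TWAS wiring around the mixed-model engine.

Conventions: GWAS and eGWAS test SNP minor-allele counts against BLUEs or
rank-normalized expression under a VanRaden kinship; TWAS tests standardized
expression vectors against ASV BLUEs under an expression-derived kinship.
FDR (Benjamini-Hochberg) is applied within each response trait; the eGWAS
Holm correction counts the number of SNPs as the number of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix, GenotypeMatrix
from .kinship_mlm import (
    KinshipMatrix,
    grm_principal_components,
    p3d_wald_scan,
    reml_null_fit,
)

__all__ = [
    "StudySpec",
    "filter_markers",
    "adjust_pvalues",
    "run_association_study",
]

MIN_OVERLAP = 30


@dataclass
class StudySpec:
    mode: str  # gwas | egwas | twas
    adjust: str = "bh_fdr"  # bh_fdr | holm | bonferroni
    alpha: float = 0.05
    kinship_kind: str = ""
    n_pcs: int = 0  # leading GRM PCs as 'Q' covariates

    def __post_init__(self):
        if self.mode not in ("gwas", "egwas", "twas"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.kinship_kind:
            self.kinship_kind = "feature" if self.mode == "twas" else "vanraden"
        expected = "feature" if self.mode == "twas" else "vanraden"
        if self.kinship_kind != expected:
            raise ValueError(
                f"mode {self.mode!r} requires kinship kind {expected!r}, "
                f"got {self.kinship_kind!r}"
            )
        if self.adjust not in ("bh_fdr", "holm", "bonferroni"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")


def filter_markers(G: GenotypeMatrix, maf_min: float = 0.05,
                   het_max: float = 0.95) -> GenotypeMatrix:
    """Keep markers with MAF >= maf_min and heterozygosity rate <= het_max."""
    codes = G.codes
    freq = codes.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    het = np.isclose(codes, 1.0).mean(axis=0)
    keep = (maf >= maf_min) & (het <= het_max)
    if not keep.any():
        raise ValueError("no marker passed the MAF/heterozygosity filter")
    return G.subset_markers(keep)


def adjust_pvalues(p: np.ndarray, method: str = "bh_fdr", alpha: float = 0.05):
    """Adjusted p-values plus, for holm/bonferroni, the first-step raw
    threshold alpha/m.

    BH is the step-up procedure (cumulative minimum of m/i * p_(i) from the
    largest p down); Holm is the step-down procedure (cumulative maximum of
    (m - i + 1) * p_(i) from the smallest p up); both capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    if method == "bh_fdr":
        adj_sorted = np.minimum.accumulate((ps * m / np.arange(1, m + 1))[::-1])[::-1]
    elif method == "holm":
        adj_sorted = np.maximum.accumulate(ps * (m - np.arange(m)))
    elif method == "bonferroni":
        adj_sorted = ps * m
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    p_adj = np.empty(m)
    p_adj[order] = np.minimum(adj_sorted, 1.0)
    threshold = alpha / m if method in ("holm", "bonferroni") else None
    return p_adj, threshold


def _standardize_columns(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (values - values.mean(axis=0)) / sd


def run_association_study(
    spec: StudySpec,
    responses: FeatureMatrix | pd.DataFrame,
    explanatory: GenotypeMatrix | FeatureMatrix,
    kinship: KinshipMatrix,
) -> dict[str, pd.DataFrame]:
    """Per response trait: null REML fit, P3D Wald scan over all explanatory
    features, multiple-testing adjustment. Returns {response_id: table}."""
    if isinstance(responses, FeatureMatrix):
        resp = responses.to_frame()
    else:
        resp = responses
    resp_ids = [str(i) for i in resp.index]

    if isinstance(explanatory, GenotypeMatrix):
        expl_ids = explanatory.sample_ids
        expl_values = explanatory.codes
        expl_names = explanatory.marker_ids
    else:
        expl_ids = explanatory.ids
        expl_values = _standardize_columns(explanatory.values)
        expl_names = explanatory.feature_ids

    common = [g for g in resp_ids if g in set(expl_ids)]
    common = [g for g in common if g in set(kinship.genotype_ids)]
    if len(common) < MIN_OVERLAP:
        raise ValueError(
            f"only {len(common)} overlapping genotypes; need >= {MIN_OVERLAP}"
        )
    resp = resp.loc[common]
    row_of = {g: i for i, g in enumerate(expl_ids)}
    M = expl_values[[row_of[g] for g in common], :]
    Kal = kinship.align(common)

    X = np.ones((len(common), 1))
    if spec.n_pcs:
        X = np.hstack([X, grm_principal_components(Kal, spec.n_pcs)])

    d, U = np.linalg.eigh(Kal.K)
    d = np.maximum(d, 0.0)
    Mstar = U.T @ M

    results = {}
    for trait in resp.columns:
        y = resp[trait].to_numpy(dtype=float)
        nullfit = reml_null_fit(y, X, Kal, genotype_ids=common, eig=(d, U))
        table = p3d_wald_scan(nullfit, M, feature_ids=list(expl_names),
                              rotated_features=Mstar)
        p_adj, threshold = adjust_pvalues(table["p"].to_numpy(), spec.adjust, spec.alpha)
        table = table.assign(
            p_adj=p_adj,
            significant=p_adj < spec.alpha,
            response=str(trait),
        )
        if threshold is not None:
            table.attrs["raw_threshold"] = threshold
        results[str(trait)] = table
    return results


def significant_hits(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long table of all significant response-feature associations."""
    frames = [t[t["significant"]] for t in results.values()]
    if not any(len(f) for f in frames):
        return pd.DataFrame(
            columns=["feature_id", "effect", "se", "wald", "p", "constant",
                     "p_adj", "significant", "response"]
        )
    return pd.concat(frames, ignore_index=True)
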
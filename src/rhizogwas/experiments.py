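"""Self-contained calibration experiments exercising the pipeline end to end.

Each function simulates its own inputs from a seed, runs the relevant part
of the pipeline and returns summary numbers. They back the acceptance
checks and the numbered analysis drivers; problem sizes are chosen so the
whole battery runs on a desktop in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import association as assoc
from . import kinship_mlm as km
from . import ld_qtl
from . import network_stats as ns
from . import phenotypes as ph
from . import prediction as pr
from . import synthetic_data as sd
from .io_formats import FeatureMatrix

__all__ = [
    "holm_thresholds",
    "scenario_counts",
    "h2_recovery",
    "mlm_calibration",
    "wald_ols_max_rel_diff",
    "adjustment_oracle_max_diff",
    "crafted_qtl_partition",
    "eqtl_truth_table_agreement",
    "hotspot_power",
    "hotspot_null_clean_rate",
    "prediction_accuracy",
    "mantel_identity",
    "mantel_null_uniformity",
]


def holm_thresholds(alpha: float = 0.05) -> tuple[float, float]:
    """First-step Holm thresholds alpha/m for the two eGWAS marker panels
    (239,172 and 292,839 SNPs)."""
    out = []
    for m in (239_172, 292_839):
        _, thr = assoc.adjust_pvalues(np.full(m, 0.5), "holm", alpha)
        out.append(thr)
    return out[0], out[1]


def scenario_counts() -> tuple[int, int]:
    """Number of prediction scenarios from 4 and from 3 omics layers."""
    four = len(pr.enumerate_scenarios(["WGS", "RNA", "Gene", "ASV"]))
    three = len(pr.enumerate_scenarios(["WGS", "RNA", "Gene"]))
    return four, three


# ---------------------------------------------------------------------------


def h2_recovery(seed: int, n_asvs: int = 50, n_genotypes: int = 200,
                true_h2: float = 0.3) -> float:
    """Mean estimated H2 over ASVs simulated at one true heritability,
    through the full count -> normalize -> plot-LMM pipeline."""
    cfg = sd.SimulationConfig(
        n_genotypes=n_genotypes, n_markers=400, n_asvs=n_asvs,
        frac_heritable_asvs=1.0, h2_range=(true_h2, true_h2),
    )
    G = sd.simulate_genotypes(cfg, seed=seed)
    counts, meta, _ = sd.simulate_asv_counts(G, cfg, seed=seed + 1)
    log_abund = ph.normalize_asv_abundance(ph.filter_asv_table(counts, 0, 0.0))
    meta = meta.loc[log_abund.ids]
    h2s = []
    for j in range(len(log_abund.feature_ids)):
        plot = pd.DataFrame({
            "genotype": meta["genotype"].to_numpy(), "environment": "E1",
            "replicate": meta["replicate"].to_numpy(),
            "block": meta["block"].to_numpy(),
            "value": log_abund.values[:, j],
        })
        h2s.append(ph.estimate_h2(ph.fit_plot_lmm(plot, "E1")))
    return float(np.mean(h2s))


def mlm_calibration(seed: int, n_markers: int = 10_000,
                    n_genotypes: int = 175) -> tuple[float, float]:
    """Empirical type-I error at alpha = 0.05 and genomic inflation lambda_GC
    for a P3D scan of null markers against a GRM-structured trait."""
    cfg = sd.panmictic_config(n_genotypes=n_genotypes, n_markers=n_markers)
    G = sd.simulate_genotypes(cfg, seed=seed)
    K = km.vanraden_grm(G)
    d, Q = np.linalg.eigh(K.K)
    rng = np.random.default_rng(seed + 1)
    g = Q @ (np.sqrt(np.maximum(d, 0.0)) * rng.standard_normal(K.n))
    y = g + rng.normal(0.0, g.std(), K.n)
    nf = km.reml_null_fit(y, np.ones((K.n, 1)), K)
    scan = km.p3d_wald_scan(nf, G.codes)
    rate = float((scan["p"] < 0.05).mean())
    lam_gc = float(np.median(scan["wald"]) / stats.chi2.ppf(0.5, 1))
    return rate, lam_gc


def wald_ols_max_rel_diff(seed: int, n: int = 200, n_markers: int = 200) -> float:
    """Max relative difference between the P3D Wald statistic under K = I and
    the squared OLS t statistic, computed marker by marker from the normal
    equations."""
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n)
    M = rng.normal(size=(n, n_markers))
    K = km.KinshipMatrix([f"s{i}" for i in range(n)], np.eye(n), "vanraden", 1.0)
    nf = km.reml_null_fit(y, np.ones((n, 1)), K)
    scan = km.p3d_wald_scan(nf, M)
    worst = 0.0
    for j in range(n_markers):
        X = np.column_stack([np.ones(n), M[:, j]])
        XtX_inv = np.linalg.inv(X.T @ X)
        b = XtX_inv @ (X.T @ y)
        resid = y - X @ b
        s2 = float(resid @ resid) / (n - 2)
        t2 = b[1] ** 2 / (s2 * XtX_inv[1, 1])
        worst = max(worst, abs(scan["wald"].iloc[j] - t2) / t2)
    return float(worst)


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def _holm_oracle(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank in range(1, m + 1):
        i = order[rank - 1]
        running = max(running, p[i] * (m - rank + 1))
        adj[i] = min(running, 1.0)
    return adj


def adjustment_oracle_max_diff(seed: int, n_vectors: int = 1000) -> float:
    """Max absolute deviation of adjust_pvalues from the textbook step-up /
    step-down oracles over random p-value vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(1e-12, 1.0, size=rng.integers(1, 60))
        bh, _ = assoc.adjust_pvalues(p, "bh_fdr")
        holm, thr = assoc.adjust_pvalues(p, "holm")
        worst = max(worst,
                    float(np.abs(bh - _bh_oracle(p)).max()),
                    float(np.abs(holm - _holm_oracle(p)).max()),
                    abs(thr - 0.05 / len(p)))
    return worst


# ---------------------------------------------------------------------------
# crafted QTL machinery instances

# 12 significant SNPs with LD intervals; hand-enumerated expected partition.
CRAFTED_SNPS = [
    # (snp, chrom, peak, start, end, p)
    ("s01", "A01", 100_000, 90_000, 110_000, 1e-8),
    ("s02", "A01", 130_000, 120_000, 140_000, 1e-6),   # peaks 30 kb from s01
    ("s03", "A01", 200_000, 150_000, 210_000, 1e-7),
    ("s04", "A01", 255_000, 205_000, 260_000, 1e-9),   # interval overlaps s03
    ("s05", "A01", 400_000, 395_000, 405_000, 1e-5),
    ("s06", "A01", 449_000, 448_000, 450_000, 1e-6),   # peaks 49 kb from s05
    ("s07", "A01", 600_000, 550_000, 650_000, 1e-10),
    ("s08", "A01", 700_000, 690_000, 710_000, 1e-12),  # linked to s07 via s09
    ("s09", "A01", 655_000, 640_000, 660_000, 1e-4),   # overlaps s07, 45 kb to s08
    ("s10", "A01", 900_000, 880_000, 920_000, 1e-6),
    ("s11", "C01", 100_000, 90_000, 110_000, 1e-6),
    ("s12", "C01", 130_000, 125_000, 135_000, 1e-6),   # tie p: lead = smaller pos
]

CRAFTED_EXPECTED = [
    ("A01", 90_000, 140_000, "s01", frozenset({"s01", "s02"})),
    ("A01", 150_000, 260_000, "s04", frozenset({"s03", "s04"})),
    ("A01", 395_000, 450_000, "s06", frozenset({"s05", "s06"})),
    ("A01", 550_000, 710_000, "s08", frozenset({"s07", "s08", "s09"})),
    ("A01", 880_000, 920_000, "s10", frozenset({"s10"})),
    ("C01", 90_000, 135_000, "s11", frozenset({"s11", "s12"})),
]


def crafted_qtl_partition() -> tuple[int, int]:
    """(number of merged QTL regions matching the hand enumeration, expected
    number) for the crafted 12-SNP instance."""
    merged = ld_qtl.merge_qtl_intervals(CRAFTED_SNPS, merge_dist=50_000)
    got = {
        (q.chromosome, q.start, q.end, q.lead_snp, frozenset(q.member_snps))
        for q in merged
    }
    expected = set(CRAFTED_EXPECTED)
    return len(got & expected), len(expected)


# 8 crafted eQTL/gene configurations with hand-enumerated classes.
EQTL_TRUTH_TABLE = [
    # (eqtl (chrom, start, end), gene (chrom, start, end), expected)
    (("A01", 100, 200), ("C01", 100, 200), "distant"),       # different chromosome
    (("A01", 100, 500), ("A01", 300, 400), "local"),         # eQTL spans gene
    (("A01", 300, 400), ("A01", 100, 600), "local"),         # nested in gene
    (("A01", 100, 200), ("A01", 30_000, 31_000), "local"),   # 29.8 kb gap upstream
    (("A01", 100_000, 120_000), ("A01", 50_000, 50_001), "local"),   # 49,999 bp gap
    (("A01", 100_000, 120_000), ("A01", 49_000, 49_999), "distant"), # 50,001 bp gap
    (("A01", 100_000, 120_000), ("A01", 170_000, 171_000), "local"), # 50 kb exactly
    (("A01", 100, 200), ("A01", 800_000, 800_500), "distant"),       # far, same chrom
]


def eqtl_truth_table_agreement() -> tuple[int, int]:
    hits = sum(
        ld_qtl.classify_eqtl(eqtl, gene, 50_000) == expected
        for eqtl, gene, expected in EQTL_TRUTH_TABLE
    )
    return hits, len(EQTL_TRUTH_TABLE)


# ---------------------------------------------------------------------------
# hotspot scan


def _hotspot_one_run(seed: int, hub_effect: float, cfg: sd.SimulationConfig):
    chrom_lengths = dict(cfg.chromosomes)
    G = sd.simulate_genotypes(cfg, seed=seed)
    expr, truth = sd.simulate_expression(G, cfg, seed=seed + 10_000)
    K = km.vanraden_grm(G)
    vals = np.column_stack([
        ph.qqnorm_transform(expr.values[:, j]) for j in range(expr.values.shape[1])
    ])
    expr_qq = FeatureMatrix(expr.ids, expr.feature_ids, vals, "expression",
                            expr.coordinates)
    res = assoc.run_association_study(
        assoc.StudySpec(mode="egwas", adjust="holm"), expr_qq.to_frame(), G, K
    )
    scans = {g: t[t["significant"]][["feature_id", "p"]] for g, t in res.items()}
    rec = ld_qtl.eqtl_records_from_scans(G, scans, expr.coordinates)
    events = ld_qtl.distant_event_positions(rec)
    hotspots = ld_qtl.detect_hotspots(events, chrom_lengths)
    hub_hit = any(
        h.chromosome == truth.attrs["hub_chrom"]
        and h.start <= truth.attrs["hub_pos"] <= h.end
        for h in hotspots
    )
    return hub_hit, len(hotspots)


def hotspot_power(seed: int, runs: int = 25) -> float:
    """Fraction of seeded full-pipeline runs in which the planted 50-target
    trans hub is flagged as a hotspot.

    Runs on the panmictic panel: a hub locus must segregate within the
    population for its trans effects to survive the kinship correction, and
    under strong ancestral-group structure a randomly placed hub is often
    fully confounded with the background the mixed model removes.
    """
    cfg = sd.panmictic_config(n_genotypes=175, n_markers=1200, n_genes=250,
                              hub_n_targets=50, hub_effect=1.0)
    hits = [
        _hotspot_one_run(seed + 37 * r, hub_effect=1.0, cfg=cfg)[0]
        for r in range(runs)
    ]
    return float(np.mean(hits))


def hotspot_null_clean_rate(seed: int, runs: int = 100, n_events: int = 200,
                            chrom_len: int = 10_000_000) -> float:
    """Fraction of uniform-event simulations with no significant hotspot."""
    rng = np.random.default_rng(seed)
    clean = 0
    for _ in range(runs):
        pos = rng.integers(1, chrom_len + 1, size=n_events).astype(float)
        hs = ld_qtl.detect_hotspots({"A01": pos}, {"A01": chrom_len},
                                    window=100_000, significance=0.01)
        clean += len(hs) == 0
    return clean / runs


# ---------------------------------------------------------------------------
# prediction


def prediction_accuracy(seed: int, repeats: int = 20,
                        h2: float = 0.5) -> tuple[float, float]:
    """(mean CV accuracy for a trait generated from the WGS kernel, shift in
    accuracy when an independent noise kernel is added to the scenario)."""
    cfg = sd.SimulationConfig(n_markers=2000)
    G = sd.simulate_genotypes(cfg, seed=seed)
    K = km.vanraden_grm(G)
    rng = np.random.default_rng(seed + 1)
    d, Q = np.linalg.eigh(K.K)
    u = Q @ (np.sqrt(np.maximum(d, 0.0)) * rng.standard_normal(K.n))
    u = u / u.std()
    y = u * np.sqrt(h2 / (1 - h2)) + rng.standard_normal(K.n)
    noise_feats = pd.DataFrame(rng.normal(size=(K.n, 300)),
                               index=[f"G{i:03d}" for i in range(K.n)])
    K_noise = km.feature_kinship(noise_feats)
    kernels = {"WGS": K, "Noise": K_noise}
    res_wgs = pr.kernel_cv_predict(y, pr.PredictionScenario(("WGS",)), kernels,
                                   folds=5, repeats=repeats, seed=seed)
    res_both = pr.kernel_cv_predict(y, pr.PredictionScenario(("Noise", "WGS")),
                                    kernels, folds=5, repeats=repeats, seed=seed)
    return res_wgs.mean_r, res_both.mean_r - res_wgs.mean_r


# ---------------------------------------------------------------------------
# Mantel


def mantel_identity(permutations: int = 1999) -> tuple[float, float]:
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 4))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return ns.mantel_test(D, D, permutations=permutations, seed=1)


def mantel_null_uniformity(seed: int, n_sims: int = 500, n: int = 8,
                           permutations: int = 199) -> float:
    """KS p-value for uniformity of Mantel p under independent matrices."""
    rng = np.random.default_rng(seed)
    ps = []
    for s in range(n_sims):
        X1 = rng.normal(size=(n, 3))
        X2 = rng.normal(size=(n, 3))
        D1 = np.sqrt(((X1[:, None] - X1[None, :]) ** 2).sum(-1))
        D2 = np.sqrt(((X2[:, None] - X2[None, :]) ** 2).sum(-1))
        ps.append(ns.mantel_test(D1, D2, permutations=permutations, seed=seed + s)[1])
    ps = np.asarray(ps)
    # discrete support (k/(B+1)); compare against the matching discrete uniform
    grid = np.arange(1, permutations + 2) / (permutations + 1)
    ks = stats.ks_2samp(ps, grid)
    return float(ks.pvalue)
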
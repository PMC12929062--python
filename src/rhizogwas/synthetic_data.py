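"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a replicated field study of a diversity panel:

* genotypes follow a founder-mosaic model. Each accession belongs to an
  ancestral group anchored on one founder; along each chromosome the founder
  lineage of a haplotype switches at LD-block boundaries, returning to the
  accession's primary founder with probability ``founder_fidelity`` and to a
  uniformly random founder otherwise. High fidelity produces the strong
  group-level kinship typical of ecotype-structured crop panels; fidelity
  equal to 1/n_founders gives an effectively panmictic mosaic whose LD decays
  at the block scale.
* plot phenotypes follow y_ijk = mu + g_i + r_j + b_jk + e_ijk with
  independent normal replicate, block-within-replicate and residual draws.
* ASV counts arise from latent log-abundances (baseline + genotype effects +
  plot noise) pushed through a per-sample multinomial with log-normal library
  sizes, so the observed table carries real compositional coupling.
* expression has optional cis effects from each gene's nearest SNP and a
  shared trans effect from a hub SNP for a configurable set of target genes.
* ionome traits are sums of kernel-driven genetic values u_i ~ N(0, V_i)
  plus residual noise, with realized variance fractions recorded.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix, GenotypeMatrix, PlotPhenotype

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_field_trial",
    "simulate_asv_counts",
    "simulate_expression",
    "simulate_ionome",
    "panmictic_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Paper-shaped defaults: 175 accessions, 3 replicates x 3 blocks per
    environment, 5 chromosomes of 10 Mb, LD-blocked SNPs, heritable ASVs and
    a trans-regulated transcriptome."""

    n_genotypes: int = 175
    n_markers: int = 5000
    n_founders: int = 6
    founder_fidelity: float = 0.95
    founder_freq_low: float = 0.2
    founder_freq_high: float = 0.8
    maf_min: float = 0.05
    ld_block_len: int = 25_000
    chromosomes: tuple = (("A01", 10_000_000), ("A02", 10_000_000),
                          ("A03", 10_000_000), ("C01", 10_000_000),
                          ("C02", 10_000_000))
    # field design
    n_reps: int = 3
    n_blocks: int = 3
    sigma_rep2: float = 0.05
    sigma_block2: float = 0.05
    # microbiome
    n_asvs: int = 300
    frac_heritable_asvs: float = 0.5
    h2_range: tuple = (0.15, 0.6)
    n_causal_per_asv: int = 2
    library_size_mean: float = 30_000.0
    library_size_sd_log: float = 0.3
    # expression
    n_genes: int = 1000
    cis_fraction: float = 0.3
    cis_effect: float = 1.0
    hub_n_targets: int = 50
    hub_effect: float = 1.0
    # ionome
    n_traits: int = 12
    trait_residual_var: float = 1.0

    def __post_init__(self):
        if self.n_genotypes < 2 or self.n_markers < 1 or self.n_founders < 2:
            raise ValueError("counts must be positive (>= 2 genotypes/founders)")
        if not 0.0 < self.founder_fidelity <= 1.0:
            raise ValueError("founder_fidelity must lie in (0, 1]")
        for _, length in self.chromosomes:
            if self.ld_block_len > length:
                raise ValueError("LD block longer than chromosome")
        if self.n_reps < 1 or self.n_blocks < 1:
            raise ValueError("need at least one replicate and block")
        lo, hi = self.h2_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("target H2 range must lie in [0, 1)")


def panmictic_config(**overrides) -> SimulationConfig:
    """Config variant without ancestral-group structure: lineages redraw
    uniformly at every block, so LD is confined to blocks and kinship is
    close to exchangeable."""
    cfg = SimulationConfig(**overrides)
    return replace(cfg, founder_fidelity=1.0 / cfg.n_founders)


# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimulationConfig, seed: int = 0) -> GenotypeMatrix:
    """Founder-mosaic diploid genotypes; markers with panel MAF below
    ``cfg.maf_min`` are discarded and topped up so the output passes the
    GWAS MAF filter by construction."""
    rng = np.random.default_rng(seed)
    n, F = cfg.n_genotypes, cfg.n_founders
    primary = rng.integers(0, F, size=n)

    total_len = sum(length for _, length in cfg.chromosomes)
    # draw ~30% extra markers so the MAF trim still leaves n_markers
    n_draw = int(np.ceil(cfg.n_markers * 1.3))
    per_chrom = np.maximum(
        rng.multinomial(n_draw, [length / total_len for _, length in cfg.chromosomes]), 1
    )

    cols, gmap = [], []
    for (chrom, length), m in zip(cfg.chromosomes, per_chrom):
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=m, replace=False))
        block_id = (pos - 1) // cfg.ld_block_len
        blocks = np.unique(block_id)
        # per block: founder lineage per haplotype per accession
        lineage = {}
        for b in blocks:
            stay = rng.random((n, 2)) < cfg.founder_fidelity
            rand = rng.integers(0, F, size=(n, 2))
            lin = np.where(stay, primary[:, None], rand)
            lineage[b] = lin
        freq = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=m)
        for j in range(m):
            hap = (rng.random(F) < freq[j]).astype(float)  # founder alleles
            lin = lineage[block_id[j]]
            code = hap[lin[:, 0]] + hap[lin[:, 1]]
            cols.append(code)
            gmap.append((f"{chrom}:{pos[j]}", chrom, int(pos[j])))

    codes = np.column_stack(cols)
    freq_panel = codes.mean(axis=0) / 2.0
    maf = np.minimum(freq_panel, 1 - freq_panel)
    keep = np.flatnonzero(maf >= cfg.maf_min)
    if len(keep) < cfg.n_markers:
        raise RuntimeError(
            f"only {len(keep)} markers pass MAF >= {cfg.maf_min}; "
            "increase founder_freq range or redraw"
        )
    keep = keep[:cfg.n_markers]
    codes = codes[:, keep]
    gmap = [gmap[i] for i in keep]
    sample_ids = [f"G{i:03d}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=[g[0] for g in gmap],
        codes=codes,
        map=pd.DataFrame(gmap, columns=["marker", "chrom", "pos"]),
    )


def simulate_field_trial(
    genetic_values: pd.Series,
    cfg: SimulationConfig,
    sigma_e2: float,
    environment: str = "E1",
    seed: int = 0,
    mu: float = 0.0,
) -> PlotPhenotype:
    """Replicated plot observations y_ijk = mu + g_i + r_j + b_jk + e_ijk."""
    rng = np.random.default_rng(seed)
    genos = list(genetic_values.index)
    rep_eff = rng.normal(0, np.sqrt(cfg.sigma_rep2), size=cfg.n_reps)
    block_eff = rng.normal(0, np.sqrt(cfg.sigma_block2), size=(cfg.n_reps, cfg.n_blocks))
    rows = []
    for j in range(cfg.n_reps):
        block_of = rng.integers(0, cfg.n_blocks, size=len(genos))
        noise = rng.normal(0, np.sqrt(sigma_e2), size=len(genos))
        for i, g in enumerate(genos):
            k = block_of[i]
            rows.append(
                (g, environment, f"rep{j + 1}", f"block{k + 1}",
                 mu + genetic_values.iloc[i] + rep_eff[j] + block_eff[j, k] + noise[i])
            )
    return PlotPhenotype(records=pd.DataFrame(
        rows, columns=["genotype", "environment", "replicate", "block", "value"]
    ))


def simulate_asv_counts(
    G: GenotypeMatrix,
    cfg: SimulationConfig,
    seed: int = 0,
    environment: str = "E1",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sample x ASV count table plus sample metadata and per-ASV truth.

    Heritable ASVs get ``n_causal_per_asv`` causal SNPs whose scaled score
    gives the genotype value. The per-ASV target H2 refers to the trait the
    pipeline analyzes (log relative abundance on a genotype-mean basis):
    closing the composition shifts every ASV by the sample's log-sum-exp
    term, which behaves as extra plot-level residual variance, so the
    genetic scale is calibrated against sigma_e^2 + var(log-sum-exp) in a
    single correction pass. Counts are multinomial within each sample with
    log-normal library sizes, so zero-heritability ASVs still covary with
    heritable ones compositionally.
    """
    rng = np.random.default_rng(seed)
    n, n_asv = G.n_samples, cfg.n_asvs
    n_her = int(round(cfg.frac_heritable_asvs * n_asv))
    targets = np.zeros(n_asv)
    targets[:n_her] = rng.uniform(*cfg.h2_range, size=n_her)
    if np.any((targets < 0) | (targets >= 1)):
        raise ValueError("target H2 outside [0, 1)")

    sigma_e2 = 1.0
    baseline = rng.normal(0.0, 1.0, size=n_asv)  # uneven composition
    truth_rows = []
    gdir = np.zeros((n, n_asv))  # unit-variance genetic scores
    for a in range(n_asv):
        h2 = targets[a]
        causal = rng.choice(G.n_markers, size=cfg.n_causal_per_asv, replace=False)
        if h2 > 0:
            score = G.codes[:, causal] @ rng.normal(1.0, 0.25, size=len(causal))
            sd = score.std()
            if sd > 0:
                gdir[:, a] = (score - score.mean()) / sd
        truth_rows.append({
            "asv": f"ASV{a:04d}", "target_h2": h2,
            "causal_markers": ";".join(G.marker_ids[c] for c in causal) if h2 > 0 else "",
        })

    def genetic_scale(resid_var):
        with np.errstate(divide="ignore"):
            s2 = targets / (1.0 - targets) * resid_var / cfg.n_reps
        return np.sqrt(s2)

    samples, meta_rows, noise_rows = [], [], []
    for j in range(cfg.n_reps):
        block_of = rng.integers(0, cfg.n_blocks, size=n)
        for i, g in enumerate(G.sample_ids):
            sid = f"{g}_{environment}_r{j + 1}"
            samples.append(sid)
            meta_rows.append((sid, g, environment, f"rep{j + 1}", f"block{block_of[i] + 1}"))
            noise_rows.append(rng.normal(0, np.sqrt(sigma_e2), n_asv))

    noise = np.asarray(noise_rows)
    geno_row = np.tile(np.arange(n), cfg.n_reps)

    # pass 1 at latent scale, then recalibrate against the realized
    # compositional variance (log-sum-exp term shared within each sample)
    latent = baseline + gdir[geno_row] * genetic_scale(sigma_e2) + noise
    lse = np.log(np.exp(latent - latent.max(axis=1, keepdims=True))
                 .sum(axis=1)) + latent.max(axis=1)
    latent = baseline + gdir[geno_row] * genetic_scale(sigma_e2 + lse.var()) + noise
    probs = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    lib = np.exp(rng.normal(np.log(cfg.library_size_mean), cfg.library_size_sd_log,
                            size=len(samples))).astype(int)
    counts = np.vstack([rng.multinomial(lib[s], probs[s]) for s in range(len(samples))])
    count_df = pd.DataFrame(counts, index=samples,
                            columns=[f"ASV{a:04d}" for a in range(n_asv)])
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "genotype", "environment", "replicate", "block"]
    ).set_index("sample")
    return count_df, meta, pd.DataFrame(truth_rows)


def simulate_expression(
    G: GenotypeMatrix,
    cfg: SimulationConfig,
    seed: int = 0,
    hub_marker: str | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Genotype x gene expression with cis effects and one trans hub.

    Genes are placed next to randomly chosen SNPs; a ``cis_fraction`` of them
    loads on that nearest SNP, and ``hub_n_targets`` genes (drawn from
    non-hub chromosomes where possible) share a trans effect from the hub
    SNP. Returns the expression matrix and the truth table (gene, cis SNP,
    hub membership).
    """
    rng = np.random.default_rng(seed)
    if cfg.hub_n_targets > cfg.n_genes:
        raise ValueError("more hub targets than genes")
    n_genes = cfg.n_genes
    anchors = rng.choice(G.n_markers, size=n_genes, replace=n_genes > G.n_markers)
    if hub_marker is None:
        hub_idx = int(rng.integers(0, G.n_markers))
    else:
        hub_idx = G.marker_ids.index(hub_marker)
    hub_chrom = G.map.iloc[hub_idx]["chrom"]
    hub_code = G.codes[:, hub_idx]
    hub_std = ((hub_code - hub_code.mean()) / hub_code.std()) if hub_code.std() else hub_code

    anchor_chroms = G.map.iloc[anchors]["chrom"].to_numpy()
    off_hub = np.flatnonzero(anchor_chroms != hub_chrom)
    pool = off_hub if len(off_hub) >= cfg.hub_n_targets else np.arange(n_genes)
    hub_targets = set(rng.choice(pool, size=cfg.hub_n_targets, replace=False).tolist())
    cis_genes = set(np.flatnonzero(rng.random(n_genes) < cfg.cis_fraction).tolist())

    values = rng.normal(0, 1.0, size=(G.n_samples, n_genes))
    coord_rows, truth_rows = [], []
    for g in range(n_genes):
        a = anchors[g]
        chrom = G.map.iloc[a]["chrom"]
        pos = int(G.map.iloc[a]["pos"])
        start = max(pos + 500, 1)
        coord_rows.append((f"gene{g:04d}", chrom, start, start + 2000))
        is_cis = g in cis_genes
        is_hub = g in hub_targets
        if is_cis:
            code = G.codes[:, a]
            if code.std() > 0:
                values[:, g] += cfg.cis_effect * (code - code.mean()) / code.std()
        if is_hub and cfg.hub_effect != 0:
            values[:, g] += cfg.hub_effect * hub_std
        truth_rows.append({
            "gene": f"gene{g:04d}", "anchor_marker": G.marker_ids[a],
            "cis": is_cis, "hub_target": is_hub,
        })
    coords = pd.DataFrame(coord_rows, columns=["feature", "chrom", "start", "end"])
    fm = FeatureMatrix(
        ids=list(G.sample_ids),
        feature_ids=[f"gene{g:04d}" for g in range(n_genes)],
        values=values,
        feature_kind="expression",
        coordinates=coords,
    )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["hub_marker"] = G.marker_ids[hub_idx]
    truth.attrs["hub_chrom"] = str(hub_chrom)
    truth.attrs["hub_pos"] = int(G.map.iloc[hub_idx]["pos"])
    return fm, truth


def simulate_ionome(
    kernels: dict[str, np.ndarray],
    weights: dict[str, float],
    cfg: SimulationConfig,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Traits as sums of kernel-driven genetic values plus noise.

    ``weights`` maps kernel name -> variance of its component u ~ N(0, V).
    Returns (trait table with cfg.n_traits iid realizations, realized
    variance-fraction truth table).
    """
    for name, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight variance for kernel {name!r}")
    rng = np.random.default_rng(seed)
    names = list(kernels.keys())
    mats = [np.asarray(kernels[k], dtype=float) for k in names]
    n = mats[0].shape[0]
    roots = []
    for V in mats:
        d, Q = np.linalg.eigh(V)
        roots.append(Q * np.sqrt(np.maximum(d, 0.0)))
    traits, truth_rows = {}, []
    for t in range(cfg.n_traits):
        y = np.zeros(n)
        parts = {}
        for name, R in zip(names, roots):
            w = weights.get(name, 0.0)
            u = R @ rng.standard_normal(n) * np.sqrt(w) if w > 0 else np.zeros(n)
            parts[name] = u
            y = y + u
        e = rng.normal(0, np.sqrt(cfg.trait_residual_var), size=n)
        y = y + e
        traits[f"trait{t:02d}"] = y
        tot = np.var(y)
        truth_rows.append({
            "trait": f"trait{t:02d}",
            **{f"frac_{k}": float(np.var(parts[k]) / tot) for k in names},
            "frac_resid": float(np.var(e) / tot),
        })
    trait_df = pd.DataFrame(traits, index=[f"G{i:03d}" for i in range(n)])
    return trait_df, pd.DataFrame(truth_rows)
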
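"""Linkage disequilibrium, LD-boundary QTL intervals, local/distant eQTL
classification and distant-eQTL hotspot detection.

LD is the squared Pearson correlation of genotype codes (composite LD). A
significant SNP's QTL interval runs outward to the last marker before LD
with the focal SNP first drops below 0.1 (one pass, no re-entry); intervals
that overlap, or whose peak SNPs are less than 50 kb apart, are merged by
single linkage into independent QTL regions represented by their most
significant ("lead") SNP. An eQTL is local when it lies on the eGene's
chromosome within 50 kb of the gene interval (inclusive), distant otherwise.
Hotspots are sliding windows (width m, step m/2) whose distant-eQTL event
count exceeds a genome-wide uniform Poisson background after BH control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

__all__ = [
    "QTLInterval",
    "EqtlRecord",
    "HotspotRegion",
    "pairwise_ld_r2",
    "ld_decay_profile",
    "ld_boundaries",
    "merge_qtl_intervals",
    "classify_eqtl",
    "detect_hotspots",
    "build_qtl_regions",
]


@dataclass
class QTLInterval:
    chromosome: str
    start: int
    end: int
    lead_snp: str
    lead_p: float
    member_snps: list

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("interval start > end")
        if not self.member_snps:
            raise ValueError("QTL interval needs at least one member SNP")


@dataclass
class EqtlRecord:
    esnp: str
    esnp_pos: int
    esnp_chrom: str
    egene: str
    gene_chrom: str
    gene_start: int
    gene_end: int
    eqtl_start: int
    eqtl_end: int
    p: float
    klass: str = ""


@dataclass
class HotspotRegion:
    chromosome: str
    start: int
    end: int
    event_count: int
    p: float
    p_adj: float
    significant: bool


def pairwise_ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype code vectors."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or len(g1) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if g1.std() == 0 or g2.std() == 0:
        raise ValueError("LD undefined for a monomorphic marker")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)


def _chrom_r2_matrixless(codes: np.ndarray, i: int, j_slice: np.ndarray) -> np.ndarray:
    """r^2 of focal column i against columns j_slice (vectorized)."""
    x = codes[:, i]
    Y = codes[:, j_slice]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * np.einsum("ij,ij->j", Yc, Yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc.T @ xc) / denom
    return np.where(np.isfinite(r), r * r, np.nan)


def ld_decay_profile(G: GenotypeMatrix, max_dist: int = 500_000,
                     bin_size: int = 5_000) -> tuple[pd.DataFrame, float | None]:
    """Mean r^2 per physical-distance bin over all intra-chromosomal pairs
    within ``max_dist``; the decay distance is the first bin midpoint whose
    cumulative-minimum-smoothed mean r^2 falls below 0.1."""
    dists, r2s = [], []
    for chrom, sub in G.map.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if len(idx) < 2:
            continue
        codes = G.codes[:, idx]
        sd = codes.std(axis=0)
        for a in range(len(idx) - 1):
            if sd[a] == 0:
                continue
            hi = np.searchsorted(pos, pos[a] + max_dist, side="right")
            js = np.arange(a + 1, hi)
            js = js[sd[js] > 0]
            if js.size == 0:
                continue
            r2 = _chrom_r2_matrixless(codes, a, js)
            dists.append(pos[js] - pos[a])
            r2s.append(r2)
    if not dists:
        return pd.DataFrame(columns=["bin_mid", "mean_r2", "n_pairs"]), None
    dist = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    ok = np.isfinite(r2)
    dist, r2 = dist[ok], r2[ok]
    bins = (dist - 1) // bin_size
    table = (
        pd.DataFrame({"bin": bins, "r2": r2})
        .groupby("bin")["r2"]
        .agg(["mean", "size"])
        .reset_index()
    )
    table["bin_mid"] = table["bin"] * bin_size + bin_size / 2.0
    table = table.rename(columns={"mean": "mean_r2", "size": "n_pairs"})
    smoothed = np.minimum.accumulate(table["mean_r2"].to_numpy())
    below = np.flatnonzero(smoothed < 0.1)
    decay = float(table["bin_mid"].iloc[below[0]]) if below.size else None
    return table[["bin_mid", "mean_r2", "n_pairs"]], decay


def ld_boundaries(G: GenotypeMatrix, snp_index: int, threshold: float = 0.1) -> tuple[int, int]:
    """Outward scan from the focal SNP: the boundary on each side is the
    position of the last marker before r^2 first drops below ``threshold``;
    if it never drops, the chromosome's terminal marker position."""
    chrom = G.map.iloc[snp_index]["chrom"]
    sub = G.map[G.map["chrom"] == chrom]
    idx = sub.index.to_numpy()
    local = int(np.flatnonzero(idx == snp_index)[0])
    pos = sub["pos"].to_numpy()
    focal = G.codes[:, snp_index]
    if focal.std() == 0:
        raise ValueError("focal SNP monomorphic")

    def scan(step: int) -> int:
        last = pos[local]
        j = local + step
        while 0 <= j < len(idx):
            other = G.codes[:, idx[j]]
            if other.std() == 0:
                r2 = 0.0
            else:
                r2 = pairwise_ld_r2(focal, other)
            if r2 < threshold:
                return last
            last = pos[j]
            j += step
        return last

    return scan(-1), scan(+1)


def merge_qtl_intervals(significant: list[tuple[str, str, int, int, int, float]],
                        merge_dist: int = 50_000) -> list[QTLInterval]:
    """Single-linkage merge of per-SNP intervals.

    ``significant`` rows are (snp_id, chrom, peak_pos, start, end, p). Two
    SNPs join one region when their intervals overlap OR their peak positions
    are strictly less than ``merge_dist`` apart. Lead SNP = minimum p, ties
    broken by smaller position.
    """
    out: list[QTLInterval] = []
    df = pd.DataFrame(
        significant, columns=["snp", "chrom", "peak", "start", "end", "p"]
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values(["peak", "snp"]).reset_index(drop=True)
        k = len(sub)
        parent = list(range(k))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        rows_ = list(sub.itertuples())
        for i in range(k):
            for j in range(i + 1, k):
                a, b = rows_[i], rows_[j]
                overlap = a.start <= b.end and b.start <= a.end
                close_peaks = abs(a.peak - b.peak) < merge_dist
                if overlap or close_peaks:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups: dict[int, list] = {}
        for i in range(k):
            groups.setdefault(find(i), []).append(rows_[i])
        for members in groups.values():
            lead = min(members, key=lambda r: (r.p, r.peak))
            start = min(min(m.start for m in members), min(m.peak for m in members))
            end = max(max(m.end for m in members), max(m.peak for m in members))
            out.append(
                QTLInterval(
                    chromosome=str(chrom), start=int(start), end=int(end),
                    lead_snp=lead.snp, lead_p=float(lead.p),
                    member_snps=[m.snp for m in members],
                )
            )
    out.sort(key=lambda q: (q.chromosome, q.start, q.end))
    return out


def classify_eqtl(eqtl: tuple[str, int, int], gene: tuple[str, int, int],
                  window: int = 50_000) -> str:
    """'local' iff same chromosome and the eQTL interval overlaps the gene
    interval or lies within ``window`` bp of it (inclusive); else 'distant'."""
    (qc, qs, qe), (gc, gs, ge) = eqtl, gene
    if qs > qe or gs > ge:
        raise ValueError("invalid interval")
    if qc != gc:
        return "distant"
    gap = max(gs - qe, qs - ge, 0)
    return "local" if gap <= window else "distant"


def detect_hotspots(events: dict[str, np.ndarray], chrom_lengths: dict[str, int],
                    window: int = 100_000, significance: float = 0.01) -> list[HotspotRegion]:
    """Sliding-window Poisson scan for distant-eQTL event excess.

    Windows of width ``window`` advance by ``window/2``; each count is tested
    against Poisson(genome-wide events per bp x window), p-values are BH
    adjusted across all windows, and overlapping significant windows are
    merged into maximal hotspot regions.
    """
    total_events = sum(len(np.asarray(v)) for v in events.values())
    if total_events == 0:
        return []
    total_len = sum(chrom_lengths[c] for c in chrom_lengths)
    rate = total_events / total_len * window
    step = max(window // 2, 1)

    rows = []
    for chrom, length in chrom_lengths.items():
        pos = np.sort(np.asarray(events.get(chrom, []), dtype=float))
        starts = np.arange(1, max(length - window + 2, 2), step)
        for s in starts:
            e = min(s + window - 1, length)
            count = int(np.searchsorted(pos, e, side="right")
                        - np.searchsorted(pos, s, side="left"))
            rows.append((chrom, int(s), int(e), count))
    counts = np.array([r[3] for r in rows])
    pvals = stats.poisson.sf(counts - 1, rate)  # P(X >= count)
    from .association import adjust_pvalues

    p_adj, _ = adjust_pvalues(np.clip(pvals, 1e-300, 1.0), "bh_fdr")
    sig = p_adj < significance

    # merge overlapping significant windows per chromosome
    out: list[HotspotRegion] = []
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, *_rest) in enumerate(rows):
        if sig[i]:
            by_chrom.setdefault(chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: rows[i][1])
        cur = None
        for i in idxs:
            _, s, e, c = rows[i]
            if cur is None:
                cur = [s, e, c, pvals[i], p_adj[i]]
            elif s <= cur[1] + 1:
                cur[1] = max(cur[1], e)
                cur[2] = max(cur[2], c)
                cur[3] = min(cur[3], pvals[i])
                cur[4] = min(cur[4], p_adj[i])
            else:
                out.append(HotspotRegion(chrom, cur[0], cur[1], cur[2],
                                         float(cur[3]), float(cur[4]), True))
                cur = [s, e, c, pvals[i], p_adj[i]]
        if cur is not None:
            out.append(HotspotRegion(chrom, cur[0], cur[1], cur[2],
                                     float(cur[3]), float(cur[4]), True))
    out.sort(key=lambda h: (h.chromosome, h.start))
    return out


def build_qtl_regions(G: GenotypeMatrix, assoc: pd.DataFrame,
                      ld_threshold: float = 0.1, merge_dist: int = 50_000) -> list[QTLInterval]:
    """LD boundaries + merge for every significant SNP of one association table.

    ``assoc`` needs columns feature_id (marker id) and p, already restricted
    to significant rows.
    """
    marker_index = {m: i for i, m in enumerate(G.marker_ids)}
    rows = []
    for r in assoc.itertuples():
        i = marker_index[r.feature_id]
        chrom = G.map.iloc[i]["chrom"]
        peak = int(G.map.iloc[i]["pos"])
        up, down = ld_boundaries(G, i, ld_threshold)
        rows.append((r.feature_id, chrom, peak, int(up), int(down), float(r.p)))
    if not rows:
        return []
    return merge_qtl_intervals(rows, merge_dist)


def eqtl_records_from_scans(
    G: GenotypeMatrix,
    scans: dict[str, pd.DataFrame],
    gene_coords: pd.DataFrame,
    ld_threshold: float = 0.1,
    merge_dist: int = 50_000,
    window: int = 50_000,
) -> pd.DataFrame:
    """eQTL intervals and local/distant classes from per-gene eGWAS scans.

    ``scans`` maps eGene id -> association table restricted to significant
    eSNPs (columns feature_id, p); eQTL intervals per gene use the same
    LD-boundary + merge procedure as QTLs. One row per (eGene, eQTL) with
    the lead eSNP, interval, class and lead p.
    """
    coords = gene_coords.set_index("feature")
    rows = []
    for gene, assoc in scans.items():
        if assoc.empty:
            continue
        gc = coords.loc[gene]
        for q in build_qtl_regions(G, assoc, ld_threshold, merge_dist):
            klass = classify_eqtl(
                (q.chromosome, q.start, q.end),
                (str(gc["chrom"]), int(gc["start"]), int(gc["end"])),
                window,
            )
            lead_pos = int(G.map.set_index("marker").loc[q.lead_snp, "pos"])
            rows.append({
                "egene": gene, "esnp": q.lead_snp, "esnp_chrom": q.chromosome,
                "esnp_pos": lead_pos, "eqtl_start": q.start, "eqtl_end": q.end,
                "gene_chrom": str(gc["chrom"]), "gene_start": int(gc["start"]),
                "gene_end": int(gc["end"]), "p": q.lead_p, "class": klass,
            })
    cols = ["egene", "esnp", "esnp_chrom", "esnp_pos", "eqtl_start", "eqtl_end",
            "gene_chrom", "gene_start", "gene_end", "p", "class"]
    return pd.DataFrame(rows, columns=cols)


def distant_event_positions(eqtl_records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Lead-eSNP positions of distant eQTLs, grouped by chromosome, as the
    event set for the hotspot scan."""
    distant = eqtl_records[eqtl_records["class"] == "distant"]
    return {
        str(chrom): sub["esnp_pos"].to_numpy(dtype=float)
        for chrom, sub in distant.groupby("esnp_chrom")
    }
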
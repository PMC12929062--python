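"""Covariation testing (Mantel) and assembly of the ASV-QTL-gene-hotspot
regulatory network.

The Mantel statistic is the correlation between the upper off-diagonal
triangles of two distance matrices; significance comes from jointly
permuting rows and columns of the second matrix, with the one-sided
upper-tail p-value (1 + #{r_perm >= r_obs}) / (1 + permutations).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["mantel_test", "assemble_network", "node_degrees"]

NODE_KINDS = ("ASV", "QTL", "gene", "hotspot")


def _check_distance_matrix(D: np.ndarray, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square")
    if D.shape[0] < 4:
        raise ValueError(f"{name} must be at least 4x4")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError(f"{name} has a nonzero diagonal")
    return D


def mantel_test(D1: np.ndarray, D2: np.ndarray, permutations: int = 1999,
                method: str = "pearson", seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices and its one-sided
    permutation p-value."""
    D1 = _check_distance_matrix(D1, "D1")
    D2 = _check_distance_matrix(D2, "D2")
    if D1.shape != D2.shape:
        raise ValueError("distance matrices differ in size")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1 = D1[iu]

    if method == "spearman":
        v1 = stats.rankdata(v1)

    def corr(a, b):
        if method == "spearman":
            b = stats.rankdata(b)
        ac = a - a.mean()
        bc = b - b.mean()
        denom = np.sqrt((ac @ ac) * (bc @ bc))
        if denom == 0:
            raise ValueError("constant distance vector; correlation undefined")
        return float(ac @ bc / denom)

    r_obs = corr(v1, D2[iu])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = corr(v1, D2[np.ix_(perm, perm)][iu])
        if r_perm >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return float(r_obs), float(p)


def assemble_network(
    gwas_hits: pd.DataFrame,
    twas_hits: pd.DataFrame,
    eqtl_records: pd.DataFrame,
    environment: str = "",
) -> pd.DataFrame:
    """Deduplicated edge list of the regulated-ASV network.

    gwas_hits: columns asv, qtl (significant GWAS QTL per ASV)
    twas_hits: columns asv, gene (significant TWAS genes per ASV)
    eqtl_records: columns gene, hotspot (eGenes whose eQTL lies inside a
        hotspot region)
    """
    frames = []
    if len(gwas_hits):
        frames.append(pd.DataFrame({
            "source": gwas_hits["asv"].astype(str), "source_kind": "ASV",
            "target": gwas_hits["qtl"].astype(str), "target_kind": "QTL",
            "evidence": "gwas",
        }))
    if len(twas_hits):
        frames.append(pd.DataFrame({
            "source": twas_hits["asv"].astype(str), "source_kind": "ASV",
            "target": twas_hits["gene"].astype(str), "target_kind": "gene",
            "evidence": "twas",
        }))
    if len(eqtl_records):
        frames.append(pd.DataFrame({
            "source": eqtl_records["gene"].astype(str), "source_kind": "gene",
            "target": eqtl_records["hotspot"].astype(str), "target_kind": "hotspot",
            "evidence": "eqtl",
        }))
    if not frames:
        return pd.DataFrame(columns=["source", "source_kind", "target",
                                     "target_kind", "environment", "evidence"])
    edges = pd.concat(frames, ignore_index=True)
    edges["environment"] = environment
    if (edges["source"] == edges["target"]).any():
        raise ValueError("self-edge in network input")
    edges = edges.drop_duplicates(
        subset=["source", "source_kind", "target", "target_kind", "evidence"]
    ).reset_index(drop=True)
    edges = edges.sort_values(["source", "target"]).reset_index(drop=True)
    return edges[["source", "source_kind", "target", "target_kind",
                  "environment", "evidence"]]


def node_degrees(edges: pd.DataFrame) -> pd.DataFrame:
    """Degree per node over the undirected edge list."""
    nodes = pd.concat([
        edges[["source", "source_kind"]].rename(
            columns={"source": "node", "source_kind": "kind"}),
        edges[["target", "target_kind"]].rename(
            columns={"target": "node", "target_kind": "kind"}),
    ])
    out = nodes.groupby(["node", "kind"]).size().reset_index(name="degree")
    return out.sort_values(["degree", "node"], ascending=[False, True]).reset_index(drop=True)


def to_graphml(edges: pd.DataFrame, path: str) -> None:
    """Export the edge list as GraphML (nodes carry their kind)."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples():
        g.add_node(row.source, kind=row.source_kind)
        g.add_node(row.target, kind=row.target_kind)
        g.add_edge(row.source, row.target, evidence=row.evidence,
                   environment=row.environment)
    nx.write_graphml(g, path)
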
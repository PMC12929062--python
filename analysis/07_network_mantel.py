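#!/usr/bin/env python
"""Covariation and network assembly: Mantel test between the expression,
ASV-abundance and ionome distance structures (1,999 permutations), then the
ASV-QTL-gene-hotspot edge list from the GWAS/TWAS/eQTL tables; write the
edge list, degree table and GraphML export under results/.
"""

import os

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform

from rhizogwas import io_formats as iof
from rhizogwas import network_stats as ns

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SIM = os.path.join(BASE, "simulated")

expr = pd.read_csv(os.path.join(SIM, "expression_KF.tsv"), sep="\t", index_col=0)
blues = pd.read_csv(os.path.join(BASE, "asv_blues_KF.tsv"), sep="\t", index_col=0)
traits = pd.read_csv(os.path.join(SIM, "ionome_KF.tsv"), sep="\t", index_col=0)
genotypes = blues.index.intersection(expr.index).intersection(traits.index)

D_expr = squareform(pdist(expr.loc[genotypes], metric="euclidean"))
D_ion = squareform(pdist(traits.loc[genotypes], metric="euclidean"))
# Bray-Curtis on shifted BLUEs of log abundance (non-negative scale)
abund = blues.loc[genotypes].to_numpy()
abund = abund - abund.min() + 1e-9
D_asv = squareform(pdist(abund, metric=braycurtis))

r1, p1 = ns.mantel_test(D_expr, D_ion, permutations=1999, seed=3)
r2, p2 = ns.mantel_test(D_asv, D_ion, permutations=1999, seed=3)
r3, p3 = ns.mantel_test(D_expr, D_asv, permutations=1999, seed=3)
print(f"Mantel expression~ionome:  r = {r1:+.3f}, p = {p1:.4f}")
print(f"Mantel microbiome~ionome:  r = {r2:+.3f}, p = {p2:.4f}")
print(f"Mantel expression~microbiome: r = {r3:+.3f}, p = {p3:.4f}")

gwas_qtl = pd.read_csv(os.path.join(BASE, "qtl_regions_KF.tsv"), sep="\t")
twas = pd.read_csv(os.path.join(BASE, "twas_significant_KF.tsv"), sep="\t")
eqtl = pd.read_csv(os.path.join(BASE, "eqtl_records_KF.tsv"), sep="\t")
hotspots = pd.read_csv(os.path.join(BASE, "eqtl_hotspots_KF.tsv"), sep="\t")

gwas_edges = gwas_qtl.assign(
    qtl=lambda d: d["chrom"] + ":" + d["start"].astype(str) + "-"
    + d["end"].astype(str))[["asv", "qtl"]]
twas_edges = (twas.rename(columns={"response": "asv", "feature_id": "gene"})
              [["asv", "gene"]] if len(twas) else pd.DataFrame())

# eGenes whose distant eQTL lead SNP falls inside a hotspot region
rows = []
for h in hotspots.itertuples():
    inside = eqtl[(eqtl["class"] == "distant")
                  & (eqtl["esnp_chrom"] == h.chrom)
                  & (eqtl["esnp_pos"].between(h.start, h.end))]
    hotspot_id = f"{h.chrom}:{h.start}-{h.end}"
    rows += [{"gene": g, "hotspot": hotspot_id} for g in inside["egene"]]
hotspot_edges = pd.DataFrame(rows)

edges = ns.assemble_network(gwas_edges, twas_edges, hotspot_edges,
                            environment="KF")
iof.write_results(edges, os.path.join(BASE, "network_edges_KF.tsv"))
degrees = ns.node_degrees(edges)
iof.write_results(degrees, os.path.join(BASE, "network_degrees_KF.tsv"))
ns.to_graphml(edges, os.path.join(BASE, "network_KF.graphml"))

print(f"{len(edges)} network edges "
      f"({(edges['evidence'] == 'gwas').sum()} ASV-QTL, "
      f"{(edges['evidence'] == 'twas').sum()} ASV-gene, "
      f"{(edges['evidence'] == 'eqtl').sum()} gene-hotspot)")
if len(degrees):
    top = degrees.iloc[0]
    print(f"highest-degree node: {top['node']} ({top['kind']}, "
          f"degree {top['degree']})")
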
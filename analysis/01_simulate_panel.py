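#!/usr/bin/env python
"""Generate the tutorial dataset: an ecotype-structured diversity panel with
rhizosphere ASV counts, root expression with a trans hub, and kernel-driven
ionome traits, written as plain TSV under results/simulated/.

The panel is deliberately smaller than the default config (800 markers, 120
ASVs, 300 genes) so the full analysis chain below runs in a few minutes.
"""

import os
from dataclasses import replace

import numpy as np
import pandas as pd

from rhizogwas import io_formats as iof
from rhizogwas import kinship_mlm as km
from rhizogwas import synthetic_data as sd

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "simulated")
SEED = 7

cfg = replace(
    sd.SimulationConfig(),
    n_markers=800, n_asvs=120, n_genes=300, n_traits=6,
    hub_n_targets=40, hub_effect=1.0,
)

os.makedirs(OUT, exist_ok=True)

G = sd.simulate_genotypes(cfg, seed=SEED)
geno_df = pd.DataFrame(G.codes, index=G.sample_ids, columns=G.marker_ids)
geno_df.rename_axis("sample").reset_index().to_csv(
    os.path.join(OUT, "genotypes.tsv"), sep="\t", index=False)

counts, meta, asv_truth = sd.simulate_asv_counts(G, cfg, seed=SEED + 1,
                                                 environment="KF")
counts.rename_axis("sample").reset_index().to_csv(
    os.path.join(OUT, "asv_counts_KF.tsv"), sep="\t", index=False)
meta.reset_index().to_csv(os.path.join(OUT, "sample_meta_KF.tsv"),
                          sep="\t", index=False)
iof.write_results(asv_truth, os.path.join(OUT, "asv_truth_KF.tsv"))

# plant the trans hub on a marker segregating *within* ancestral groups:
# variance left after projecting out the leading kinship eigenvectors.
# A structure-confounded hub is invisible to the Q+K model by design.
K_struct = km.vanraden_grm(G)
pcs = km.grm_principal_components(K_struct, cfg.n_founders)
Q, _ = np.linalg.qr(np.column_stack([np.ones(G.n_samples), pcs]))
resid = G.codes - Q @ (Q.T @ G.codes)
hub_marker = G.marker_ids[int(np.argmax(resid.var(axis=0)))]

expr, expr_truth = sd.simulate_expression(G, cfg, seed=SEED + 2,
                                          hub_marker=hub_marker)
iof.write_results(expr, os.path.join(OUT, "expression_KF.tsv"))
iof.coordinates_to_bed(expr.coordinates).to_csv(
    os.path.join(OUT, "gene_coords.bed"), sep="\t", index=False, header=False)
iof.write_results(expr_truth.assign(
    hub_marker=expr_truth.attrs["hub_marker"]),
    os.path.join(OUT, "expression_truth_KF.tsv"))

K_wgs = K_struct
traits, trait_truth = sd.simulate_ionome(
    {"WGS": K_wgs.K}, {"WGS": 1.0}, cfg, seed=SEED + 3)
traits.rename_axis("genotype").reset_index().to_csv(
    os.path.join(OUT, "ionome_KF.tsv"), sep="\t", index=False)
iof.write_results(trait_truth, os.path.join(OUT, "ionome_truth_KF.tsv"))

print(f"panel: {G.n_samples} genotypes x {G.n_markers} markers, "
      f"{counts.shape[0]} rhizosphere samples x {counts.shape[1]} ASVs, "
      f"{expr.values.shape[1]} genes (hub at "
      f"{expr_truth.attrs['hub_chrom']}:{expr_truth.attrs['hub_pos']}), "
      f"{traits.shape[1]} ionome traits -> {os.path.abspath(OUT)}")
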
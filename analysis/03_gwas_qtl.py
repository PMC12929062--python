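#!/usr/bin/env python
"""Mixed-model GWAS of the heritable-ASV BLUEs against the panel SNPs
(VanRaden kinship, P3D Wald scan, per-ASV FDR), then LD-boundary QTL
interval construction and 50-kb merging; write association and QTL tables
under results/.
"""

import os

import pandas as pd

from rhizogwas import association as assoc
from rhizogwas import io_formats as iof
from rhizogwas import kinship_mlm as km
from rhizogwas import ld_qtl

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SIM = os.path.join(BASE, "simulated")

G = iof.read_genotype_matrix(os.path.join(SIM, "genotypes.tsv"), dialect="tsv")
G = assoc.filter_markers(G, maf_min=0.05, het_max=0.95)
blues = pd.read_csv(os.path.join(BASE, "asv_blues_KF.tsv"), sep="\t",
                    index_col=0)
truth = pd.read_csv(os.path.join(SIM, "asv_truth_KF.tsv"), sep="\t")

K = km.vanraden_grm(G)
res = assoc.run_association_study(
    assoc.StudySpec(mode="gwas", adjust="bh_fdr"), blues, G, K)

sig = assoc.significant_hits(res)
iof.write_results(sig, os.path.join(BASE, "gwas_significant_KF.tsv"))

qtl_rows = []
causal_led = 0
causal_of = truth.set_index("asv")["causal_markers"].str.split(";").to_dict()
for asv, tab in res.items():
    s = tab[tab["significant"]][["feature_id", "p"]]
    if s.empty:
        continue
    for q in ld_qtl.build_qtl_regions(G, s):
        qtl_rows.append({
            "asv": asv, "chrom": q.chromosome, "start": q.start, "end": q.end,
            "lead_snp": q.lead_snp, "lead_p": q.lead_p,
            "n_members": len(q.member_snps),
        })
        if q.lead_snp in (causal_of.get(asv) or []):
            causal_led += 1
qtl_table = pd.DataFrame(qtl_rows)
iof.write_results(qtl_table, os.path.join(BASE, "qtl_regions_KF.tsv"))

n_asv_hit = qtl_table["asv"].nunique() if len(qtl_table) else 0
print(f"{len(sig)} significant SNP-ASV associations over {n_asv_hit} ASVs")
print(f"{len(qtl_table)} merged QTL regions; {causal_led} led by a true "
      f"causal SNP of their ASV")
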
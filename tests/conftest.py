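import numpy as np
import pandas as pd
import pytest

from rhizogwas import synthetic_data as sd
from rhizogwas.kinship_mlm import vanraden_grm


@pytest.fixture(scope="session")
def small_panel():
    """Panmictic 120-genotype, 300-marker panel on two chromosomes."""
    cfg = sd.panmictic_config(
        n_genotypes=120, n_markers=300, ld_block_len=10_000,
        chromosomes=(("A01", 2_000_000), ("C01", 2_000_000)),
    )
    return cfg, sd.simulate_genotypes(cfg, seed=101)


@pytest.fixture(scope="session")
def structured_panel():
    """Ecotype-structured 175-genotype panel (paper-shaped defaults, fewer markers)."""
    cfg = sd.SimulationConfig(n_markers=800)
    return cfg, sd.simulate_genotypes(cfg, seed=202)


@pytest.fixture(scope="session")
def structured_grm(structured_panel):
    _, G = structured_panel
    return vanraden_grm(G)


@pytest.fixture()
def toy_plot_table():
    """Balanced 6-genotype x 2-replicate table with known genotype means."""
    rng = np.random.default_rng(11)
    rows = []
    means = {f"g{i}": float(i) for i in range(6)}
    for rep in ("r1", "r2"):
        for g, m in means.items():
            rows.append((g, "KF", rep, "b1", m + rng.normal(0, 0.1)))
    return pd.DataFrame(rows, columns=["genotype", "environment", "replicate",
                                       "block", "value"])


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=A01,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5
A01\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\t0/0\t0/0
A01\t200\tm2\tA\tG\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1\t0/1\t1/0
A01\t300\tm3\tC\tG\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t./.\t0/1
A01\t400\tm4\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/1\t1/0\t0/1\t1/0
"""

MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=A01,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
A01\t100\tm1\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture()
def multiallelic_vcf(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(MULTIALLELIC_VCF)
    return str(path)
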
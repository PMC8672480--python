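import numpy as np
import pandas as pd
import pytest

import scpopsim as sp


@pytest.fixture(scope="session")
def default_ps():
    return sp.default_params()


@pytest.fixture(scope="session")
def small_genotypes():
    """200 SNPs x 20 individuals on one 2 Mb chromosome."""
    return sp.simulate_genotypes(200, 20, maf_range=(0.1, 0.5),
                                 chrom_length=2_000_000, seed=11)


@pytest.fixture(scope="session")
def small_annotation():
    return sp.simulate_annotation(50, chrom_length=2_000_000, seed=11)


@pytest.fixture(scope="session")
def smoke_bundle(default_ps):
    """One small end-to-end simulation reused by read-only tests."""
    ps = default_ps.with_overrides({
        "sc.n_genes": 500, "design.n_individuals": 6,
        "design.cells_per_individual": 100, "design.master_seed": 123})
    return sp.simulate(ps, keep_intermediates=True)


@pytest.fixture()
def vcf_file(tmp_path):
    """Handwritten 7-record VCF: 5 usable SNPs plus records that must drop."""
    text = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\t0/0
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t1/1\t0/1\t1/1
1\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0/1\t0/1\t1/1\t0/0
1\t400\trs4\tT\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\t0/0
1\t500\trs5\tA\tC\t.\tPASS\t.\tGT\t0/0\t./.\t0/1\t0/0
1\t600\trs6\tG\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0
1\t700\trs7\tC\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/1
"""
    path = tmp_path / "fixture.vcf"
    path.write_text(text)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_expr_matrix(mean_shape, mean_rate, cv_shape, cv_rate, n_genes,
                     n_individuals, seed):
    """Genes x individuals matrix with known mean/cv generating gammas."""
    rng = np.random.default_rng(seed)
    lam = rng.gamma(mean_shape, 1.0 / mean_rate, size=n_genes)
    cv = rng.gamma(cv_shape, 1.0 / cv_rate, size=n_genes)
    values = rng.normal(lam[:, None], (lam * cv)[:, None],
                        size=(n_genes, n_individuals))
    values = np.maximum(values, 0.0)
    return pd.DataFrame(values), lam, cv
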
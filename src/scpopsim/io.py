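"""Reading reference matrices and writing/validating simulation output.

Output directories contain: counts.mtx (Matrix Market, genes x cells),
cells.tsv, key.tsv + individuals.tsv (the SimKey), genes.tsv (annotation
subset of the key), and config.json (the resolved parameters) so a run can
be re-validated and re-created from the files alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .cellsim import CountBundle
from .popmeans import SimKey

logger = logging.getLogger("scpopsim")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene ids, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty matrix")
    return df.astype(float)


def read_matrix_mtx(mtx_path, row_tsv, col_tsv) -> pd.DataFrame:
    """MTX matrix with one-column row/column id files (no header)."""
    mat = spio.mmread(str(mtx_path))
    rows = pd.read_csv(row_tsv, sep="\t", header=None)[0].astype(str)
    cols = pd.read_csv(col_tsv, sep="\t", header=None)[0].astype(str)
    dense = np.asarray(sparse.csr_matrix(mat).todense(), dtype=float)
    if dense.shape != (len(rows), len(cols)):
        raise ValueError("MTX dimensions do not match row/column id files")
    return pd.DataFrame(dense, index=rows, columns=cols)


def write_bundle(bundle: CountBundle, directory, params=None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / "counts.mtx"), bundle.counts.tocoo(),
                 field="integer")
    bundle.cell_meta.drop(columns=["cell_id"]).to_csv(
        directory / "cells.tsv", sep="\t")
    bundle.key.to_tsv(directory)
    ann_cols = [c for c in ("chrom", "pos") if c in bundle.key.gene_key]
    bundle.key.gene_key[ann_cols].rename_axis("gene_id").to_csv(
        directory / "genes.tsv", sep="\t")
    if params is not None:
        params.to_json(directory / "config.json")
    logger.info("wrote bundle to %s (%d genes x %d cells)", directory,
                *bundle.counts.shape)
    return directory


def read_bundle(directory) -> CountBundle:
    directory = Path(directory)
    counts = sparse.csr_matrix(spio.mmread(str(directory / "counts.mtx")))
    cell_meta = pd.read_csv(directory / "cells.tsv", sep="\t",
                            index_col="cell_id", keep_default_na=False)
    cell_meta.insert(0, "cell_id", cell_meta.index)
    key = SimKey.from_tsv(directory)
    return CountBundle(counts=counts, cell_meta=cell_meta, key=key)


def validate_bundle(directory, maf_min: float | None = None,
                    dist_max: float | None = None,
                    genotypes=None) -> CountBundle:
    """Re-assert output invariants from the files alone.

    Checks count dimensions against metadata, non-negativity/integrality,
    positive betas, and — when genotypes are supplied — the MAF and distance
    bounds of every eQTL assignment.
    """
    bundle = read_bundle(directory)
    counts = bundle.counts
    if counts.data.size:
        if counts.data.min() < 0 or np.any(counts.data != np.round(counts.data)):
            raise ValueError("counts must be non-negative integers")
    key = bundle.key.gene_key
    egenes = key[key["eqtl_snp"] != ""]
    if (egenes["eqtl_beta"] <= 0).any():
        raise ValueError("eQTL betas must be > 0")
    if genotypes is not None:
        snp_of = {s: k for k, s in enumerate(genotypes.snp_ids)}
        for gene, row in egenes.iterrows():
            k = snp_of.get(row["eqtl_snp"])
            if k is None:
                raise ValueError(f"eSNP {row['eqtl_snp']} not in genotypes")
            if not np.isin(genotypes.dosage[k], (0, 1, 2)).all():
                raise ValueError("dosages out of range")
            if maf_min is not None and genotypes.maf[k] < maf_min:
                raise ValueError(f"eSNP {row['eqtl_snp']} fails maf_min")
            if dist_max is not None and "pos" in key.columns:
                if abs(int(genotypes.pos[k]) - int(row["pos"])) > dist_max:
                    raise ValueError(f"eQTL for {gene} exceeds dist_max")
    logger.info("validated bundle at %s", directory)
    return bundle
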
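"""Single-cell counts from population means.

Second half of the gamma-Poisson hierarchy: cells are laid out across
batches/individuals/groups, batch factors and expected library sizes are
sampled, the per-cell expected means are rescaled to the library size, the
biological coefficient of variation inflates each mean through a gamma
mixing step, and counts are Poisson draws (optionally thinned by logistic
dropout). ``simulate`` orchestrates the whole pipeline end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from ._streams import substream
from .genotypes import (GeneAnnotation, GenotypeMatrix, assign_eqtl,
                        filter_genotypes, simulate_annotation,
                        simulate_genotypes)
from .params import DesignParams, ParameterSet, SCParams, per_level
from .popmeans import (PopMeans, SimKey, apply_de, apply_eqtl, build_sim_key,
                       quantile_normalize, sample_base_means,
                       sample_individual_means, sample_variances,
                       use_empirical_means)

logger = logging.getLogger("scpopsim")

_CELL_CHUNK = 4096  # cells sampled per block to bound peak memory


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CellDesign:
    """Cell layout: one row per cell plus the batch membership map."""

    cells: pd.DataFrame               # cell_id, individual, batch, group, condition
    batch_members: dict[str, list[str]]  # batch -> individuals in it

    def __post_init__(self) -> None:
        need = {"cell_id", "individual", "batch", "group", "condition"}
        if not need <= set(self.cells.columns):
            raise ValueError(f"cell table must have columns {sorted(need)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def batches(self) -> list[str]:
        return list(self.batch_members)


@dataclass
class CountBundle:
    """Sparse counts plus all metadata and ground truth of one simulation."""

    counts: sparse.csr_matrix         # genes x cells, integer
    cell_meta: pd.DataFrame           # CellDesign columns, indexed by cell_id
    key: SimKey
    intermediates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.key.gene_key), len(self.cell_meta)):
            raise ValueError("counts dimensions do not match metadata")
        if self.counts.data.size and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.key.gene_key.index)

    @property
    def gene_meta(self) -> pd.DataFrame:
        return self.key.gene_key

    def to_anndata(self):
        """View as an AnnData (cells x genes), if anndata is installed."""
        import anndata

        return anndata.AnnData(X=self.counts.T.tocsr(),
                               obs=self.cell_meta.copy(),
                               var=self.key.gene_key.copy())


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def build_design(design: DesignParams, individual_ids: Sequence[str] | None = None,
                 seed: int | None = None) -> CellDesign:
    """Allocate individuals to batches and lay out cells.

    Batches are filled from a shuffled roster of individuals; once every
    individual is placed, each remaining slot is filled by a technical
    replicate drawn uniformly (without replacement within a batch) from the
    individuals not already in that batch. Cells within a batch are split
    evenly across its individuals (remainder cells go to random members);
    cell groups are drawn per cell and conditions assigned per individual by
    largest-remainder rounding of the cohort proportions.
    """
    if individual_ids is None:
        individual_ids = [f"i{j + 1}" for j in range(design.n_individuals)]
    individual_ids = [str(i) for i in individual_ids]
    if len(individual_ids) != design.n_individuals:
        raise ValueError("individual_ids length must equal n_individuals")
    rng = substream(design.master_seed if seed is None else seed, "design")

    batch_cells, batch_size = design.resolved_batches()
    if batch_size > design.n_individuals:
        raise ValueError("batch_size cannot exceed n_individuals")
    n_batches = len(batch_cells)
    batch_names = [f"b{k + 1}" for k in range(n_batches)]

    roster = list(rng.permutation(individual_ids))
    members: dict[str, list[str]] = {b: [] for b in batch_names}
    for b in batch_names:
        while len(members[b]) < batch_size and roster:
            members[b].append(roster.pop(0))
        if len(members[b]) < batch_size:
            outside = [i for i in individual_ids if i not in members[b]]
            extra = rng.choice(outside, size=batch_size - len(members[b]),
                               replace=False)
            members[b].extend(str(i) for i in extra)
    placed = {i for mem in members.values() for i in mem}
    unplaced = [i for i in individual_ids if i not in placed]
    if unplaced:
        raise ValueError(
            f"{len(unplaced)} individuals received no batch; increase the "
            "number of batches or batch_size")

    # Conditions per individual: largest-remainder apportionment.
    probs = np.asarray(design.condition_probs, dtype=float)
    n_ind = design.n_individuals
    base = np.floor(probs * n_ind).astype(int)
    rem = probs * n_ind - base
    for k in np.argsort(-rem)[: n_ind - base.sum()]:
        base[k] += 1
    cond_labels = np.repeat(design.condition_names, base)
    cond_of = dict(zip(rng.permutation(individual_ids), cond_labels))

    rows = []
    group_probs = np.asarray(design.group_probs, dtype=float)
    cell_counter = 0
    for b, n_cells in zip(batch_names, batch_cells):
        mem = members[b]
        per_ind = np.full(len(mem), n_cells // len(mem))
        extra_idx = rng.choice(len(mem), size=n_cells % len(mem), replace=False)
        per_ind[extra_idx] += 1
        for ind, n_c in zip(mem, per_ind):
            groups = rng.choice(design.group_names, size=n_c, p=group_probs)
            for g in groups:
                cell_counter += 1
                rows.append((f"cell{cell_counter}", ind, b, g, cond_of[ind]))
    cells = pd.DataFrame(rows, columns=["cell_id", "individual", "batch",
                                        "group", "condition"])
    logger.info("design: %d cells, %d individuals, %d batches, %d groups, "
                "%d conditions", len(cells), n_ind, n_batches,
                len(design.group_names), len(design.condition_names))
    return CellDesign(cells=cells, batch_members=members)


# ---------------------------------------------------------------------------
# Cell-level sampling
# ---------------------------------------------------------------------------

def sample_batch_factors(n_genes: int, batches: Sequence[str],
                         batch_loc, batch_scale, seed: int = 0) -> pd.DataFrame:
    """Multiplicative gene x batch factors, logNormal(loc, scale), made
    bidirectional by replacing f with 1/f with probability 0.5."""
    locs = per_level(batch_loc, len(batches), "batch_loc")
    scales = per_level(batch_scale, len(batches), "batch_scale")
    rng = substream(seed, "batch")
    out = np.empty((n_genes, len(batches)))
    for k in range(len(batches)):
        f = rng.lognormal(locs[k], scales[k], size=n_genes)
        flip = rng.random(n_genes) < 0.5
        f[flip] = 1.0 / f[flip]
        out[:, k] = f
    return pd.DataFrame(out, columns=list(batches))


def sample_library_sizes(cell_ids: Sequence[str], sc: SCParams,
                         seed: int = 0) -> pd.Series:
    """Expected total counts per cell: logNormal(lib_loc, lib_scale)."""
    rng = substream(seed, "lib")
    return pd.Series(rng.lognormal(sc.lib_loc, sc.lib_scale, size=len(cell_ids)),
                     index=list(cell_ids), name="library_size")


def compute_cell_means(pm: PopMeans, design: CellDesign,
                       batch_factors: pd.DataFrame,
                       lib_sizes: pd.Series) -> np.ndarray:
    """Per-cell expected means: popmeans x batch factor, rescaled to L_c."""
    ind_col = {i: j for j, i in enumerate(pm.individual_ids)}
    grp_col = {g: k for k, g in enumerate(pm.groups)}
    cells = design.cells
    j = cells["individual"].map(ind_col).to_numpy()
    g = cells["group"].map(grp_col).to_numpy()
    bf = batch_factors[cells["batch"]].to_numpy()  # genes x cells
    mu = pm.values[:, j, g] * bf
    colsum = mu.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("a cell has zero total expected expression")
    mu *= lib_sizes.loc[cells["cell_id"]].to_numpy() / colsum
    return mu


def sample_counts(cell_means: np.ndarray, sc: SCParams, seed: int = 0,
                  chisq_per_gene: bool = True) -> sparse.csr_matrix:
    """Gamma-Poisson counts with BCV-inflated means.

    Per gene i and cell c the effective BCV is
    B_ic = (bcv_common + 1 / sqrt(mu_ic)) * sqrt(bcv_df / X_i),
    X_i ~ chi-square(bcv_df) drawn once per gene (or per entry when
    ``chisq_per_gene`` is False); the mean is mixed through
    mu' ~ gamma(shape 1/B^2, scale mu B^2) and the count is Poisson(mu').
    """
    mu = np.asarray(cell_means, dtype=float)
    if np.any(mu < 0):
        raise ValueError("cell means must be >= 0")
    rng = substream(seed, "counts")
    n_genes, n_cells = mu.shape
    if chisq_per_gene:
        chisq = rng.chisquare(sc.bcv_df, size=n_genes)
    blocks = []
    for start in range(0, n_cells, _CELL_CHUNK):
        m = mu[:, start:start + _CELL_CHUNK]
        if not chisq_per_gene:
            chi = rng.chisquare(sc.bcv_df, size=m.shape)
        else:
            chi = chisq[:, None]
        pos = m > 0
        counts = np.zeros(m.shape, dtype=np.int64)
        if pos.any():
            mpos = m[pos]
            scale_chi = np.broadcast_to(np.sqrt(sc.bcv_df / chi), m.shape)[pos]
            bcv = (sc.bcv_common + 1.0 / np.sqrt(mpos)) * scale_chi
            b2 = bcv * bcv
            trended = rng.gamma(1.0 / b2, mpos * b2)
            counts[pos] = rng.poisson(trended)
        blocks.append(sparse.csr_matrix(counts))
    out = sparse.hstack(blocks, format="csr")
    out.sort_indices()
    return out


def apply_dropout(counts: sparse.csr_matrix, cell_means: np.ndarray,
                  sc: SCParams, seed: int = 0) -> sparse.csr_matrix:
    """Zero entries with probability expit(dropout_shape * (ln mu - mid)).

    With the conventional negative shape, the probability of keeping a count
    is an increasing logistic function of the log expected mean. Structural
    zeros stay zero; a no-op when dropout is disabled.
    """
    if not sc.dropout_enabled:
        return counts
    from scipy.special import expit

    rng = substream(seed, "dropout")
    coo = counts.tocoo()
    mu = cell_means[coo.row, coo.col]
    with np.errstate(divide="ignore"):
        drop_p = expit(sc.dropout_shape * (np.log(mu) - sc.dropout_mid))
    keep = rng.random(drop_p.size) >= drop_p
    out = sparse.csr_matrix((coo.data[keep], (coo.row[keep], coo.col[keep])),
                            shape=counts.shape, dtype=counts.dtype)
    out.sort_indices()
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(params: ParameterSet, G: GenotypeMatrix | None = None,
             genes: GeneAnnotation | None = None,
             empirical_means: pd.DataFrame | None = None,
             n_snps: int | None = None, chrom_length: int = 20_000_000,
             keep_intermediates: bool = False) -> CountBundle:
    """Run the full pipeline and return counts with ground truth attached.

    When genotypes or gene annotation are omitted they are simulated
    (unstructured Binomial dosages; uniform gene anchors on one chromosome).
    ``empirical_means`` switches on replication mode: the provided matrix
    replaces the sampled baseline means and its individual/gene ids
    propagate to all outputs.
    """
    seed = params.design.master_seed
    design_params = params.design

    def stage(name):
        logger.info("stage %s (seed %d)", name, seed)

    try:
        if empirical_means is not None:
            gene_ids = [str(g) for g in empirical_means.index]
            individual_ids = [str(c) for c in empirical_means.columns]
            if len(individual_ids) != design_params.n_individuals:
                design_params = type(design_params)(
                    **{**design_params.__dict__,
                       "n_individuals": len(individual_ids)})
            n_genes = len(gene_ids)
        else:
            n_genes = params.sc.n_genes
            gene_ids = None
            individual_ids = [f"i{j + 1}"
                              for j in range(design_params.n_individuals)]

        stage("genotypes")
        if genes is None:
            genes = simulate_annotation(n_genes, chrom_length, seed)
            if gene_ids is not None:
                genes = GeneAnnotation(gene_ids=gene_ids, chrom=genes.chrom,
                                       pos=genes.pos)
        if gene_ids is None:
            gene_ids = list(genes.gene_ids)
        if G is None:
            G = simulate_genotypes(
                n_snps if n_snps is not None else 10 * n_genes,
                design_params.n_individuals,
                maf_range=(params.eqtl.maf_min, params.eqtl.maf_max),
                chrom_length=chrom_length, seed=seed,
                chrom=str(genes.chrom[0]))
            G = GenotypeMatrix(snp_ids=G.snp_ids, chrom=G.chrom, pos=G.pos,
                               dosage=G.dosage, sample_ids=individual_ids)
        else:
            G = filter_genotypes(G, maf_min=0.0)
            missing = [i for i in individual_ids if i not in G.sample_ids]
            if missing:
                raise ValueError(f"no genotypes for individuals {missing[:5]}")

        stage("design")
        design = build_design(design_params, individual_ids, seed)
        condition_of = dict(zip(design.cells["individual"],
                                design.cells["condition"]))
        groups = design_params.group_names

        stage("eqtl-assignment")
        assignments = assign_eqtl(
            genes, G, params.eqtl, seed=seed, groups=groups,
            conditions=design_params.condition_names) \
            if params.eqtl.eqtl_prob > 0 else []

        stage("population-means")
        if empirical_means is not None:
            baseline = use_empirical_means(
                empirical_means, bulk_derived=params.pop.bulk_derived,
                sc=params.sc, eqtl_requested=bool(assignments))
            base_means = baseline.mean(axis=1).to_numpy()
            flags = np.zeros(n_genes, dtype=bool)
            factors = np.ones(n_genes)
            cvs = (baseline.std(axis=1, ddof=1)
                   / baseline.mean(axis=1).replace(0, np.nan)).fillna(0.0) \
                .to_numpy()
        else:
            base_means, flags, factors = sample_base_means(
                params.pop, params.sc, n_genes, seed)
            cvs = sample_variances(base_means, params.pop, seed)
            baseline = sample_individual_means(base_means, cvs,
                                               individual_ids, seed)
            baseline.index = pd.Index(gene_ids, name="gene_id")
            if params.pop.bulk_derived:
                baseline = quantile_normalize(baseline, params.sc)

        pm = apply_eqtl(baseline, assignments, G, groups=groups,
                        condition_of=condition_of)
        pm, de_factors, cde_factors = apply_de(pm, params.de, seed)
        key = build_sim_key(gene_ids, base_means, flags, factors, cvs,
                            assignments, de_factors, cde_factors, baseline,
                            condition_of, annotation=genes)

        stage("cell-simulation")
        batch_factors = sample_batch_factors(
            n_genes, design.batches, design_params.batch_loc,
            design_params.batch_scale, seed)
        lib_sizes = sample_library_sizes(design.cells["cell_id"], params.sc,
                                         seed)
        cell_means = compute_cell_means(pm, design, batch_factors, lib_sizes)
        counts = sample_counts(cell_means, params.sc, seed)
        counts = apply_dropout(counts, cell_means, params.sc, seed)
    except Exception as err:
        raise type(err)(f"simulation failed: {err}") from err

    intermediates = {}
    if keep_intermediates:
        intermediates = {"popmeans": pm, "batch_factors": batch_factors,
                         "library_sizes": lib_sizes, "cell_means": cell_means,
                         "genotypes": G, "annotation": genes}
    cell_meta = design.cells.set_index("cell_id", drop=False)
    return CountBundle(counts=counts, cell_meta=cell_meta, key=key,
                       intermediates=intermediates)
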
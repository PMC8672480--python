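"""Genes x individuals mean-expression layer.

This is the first half of the gamma-Poisson hierarchy: each gene receives a
population-wide mean lambda_i ~ gamma(alpha_m, beta_m) (optionally replaced
by an outlier value), an across-individual coefficient of variation
sigma_i ~ gamma(alpha_v, beta_v * s_v) drawn from its mean bin, and each
individual a baseline mean lambda_ij ~ N(lambda_i, sd = lambda_i * sigma_i).
When the population parameters came from bulk data the baseline means are
quantile normalized per individual to the single-cell gene-mean gamma.
eQTL effects enter as lambda_ij += lambda_ij * G_ij * omega_i on the
targeted group slices / condition cohorts, and group/condition DE effects
multiply by log-normal factors. The per-gene ground truth is retained in a
SimKey sufficient (with genotypes and the master seed) to recreate a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._streams import substream
from .genotypes import EqtlAssignment, GenotypeMatrix, assignments_to_frame
from .params import DEParams, PopParams, SCParams, per_level

logger = logging.getLogger("scpopsim")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PopMeans:
    """Expected means per gene x individual x cell group, after all effects."""

    values: np.ndarray          # (n_genes, n_individuals, n_groups), >= 0
    gene_ids: list[str]
    individual_ids: list[str]
    groups: list[str]
    condition_of: dict[str, str]  # individual -> condition label

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be genes x individuals x groups")
        if np.any(self.values < 0):
            raise ValueError("expected means must be non-negative")

    def slice(self, group: str) -> pd.DataFrame:
        g = self.groups.index(group)
        return pd.DataFrame(self.values[:, :, g], index=self.gene_ids,
                            columns=self.individual_ids)

    def to_tsv(self, path) -> None:
        frames = []
        for g, name in enumerate(self.groups):
            df = self.slice(name).copy()
            df.insert(0, "group", name)
            frames.append(df)
        pd.concat(frames).rename_axis("gene_id").to_csv(path, sep="\t")


@dataclass
class SimKey:
    """Per-gene and per-individual ground truth of one simulation."""

    gene_key: pd.DataFrame        # indexed by gene_id
    individual_key: pd.DataFrame  # indexed by individual, column "condition"
    baseline_means: pd.DataFrame  # genes x individuals, pre-effect means

    def __post_init__(self) -> None:
        if not self.gene_key.index.equals(self.baseline_means.index):
            raise ValueError("gene_key and baseline_means must share gene order")

    @property
    def egenes(self) -> pd.Index:
        return self.gene_key.index[self.gene_key["eqtl_snp"] != ""]

    def to_tsv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        merged = self.gene_key.join(
            self.baseline_means.add_prefix("mean_"))
        merged.rename_axis("gene_id").to_csv(directory / "key.tsv", sep="\t")
        self.individual_key.rename_axis("individual").to_csv(
            directory / "individuals.tsv", sep="\t")

    @classmethod
    def from_tsv(cls, directory) -> "SimKey":
        directory = Path(directory)
        merged = pd.read_csv(directory / "key.tsv", sep="\t",
                             index_col="gene_id",
                             keep_default_na=False, dtype={"chrom": str})
        mean_cols = [c for c in merged.columns if c.startswith("mean_")]
        baseline = merged[mean_cols].copy()
        baseline.columns = [c[len("mean_"):] for c in mean_cols]
        gene_key = merged.drop(columns=mean_cols)
        ind_key = pd.read_csv(directory / "individuals.tsv", sep="\t",
                              index_col="individual", keep_default_na=False)
        return cls(gene_key=gene_key, individual_key=ind_key,
                   baseline_means=baseline.astype(float))


# ---------------------------------------------------------------------------
# Sampling operations
# ---------------------------------------------------------------------------

def sample_base_means(pop: PopParams, sc: SCParams, n_genes: int,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample population-wide gene means with optional outlier replacement.

    Returns (means, outlier_flags, outlier_factors); non-outliers carry a
    factor of 1. An outlier gene's mean becomes median(means) * factor with
    factor ~ logNormal(out_loc, out_scale).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = substream(seed, "means")
    means = rng.gamma(pop.mean_shape, 1.0 / pop.mean_rate, size=n_genes)
    flags = rng.random(n_genes) < sc.out_prob
    factors = np.ones(n_genes)
    if flags.any():
        factors[flags] = rng.lognormal(sc.out_loc, sc.out_scale,
                                       size=int(flags.sum()))
        means = means.copy()
        means[flags] = np.median(means) * factors[flags]
    return means, flags, factors


def _bin_of(means: np.ndarray, pop: PopParams) -> np.ndarray:
    edges = np.asarray(pop.bin_edges, dtype=float)
    if edges.size == 0:
        raise ValueError("PopParams.bin_edges is empty; estimate or use defaults")
    # Genes outside every bin use the nearest (first/last) bin.
    return np.clip(np.searchsorted(edges, means, side="right") - 1,
                   0, pop.n_bins - 1)


def sample_variances(means: np.ndarray, pop: PopParams, seed: int = 0) -> np.ndarray:
    """Sample each gene's across-individual cv from its mean-bin gamma.

    The rate of the bin's gamma is multiplied by the similarity scale s_v,
    so larger s_v shrinks the cv and makes individuals more alike.
    """
    rng = substream(seed, "variances")
    bins = _bin_of(np.asarray(means, dtype=float), pop)
    shapes = np.asarray(pop.cv_shape_per_bin, dtype=float)[bins]
    rates = np.asarray(pop.cv_rate_per_bin, dtype=float)[bins] * pop.similarity_scale
    return rng.gamma(shapes, 1.0 / rates)


def sample_individual_means(means: np.ndarray, cvs: np.ndarray,
                            individual_ids: Sequence[str],
                            seed: int = 0) -> pd.DataFrame:
    """Baseline per-individual means: N(lambda_i, sd = lambda_i * sigma_i).

    sigma_i is a coefficient of variation, so lambda_i * sigma_i is the
    standard deviation of the normal. Negative draws are floored at 0.
    """
    means = np.asarray(means, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if means.shape != cvs.shape:
        raise ValueError("means and cvs must be aligned by gene")
    rng = substream(seed, "individuals")
    n_ind = len(individual_ids)
    draws = rng.normal(loc=means[:, None],
                       scale=(means * cvs)[:, None],
                       size=(means.size, n_ind))
    np.maximum(draws, 0.0, out=draws)
    return pd.DataFrame(draws,
                        index=[f"gene{i + 1}" for i in range(means.size)],
                        columns=list(individual_ids))


def quantile_normalize(means: pd.DataFrame | np.ndarray,
                       sc: SCParams) -> pd.DataFrame | np.ndarray:
    """Map each individual's means onto gamma(alpha_sc, beta_sc) quantiles.

    Column-wise: values are replaced by the gamma quantile at plotting
    position (rank - 0.5) / n_genes, with average ranks for ties, so the
    within-column order is preserved exactly.
    """
    values = means.to_numpy(dtype=float) if isinstance(means, pd.DataFrame) \
        else np.asarray(means, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("quantile normalization needs >= 2 genes")
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = stats.gamma.ppf((ranks - 0.5) / n, sc.mean_shape,
                                    scale=1.0 / sc.mean_rate)
    if isinstance(means, pd.DataFrame):
        return pd.DataFrame(out, index=means.index, columns=means.columns)
    return out


def use_empirical_means(matrix: pd.DataFrame, bulk_derived: bool = True,
                        sc: SCParams | None = None,
                        eqtl_requested: bool = False) -> pd.DataFrame:
    """Replication mode: use an empirical genes x individuals matrix directly.

    Skips the mean/cv/individual sampling; quantile normalization to the
    single-cell gamma is still applied when the matrix is bulk-derived and
    single-cell parameters are available. Requesting simulated eQTL effects
    on top of empirical means is allowed but warned about, since effects
    already present in the data will compound with the simulated ones.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if (matrix.to_numpy() < 0).any():
        raise ValueError("empirical means must be non-negative")
    if eqtl_requested:
        logger.warning("replication mode with simulated eQTL effects: simulated "
                       "effects may compound with eQTL already in the data")
    if bulk_derived and sc is not None:
        return quantile_normalize(matrix, sc)
    return matrix.astype(float)


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------

def _as_popmeans(means: pd.DataFrame, groups: Sequence[str],
                 condition_of: dict[str, str]) -> PopMeans:
    tensor = np.repeat(means.to_numpy(dtype=float)[:, :, None],
                       len(groups), axis=2)
    return PopMeans(values=tensor, gene_ids=[str(g) for g in means.index],
                    individual_ids=[str(c) for c in means.columns],
                    groups=list(groups), condition_of=dict(condition_of))


def apply_eqtl(means: pd.DataFrame, key: Sequence[EqtlAssignment],
               G: GenotypeMatrix, groups: Sequence[str] = ("g1",),
               condition_of: dict[str, str] | None = None) -> PopMeans:
    """Add eQTL effects: lambda_ij += lambda_ij * G_ij * omega_i.

    Global effects touch every group slice and individual; "group:<g>"
    effects only that slice; "condition:<c>" effects only the columns of
    individuals in that cohort (in every slice).
    """
    individuals = [str(c) for c in means.columns]
    if condition_of is None:
        condition_of = {ind: "c1" for ind in individuals}
    missing = [i for i in individuals if i not in G.sample_ids]
    if missing:
        raise ValueError(f"individuals missing from genotypes: {missing[:5]}")
    pm = _as_popmeans(means, groups, condition_of)
    gene_row = {g: i for i, g in enumerate(pm.gene_ids)}
    snp_row = {s: i for i, s in enumerate(G.snp_ids)}
    col_of = [G.sample_ids.index(i) for i in individuals]
    for a in key:
        if a.gene_id not in gene_row:
            raise ValueError(f"eQTL key names unknown gene {a.gene_id!r}")
        if a.snp_id not in snp_row:
            raise ValueError(f"eSNP {a.snp_id!r} not present in genotypes")
        dosage = G.dosage[snp_row[a.snp_id]][col_of].astype(float)
        bump = 1.0 + dosage * a.beta          # per-individual multiplier
        i = gene_row[a.gene_id]
        if a.specificity == "global":
            pm.values[i] *= bump[:, None]
        elif a.specificity.startswith("group:"):
            g = pm.groups.index(a.specificity.split(":", 1)[1])
            pm.values[i, :, g] *= bump
        elif a.specificity.startswith("condition:"):
            cohort = a.specificity.split(":", 1)[1]
            in_cohort = np.array([condition_of[ind] == cohort
                                  for ind in individuals])
            pm.values[i, in_cohort, :] *= bump[in_cohort, None]
        else:  # pragma: no cover - guarded by EqtlAssignment validation
            raise ValueError(f"bad specificity {a.specificity!r}")
    return pm


def apply_de(pm: PopMeans, de: DEParams, seed: int = 0
             ) -> tuple[PopMeans, pd.DataFrame, pd.DataFrame]:
    """Apply group and condition DE factors; returns (means, de, cde factors).

    Per group g, a Bernoulli(de_prob[g]) mask selects DE genes; each gets a
    factor f ~ logNormal(de_loc[g], de_scale[g]), inverted to 1/f with
    probability de_down_prob[g], multiplying that group's slice. Condition
    factors are drawn per cohort the same way and multiply the columns of
    member individuals across all slices. Non-selected genes keep factor 1.
    """
    rng = substream(seed, "de")
    n_genes = len(pm.gene_ids)
    groups = pm.groups
    conditions = sorted(set(pm.condition_of.values()))

    de_prob = per_level(de.de_prob, len(groups), "de_prob")
    de_down = per_level(de.de_down_prob, len(groups), "de_down_prob")
    de_loc = per_level(de.de_loc, len(groups), "de_loc")
    de_scale = per_level(de.de_scale, len(groups), "de_scale")
    de_factors = pd.DataFrame(1.0, index=pm.gene_ids, columns=groups)
    if len(groups) > 1:
        for g, name in enumerate(groups):
            mask = rng.random(n_genes) < de_prob[g]
            f = rng.lognormal(de_loc[g], de_scale[g], size=int(mask.sum()))
            down = rng.random(f.size) < de_down[g]
            f[down] = 1.0 / f[down]
            de_factors.loc[mask, name] = f
            pm.values[mask, :, g] *= f[:, None]

    cde_prob = per_level(de.cde_prob, len(conditions), "cde_prob")
    cde_down = per_level(de.cde_down_prob, len(conditions), "cde_down_prob")
    cde_loc = per_level(de.cde_loc, len(conditions), "cde_loc")
    cde_scale = per_level(de.cde_scale, len(conditions), "cde_scale")
    cde_factors = pd.DataFrame(1.0, index=pm.gene_ids, columns=conditions)
    if len(conditions) > 1:
        member = {c: np.array([pm.condition_of[i] == c
                               for i in pm.individual_ids])
                  for c in conditions}
        for k, cname in enumerate(conditions):
            mask = rng.random(n_genes) < cde_prob[k]
            f = rng.lognormal(cde_loc[k], cde_scale[k], size=int(mask.sum()))
            down = rng.random(f.size) < cde_down[k]
            f[down] = 1.0 / f[down]
            cde_factors.loc[mask, cname] = f
            cols = member[cname]
            pm.values[np.ix_(mask, cols)] *= f[:, None, None]
    return pm, de_factors, cde_factors


# ---------------------------------------------------------------------------
# Key assembly
# ---------------------------------------------------------------------------

def build_sim_key(gene_ids: Sequence[str], base_means: np.ndarray,
                  outlier_flags: np.ndarray, outlier_factors: np.ndarray,
                  cvs: np.ndarray, assignments: Sequence[EqtlAssignment],
                  de_factors: pd.DataFrame, cde_factors: pd.DataFrame,
                  baseline_means: pd.DataFrame,
                  condition_of: dict[str, str],
                  annotation=None) -> SimKey:
    """Collect the per-gene ground truth into a SimKey."""
    gene_ids = [str(g) for g in gene_ids]
    key = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    if annotation is not None:
        key["chrom"] = annotation.chrom
        key["pos"] = annotation.pos
    key["base_mean"] = np.asarray(base_means, dtype=float)
    key["outlier"] = np.asarray(outlier_flags, dtype=bool)
    key["outlier_factor"] = np.asarray(outlier_factors, dtype=float)
    key["cv"] = np.asarray(cvs, dtype=float)
    eq = assignments_to_frame(assignments).set_index("gene_id") \
        if len(assignments) else pd.DataFrame(
            columns=["snp_id", "beta", "specificity", "coreg_partner"])
    key["eqtl_snp"] = eq["snp_id"].reindex(gene_ids).fillna("").astype(str)
    key["eqtl_beta"] = pd.to_numeric(eq["beta"].reindex(gene_ids),
                                     errors="coerce").fillna(0.0)
    key["eqtl_specificity"] = eq["specificity"].reindex(gene_ids) \
        .fillna("").astype(str)
    key["coreg_partner"] = eq["coreg_partner"].reindex(gene_ids) \
        .fillna("").astype(str)
    for col in de_factors.columns:
        key[f"de_factor_{col}"] = de_factors[col].to_numpy()
    for col in cde_factors.columns:
        key[f"cde_factor_{col}"] = cde_factors[col].to_numpy()
    ind_key = pd.DataFrame(
        {"condition": [condition_of[i] for i in baseline_means.columns]},
        index=pd.Index([str(c) for c in baseline_means.columns],
                       name="individual"))
    baseline = baseline_means.copy()
    baseline.index = pd.Index(gene_ids, name="gene_id")
    return SimKey(gene_key=key, individual_key=ind_key,
                  baseline_means=baseline)
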
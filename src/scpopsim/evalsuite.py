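"""Evaluation of simulated data: aggregation, comparison metrics, and
simplified DE / cis-eQTL discovery pipelines scored against the ground truth.

The eQTL mapper is deliberately lightweight: mean-aggregated counts are
rank-inverse-normal transformed per gene and each cis SNP (within a
symmetric window around the gene anchor) is tested with an ordinary
least-squares fit; the top SNP per gene is taken and Benjamini-Hochberg
correction is applied across genes. No kinship or expression-PC covariates
are included, which is appropriate for unstructured synthetic genotypes; an
optional covariate hook residualizes both sides before the per-SNP fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .genotypes import GeneAnnotation, GenotypeMatrix

logger = logging.getLogger("scpopsim")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregatedMatrix:
    """Genes x individuals aggregate of single-cell counts."""

    values: pd.DataFrame
    method: str  # "mean", "sum" or "meanlog"

    @property
    def individuals(self) -> list[str]:
        return [str(c) for c in self.values.columns]


def aggregate(counts, cell_to_individual, method: str = "mean",
              gene_ids=None) -> AggregatedMatrix:
    """Aggregate genes x cells counts per individual.

    ``method`` is "mean" (mean of counts), "sum" (pseudobulk), or "meanlog"
    (mean of log1p counts).
    """
    if method not in ("mean", "sum", "meanlog"):
        raise ValueError(f"unknown aggregation method {method!r}")
    mapping = pd.Series(cell_to_individual)
    if isinstance(counts, pd.DataFrame):
        gene_ids = list(counts.index)
        mat = sparse.csr_matrix(counts.to_numpy())
        mapping.index = pd.RangeIndex(len(mapping))
    else:
        mat = sparse.csr_matrix(counts)
        mapping = mapping.reset_index(drop=True)
    if mapping.size != mat.shape[1] or mapping.isna().any():
        raise ValueError("every cell must map to an individual")
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(mat.shape[0])]

    individuals = list(pd.unique(mapping))
    onehot = sparse.csr_matrix(
        (np.ones(mapping.size),
         (np.arange(mapping.size),
          mapping.map({ind: k for k, ind in enumerate(individuals)}))),
        shape=(mapping.size, len(individuals)))
    src = mat.copy()
    if method == "meanlog":
        src.data = np.log1p(src.data.astype(float))
    agg = np.asarray((src @ onehot).todense(), dtype=float)
    if method in ("mean", "meanlog"):
        agg /= np.asarray(onehot.sum(axis=0)).ravel()
    return AggregatedMatrix(
        values=pd.DataFrame(agg, index=gene_ids, columns=individuals),
        method=method)


# ---------------------------------------------------------------------------
# Comparison metrics
# ---------------------------------------------------------------------------

def variance_explained(logcounts, factor_labels) -> pd.Series:
    """Per-gene percentage of variance explained by a categorical factor.

    One-way group-mean decomposition: 100 x between-group SS / total SS.
    Constant genes return 0 by convention.
    """
    if isinstance(logcounts, pd.DataFrame):
        values = logcounts.to_numpy(dtype=float)
        index = logcounts.index
    else:
        values = np.asarray(logcounts, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    labels = np.asarray(factor_labels)
    if labels.size != values.shape[1]:
        raise ValueError("one label per column required")
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("factor needs >= 2 levels")
    grand = values.mean(axis=1, keepdims=True)
    total_ss = ((values - grand) ** 2).sum(axis=1)
    between_ss = np.zeros_like(total_ss)
    for lev in levels:
        cols = labels == lev
        gm = values[:, cols].mean(axis=1)
        between_ss += cols.sum() * (gm - grand.ravel()) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(total_ss > 0, between_ss / total_ss, 0.0)
    return pd.Series(100.0 * r2, index=index, name="pct_variance_explained")


def silhouette_widths(logcounts, cluster_labels) -> pd.Series:
    """Per-cell silhouette widths, Euclidean distance on columns (cells)."""
    from sklearn.metrics import silhouette_samples

    if isinstance(logcounts, pd.DataFrame):
        X = logcounts.to_numpy(dtype=float).T
        index = logcounts.columns
    else:
        X = np.asarray(logcounts, dtype=float).T
        index = pd.RangeIndex(X.shape[0])
    labels = np.asarray(cluster_labels)
    if len(pd.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    widths = silhouette_samples(X, labels, metric="euclidean")
    return pd.Series(widths, index=index, name="silhouette_width")


# ---------------------------------------------------------------------------
# Discovery pipelines
# ---------------------------------------------------------------------------

def de_test_pseudobulk(counts, cell_to_individual, condition_labels,
                       gene_ids=None) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two conditions on pseudobulk counts.

    Counts are sum-aggregated per individual, individuals are split by
    condition, a two-sided rank-sum test is run per gene, and p-values are
    Benjamini-Hochberg adjusted across genes.
    """
    pseudo = aggregate(counts, cell_to_individual, method="sum",
                       gene_ids=gene_ids)
    cond = pd.Series(condition_labels)
    cond.index = cond.index.map(str)
    cond = cond.reindex(pseudo.individuals)
    if cond.isna().any():
        raise ValueError("every individual needs a condition label")
    levels = pd.unique(cond)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {len(levels)}")
    a_cols = cond[cond == levels[0]].index
    b_cols = cond[cond == levels[1]].index
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 individuals per condition")
    A = pseudo.values[a_cols].to_numpy()
    B = pseudo.values[b_cols].to_numpy()
    res = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided",
                             method="auto")
    pvals = np.asarray(res.pvalue, dtype=float)
    qvals = stats.false_discovery_control(pvals, method="bh")
    lfc = np.log2((A.mean(axis=1) + 1.0) / (B.mean(axis=1) + 1.0))
    return pd.DataFrame({"p": pvals, "q": qvals, "log2fc": lfc},
                        index=pseudo.values.index)


def _inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, row-wise, (rank - 0.5)/n positions."""
    out = np.empty_like(values, dtype=float)
    n = values.shape[1]
    for i in range(values.shape[0]):
        ranks = stats.rankdata(values[i], method="average")
        out[i] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def _fit_multiplicative_effect(y: np.ndarray, dosage: np.ndarray) -> float:
    """Effect size of a multiplicative cis effect y = lambda * (1 + G * omega).

    Chooses omega minimizing the squared coefficient of variation of the
    dosage-deflated values y / (1 + G * omega); at the true omega the
    deflated values recover the baseline and their relative spread is
    smallest. Exact for noise-free multiplicative relationships.
    """
    from scipy import optimize

    x = dosage.astype(float)

    def deflated_cv2(om):
        z = y / (1.0 + max(om, -0.49) * x)
        m = z.mean()
        return z.var() / (m * m) if m > 0 else np.inf

    res = optimize.minimize_scalar(deflated_cv2, bounds=(-0.4, 10.0),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def map_eqtl_simple(agg: AggregatedMatrix, G: GenotypeMatrix,
                    genes: GeneAnnotation, window_bp: float = 100_000,
                    covariates: np.ndarray | None = None) -> pd.DataFrame:
    """Per-gene top cis-SNP association with BH correction across genes.

    For each gene, all SNPs within ``window_bp`` of the gene anchor are
    tested by OLS of the rank-inverse-normal transformed aggregate on
    dosage. The top SNP (smallest p) is recorded; its p-value is corrected
    for the number of cis SNPs tested (Sidak, ``p_gene``) and BH correction
    across genes runs on the corrected values. The reported ``beta`` is the
    multiplicative effect size at the top SNP (the scale on which cis
    effects act on expression); ``beta_int`` keeps the OLS slope on the
    transformed scale. Genes with no cis SNP are skipped (``skipped``
    column).
    """
    individuals = agg.individuals
    n = len(individuals)
    if n < 20:
        logger.warning("map_eqtl_simple: only %d individuals; estimates will "
                       "be noisy below ~20", n)
    missing = [i for i in individuals if i not in G.sample_ids]
    if missing:
        raise ValueError(f"individuals missing from genotypes: {missing[:5]}")
    cols = [G.sample_ids.index(i) for i in individuals]
    dosage = G.dosage[:, cols].astype(float)

    expr = agg.values.to_numpy(dtype=float)
    y_all = _inverse_normal(expr)
    if covariates is not None:
        C = np.column_stack([np.ones(n), covariates])
        proj = C @ np.linalg.pinv(C)
        y_all = y_all - y_all @ proj.T
        dosage = dosage - dosage @ proj.T

    raw_expr = agg.values.to_numpy(dtype=float)
    anchor = dict(zip(genes.gene_ids, zip(genes.chrom, genes.pos)))
    rows = []
    n_skipped = 0
    for gi, gene in enumerate(agg.values.index):
        gene = str(gene)
        if gene not in anchor:
            raise ValueError(f"gene {gene!r} missing from the annotation")
        chrom, pos = anchor[gene]
        cis = np.flatnonzero((G.chrom == chrom)
                             & (np.abs(G.pos - pos) <= window_bp))
        y = y_all[gi]
        if cis.size == 0 or y.std() == 0:
            n_skipped += 1
            rows.append((gene, "", np.nan, np.nan, np.nan, np.nan, 0, True))
            continue
        X = dosage[cis]
        xm = X - X.mean(axis=1, keepdims=True)
        ym = y - y.mean()
        sxx = (xm ** 2).sum(axis=1)
        ok = sxx > 0
        sxy = xm @ ym
        syy = float((ym ** 2).sum())
        beta_int = np.full(cis.size, np.nan)
        pv = np.full(cis.size, np.nan)
        beta_int[ok] = sxy[ok] / sxx[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            rss = np.maximum(syy - beta_int[ok] * sxy[ok], 0.0)
            se = np.sqrt(rss / (n - 2) / sxx[ok])
            tstat = np.where(se > 0, beta_int[ok] / se, np.inf)
        pv[ok] = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        if not np.any(np.isfinite(pv)):
            n_skipped += 1
            rows.append((gene, "", np.nan, np.nan, np.nan, np.nan, 0, True))
            continue
        top = int(np.nanargmin(pv))
        n_tested = int(np.isfinite(pv).sum())
        p_top = float(pv[top])
        p_gene = float(-np.expm1(n_tested * np.log1p(-min(p_top, 1.0))))
        beta = _fit_multiplicative_effect(raw_expr[gi], dosage[cis[top]])
        rows.append((gene, G.snp_ids[cis[top]], beta, float(beta_int[top]),
                     p_top, p_gene, n_tested, False))
    if n_skipped:
        logger.info("map_eqtl_simple: skipped %d genes without testable cis "
                    "SNPs", n_skipped)
    out = pd.DataFrame(rows, columns=["gene_id", "snp_id", "beta", "beta_int",
                                      "p", "p_gene", "n_cis", "skipped"]
                       ).set_index("gene_id")
    tested = ~out["skipped"]
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = stats.false_discovery_control(
            out.loc[tested, "p_gene"].to_numpy(), method="bh")
    out["q"] = q
    return out


@dataclass
class ConfusionSummary:
    """Confusion counts and TPR/FDR of a discovery set against the truth."""

    tp: int
    tn: int
    fp: int
    fn: int
    fdr_defined: bool = True

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"TP": self.tp, "TN": self.tn, "FP": self.fp,
                              "FN": self.fn, "TPR": self.tpr, "FDR": self.fdr,
                              "fdr_defined": self.fdr_defined}])


def run_eqtl_experiment(seed: int, n_genes: int = 504,
                        n_individuals: int = 100,
                        cells_per_individual: int = 80,
                        eqtl_prob: float = 0.7, n_snps: int = 10_000,
                        window_bp: float = 100_000.0,
                        q_threshold: float = 0.05) -> dict:
    """Simulate, map cis-eQTL and score one power experiment.

    Simulates unstructured genotypes and counts under the default
    parameters (eGene-eSNP distance capped at the mapping window so every
    planted effect is discoverable), mean-aggregates per individual, runs
    the simplified mapper, and returns the per-gene results plus the
    confusion summary and the Pearson correlation between estimated and
    simulated effect sizes among true-positive eGenes.
    """
    from .cellsim import simulate
    from .params import default_params

    ps = default_params().with_overrides({
        "sc.n_genes": n_genes, "design.n_individuals": n_individuals,
        "design.cells_per_individual": cells_per_individual,
        "eqtl.eqtl_prob": eqtl_prob, "eqtl.dist_max": float(window_bp),
        "design.master_seed": int(seed)})
    bundle = simulate(ps, n_snps=n_snps, keep_intermediates=True)
    agg = aggregate(bundle.counts, bundle.cell_meta["individual"].to_numpy(),
                    method="mean", gene_ids=bundle.gene_ids)
    results = map_eqtl_simple(agg, bundle.intermediates["genotypes"],
                              bundle.intermediates["annotation"],
                              window_bp=window_bp)
    confusion = score_discoveries(bundle.key.egenes, results, q_threshold)
    key = bundle.key.gene_key
    sig = results.index[results["q"].fillna(1.0) < q_threshold]
    tp = [g for g in sig if key.loc[g, "eqtl_snp"] != ""]
    r_tp = float(np.corrcoef(results.loc[tp, "beta"],
                             key.loc[tp, "eqtl_beta"])[0, 1]) \
        if len(tp) >= 3 else float("nan")
    return {"bundle": bundle, "results": results, "confusion": confusion,
            "true_positives": tp, "r_tp": r_tp}


def score_discoveries(truth_positives, calls: pd.DataFrame,
                      q_threshold: float = 0.05,
                      q_column: str = "q") -> ConfusionSummary:
    """Confusion summary of q-thresholded calls against true positive genes.

    ``calls`` must be indexed by gene and carry a q-value column; the truth
    is the set of genes simulated with an effect. Genes with NaN q (skipped)
    count as negative calls. With zero positive calls the FDR is undefined
    and reported as 0 with ``fdr_defined=False``.
    """
    truth = set(map(str, truth_positives))
    genes = set(map(str, calls.index))
    if not truth <= genes:
        raise ValueError("truth contains genes absent from the calls")
    sig = set(map(str, calls.index[calls[q_column].fillna(1.0) < q_threshold]))
    tp = len(sig & truth)
    fp = len(sig - truth)
    fn = len(truth - sig)
    tn = len(genes) - tp - fp - fn
    return ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn,
                            fdr_defined=bool(tp + fp))
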
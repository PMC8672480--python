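"""Model parameters: domain types, estimation from reference data, defaults.

The simulator is parameterised by five families:

* single-cell parameters (library size, gene-mean gamma, expression outliers,
  biological coefficient of variation, dropout) describing one homogeneous
  cell population from one donor;
* population parameters (gamma of population-wide gene means, and per
  mean-bin gammas for the coefficient of variation of a gene's mean across
  individuals) describing inter-individual variability;
* eQTL parameters (effect-size gamma plus the knobs controlling how variants
  are paired with genes);
* differential-expression parameters for cell groups and condition cohorts;
* experimental-design parameters (individuals, cells, batches, groups,
  cohorts, master seed).

Each family can be estimated from user data or taken from embedded defaults.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

logger = logging.getLogger("scpopsim")

# Estimation constants (documented, overridable through function arguments).
WINSOR_Q = 0.10          # upper/lower quantile winsorized before the gene-mean fit
OUTLIER_MADS = 2.0       # MAD multiplier above the median log-mean flagging outliers
LOW_EXPR_THRESHOLD = 0.1  # population filter: expression below this ...
LOW_EXPR_MAX_FRAC = 0.5   # ... in more than this fraction of individuals drops a gene


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def _check_pos(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value}")


@dataclass
class SCParams:
    """Single-cell level parameters (one donor, homogeneous cells)."""

    n_genes: int = 1000
    mean_shape: float = 0.6    # alpha_sc: gamma shape of single-cell gene means
    mean_rate: float = 0.3     # beta_sc: gamma rate
    lib_loc: float = 11.0      # log-normal location of library sizes
    lib_scale: float = 0.2     # log-normal scale of library sizes
    out_prob: float = 0.05     # probability a gene is an expression outlier
    out_loc: float = 4.0       # log-normal location of outlier factors
    out_scale: float = 0.5     # log-normal scale of outlier factors
    bcv_common: float = 0.1    # common biological coefficient of variation
    bcv_df: float = 60.0       # BCV degrees of freedom
    dropout_enabled: bool = False
    dropout_mid: float = 0.0   # logistic midpoint on the ln-mean scale
    dropout_shape: float = -1.0  # logistic slope (negative: high means kept)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        _check_pos(self.mean_shape, "mean_shape")
        _check_pos(self.mean_rate, "mean_rate")
        _check_prob(self.out_prob, "out_prob")
        _check_pos(self.bcv_df, "bcv_df")
        if self.lib_scale < 0 or self.out_scale < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.bcv_common < 0:
            raise ValueError("bcv_common must be >= 0")


@dataclass
class PopParams:
    """Population-scale parameters: gene-mean gamma and binned cv gammas."""

    mean_shape: float = 0.34   # alpha_m
    mean_rate: float = 0.008   # beta_m
    n_bins: int = 10
    bin_edges: list[float] = field(default_factory=list)
    cv_shape_per_bin: list[float] = field(default_factory=list)
    cv_rate_per_bin: list[float] = field(default_factory=list)
    similarity_scale: float = 1.0  # s_v, multiplies the per-bin cv rate
    bulk_derived: bool = True  # whether means need quantile normalization to
    #                            the single-cell gamma before cell simulation

    def __post_init__(self) -> None:
        _check_pos(self.mean_shape, "mean_shape")
        _check_pos(self.mean_rate, "mean_rate")
        _check_pos(self.similarity_scale, "similarity_scale")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.bin_edges:
            edges = np.asarray(self.bin_edges, dtype=float)
            if edges.size != self.n_bins + 1:
                raise ValueError("bin_edges must have n_bins + 1 entries")
            if np.any(np.diff(edges) <= 0):
                raise ValueError("bin_edges must be strictly increasing")
            if (len(self.cv_shape_per_bin) != self.n_bins
                    or len(self.cv_rate_per_bin) != self.n_bins):
                raise ValueError("need one (cv_shape, cv_rate) pair per bin")
            for a, b in zip(self.cv_shape_per_bin, self.cv_rate_per_bin):
                _check_pos(a, "cv_shape")
                _check_pos(b, "cv_rate")


@dataclass
class EqtlParams:
    """eQTL effect-size distribution and assignment controls."""

    es_shape: float = 3.6      # alpha_e: gamma shape of |effect sizes|
    es_rate: float = 12.0      # beta_e: gamma rate
    eqtl_prob: float = 0.5     # fraction of genes assigned an eQTL (eGenes)
    maf_min: float = 0.05      # eSNP minor-allele-frequency bounds
    maf_max: float = 0.5
    dist_max: float = 1_000_000.0  # max eGene-eSNP distance, bp
    coreg_prop: float = 0.0    # fraction of eGenes sharing an eSNP with another
    group_specific_prop: float = 0.2     # fraction of effects applied to one group
    condition_specific_prop: float = 0.2  # fraction applied to one cohort

    def __post_init__(self) -> None:
        _check_pos(self.es_shape, "es_shape")
        _check_pos(self.es_rate, "es_rate")
        for name in ("eqtl_prob", "coreg_prop", "group_specific_prop",
                     "condition_specific_prop"):
            _check_prob(getattr(self, name), name)
        if not (0 < self.maf_min < self.maf_max <= 0.5):
            raise ValueError("require 0 < maf_min < maf_max <= 0.5")
        _check_pos(self.dist_max, "dist_max")


@dataclass
class DEParams:
    """Differential-expression factors for cell groups and condition cohorts.

    Each field is a scalar applied to every group (cohort), or a list with
    one entry per group (cohort).
    """

    de_prob: float | list[float] = 0.1
    de_down_prob: float | list[float] = 0.5
    de_loc: float | list[float] = 0.1       # mu_de
    de_scale: float | list[float] = 0.4     # sigma_de
    cde_prob: float | list[float] = 0.1
    cde_down_prob: float | list[float] = 0.5
    cde_loc: float | list[float] = 0.1
    cde_scale: float | list[float] = 0.4

    def __post_init__(self) -> None:
        for name in ("de_prob", "de_down_prob", "cde_prob", "cde_down_prob"):
            for v in np.atleast_1d(getattr(self, name)):
                _check_prob(float(v), name)
        for name in ("de_scale", "cde_scale"):
            for v in np.atleast_1d(getattr(self, name)):
                if v < 0:
                    raise ValueError(f"{name} must be >= 0")


def per_level(value: float | Sequence[float], n: int, name: str) -> np.ndarray:
    """Broadcast a scalar-or-list DE/batch parameter to one value per level."""
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(n, float(arr[0]))
    if arr.size != n:
        raise ValueError(f"{name} has {arr.size} entries, expected {n}")
    return arr.astype(float)


@dataclass
class DesignParams:
    """Experimental design: individuals, cells, batches, groups, cohorts."""

    n_individuals: int = 10
    cells_per_individual: int = 100
    batch_n_cells: list[int] | None = None  # cells per batch; None = one batch
    batch_size: int | None = None           # individuals per batch; None = all
    batch_loc: float | list[float] = 0.1    # per-batch log-normal factor location
    batch_scale: float | list[float] = 0.1  # per-batch log-normal factor scale
    group_probs: list[float] = field(default_factory=lambda: [1.0])
    condition_probs: list[float] = field(default_factory=lambda: [1.0])
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.cells_per_individual < 1:
            raise ValueError("cells_per_individual must be >= 1")
        for name in ("group_probs", "condition_probs"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if probs.size < 1 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        if self.batch_size is not None and self.batch_size > self.n_individuals:
            raise ValueError("batch_size cannot exceed n_individuals")

    @property
    def n_batches(self) -> int:
        return 1 if self.batch_n_cells is None else len(self.batch_n_cells)

    def resolved_batches(self) -> tuple[list[int], int]:
        """Return (cells per batch, individuals per batch) with defaults filled."""
        if self.batch_n_cells is None:
            cells = [self.n_individuals * self.cells_per_individual]
        else:
            cells = list(self.batch_n_cells)
        size = self.n_individuals if self.batch_size is None else self.batch_size
        return cells, size

    @property
    def group_names(self) -> list[str]:
        return [f"g{i + 1}" for i in range(len(self.group_probs))]

    @property
    def condition_names(self) -> list[str]:
        return [f"c{i + 1}" for i in range(len(self.condition_probs))]


@dataclass
class ParameterSet:
    """All simulator parameters; serializes losslessly to JSON/YAML."""

    sc: SCParams = field(default_factory=SCParams)
    pop: PopParams = field(default_factory=PopParams)
    eqtl: EqtlParams = field(default_factory=EqtlParams)
    de: DEParams = field(default_factory=DEParams)
    design: DesignParams = field(default_factory=DesignParams)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {"sc": SCParams, "pop": PopParams, "eqtl": EqtlParams,
                 "de": DEParams, "design": DesignParams}
        kwargs = {}
        for key, typ in known.items():
            sub = dict(d.get(key, {}))
            valid = {f for f in typ.__dataclass_fields__}
            unknown = set(sub) - valid
            if unknown:
                raise ValueError(f"unknown {key} parameter(s): {sorted(unknown)}")
            kwargs[key] = typ(**sub)
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown parameter famil(ies): {sorted(unknown)}")
        return cls(**kwargs)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ParameterSet":
        try:
            d = json.loads(source)
        except (ValueError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ParameterSet":
        if isinstance(source, str) and "\n" in source:
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)

    def with_overrides(self, overrides: dict[str, object]) -> "ParameterSet":
        """Apply dotted-key overrides like ``{"eqtl.eqtl_prob": 0.7}``."""
        out = self
        for key, value in overrides.items():
            family, _, name = key.partition(".")
            if not name or family not in ("sc", "pop", "eqtl", "de", "design"):
                raise ValueError(f"override key {key!r} is not <family>.<param>")
            sub = getattr(out, family)
            if name not in sub.__dataclass_fields__:
                raise ValueError(f"unknown parameter {name!r} in family {family!r}")
            out = replace(out, **{family: replace(sub, **{name: value})})
        return out


# ---------------------------------------------------------------------------
# Gamma fitting
# ---------------------------------------------------------------------------

def fit_gamma(x, what: str = "data", method: str = "mle") -> tuple[float, float]:
    """Fit a gamma(shape, rate) to positive data.

    ``method="mle"`` is maximum likelihood with a method-of-moments start;
    ``method="cvm"`` minimizes the Cramér-von Mises distance, which is robust
    to heavy upper tails and is used for the single-cell gene-mean fit.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 2:
        raise ValueError(f"gamma fit for {what}: need >= 2 positive values")
    m = x.mean()
    v = x.var(ddof=1)
    if v == 0:
        raise ValueError(f"gamma fit for {what}: degenerate zero-variance input")
    shape0 = m * m / v
    rate0 = m / v
    if method == "mle":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, _, scale = stats.gamma.fit(x, shape0, floc=0, scale=1.0 / rate0)
        return float(shape), float(1.0 / scale)
    if method == "cvm":
        xs = np.sort(x)
        probs = (2 * np.arange(1, xs.size + 1) - 1) / (2.0 * xs.size)

        def objective(logp):
            a, r = np.exp(logp)
            cdf = stats.gamma.cdf(xs, a, scale=1.0 / r)
            return float(np.sum((cdf - probs) ** 2))

        res = optimize.minimize(objective, np.log([shape0, rate0]),
                                method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-10})
        shape, rate = np.exp(res.x)
        return float(shape), float(rate)
    raise ValueError(f"unknown gamma fitting method {method!r}")


# ---------------------------------------------------------------------------
# Estimation from reference data
# ---------------------------------------------------------------------------

def _as_matrix(data) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(data, pd.DataFrame):
        return (data.to_numpy(dtype=float),
                [str(i) for i in data.index],
                [str(c) for c in data.columns])
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    return (arr,
            [f"gene{i + 1}" for i in range(arr.shape[0])],
            [f"s{j + 1}" for j in range(arr.shape[1])])


def estimate_population_params(expr, n_bins: int = 10,
                               similarity_scale: float = 1.0) -> PopParams:
    """Estimate population parameters from a genes x individuals matrix.

    Genes expressed below ``LOW_EXPR_THRESHOLD`` in more than half the
    individuals are excluded. A gamma is fit to the surviving gene means
    (``mean_shape``/``mean_rate``); genes are then partitioned into
    ``n_bins`` equal-count bins by mean and a gamma is fit to each bin's
    coefficients of variation (sd across individuals / mean).
    """
    values, _, _ = _as_matrix(expr)
    if values.size == 0:
        raise ValueError("no expressed genes: empty matrix")
    if values.shape[1] < 2:
        raise ValueError("need expression for >= 2 individuals")
    low = (values < LOW_EXPR_THRESHOLD).mean(axis=1) > LOW_EXPR_MAX_FRAC
    values = values[~low]
    if values.shape[0] == 0:
        raise ValueError("no expressed genes survive the low-expression filter")
    if values.shape[0] < n_bins:
        raise ValueError(
            f"only {values.shape[0]} genes survive filtering; need >= n_bins={n_bins}")

    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    cvs = np.divide(sds, means, out=np.zeros_like(sds), where=means > 0)

    mean_shape, mean_rate = fit_gamma(means, "population gene means")

    # Equal-count bins over gene means; edges widened at the extremes so
    # every simulated mean falls in some bin.
    quantiles = np.quantile(means, np.linspace(0, 1, n_bins + 1))
    quantiles[0] = 0.0
    quantiles[-1] = np.inf
    if np.any(np.diff(quantiles) <= 0):
        raise ValueError("gene means too tied to form equal-count bins")
    which = np.clip(np.searchsorted(quantiles, means, side="right") - 1,
                    0, n_bins - 1)
    cv_shapes, cv_rates = [], []
    for b in range(n_bins):
        bin_cvs = cvs[which == b]
        bin_cvs = bin_cvs[bin_cvs > 0]
        if bin_cvs.size < 2:
            raise ValueError(f"mean bin {b} has fewer than 2 usable genes")
        a, r = fit_gamma(bin_cvs, f"cv in mean bin {b}")
        cv_shapes.append(a)
        cv_rates.append(r)

    logger.info("population fit: %d genes kept, mean gamma(%.4g, %.4g), %d bins",
                values.shape[0], mean_shape, mean_rate, n_bins)
    return PopParams(mean_shape=mean_shape, mean_rate=mean_rate, n_bins=n_bins,
                     bin_edges=[float(q) for q in quantiles],
                     cv_shape_per_bin=cv_shapes, cv_rate_per_bin=cv_rates,
                     similarity_scale=similarity_scale)


def estimate_eqtl_params(betas) -> tuple[float, float]:
    """Fit a gamma to |effect sizes| from an eQTL study; returns (shape, rate)."""
    betas = np.asarray(betas, dtype=float)
    betas = betas[np.isfinite(betas)]
    n_neg = int(np.sum(betas < 0))
    mags = np.abs(betas)
    mags = mags[mags > 0]
    if mags.size < 10:
        raise ValueError("need >= 10 finite non-zero effect sizes")
    if n_neg:
        logger.info("estimate_eqtl_params: %d negative effect sizes folded to "
                    "magnitudes", n_neg)
    return fit_gamma(mags, "eQTL effect sizes")


def _estimate_bcv(norm: np.ndarray) -> tuple[float, float]:
    """Moment-based common BCV and df from normalized counts.

    Per-gene quadratic overdispersion phi = (var - mean) / mean^2 is computed,
    the common dispersion is the median of positive estimates, and the df is
    recovered by matching the spread of log dispersions around a quadratic
    mean trend to the variance of a log scaled chi-square.
    """
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    ok = mu > 0
    phi = (var[ok] - mu[ok]) / mu[ok] ** 2
    pos = phi > 0
    if not np.any(pos):
        return 0.1, 60.0
    common = float(np.sqrt(np.median(phi[pos])))
    logphi = np.log(phi[pos])
    logmu = np.log(mu[ok][pos])
    if logphi.size >= 10:
        coef = np.polyfit(logmu, logphi, 2)
        resid = logphi - np.polyval(coef, logmu)
        v = float(resid.var(ddof=1))
        # Var(log chi2_df) = trigamma(df / 2); invert for df.
        try:
            df = float(optimize.brentq(
                lambda d: special.polygamma(1, d / 2.0) - v, 0.2, 1e6))
        except ValueError:
            df = 60.0
    else:
        df = 60.0
    return max(common, 1e-8), df


def estimate_sc_params(counts, winsor_q: float = WINSOR_Q,
                       outlier_mads: float = OUTLIER_MADS) -> SCParams:
    """Estimate single-cell parameters from a genes x cells count matrix.

    Library sizes get a log-normal fit; per-gene means of library-normalized
    counts are winsorized and fit with a gamma (Cramér-von Mises); expression
    outliers are flagged by a median-absolute-deviation rule on log means and
    their factors fit with a log-normal; BCV parameters come from a trended
    moment estimate of the quadratic overdispersion; and a logistic curve of
    zero-proportion against log mean provides the dropout parameters
    (dropout stays disabled unless switched on for simulation).
    """
    values, _, _ = _as_matrix(counts)
    n_genes, n_cells = values.shape
    if n_cells < 2:
        raise ValueError("need counts for >= 2 cells")
    if not np.any(values > 0):
        raise ValueError("all-zero count matrix")
    if n_cells < 100:
        warnings.warn(f"only {n_cells} cells; single-cell parameter estimates "
                      "are unstable below ~100 cells", stacklevel=2)

    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every cell must have at least one count")
    log_totals = np.log(totals)
    lib_loc = float(log_totals.mean())
    lib_scale = float(log_totals.std(ddof=1))
    if lib_scale == 0:
        raise ValueError("degenerate library-size fit: identical cell totals")

    norm = values / totals * math.exp(lib_loc)
    gene_means = norm.mean(axis=1)
    expressed = gene_means[gene_means > 0]
    wins = np.asarray(stats.mstats.winsorize(expressed, limits=(winsor_q, winsor_q)))
    mean_shape, mean_rate = fit_gamma(wins, "single-cell gene means", method="cvm")

    # Outliers: genes whose log mean exceeds median + outlier_mads * MAD.
    lmeans = np.log(expressed)
    med = np.median(lmeans)
    mad = stats.median_abs_deviation(lmeans, scale="normal")
    out_mask = lmeans > med + outlier_mads * mad
    out_prob = float(out_mask.mean())
    if out_mask.sum() >= 2:
        factors = expressed[out_mask] / np.median(expressed)
        lf = np.log(factors)
        out_loc = float(lf.mean())
        out_scale = float(max(lf.std(ddof=1), 1e-8))
    else:
        out_loc, out_scale = 4.0, 0.5

    bcv_common, bcv_df = _estimate_bcv(norm)

    # Dropout: logistic fit of per-gene zero proportion against ln mean.
    zero_frac = (values == 0).mean(axis=1)
    ok = gene_means > 0
    x = np.log(gene_means[ok])
    y = zero_frac[ok]
    dropout_mid, dropout_shape = 0.0, -1.0
    if x.size >= 10 and y.std() > 0:
        def drop_curve(lx, mid, shape):
            return special.expit(-shape * (lx - mid))

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    drop_curve, x, y, p0=(float(np.median(x)), 1.0), maxfev=2000)
            dropout_mid, dropout_shape = float(popt[0]), float(-popt[1])
        except RuntimeError:
            logger.info("dropout logistic fit did not converge; using defaults")

    logger.info("single-cell fit: %d genes x %d cells, lib logN(%.3g, %.3g), "
                "mean gamma(%.3g, %.3g), bcv (%.3g, df %.3g)",
                n_genes, n_cells, lib_loc, lib_scale, mean_shape, mean_rate,
                bcv_common, bcv_df)
    return SCParams(n_genes=n_genes, mean_shape=mean_shape, mean_rate=mean_rate,
                    lib_loc=lib_loc, lib_scale=lib_scale, out_prob=out_prob,
                    out_loc=out_loc, out_scale=out_scale, bcv_common=bcv_common,
                    bcv_df=bcv_df, dropout_enabled=False,
                    dropout_mid=dropout_mid, dropout_shape=dropout_shape)


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

# Default population / eQTL constants emulate a bulk cohort fit (thyroid-like
# tissue): gene means are strongly right-skewed, the across-individual cv
# declines with mean expression, and |eQTL| effect sizes centre near 0.3.
_DEFAULT_CV_MEANS = [0.85, 0.60, 0.50, 0.45, 0.42, 0.40, 0.37, 0.35, 0.32, 0.30]
_DEFAULT_CV_SHAPE = 8.0


def default_params() -> ParameterSet:
    """Built-in defaults allowing simulation with zero reference inputs."""
    # Bin edges at the deciles of the default mean gamma, widened at the ends.
    qs = stats.gamma.ppf(np.linspace(0, 1, 11), 0.34, scale=1.0 / 0.008)
    edges = [0.0] + [float(q) for q in qs[1:-1]] + [float("inf")]
    pop = PopParams(
        mean_shape=0.34, mean_rate=0.008, n_bins=10, bin_edges=edges,
        cv_shape_per_bin=[_DEFAULT_CV_SHAPE] * 10,
        cv_rate_per_bin=[_DEFAULT_CV_SHAPE / m for m in _DEFAULT_CV_MEANS],
        similarity_scale=1.0, bulk_derived=True)
    return ParameterSet(sc=SCParams(), pop=pop, eqtl=EqtlParams(),
                        de=DEParams(), design=DesignParams())
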
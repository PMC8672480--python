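"""Genotype dosages: VCF ingestion, filtering, simulation, eSNP assignment.

Genotypes are held as a SNP x individual matrix of minor-allele dosages
(0/1/2). eQTL assignment pairs each selected eGene with a cis eSNP subject
to minor-allele-frequency and distance constraints, samples a positive
multiplicative effect size for it, optionally shares one eSNP between pairs
of eGenes (genetically-driven co-expression), and labels a fraction of
effects as cell-group- or condition-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._streams import substream
from .params import EqtlParams

logger = logging.getLogger("scpopsim")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Minor-allele dosages (SNP x individual) with positions and MAFs."""

    snp_ids: list[str]
    chrom: np.ndarray      # per-SNP chromosome, str
    pos: np.ndarray        # per-SNP 1-based position
    dosage: np.ndarray     # SNP x individual, values in {0, 1, 2}
    sample_ids: list[str]
    maf: np.ndarray = field(default=None)  # recomputed from dosages

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != len(self.snp_ids):
            raise ValueError("dosage must be SNP x individual")
        if self.dosage.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids do not match dosage columns")
        if not np.isin(self.dosage, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if np.any(self.pos <= 0):
            raise ValueError("positions must be 1-based and positive")
        # MAF is always recomputed from the dosage matrix, never trusted.
        freq = self.dosage.mean(axis=1) / 2.0
        self.maf = np.minimum(freq, 1.0 - freq)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def take(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx], pos=self.pos[idx],
            dosage=self.dosage[idx], sample_ids=list(self.sample_ids))


@dataclass
class GeneAnnotation:
    """Gene anchor positions (TSS or midpoint, user's choice) per chromosome."""

    gene_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if np.any(self.pos <= 0):
            raise ValueError("gene positions must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(gene_ids=[str(g) for g in df["gene_id"]],
                   chrom=df["chrom"].to_numpy(), pos=df["pos"].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": self.gene_ids, "chrom": self.chrom,
                      "pos": self.pos}).to_csv(path, sep="\t", index=False)


@dataclass
class EqtlAssignment:
    """One eGene-eSNP pairing with its effect size and specificity label."""

    gene_id: str
    snp_id: str
    beta: float                 # omega_i, strictly positive
    specificity: str = "global"  # "global", "group:<g>" or "condition:<c>"
    coreg_partner: str | None = None

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("eQTL beta must be > 0")
        if self.specificity != "global" and ":" not in self.specificity:
            raise ValueError("specificity must be global, group:<g> or condition:<c>")


def assignments_to_frame(assignments: Sequence[EqtlAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": a.gene_id, "snp_id": a.snp_id, "beta": a.beta,
          "specificity": a.specificity,
          "coreg_partner": a.coreg_partner or ""} for a in assignments],
        columns=["gene_id", "snp_id", "beta", "specificity", "coreg_partner"])


# ---------------------------------------------------------------------------
# Ingestion / simulation
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a minor-allele dosage matrix.

    Multiallelic records, non-SNP records, records with any missing genotype
    and monomorphic records are dropped (counts logged). Dosages are flipped
    so they always count the minor allele; MAFs are recomputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples/GT field")
    snp_ids, chroms, positions, rows = [], [], [], []
    n_multi = n_missing = n_mono = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or not var.is_snp:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types)  # gts012: 0/1/2 alt dosage, 3 unknown
        if np.any(gt == 3):
            n_missing += 1
            continue
        alt_freq = gt.mean() / 2.0
        if alt_freq in (0.0, 1.0):
            n_mono += 1
            continue
        if alt_freq > 0.5:
            gt = 2 - gt
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        positions.append(var.POS)
        rows.append(gt.astype(np.int8))
    vcf.close()
    if n_multi or n_missing or n_mono:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP, %d with missing "
                    "GT, %d monomorphic records", n_multi, n_missing, n_mono)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic SNPs")
    return GenotypeMatrix(snp_ids=snp_ids, chrom=np.array(chroms),
                          pos=np.array(positions), dosage=np.vstack(rows),
                          sample_ids=samples)


def filter_genotypes(G: GenotypeMatrix, maf_min: float = 0.05,
                     max_missing: float = 0.0) -> GenotypeMatrix:
    """Drop SNPs with MAF <= ``maf_min`` (strict keep-if-greater convention).

    ``max_missing`` is accepted for interface completeness; matrices produced
    by this package contain no missing dosages, so it never removes SNPs here.
    """
    keep = G.maf > maf_min
    if not np.any(keep):
        raise ValueError("all SNPs removed by the MAF filter")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_genotypes: removed %d / %d SNPs at maf_min=%g",
                    dropped, G.n_snps, maf_min)
    return G.take(np.flatnonzero(keep))


def simulate_genotypes(n_snps: int, n_individuals: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       chrom_length: int = 20_000_000, seed: int = 0,
                       chrom: str = "1") -> GenotypeMatrix:
    """Simulate unstructured genotypes: Binomial(2, f) dosages, f ~ U(maf_range).

    No linkage disequilibrium or relatedness is simulated; positions are
    uniform over [1, chrom_length] and sorted. Monomorphic draws (possible at
    small sample sizes) are resampled so every SNP is polymorphic.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    rng = substream(seed, "genotypes")
    freqs = rng.uniform(lo, hi, size=n_snps)
    dosage = rng.binomial(2, freqs[:, None], size=(n_snps, n_individuals))
    for _ in range(100):
        mono = (dosage.min(axis=1) == dosage.max(axis=1))
        if not mono.any():
            break
        dosage[mono] = rng.binomial(2, freqs[mono, None],
                                    size=(int(mono.sum()), n_individuals))
    pos = np.sort(rng.integers(1, chrom_length + 1, size=n_snps))
    return GenotypeMatrix(
        snp_ids=[f"snp{i + 1}" for i in range(n_snps)],
        chrom=np.full(n_snps, chrom), pos=pos,
        dosage=dosage.astype(np.int8),
        sample_ids=[f"i{j + 1}" for j in range(n_individuals)])


def simulate_annotation(n_genes: int, chrom_length: int = 20_000_000,
                        seed: int = 0, chrom: str = "1") -> GeneAnnotation:
    """Synthetic gene anchors uniform over one chromosome, sorted by position."""
    rng = substream(seed, "annotation")
    pos = np.sort(rng.integers(1, chrom_length + 1, size=n_genes))
    return GeneAnnotation(gene_ids=[f"gene{i + 1}" for i in range(n_genes)],
                          chrom=np.full(n_genes, chrom), pos=pos)


# ---------------------------------------------------------------------------
# eSNP assignment
# ---------------------------------------------------------------------------

def _eligible_snps(genes: GeneAnnotation, G: GenotypeMatrix,
                   params: EqtlParams) -> list[np.ndarray]:
    """Per gene, indices of SNPs passing the MAF and distance constraints."""
    maf_ok = (G.maf >= params.maf_min) & (G.maf <= params.maf_max)
    out = []
    for chrom, gpos in zip(genes.chrom, genes.pos):
        on_chrom = (G.chrom == chrom) & maf_ok
        dist_ok = np.abs(G.pos - gpos) <= params.dist_max
        out.append(np.flatnonzero(on_chrom & dist_ok))
    return out


def assign_eqtl(genes: GeneAnnotation, G: GenotypeMatrix, params: EqtlParams,
                seed: int = 0, groups: Sequence[str] = ("g1",),
                conditions: Sequence[str] = ("c1",)) -> list[EqtlAssignment]:
    """Assign eSNPs, effect sizes and specificity labels to eGenes.

    ``round(eqtl_prob * n_genes)`` eGenes are drawn uniformly among genes
    having at least one eligible eSNP; each receives a uniformly chosen
    eligible eSNP and a beta ~ gamma(es_shape, es_rate). A fraction
    ``coreg_prop`` of eGenes (rounded down to an even count) is arranged in
    disjoint pairs sharing one eSNP eligible for both members. Specificity
    labels are drawn only when more than one group (condition) exists.
    """
    rng = substream(seed, "eqtl")
    n_target = int(np.floor(params.eqtl_prob * genes.n_genes + 0.5))
    if n_target == 0:
        return []

    eligible = _eligible_snps(genes, G, params)
    has_any = [i for i, e in enumerate(eligible) if e.size > 0]
    n_ineligible = genes.n_genes - len(has_any)
    if n_ineligible:
        logger.warning("assign_eqtl: %d / %d genes have no eligible eSNP",
                       n_ineligible, genes.n_genes)
    if len(has_any) < n_target:
        raise ValueError(
            f"need {n_target} eGenes but only {len(has_any)} genes have an "
            "eligible eSNP (check maf and distance bounds)")

    egene_idx = rng.choice(has_any, size=n_target, replace=False)
    snp_for = {int(i): int(rng.choice(eligible[i])) for i in egene_idx}
    betas = rng.gamma(params.es_shape, 1.0 / params.es_rate, size=n_target)

    # Co-regulation: disjoint eGene pairs sharing an eSNP eligible for both.
    partner: dict[int, int] = {}
    n_coreg = int(np.floor(params.coreg_prop * n_target + 0.5))
    n_pairs = n_coreg // 2
    if n_pairs:
        pool = list(rng.permutation(egene_idx))
        elig_sets = {int(i): set(eligible[int(i)].tolist()) for i in egene_idx}
        pairs: list[tuple[int, int]] = []
        while len(pairs) < n_pairs and len(pool) >= 2:
            a = int(pool.pop(0))
            match = None
            for k, b in enumerate(pool):
                if elig_sets[a] & elig_sets[int(b)]:
                    match = k
                    break
            if match is None:
                continue  # a cannot be paired; try the next gene
            b = int(pool.pop(match))
            shared = snp_for[a] if snp_for[a] in elig_sets[b] else \
                int(rng.choice(sorted(elig_sets[a] & elig_sets[b])))
            snp_for[a] = snp_for[b] = shared
            pairs.append((a, b))
        if len(pairs) < n_pairs:
            raise ValueError(
                f"could only form {len(pairs)} of {n_pairs} co-regulated eGene "
                "pairs; genes are too sparse for the requested coreg_prop")
        for a, b in pairs:
            partner[a] = b
            partner[b] = a

    # Specificity: disjoint chunks of the shuffled eGene list.
    specificity = {int(i): "global" for i in egene_idx}
    shuffled = list(rng.permutation(egene_idx))
    n_group = int(np.floor(params.group_specific_prop * n_target + 0.5)) \
        if len(groups) > 1 else 0
    n_cond = int(np.floor(params.condition_specific_prop * n_target + 0.5)) \
        if len(conditions) > 1 else 0
    n_cond = min(n_cond, n_target - n_group)
    for i in shuffled[:n_group]:
        specificity[int(i)] = f"group:{rng.choice(groups)}"
    for i in shuffled[n_group:n_group + n_cond]:
        specificity[int(i)] = f"condition:{rng.choice(conditions)}"

    out = []
    for k, i in enumerate(egene_idx):
        i = int(i)
        out.append(EqtlAssignment(
            gene_id=genes.gene_ids[i], snp_id=G.snp_ids[snp_for[i]],
            beta=float(betas[k]), specificity=specificity[i],
            coreg_partner=genes.gene_ids[partner[i]] if i in partner else None))
    logger.info("assign_eqtl: %d eGenes (%d co-regulated, %d group-specific, "
                "%d condition-specific)", n_target, 2 * n_pairs, n_group, n_cond)
    return out
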
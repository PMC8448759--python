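"""Synthetic genotype-phenotype data under the liability-threshold model.

Genotypes are independent biallelic dosages: per-variant minor-allele
frequencies are drawn uniformly from a range and dosages are Binomial(2, MAF).
Phenotypes come from a latent Gaussian liability

    L = sqrt(h2) * g + sqrt(1 - h2) * e,    e ~ N(0, 1),

where g is the standardised genetic score and h2 is the narrow-sense
heritability of the liability; individuals with L above the quantile set by
the prevalence are cases. Two causal architectures are provided:

* ``additive`` — a fraction (the polygenicity) of variants receives standard
  normal effect sizes and g is their weighted dosage sum;
* ``pairwise_and`` — each causal gene carries two causal variants and
  contributes 1 to g when a sample carries at least one minor allele at
  *both* (a non-linearity no single-variant linear model captures fully).

The module also computes the theoretical maximum AUC attainable by any
genotype-based classifier at a given heritability and prevalence — the AUC
of the true genetic liability g — by numerical integration.

The generator deliberately omits linkage disequilibrium, population
structure, and imputation noise; variants are exchangeable within genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .annotations import AnnotationTable


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic cohort.

    Defaults describe a desk-scale additive cohort: 5,000 samples, 20 genes
    of 10 variants each, MAF ~ U(0.05, 0.5), heritability 0.5, 10% of
    variants causal, prevalence 0.5 (a balanced case-control design).
    """

    n_samples: int = 5000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 20
    variants_per_gene: int = 10
    causal_genes: int = 2
    causal_snps_per_gene: int = 2
    h2: float = 0.5
    polygenicity: float = 0.1
    prevalence: float = 0.5
    interaction_mode: str = "additive"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0.0 <= self.polygenicity <= 1.0):
            raise ValueError("polygenicity must be in [0, 1]")
        if self.n_genes * self.variants_per_gene != self.n_variants:
            raise ValueError("n_variants must equal n_genes * variants_per_gene")
        if self.causal_genes > self.n_genes:
            raise ValueError("causal_genes exceeds n_genes")
        if self.causal_snps_per_gene > self.variants_per_gene:
            raise ValueError("causal_snps_per_gene exceeds variants_per_gene")
        if self.interaction_mode not in ("additive", "pairwise_and"):
            raise ValueError(f"unknown interaction_mode {self.interaction_mode!r}")


def proof_of_concept_config(**overrides) -> SimulationConfig:
    """Conditions of the two-causal-SNPs-per-gene interaction demonstration.

    Each causal gene carries a pair of variants that jointly trigger disease
    risk; the construction is close to deterministic, reflected in a high
    default heritability (0.9) and MAFs bounded away from rare (0.1-0.5) so
    the joint carrier state is common enough to learn from.
    """
    defaults = dict(
        interaction_mode="pairwise_and", h2=0.9, maf_range=(0.1, 0.5),
        prevalence=0.5, causal_genes=2, causal_snps_per_gene=2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class SimulatedDataset:
    genotypes: np.ndarray  # (n_samples, n_variants) dosages in {0,1,2}
    labels: np.ndarray
    liabilities: np.ndarray
    variant_ids: tuple
    gene_ids: tuple
    annotation: AnnotationTable
    true_causal_variants: tuple
    true_causal_genes: tuple
    config: SimulationConfig = None


def _variant_ids(cfg: SimulationConfig):
    width = len(str(cfg.n_variants - 1))
    return tuple(f"snp{v:0{width}d}" for v in range(cfg.n_variants))


def _gene_ids(cfg: SimulationConfig):
    width = len(str(cfg.n_genes - 1))
    return tuple(f"gene{g:0{width}d}" for g in range(cfg.n_genes))


def gene_annotation(cfg: SimulationConfig) -> AnnotationTable:
    """Variant->gene table partitioning variants into consecutive blocks."""
    vids, gids = _variant_ids(cfg), _gene_ids(cfg)
    pairs = [(vids[v], gids[v // cfg.variants_per_gene]) for v in range(cfg.n_variants)]
    return AnnotationTable.from_pairs(pairs, kind="snp_gene")


def simulate_genotypes(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Independent Binomial(2, MAF) dosages; MAF ~ U(maf_range) per variant."""
    rng = rng or np.random.default_rng(cfg.seed)
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_variants)
    return rng.binomial(2, mafs, size=(cfg.n_samples, cfg.n_variants)).astype(np.int8)


def _liability_labels(g_raw: np.ndarray, cfg: SimulationConfig,
                      rng: np.random.Generator):
    """Standardise the genetic score, mix in noise, threshold at the prevalence."""
    sd = g_raw.std()
    if sd == 0:
        raise ValueError("genetic score has zero variance; no causal signal")
    g = (g_raw - g_raw.mean()) / sd
    noise = rng.standard_normal(g.shape[0])
    liability = np.sqrt(cfg.h2) * g + np.sqrt(1.0 - cfg.h2) * noise
    threshold = stats.norm.ppf(1.0 - cfg.prevalence)
    labels = (liability > threshold).astype(np.int8)
    return labels, liability, g


def simulate_liability_phenotype(genotypes: np.ndarray, cfg: SimulationConfig,
                                 rng: np.random.Generator | None = None):
    """Additive liability phenotype.

    ``round(polygenicity * n_variants)`` causal variants receive N(0,1)
    effect sizes; the genetic score is standardised so the realised
    liability-scale heritability equals ``cfg.h2`` by construction. Returns
    (labels, liabilities, causal_indices, effects). With ``h2 = 0`` labels
    are independent of genotype.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n, m = genotypes.shape
    n_causal = int(round(cfg.polygenicity * m))
    if n_causal == 0 and cfg.h2 > 0:
        raise ValueError("h2 > 0 requires at least one causal variant")
    causal = np.sort(rng.choice(m, size=max(n_causal, 1), replace=False))
    effects = rng.standard_normal(causal.size)
    if cfg.h2 == 0:
        liability = rng.standard_normal(n)
        threshold = stats.norm.ppf(1.0 - cfg.prevalence)
        return (liability > threshold).astype(np.int8), liability, causal, effects * 0.0
    g_raw = genotypes[:, causal].astype(float) @ effects
    labels, liability, _ = _liability_labels(g_raw, cfg, rng)
    return labels, liability, causal, effects


def _pairwise_and_score(genotypes: np.ndarray, pair_idx: np.ndarray) -> np.ndarray:
    """Per-sample count of causal genes with minor alleles at both pair members."""
    both = np.ones(genotypes.shape[0], dtype=float)
    score = np.zeros(genotypes.shape[0], dtype=float)
    for a, b in pair_idx:
        score += ((genotypes[:, a] >= 1) & (genotypes[:, b] >= 1)).astype(float)
    return score


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Full synthetic cohort: genotypes, labels, truth, and annotation table."""
    rng = np.random.default_rng(cfg.seed)
    genotypes = simulate_genotypes(cfg, rng)
    vids, gids = _variant_ids(cfg), _gene_ids(cfg)

    if cfg.interaction_mode == "additive":
        labels, liability, causal, _ = simulate_liability_phenotype(genotypes, cfg, rng)
        causal_variants = tuple(vids[i] for i in causal)
        causal_genes = tuple(sorted({gids[i // cfg.variants_per_gene] for i in causal}))
    else:
        if cfg.variants_per_gene < 2:
            raise ValueError("pairwise_and requires at least 2 variants per gene")
        if cfg.causal_snps_per_gene != 2:
            raise ValueError("pairwise_and uses exactly 2 causal variants per gene")
        gene_idx = np.sort(rng.choice(cfg.n_genes, cfg.causal_genes, replace=False))
        pairs = []
        for gi in gene_idx:
            offs = rng.choice(cfg.variants_per_gene, 2, replace=False)
            pairs.append(gi * cfg.variants_per_gene + np.sort(offs))
        pair_idx = np.array(pairs)
        score = _pairwise_and_score(genotypes, pair_idx)
        labels, liability, _ = _liability_labels(score, cfg, rng)
        causal_variants = tuple(vids[i] for i in np.sort(pair_idx.ravel()))
        causal_genes = tuple(gids[i] for i in gene_idx)

    return SimulatedDataset(
        genotypes=genotypes, labels=labels, liabilities=liability,
        variant_ids=vids, gene_ids=gids, annotation=gene_annotation(cfg),
        true_causal_variants=causal_variants, true_causal_genes=causal_genes,
        config=cfg,
    )


def simulate_proof_of_concept(cfg: SimulationConfig | None = None,
                              **overrides) -> SimulatedDataset:
    """Two-causal-SNPs-per-gene interaction cohort (see
    :func:`proof_of_concept_config` for the default conditions)."""
    if cfg is None:
        cfg = proof_of_concept_config(**overrides)
    if cfg.interaction_mode != "pairwise_and":
        raise ValueError("proof of concept requires interaction_mode='pairwise_and'")
    return simulate_dataset(cfg)


def theoretical_max_auc(h2: float, prevalence: float = 0.5,
                        case_fraction_in_sample: float | None = None) -> float:
    """AUC of the Bayes-optimal genotype score under the liability model.

    The best any genotype-based classifier can do is rank by the genetic
    liability g ~ N(0, h2). Cases satisfy g + e > Phi^-1(1 - prevalence)
    with e ~ N(0, 1 - h2); the AUC of g for cases versus controls is
    computed by numerical integration of the conditional densities of g.
    ``case_fraction_in_sample`` is accepted for signature completeness but
    does not move the value: AUC is invariant to the case-control mix.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must be in [0, 1]")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    if h2 == 0.0:
        return 0.5
    if h2 == 1.0:
        # score equals the liability itself: cases and controls separate exactly
        return 1.0
    sg = np.sqrt(h2)
    se = np.sqrt(1.0 - h2)
    t = stats.norm.ppf(1.0 - prevalence)
    k = prevalence
    grid = np.linspace(-8.0 * sg, 8.0 * sg, 200_001)
    phi = stats.norm.pdf(grid, scale=sg)
    p_case = stats.norm.sf((t - grid) / se)
    f_case = phi * p_case / k
    f_ctrl = phi * (1.0 - p_case) / (1.0 - k)
    F_ctrl = integrate.cumulative_trapezoid(f_ctrl, grid, initial=0.0)
    return float(np.trapezoid(f_case * F_ctrl, grid))


def balance_case_control(labels: np.ndarray, rng: np.random.Generator,
                         case_fraction: float = 0.5) -> np.ndarray:
    """Indices of an ascertained subsample with the requested case fraction.

    Keeps every sample of the limiting class and randomly downsamples the
    other, emulating a matched case-control design.
    """
    labels = np.asarray(labels)
    cases = np.flatnonzero(labels == 1)
    controls = np.flatnonzero(labels == 0)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need both cases and controls to balance")
    # largest total n achieving the requested fraction
    n_total = min(cases.size / case_fraction, controls.size / (1.0 - case_fraction))
    n_cases = int(np.floor(n_total * case_fraction))
    n_controls = int(np.floor(n_total)) - n_cases
    keep = np.concatenate([
        rng.choice(cases, n_cases, replace=False),
        rng.choice(controls, n_controls, replace=False),
    ])
    return np.sort(keep)
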
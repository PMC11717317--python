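"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator works directly on summary statistics — no individual-level
genotypes — which is all two-sample MR consumes.  For standardized traits
measured in non-overlapping samples of sizes N_X and N_Y, a variant with
allele frequency p has

    se = 1 / sqrt(2 p (1 - p) N)

and the observed associations are

    beta_X_j ~ Normal(gamma_j,                 se_X_j²)
    beta_Y_j ~ Normal(theta * gamma_j + alpha_j, se_Y_j²)

where gamma_j is the variant's true effect on the exposure, theta the causal
effect, and alpha_j a direct (pleiotropic) effect on the outcome: zero,
balanced (mean 0), or directional (nonzero mean).  An optional confounder
block adds a shared per-variant path into both traits.  Everything is
deterministic given the seed.

Defaults emulate the strong-instrument regime of a large GWAS:
50 variants, N = 100,000 per sample, MAF ~ U(0.05, 0.5),
gamma_j ~ N(0.08, 0.02²) (per-variant F around 200-400), theta = 0.1.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import SummaryDataset, VariantAssociation

#: Allele pairs that are not strand-ambiguous.
NON_PALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class ConfounderConfig:
    """A shared per-variant path kappa_j ~ N(0, loading_sd²) feeding both
    traits: exposure gains effect_exposure * kappa_j, outcome gains
    effect_outcome * kappa_j (on top of the causal path)."""

    effect_exposure: float = 1.0
    effect_outcome: float = 1.0
    loading_sd: float = 0.02


@dataclass
class SimulationConfig:
    n_variants: int = 50
    n_exposure_sample: int = 100_000
    n_outcome_sample: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_mean: float = 0.08
    gamma_sd: float = 0.02
    theta_true: float = 0.1
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.004
    pleiotropy_mean: float = 0.004  # used only in directional mode
    confounder: ConfounderConfig | None = None
    include_palindromic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.n_exposure_sample <= 0 or self.n_outcome_sample <= 0:
            raise ValueError("sample sizes must be positive")
        if self.n_variants < 3:
            raise ValueError("n_variants must be >= 3")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")


@dataclass
class SimulationTruth:
    theta_true: float
    gamma: np.ndarray
    alpha: np.ndarray
    config: SimulationConfig


@dataclass
class SimulatedStudy:
    exposure: SummaryDataset
    outcome: SummaryDataset
    truth: SimulationTruth


def se_standardized(maf: np.ndarray, n: float) -> np.ndarray:
    """SE of a per-allele effect on a standardized trait: 1/sqrt(2p(1-p)N)."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _draw_alleles(rng: np.random.Generator, n: int, include_palindromic: bool):
    pool = NON_PALINDROMIC_PAIRS + (PALINDROMIC_PAIRS if include_palindromic else ())
    idx = rng.integers(0, len(pool), size=n)
    return [pool[i] for i in idx]


def _dataset(label, ids, alleles, maf, beta, se, rng_none=None) -> SummaryDataset:
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    ds = SummaryDataset(label, provenance="simulated")
    for j, vid in enumerate(ids):
        ds.add(
            VariantAssociation(
                variant_id=vid,
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                beta=float(beta[j]),
                se=float(se[j]),
                eaf=float(maf[j]),
                pval=float(pval[j]),
            )
        )
    return ds


def simulate_two_sample(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Draw one paired exposure/outcome summary dataset under the model.

    ``seed`` overrides ``cfg.seed`` when given.  Both datasets share
    variant IDs, alleles and allele frequencies; estimation errors are
    independent across the two samples (non-overlapping designs).
    """
    cfg = cfg or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_variants
    ids = [f"rs{90000000 + j}" for j in range(m)]
    alleles = _draw_alleles(rng, m, cfg.include_palindromic)
    maf = rng.uniform(*cfg.maf_range, size=m)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=m)

    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(m)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, size=m)
    else:
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=m)

    mean_x = gamma.copy()
    mean_y = cfg.theta_true * gamma + alpha
    if cfg.confounder is not None:
        kappa = rng.normal(0.0, cfg.confounder.loading_sd, size=m)
        mean_x = gamma + cfg.confounder.effect_exposure * kappa
        mean_y = cfg.theta_true * mean_x + cfg.confounder.effect_outcome * kappa + alpha

    se_x = se_standardized(maf, cfg.n_exposure_sample)
    se_y = se_standardized(maf, cfg.n_outcome_sample)
    beta_x = mean_x + se_x * rng.standard_normal(m)
    beta_y = mean_y + se_y * rng.standard_normal(m)

    exposure = _dataset("exposure_sim", ids, alleles, maf, beta_x, se_x)
    outcome = _dataset("outcome_sim", ids, alleles, maf, beta_y, se_y)
    truth = SimulationTruth(cfg.theta_true, gamma, alpha, cfg)
    return SimulatedStudy(exposure, outcome, truth)


@dataclass
class MVMRSimulationConfig:
    """K-exposure extension: outcome mean is sum_k theta_k * gamma_kj + alpha_j,
    with exposures optionally correlated through shared confounder loadings."""

    n_variants: int = 100
    n_exposure_sample: int = 100_000
    n_outcome_sample: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    thetas: tuple[float, ...] = (0.1, 0.05)
    gamma_means: tuple[float, ...] = (0.08, 0.08)
    gamma_sds: tuple[float, ...] = (0.02, 0.02)
    confounder_loadings: tuple[float, ...] | None = None  # per-exposure weight on kappa_j
    confounder_outcome: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.004
    pleiotropy_mean: float = 0.004
    seed: int = 0

    @property
    def k(self) -> int:
        return len(self.thetas)


def simulate_mvmr(cfg: MVMRSimulationConfig | None = None, seed: int | None = None):
    """Simulate K exposures and one outcome on a shared variant panel.

    Returns ``(exposures, outcome, truth)`` where truth holds the direct
    effects and per-exposure gamma matrices.
    """
    cfg = cfg or MVMRSimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if not (len(cfg.gamma_means) == len(cfg.gamma_sds) == cfg.k):
        raise ValueError("thetas, gamma_means, gamma_sds must have equal length")
    rng = np.random.default_rng(cfg.seed)
    m, k = cfg.n_variants, cfg.k
    ids = [f"rs{90000000 + j}" for j in range(m)]
    alleles = _draw_alleles(rng, m, include_palindromic=False)
    maf = rng.uniform(*cfg.maf_range, size=m)
    gamma = np.column_stack(
        [rng.normal(cfg.gamma_means[i], cfg.gamma_sds[i], size=m) for i in range(k)]
    )
    if cfg.confounder_loadings is not None:
        kappa = rng.normal(0.0, 0.02, size=m)
        gamma = gamma + np.outer(kappa, np.asarray(cfg.confounder_loadings))
    else:
        kappa = np.zeros(m)

    if cfg.pleiotropy_mode == "none":
        alpha = np.zeros(m)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy_sd, size=m)
    else:
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=m)

    mean_y = gamma @ np.asarray(cfg.thetas) + cfg.confounder_outcome * kappa + alpha
    se_x = se_standardized(maf, cfg.n_exposure_sample)
    se_y = se_standardized(maf, cfg.n_outcome_sample)

    exposures = []
    for i in range(k):
        beta_x = gamma[:, i] + se_x * rng.standard_normal(m)
        exposures.append(_dataset(f"exposure{i + 1}_sim", ids, alleles, maf, beta_x, se_x))
    beta_y = mean_y + se_y * rng.standard_normal(m)
    outcome = _dataset("outcome_sim", ids, alleles, maf, beta_y, se_y)
    truth = {"thetas": np.asarray(cfg.thetas, dtype=float), "gamma": gamma, "alpha": alpha, "config": cfg}
    return exposures, outcome, truth


def evaluate_recovery(results: pd.DataFrame, theta_true: float, alpha: float = 0.05) -> pd.DataFrame:
    """Per-method recovery metrics over simulation replicates.

    ``results`` needs columns ``method``, ``b``, ``se``, ``pval`` (one row
    per method per replicate; >= 100 replicates).  Reports bias with its
    Monte-Carlo SE, empirical SD of the estimates, mean estimated SE,
    95%-CI coverage of the truth, and the rejection rate at ``alpha``
    (type-I error when theta_true = 0, power otherwise).
    """
    n_rep = results.groupby("method").size().min()
    if n_rep < 100:
        raise ValueError("evaluate_recovery requires >= 100 replicates per method")
    rows = []
    for method, grp in results.groupby("method", sort=False):
        b = grp["b"].to_numpy()
        se = grp["se"].to_numpy()
        covered = np.abs(b - theta_true) <= 1.96 * se
        rows.append(
            {
                "method": method,
                "n_replicates": len(grp),
                "bias": b.mean() - theta_true,
                "mcse_bias": b.std(ddof=1) / np.sqrt(len(grp)),
                "empirical_se": b.std(ddof=1),
                "mean_estimated_se": se.mean(),
                "coverage": covered.mean(),
                "rejection_rate": (grp["pval"].to_numpy() < alpha).mean(),
            }
        )
    return pd.DataFrame(rows)
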
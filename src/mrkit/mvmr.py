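"""Multivariable Mendelian randomization.

MVMR regresses the outcome associations on the association matrix of K >= 2
exposures jointly, so each coefficient is the direct effect of that
exposure conditional on the others.  The instrument set is the union of the
per-exposure instruments, restricted to variants available in every dataset
("union-then-available"), harmonized to the primary exposure's effect
allele.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95
from .instruments import LDSource, SelectionConfig, ld_clump
from .summary_io import COMPLEMENT, SummaryDataset, is_palindromic


@dataclass
class MVMRRecord:
    variant_id: str
    beta_exposures: np.ndarray  # length K
    se_exposures: np.ndarray
    beta_outcome: float
    se_outcome: float


@dataclass
class MVMRSet:
    outcome_label: str
    exposure_labels: list[str]  # first label = primary exposure
    records: list[MVMRRecord] = field(default_factory=list)
    audit: list[tuple[str, str]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.exposure_labels)

    def __len__(self) -> int:
        return len(self.records)

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        X = np.array([r.beta_exposures for r in self.records], dtype=float)
        y = np.array([r.beta_outcome for r in self.records], dtype=float)
        sy = np.array([r.se_outcome for r in self.records], dtype=float)
        return X, y, sy


@dataclass
class MVMREstimate:
    """Per-exposure direct effects from one joint fit."""

    outcome_label: str
    exposure_labels: list[str]
    n_snp: int
    theta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pval: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        co = [l for l in self.exposure_labels]
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome_label,
                    "exposure": label,
                    "adjusted_for": ",".join(x for x in self.exposure_labels if x != label),
                    "nsnp": self.n_snp,
                    "b": self.theta[i],
                    "se": self.se[i],
                    "pval": self.pval[i],
                    "or": np.exp(self.theta[i]),
                    "or_lci95": np.exp(self.ci_low[i]),
                    "or_uci95": np.exp(self.ci_high[i]),
                }
                for i, label in enumerate(co)
            ]
        )


def _align_to(primary_ea: str, primary_oa: str, assoc) -> tuple[float, float | None] | None:
    """Beta (and EAF) of `assoc` expressed for the primary effect allele.

    Returns None when the allele pairs cannot be reconciled.
    """
    e, o = assoc.effect_allele, assoc.other_allele
    flipped_eaf = None if assoc.eaf is None else 1.0 - assoc.eaf
    if (e, o) == (primary_ea, primary_oa):
        return assoc.beta, assoc.eaf
    if (e, o) == (primary_oa, primary_ea):
        return -assoc.beta, flipped_eaf
    ce, co = COMPLEMENT[e], COMPLEMENT[o]
    if (ce, co) == (primary_ea, primary_oa):
        return assoc.beta, assoc.eaf
    if (ce, co) == (primary_oa, primary_ea):
        return -assoc.beta, flipped_eaf
    return None


def assemble_mvmr_set(
    exposures: list[SummaryDataset],
    outcome: SummaryDataset,
    instrument_ids: list[list[str]],
    drop_palindromic: bool = True,
    instrument_rule: str = "union",
    ld: LDSource | None = None,
    cfg: SelectionConfig | None = None,
) -> MVMRSet:
    """Build the joint instrument set for MVMR.

    The candidate set is the union (default) or intersection of the
    per-exposure instrument IDs, restricted to variants present in every
    exposure dataset and in the outcome dataset, then harmonized pairwise
    to the primary (first) exposure's effect allele.  Palindromic variants
    are dropped per policy.  When an :class:`LDSource` is supplied the
    pooled candidate set is jointly clumped with the usual r²/window
    thresholds before estimation.

    Raises
    ------
    ValueError
        If fewer than 2 exposures are given or the final set has fewer
        than K+1 variants.
    """
    if len(exposures) < 2:
        raise ValueError("MVMR requires at least 2 exposures")
    if len(instrument_ids) != len(exposures):
        raise ValueError("one instrument list per exposure is required")
    if instrument_rule not in ("union", "intersection"):
        raise ValueError(f"unknown instrument rule {instrument_rule!r}")
    k = len(exposures)
    primary = exposures[0]
    sets = [set(ids) for ids in instrument_ids]
    candidates = set.union(*sets) if instrument_rule == "union" else set.intersection(*sets)
    # preserve primary-exposure file order for determinism
    ordered = [vid for vid in primary.variant_ids() if vid in candidates]
    ordered += sorted(candidates - set(ordered))

    mv = MVMRSet(outcome.trait_label, [ds.trait_label for ds in exposures])
    kept_assocs = {}
    for vid in ordered:
        absent = [ds.trait_label for ds in exposures if vid not in ds]
        if vid not in outcome:
            absent.append(outcome.trait_label)
        if absent:
            mv.audit.append((vid, f"absent in {', '.join(absent)}"))
            continue
        ref = primary[vid]
        if drop_palindromic and is_palindromic(ref.effect_allele, ref.other_allele):
            mv.audit.append((vid, "palindromic"))
            continue
        betas = np.empty(k)
        ses = np.empty(k)
        ok = True
        for i, ds in enumerate(exposures):
            aligned = _align_to(ref.effect_allele, ref.other_allele, ds[vid])
            if aligned is None:
                mv.audit.append((vid, f"allele mismatch in {ds.trait_label}"))
                ok = False
                break
            betas[i], ses[i] = aligned[0], ds[vid].se
        if not ok:
            continue
        aligned_out = _align_to(ref.effect_allele, ref.other_allele, outcome[vid])
        if aligned_out is None:
            mv.audit.append((vid, f"allele mismatch in {outcome.trait_label}"))
            continue
        kept_assocs[vid] = ref
        mv.records.append(
            MVMRRecord(vid, betas, ses, aligned_out[0], outcome[vid].se)
        )

    if ld is not None and mv.records:
        pooled = SummaryDataset(primary.trait_label, dict(kept_assocs))
        clumped, audit = ld_clump(pooled, ld, cfg)
        keep = set(clumped.variant_ids())
        for vid, stage, reason in audit.removals:
            mv.audit.append((vid, f"joint clump: {reason}"))
        mv.records = [r for r in mv.records if r.variant_id in keep]

    if len(mv.records) < k + 1:
        raise ValueError(
            f"MVMR under-identified: {len(mv.records)} variants for {k} exposures "
            f"(need at least {k + 1})"
        )
    return mv


def mvmr_ivw(mv: MVMRSet) -> MVMREstimate:
    """Multivariable IVW: WLS of outcome betas on the exposure-beta matrix.

    No intercept; weights 1/se_outcome²; SEs carry the multiplicative
    overdispersion scale max(1, sqrt(RSS_w/(L-K))); p-values two-sided
    from t(L-K).

    Raises
    ------
    ValueError
        If the set is under-identified or the exposure matrix is rank
        deficient (collinear exposures).
    """
    X, y, sy = mv.matrices()
    L, k = X.shape
    if L < k + 1:
        raise ValueError("MVMR under-identified: need at least K+1 variants")
    # an exposure with identically-zero betas contributes nothing: drop it
    # from the fit (its coefficient is 0 by construction) so the model
    # degenerates gracefully to the lower-dimensional regression
    zero_cols = np.flatnonzero(np.all(X == 0.0, axis=0))
    active = np.setdiff1d(np.arange(k), zero_cols)
    Xa = X[:, active]
    rank = np.linalg.matrix_rank(Xa) if active.size else 0
    if rank < active.size:
        raise ValueError(
            f"exposure-beta matrix is rank deficient (rank {rank} < {active.size}); "
            f"collinear exposures among: "
            f"{', '.join(mv.exposure_labels[i] for i in active)}"
        )
    import statsmodels.api as sm

    fit = sm.WLS(y, Xa, weights=1.0 / sy**2).fit()
    sigma2 = float(fit.mse_resid)
    scale = np.sqrt(max(1.0, sigma2))
    theta = np.zeros(k)
    se = np.full(k, np.inf)
    theta[active] = np.asarray(fit.params, dtype=float)
    se[active] = np.sqrt(np.diag(fit.normalized_cov_params)) * scale
    pval = np.ones(k)
    pval[active] = 2.0 * stats.t.sf(
        np.abs(theta[active]) / se[active], L - active.size
    )
    return MVMREstimate(
        outcome_label=mv.outcome_label,
        exposure_labels=list(mv.exposure_labels),
        n_snp=L,
        theta=theta,
        se=se,
        ci_low=theta - Z95 * se,
        ci_high=theta + Z95 * se,
        pval=pval,
    )
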
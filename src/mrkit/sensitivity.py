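"""Heterogeneity and pleiotropy diagnostics, plus the study decision rules.

* Cochran's Q against chi²(L-1) tests heterogeneity of the per-variant
  ratio estimates; Q p < 0.05 selects the multiplicative-random-effects
  IVW model, otherwise the fixed-effect model.
* The MR-Egger intercept, with p < 0.05, flags directional pleiotropy.
* Leave-one-out re-estimates IVW with each variant removed in turn.
* A result is called robust when at least one of IVW, MR-Egger and the
  weighted median is significant and all three slopes share one sign.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EggerFit, MREstimate, _ratios, ivw
from .summary_io import HarmonizedSet

ALPHA_DEFAULT = 0.05


def cochran_q(hs: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q = sum w_j (theta_j - theta_IVW)², df = L-1, chi² p."""
    if len(hs) < 2:
        raise ValueError("cochran_q requires at least 2 variants")
    theta_j, se_j = _ratios(hs)
    w = 1.0 / se_j**2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    q = float(np.sum(w * (theta_j - theta) ** 2))
    df = len(hs) - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger_intercept_test(fit: EggerFit, alpha: float = ALPHA_DEFAULT) -> bool:
    """True iff the Egger intercept p-value flags directional pleiotropy."""
    return fit.intercept_pval < alpha


def select_primary_model(q_pval: float, alpha: float = ALPHA_DEFAULT) -> str:
    """'ivw_mre' under heterogeneity (Q p < alpha), else 'ivw_fe'."""
    if not 0.0 <= q_pval <= 1.0:
        raise ValueError("q_pval must lie in [0, 1]")
    return "ivw_mre" if q_pval < alpha else "ivw_fe"


def leave_one_out(hs: HarmonizedSet, effects_model: str = "mre") -> pd.DataFrame:
    """IVW re-estimated with each variant left out in turn (input order)."""
    if len(hs) < 3:
        raise ValueError("leave_one_out requires at least 3 variants")
    rows = []
    for rec in hs.records:
        est = ivw(hs.subset_excluding(rec.variant_id), effects_model)
        rows.append(
            {"left_out": rec.variant_id, "b": est.theta, "se": est.se, "pval": est.pval}
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_pval: float
    heterogeneous: bool
    pleiotropic: bool
    selected_model: str
    loo: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_frame(self, exposure: str = "", outcome: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "exposure": exposure,
                    "outcome": outcome,
                    "intercept": self.egger_intercept,
                    "intercept_p": self.egger_intercept_pval,
                    "Q": self.q_stat,
                    "Q_df": self.q_df,
                    "Q_pval": self.q_pval,
                    "heterogeneous": self.heterogeneous,
                    "pleiotropic": self.pleiotropic,
                    "selected_model": self.selected_model,
                }
            ]
        )


def sensitivity_report(
    hs: HarmonizedSet, egger: EggerFit, alpha: float = ALPHA_DEFAULT, effects_model: str = "mre"
) -> SensitivityReport:
    """Run the full diagnostic suite on one harmonized set."""
    q, df, q_p = cochran_q(hs)
    return SensitivityReport(
        q_stat=q,
        q_df=df,
        q_pval=q_p,
        egger_intercept=egger.intercept,
        egger_intercept_pval=egger.intercept_pval,
        heterogeneous=q_p < alpha,
        pleiotropic=egger_intercept_test(egger, alpha),
        selected_model=select_primary_model(q_p, alpha),
        loo=leave_one_out(hs, effects_model) if len(hs) >= 3 else pd.DataFrame(),
    )


@dataclass
class RobustnessCall:
    robust: bool
    rationale: str
    bonferroni_alpha: float


def robustness_call(
    ivw_est: MREstimate,
    egger: EggerFit,
    wm: MREstimate,
    alpha: float = ALPHA_DEFAULT,
    bonferroni_alpha: float | None = None,
) -> RobustnessCall:
    """Apply the robust-causality rule to the three main methods.

    Robust iff at least one of IVW, MR-Egger slope, weighted median has
    p < alpha AND all three slopes share one sign.  ``alpha`` is the raw
    threshold; a Bonferroni-adjusted threshold, when supplied, is recorded
    alongside the call for reporting.
    """
    trio = [("IVW", ivw_est), ("MR-Egger", egger.slope), ("WM", wm)]
    sig = [name for name, e in trio if e.pval < alpha]
    signs = {np.sign(e.theta) for _, e in trio}
    concordant = len(signs) == 1 and 0.0 not in signs
    robust = bool(sig) and concordant
    rationale = (
        f"significant at alpha={alpha:g}: {', '.join(sig) if sig else 'none'}; "
        f"slopes {'sign-concordant' if concordant else 'not sign-concordant'} "
        f"({', '.join(f'{name}={e.theta:+.4g}' for name, e in trio)})"
    )
    return RobustnessCall(
        robust=robust,
        rationale=rationale,
        bonferroni_alpha=bonferroni_alpha if bonferroni_alpha is not None else alpha,
    )


def export_diagnostics(
    hs: HarmonizedSet, estimates: list[MREstimate] | None = None
) -> dict[str, pd.DataFrame]:
    """Data tables behind the standard MR diagnostic plots.

    Returns ``scatter`` (per-variant effects plus per-method fitted
    slopes), ``funnel`` (ratio estimate vs precision, with the IVW
    vertical), and ``forest`` (per-method summary rows).  Rendering is
    left to any plotting layer.
    """
    estimates = estimates or []
    theta_j, se_j = _ratios(hs)
    scatter = hs.to_frame()[
        ["variant_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
    ].copy()
    for e in estimates:
        scatter[f"fit_{e.method}"] = e.theta * scatter["beta_exposure"]
    funnel = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in hs.records],
            "b_wald": theta_j,
            "precision": 1.0 / se_j,
        }
    )
    ivw_theta = [e.theta for e in estimates if e.method.startswith("ivw")]
    funnel["ivw_vertical"] = ivw_theta[0] if ivw_theta else np.nan
    forest = pd.DataFrame(
        [
            {
                "method": e.method,
                "nsnp": e.n_snp,
                "b": e.theta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
            }
            for e in estimates
        ]
    )
    return {"scatter": scatter, "funnel": funnel, "forest": forest}
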
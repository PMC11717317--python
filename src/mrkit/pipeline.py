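"""Full-study orchestration: SVMR across outcomes, the MVMR adjustment
grid, Bonferroni correction, robustness labelling, and reproducible output.

The single-variable arm harmonizes the exposure against each outcome,
runs the six-method estimator suite plus the sensitivity diagnostics, and
labels each outcome with the heterogeneity-based model choice and the
robust-causality rule.  The multivariable arm re-estimates the primary
exposure's direct effect adjusted for one co-exposure at a time.  Every
random draw derives from the single study seed, so one seed gives a
byte-identical output tree.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import all_estimates, ivw, mr_egger, results_table, weighted_median
from .instruments import SelectionConfig, filter_instruments
from .mvmr import assemble_mvmr_set, mvmr_ivw
from .sensitivity import (
    RobustnessCall,
    SensitivityReport,
    robustness_call,
    sensitivity_report,
)
from .summary_io import SummaryDataset, harmonize, read_summary_table

logger = logging.getLogger("mrkit")


def bonferroni_adjust(pvals, m: int):
    """Bonferroni correction: min(1, p * m) elementwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    arr = np.minimum(1.0, np.asarray(pvals, dtype=float) * m)
    return float(arr) if np.ndim(pvals) == 0 else arr


@dataclass
class StudyConfig:
    """Configuration for a full SVMR + MVMR study."""

    exposure: str | SummaryDataset
    outcomes: dict[str, str | SummaryDataset] = field(default_factory=dict)
    confounders: dict[str, str | SummaryDataset] = field(default_factory=dict)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    alpha: float = 0.05
    bonferroni_m: int | None = None  # defaults to the number of outcomes
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int = 0
    drop_palindromic: bool = True
    apply_instrument_filter: bool = True


@dataclass
class OutcomeResult:
    outcome_label: str
    estimates: pd.DataFrame
    sensitivity: SensitivityReport
    robustness: RobustnessCall
    pval_bonferroni: float


@dataclass
class ResultsBundle:
    per_outcome: dict[str, OutcomeResult] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    mvmr_grid: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def estimates_table(self) -> pd.DataFrame:
        frames = [r.estimates for r in self.per_outcome.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def sensitivity_table(self) -> pd.DataFrame:
        frames = [
            r.sensitivity.to_frame(exposure=r.estimates["exposure"].iloc[0], outcome=lbl)
            for lbl, r in self.per_outcome.items()
        ]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def write_dir(self, out_dir: str | Path) -> None:
        """Serialize the bundle to TSVs plus a run-manifest text file."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimates_table().to_csv(out / "estimates.tsv", sep="\t", index=False)
        self.sensitivity_table().to_csv(out / "sensitivity.tsv", sep="\t", index=False)
        loo = []
        for lbl, r in self.per_outcome.items():
            t = r.sensitivity.loo.copy()
            t.insert(0, "outcome", lbl)
            loo.append(t)
        (pd.concat(loo, ignore_index=True) if loo else pd.DataFrame()).to_csv(
            out / "leave_one_out.tsv", sep="\t", index=False
        )
        robust = pd.DataFrame(
            [
                {
                    "outcome": lbl,
                    "robust": r.robustness.robust,
                    "rationale": r.robustness.rationale,
                    "bonferroni_alpha": r.robustness.bonferroni_alpha,
                    "pval_bonferroni": r.pval_bonferroni,
                }
                for lbl, r in self.per_outcome.items()
            ]
        )
        robust.to_csv(out / "robustness.tsv", sep="\t", index=False)
        if not self.mvmr_grid.empty:
            self.mvmr_grid.to_csv(out / "mvmr.tsv", sep="\t", index=False)
        with open(out / "manifest.txt", "w") as fh:
            for k, v in self.manifest.items():
                fh.write(f"{k}: {v}\n")
            for line in self.log:
                fh.write(f"log: {line}\n")
            for lbl, msg in self.failures.items():
                fh.write(f"failure: {lbl}: {msg}\n")


def _as_dataset(src: str | SummaryDataset, label: str) -> SummaryDataset:
    from dataclasses import replace

    if isinstance(src, SummaryDataset):
        # relabel (shallow copy) so result tables carry the configured name
        return replace(src, trait_label=label)
    ds = read_summary_table(src, trait_label=label, provenance=str(src))
    return ds


def run_svmr(cfg: StudyConfig) -> ResultsBundle:
    """Single-variable MR of the exposure against every configured outcome.

    Per-outcome failures are recorded in ``bundle.failures`` and the run
    continues with the remaining outcomes.  Deterministic given
    ``cfg.seed``.
    """
    if not cfg.outcomes:
        raise ValueError("StudyConfig needs at least one outcome")
    exposure = _as_dataset(cfg.exposure, "exposure")
    bundle = ResultsBundle()
    m = cfg.bonferroni_m or len(cfg.outcomes)
    bundle.manifest = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "bonferroni_m": m,
        "n_boot": cfg.n_boot,
        "n_outcomes": len(cfg.outcomes),
        "exposure_variants": len(exposure),
    }
    if cfg.apply_instrument_filter:
        exposure, audit = filter_instruments(exposure, cfg.selection)
        bundle.manifest["instruments_retained"] = len(exposure)
        for vid, stage, reason in audit.removals:
            bundle.log.append(f"instrument excluded ({stage}): {vid}: {reason}")

    seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.outcomes))
    for (label, src), seed_seq in zip(sorted(cfg.outcomes.items()), seeds):
        try:
            outcome = _as_dataset(src, label)
            hs = harmonize(exposure, outcome, drop_palindromic=cfg.drop_palindromic)
            for rec in hs.audit:
                bundle.log.append(f"{label}: {rec.variant_id} {rec.action}")
            sub_seed = int(seed_seq.generate_state(1)[0] % (2**31))
            ests = all_estimates(
                hs, n_boot=cfg.n_boot, seed=sub_seed, bandwidth_factor=cfg.bandwidth_factor
            )
            egger = mr_egger(hs)
            report = sensitivity_report(hs, egger, alpha=cfg.alpha)
            primary = next(e for e in ests if e.method == report.selected_model)
            wm = next(e for e in ests if e.method == "weighted_median")
            call = robustness_call(
                primary, egger, wm, alpha=cfg.alpha, bonferroni_alpha=cfg.alpha / m
            )
            bundle.per_outcome[label] = OutcomeResult(
                outcome_label=label,
                estimates=results_table(hs, ests),
                sensitivity=report,
                robustness=call,
                pval_bonferroni=bonferroni_adjust(primary.pval, m),
            )
        except Exception as exc:  # per-outcome isolation
            logger.warning("outcome %s failed: %s", label, exc)
            bundle.failures[label] = str(exc)
    return bundle


def run_mvmr_grid(cfg: StudyConfig) -> pd.DataFrame:
    """K=2 MVMR of the primary exposure against each (outcome, confounder)
    pair: one grid row per pair, reporting the exposure's direct effect
    adjusted for that confounder.  Under-identified or failing pairs are
    flagged in an ``error`` column and the grid continues.
    """
    if not cfg.confounders:
        raise ValueError("run_mvmr_grid needs at least one confounder dataset")
    exposure = _as_dataset(cfg.exposure, "exposure")
    if cfg.apply_instrument_filter:
        exposure, _ = filter_instruments(exposure, cfg.selection)
    rows = []
    for conf_label, conf_src in sorted(cfg.confounders.items()):
        try:
            conf = _as_dataset(conf_src, conf_label)
            conf_inst = [
                a.variant_id
                for a in conf.associations.values()
                if a.pval < cfg.selection.pval_threshold
            ]
        except Exception as exc:
            for out_label in sorted(cfg.outcomes):
                rows.append(
                    {"outcome": out_label, "exposure": exposure.trait_label,
                     "adjusted_for": conf_label, "error": str(exc)}
                )
            continue
        for out_label, out_src in sorted(cfg.outcomes.items()):
            try:
                outcome = _as_dataset(out_src, out_label)
                mv = assemble_mvmr_set(
                    [exposure, conf],
                    outcome,
                    [exposure.variant_ids(), conf_inst],
                    drop_palindromic=cfg.drop_palindromic,
                )
                est = mvmr_ivw(mv)
                frame = est.to_frame()
                primary_row = frame[frame["exposure"] == exposure.trait_label].iloc[0].to_dict()
                primary_row["error"] = ""
                rows.append(primary_row)
            except Exception as exc:
                rows.append(
                    {"outcome": out_label, "exposure": exposure.trait_label,
                     "adjusted_for": conf_label, "error": str(exc)}
                )
    return pd.DataFrame(rows)


def run_study(cfg: StudyConfig) -> ResultsBundle:
    """SVMR plus (when confounders are configured) the MVMR grid."""
    bundle = run_svmr(cfg)
    if cfg.confounders:
        bundle.mvmr_grid = run_mvmr_grid(cfg)
    return bundle
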
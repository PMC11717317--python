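"""Instrument quality control for Mendelian randomization.

Candidate instruments pass through a chain of filters mirroring standard
two-sample MR practice: genome-wide significance (p < 5e-8), minor-allele
frequency > 1%, LD clumping (r² > 0.001 within a 10,000 kb window), removal
of a complex-LD region (the HLA locus by default), a user-supplied
confounder-associated exclusion list, and removal of weak instruments
(F < 10).

Two instrument-strength statistics are provided:

``compute_f_wald``
    F = (beta / se)², the squared Wald z-score.  This is the pipeline
    default for the weak-instrument filter: it is the statistic per-variant
    F columns in published instrument tables are computed from.
``compute_f_from_r2``
    F = R² (N - k - 1) / (k (1 - R²)) with R² = 2 beta² EAF (1 - EAF), the
    textbook variance-explained form.  For a single strong variant in a
    large GWAS it is typically an order of magnitude larger than the
    per-variant Wald form; both are exposed and the choice is explicit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .summary_io import SummaryDataset

logger = logging.getLogger("mrkit")

#: HLA / MHC locus on chromosome 6 (GRCh37), excluded by default for its
#: complex long-range LD.
HLA_REGION = ("6", 25_000_000, 34_000_000)


@dataclass
class SelectionConfig:
    """Thresholds for the instrument-selection chain (study defaults)."""

    pval_threshold: float = 5e-8
    maf_min: float = 0.01
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    excluded_regions: tuple[tuple[str, int, int], ...] = (HLA_REGION,)
    excluded_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.pval_threshold, self.maf_min, self.clump_window_kb, self.f_min) <= 0:
            raise ValueError("all thresholds must be strictly positive")
        if not 0.0 < self.clump_r2 < 1.0:
            raise ValueError("clump_r2 must lie in (0, 1)")


@dataclass
class LDSource:
    """Pairwise r² lookup backed by a symmetric table.

    Missing pairs are treated as unlinked (r² = 0) by :func:`ld_clump`,
    with a logged warning, so a sparse table listing only correlated pairs
    is sufficient.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    note: str = ""

    def r2(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        v = self.pairs.get((a, b))
        if v is None:
            v = self.pairs.get((b, a))
        return v

    @classmethod
    def from_tsv(cls, path, note: str = "") -> "LDSource":
        frame = pd.read_csv(path, sep="\t")
        pairs = {
            (str(r.snp_a), str(r.snp_b)): float(r.r2)
            for r in frame.itertuples(index=False)
        }
        return cls(pairs, note or str(path))


@dataclass
class SelectionAudit:
    """Per-stage survivor counts and per-variant removal reasons."""

    stage_counts: dict[str, int] = field(default_factory=dict)
    removals: list[tuple[str, str, str]] = field(default_factory=list)  # (id, stage, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removals, columns=["variant_id", "stage", "reason"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_r2(beta: float, eaf: float) -> float:
    """Variance in the exposure explained by one variant: 2 beta² EAF (1-EAF)."""
    if not 0.0 <= eaf <= 1.0:
        raise ValueError("eaf must lie in [0, 1]")
    return 2.0 * beta * beta * eaf * (1.0 - eaf)


def compute_f_from_r2(r2: float, n_samples: float, k_variants: int = 1) -> float:
    """Instrument F statistic from variance explained: R² (N-k-1) / (k (1-R²))."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must lie in [0, 1)")
    if k_variants < 1:
        raise ValueError("k_variants must be >= 1")
    if n_samples <= k_variants + 1:
        raise ValueError("n_samples must exceed k_variants + 1")
    return r2 * (n_samples - k_variants - 1) / (k_variants * (1.0 - r2))


def compute_f_wald(beta: float, se: float) -> float:
    """Per-variant F statistic as the squared Wald ratio, (beta/se)²."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = beta / se
    return z * z


def filter_instruments(
    ds: SummaryDataset, cfg: SelectionConfig | None = None
) -> tuple[SummaryDataset, SelectionAudit]:
    """Apply the non-LD filters: significance, MAF, weak-instrument F,
    exclusion list, excluded regions.

    Each removed variant is audited with its first failing rule, tested in
    the order significance -> MAF -> F -> exclusion list -> region.  The
    region filter needs chromosome/position and silently passes variants
    without coordinates.  Retained rows keep their input order.

    Raises
    ------
    ValueError
        If the input is empty or no variant survives.
    """
    cfg = cfg or SelectionConfig()
    if len(ds) == 0:
        raise ValueError("filter_instruments requires a nonempty dataset")
    excluded = set(cfg.excluded_variants)
    audit = SelectionAudit()
    survivors: dict[str, object] = dict(ds.associations)

    def stage(name: str, fails) -> None:
        nonlocal survivors
        kept = {}
        for vid, a in survivors.items():
            reason = fails(a)
            if reason:
                audit.removals.append((vid, name, reason))
            else:
                kept[vid] = a
        survivors = kept
        audit.stage_counts[f"post_{name}"] = len(survivors)

    audit.stage_counts["input"] = len(survivors)
    stage(
        "significance",
        lambda a: None if a.pval < cfg.pval_threshold else f"pval {a.pval:g} >= {cfg.pval_threshold:g}",
    )
    stage(
        "maf",
        lambda a: (
            None
            if a.maf is None or a.maf > cfg.maf_min
            else f"MAF {a.maf:g} <= {cfg.maf_min:g}"
        ),
    )
    stage(
        "f",
        lambda a: (
            None
            if compute_f_wald(a.beta, a.se) >= cfg.f_min
            else f"weak instrument: F {compute_f_wald(a.beta, a.se):.3f} < {cfg.f_min:g}"
        ),
    )
    stage(
        "exclusion_list",
        lambda a: "on user exclusion list" if a.variant_id in excluded else None,
    )

    def in_region(a) -> str | None:
        if a.chrom is None or a.pos is None:
            return None
        for chrom, start, end in cfg.excluded_regions:
            if str(a.chrom) == str(chrom) and start <= a.pos <= end:
                return f"inside excluded region {chrom}:{start}-{end}"
        return None

    stage("region", in_region)

    if not survivors:
        raise ValueError(
            "no instruments survive the filters; review the thresholds in SelectionConfig"
        )
    out = SummaryDataset(ds.trait_label, dict(survivors), ds.provenance)
    return out, audit


def ld_clump(
    ds: SummaryDataset, ld: LDSource, cfg: SelectionConfig | None = None
) -> tuple[SummaryDataset, SelectionAudit]:
    """Greedy LD clumping: keep the most significant variant of each clump.

    Variants are visited in ascending p-value order (ties broken by variant
    ID); a variant is rejected if it lies within ``clump_window_kb`` of an
    already-accepted variant on the same chromosome with r² above
    ``clump_r2``.  The output is in that canonical order, so clumping does
    not depend on input row order.

    Raises
    ------
    ValueError
        If any variant lacks chromosome or position.
    """
    cfg = cfg or SelectionConfig()
    missing = [a.variant_id for a in ds.associations.values() if a.chrom is None or a.pos is None]
    if missing:
        raise ValueError(f"ld_clump requires chrom/pos for all variants; missing for {missing[:5]}")
    audit = SelectionAudit()
    audit.stage_counts["input"] = len(ds)
    ordered = sorted(ds.associations.values(), key=lambda a: (a.pval, a.variant_id))
    window_bp = cfg.clump_window_kb * 1000.0
    accepted: list = []
    for cand in ordered:
        hit = None
        for acc in accepted:
            if str(acc.chrom) != str(cand.chrom):
                continue
            if abs(acc.pos - cand.pos) > window_bp:
                continue
            r2 = ld.r2(acc.variant_id, cand.variant_id)
            if r2 is None:
                logger.warning(
                    "LD source has no entry for (%s, %s); assuming r2=0",
                    acc.variant_id,
                    cand.variant_id,
                )
                continue
            if r2 > cfg.clump_r2:
                hit = (acc.variant_id, r2)
                break
        if hit is None:
            accepted.append(cand)
        else:
            audit.removals.append(
                (cand.variant_id, "clump", f"r2 {hit[1]:g} with {hit[0]} within window")
            )
    audit.stage_counts["post_clump"] = len(accepted)
    out = SummaryDataset(ds.trait_label, {a.variant_id: a for a in accepted}, ds.provenance)
    return out, audit
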
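"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR consumes per-variant association estimates for an exposure and
an outcome measured in separate samples.  Before any estimator can run, the
two tables must be aligned so that every variant's effect is expressed for
the same effect allele in both studies ("harmonization").  This module holds
the record types, the table reader, and the harmonization rules:

* identical allele pairs are kept as-is;
* swapped allele labels flip the sign of the outcome beta (and EAF -> 1-EAF);
* pairs differing by strand complement (A/G vs T/C) are aligned after
  complementing;
* palindromic variants (A/T, C/G), whose strand is ambiguous, are dropped by
  default;
* irreconcilable allele pairs are dropped as mismatches.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import pandas as pd

logger = logging.getLogger("mrkit")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Column names accepted without an explicit mapping.
STANDARD_COLUMNS: dict[str, str] = {
    "SNP": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "eaf": "eaf",
    "pval": "pval",
    "chr": "chrom",
    "pos": "pos",
    "samplesize": "n",
}

REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float = 1.0
    chrom: str | None = None
    pos: int | None = None
    n: float | None = None

    def problems(self) -> list[str]:
        """Invariant violations, empty if the record is valid."""
        out = []
        if self.effect_allele not in VALID_ALLELES:
            out.append(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            out.append(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            out.append("effect allele equals other allele")
        if not (self.se > 0) or math.isnan(self.se):
            out.append("nonpositive SE")
        if self.eaf is not None and not math.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            out.append("EAF outside [0, 1]")
        if not (0.0 < self.pval <= 1.0):
            out.append("p-value outside (0, 1]")
        if math.isnan(self.beta):
            out.append("missing beta")
        return out

    @property
    def maf(self) -> float | None:
        if self.eaf is None or math.isnan(self.eaf):
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass
class SummaryDataset:
    """A labelled collection of variant associations for one trait."""

    trait_label: str
    associations: dict[str, VariantAssociation] = field(default_factory=dict)
    provenance: str = ""
    audit: list[tuple[str, str]] = field(default_factory=list)  # (variant_id, reason)

    def __len__(self) -> int:
        return len(self.associations)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.associations

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        return self.associations[variant_id]

    def variant_ids(self) -> list[str]:
        return list(self.associations)

    def add(self, assoc: VariantAssociation) -> bool:
        """Add a record if valid and not a duplicate; audit otherwise."""
        probs = assoc.problems()
        if probs:
            self.audit.append((assoc.variant_id, "; ".join(probs)))
            logger.warning("%s: excluded %s (%s)", self.trait_label, assoc.variant_id, "; ".join(probs))
            return False
        if assoc.variant_id in self.associations:
            self.audit.append((assoc.variant_id, "duplicate variant_id (first occurrence kept)"))
            return False
        self.associations[assoc.variant_id] = assoc
        return True

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        keep = set(variant_ids)
        return SummaryDataset(
            self.trait_label,
            {vid: a for vid, a in self.associations.items() if vid in keep},
            self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "SNP": a.variant_id,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "beta": a.beta,
                "se": a.se,
                "eaf": a.eaf,
                "pval": a.pval,
                "chr": a.chrom,
                "pos": a.pos,
                "samplesize": a.n,
            }
            for a in self.associations.values()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, trait_label: str, provenance: str = "") -> "SummaryDataset":
        ds = cls(trait_label, provenance=provenance)
        for row in frame.itertuples(index=False):
            d = row._asdict()
            ds.add(
                VariantAssociation(
                    variant_id=str(d["SNP"]),
                    effect_allele=str(d["effect_allele"]).upper(),
                    other_allele=str(d["other_allele"]).upper(),
                    beta=float(d["beta"]),
                    se=float(d["se"]),
                    eaf=_opt_float(d.get("eaf")),
                    pval=float(d["pval"]),
                    chrom=None if pd.isna(d.get("chr")) else str(d.get("chr")),
                    pos=None if pd.isna(d.get("pos")) else int(d.get("pos")),
                    n=_opt_float(d.get("samplesize")),
                )
            )
        return ds

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _opt_float(x) -> float | None:
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else x


def read_summary_table(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    trait_label: str = "trait",
    provenance: str = "",
) -> SummaryDataset:
    """Read a delimited GWAS summary table into a :class:`SummaryDataset`.

    Parameters
    ----------
    source
        Path or open text handle; tab- or comma-delimited with a header row.
        The delimiter is auto-detected from the header line (tab preferred).
    column_map
        Mapping from column names in the file to the standard fields
        (``variant_id``, ``effect_allele``, ``other_allele``, ``beta``,
        ``se``, ``eaf``, ``pval``, ``chrom``, ``pos``, ``n``).  When omitted,
        the standard names (SNP, effect_allele, ...) are assumed.

    Rows violating the record invariants (nonpositive SE, EAF outside
    [0, 1], ...) are excluded and logged; duplicated variant IDs keep the
    first occurrence.  Allele strings are upper-cased.

    Raises
    ------
    KeyError
        If a mapped column is missing from the file.
    ValueError
        If no valid rows remain.
    """
    frame = _read_delimited(source)
    cmap = dict(column_map) if column_map is not None else {
        c: f for c, f in STANDARD_COLUMNS.items() if c in frame.columns
    }
    missing = [c for c in cmap if c not in frame.columns]
    if missing:
        raise KeyError(f"mapped column(s) missing from table: {', '.join(missing)}")
    fields = set(cmap.values())
    absent = [f for f in REQUIRED_FIELDS if f not in fields]
    if absent:
        raise KeyError(f"column map does not cover required field(s): {', '.join(absent)}")

    renamed = frame.rename(columns=cmap)
    ds = SummaryDataset(trait_label, provenance=provenance)
    for _, row in renamed.iterrows():
        try:
            assoc = VariantAssociation(
                variant_id=str(row["variant_id"]),
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                beta=float(row["beta"]),
                se=float(row["se"]),
                eaf=_opt_float(row["eaf"]) if "eaf" in renamed.columns else None,
                pval=float(row["pval"]),
                chrom=str(row["chrom"]) if "chrom" in renamed.columns and not pd.isna(row["chrom"]) else None,
                pos=int(row["pos"]) if "pos" in renamed.columns and not pd.isna(row["pos"]) else None,
                n=_opt_float(row["n"]) if "n" in renamed.columns else None,
            )
        except (TypeError, ValueError) as exc:
            ds.audit.append((str(row.get("variant_id", "?")), f"unparseable row: {exc}"))
            continue
        ds.add(assoc)
    if len(ds) == 0:
        raise ValueError(f"no valid rows in summary table for {trait_label!r}")
    return ds


def _read_delimited(source: str | IO[str]) -> pd.DataFrame:
    if hasattr(source, "read"):
        text = source.read()
        import io as _io

        header = text.splitlines()[0] if text else ""
        sep = "\t" if "\t" in header else ","
        return pd.read_csv(_io.StringIO(text), sep=sep)
    with open(source) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(source, sep=sep)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is its own strand complement ({A,T} or {C,G})."""
    pair = {effect_allele, other_allele}
    if not pair <= VALID_ALLELES:
        raise ValueError(f"non-ACGT allele in pair {effect_allele}/{other_allele}")
    return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass
class HarmonizedRecord:
    """Exposure/outcome associations for one variant on a common effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    eaf_exposure: float | None
    beta_outcome: float
    se_outcome: float
    eaf_outcome: float | None
    action: str  # kept | sign_flipped | dropped_palindromic | dropped_mismatch
    pval_exposure: float = 1.0
    pval_outcome: float = 1.0


@dataclass
class HarmonizedSet:
    """Retained harmonized records plus an audit of the drops."""

    exposure_label: str
    outcome_label: str
    records: list[HarmonizedRecord] = field(default_factory=list)
    audit: list[HarmonizedRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "variant_id", "effect_allele", "other_allele",
            "beta_exposure", "se_exposure", "eaf_exposure",
            "beta_outcome", "se_outcome", "eaf_outcome",
            "pval_exposure", "pval_outcome", "action",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records], columns=cols)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"variant_id": r.variant_id, "action": r.action} for r in self.audit],
            columns=["variant_id", "action"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def subset_excluding(self, variant_id: str) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_label,
            self.outcome_label,
            [r for r in self.records if r.variant_id != variant_id],
        )


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    drop_palindromic: bool = True,
) -> HarmonizedSet:
    """Align exposure and outcome associations onto the exposure effect allele.

    Shared variants are processed in exposure-file order.  Palindromic pairs
    are dropped when ``drop_palindromic`` (the default, matching the study's
    rule); strand-complement pairs are aligned after complementing; allele
    combinations that cannot be reconciled are dropped as mismatches.

    Raises
    ------
    ValueError
        If either dataset is empty or no variant is shared.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize requires nonempty exposure and outcome datasets")
    shared = [vid for vid in exposure.variant_ids() if vid in outcome]
    if not shared:
        raise ValueError(
            f"no shared variants between {exposure.trait_label!r} and {outcome.trait_label!r}"
        )
    hs = HarmonizedSet(exposure.trait_label, outcome.trait_label)
    for vid in shared:
        ex, oc = exposure[vid], outcome[vid]
        rec = _harmonize_pair(ex, oc, drop_palindromic)
        if rec.action in ("kept", "sign_flipped"):
            hs.records.append(rec)
        else:
            hs.audit.append(rec)
    return hs


def _harmonize_pair(
    ex: VariantAssociation, oc: VariantAssociation, drop_palindromic: bool
) -> HarmonizedRecord:
    e1, o1 = ex.effect_allele, ex.other_allele
    e2, o2 = oc.effect_allele, oc.other_allele

    def record(action, beta_oc, eaf_oc):
        return HarmonizedRecord(
            variant_id=ex.variant_id,
            effect_allele=e1,
            other_allele=o1,
            beta_exposure=ex.beta,
            se_exposure=ex.se,
            eaf_exposure=ex.eaf,
            beta_outcome=beta_oc,
            se_outcome=oc.se,
            eaf_outcome=eaf_oc,
            action=action,
            pval_exposure=ex.pval,
            pval_outcome=oc.pval,
        )

    if is_palindromic(e1, o1) and drop_palindromic:
        return record("dropped_palindromic", oc.beta, oc.eaf)

    flipped_eaf = None if oc.eaf is None else 1.0 - oc.eaf
    if (e2, o2) == (e1, o1):
        return record("kept", oc.beta, oc.eaf)
    if (e2, o2) == (o1, e1):
        return record("sign_flipped", -oc.beta, flipped_eaf)
    # strand flip: outcome alleles are the complement of the exposure alleles
    ce2, co2 = COMPLEMENT[e2], COMPLEMENT[o2]
    if (ce2, co2) == (e1, o1):
        return record("kept", oc.beta, oc.eaf)
    if (ce2, co2) == (o1, e1):
        return record("sign_flipped", -oc.beta, flipped_eaf)
    return record("dropped_mismatch", oc.beta, oc.eaf)
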
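"""Bundled reference tables.

``load_hoa_instruments``
    The published table of 40 genome-wide-significant hip-osteoarthritis
    instruments (effect/other allele, beta, EAF, SE, p, per-variant F,
    nearest gene, consequence), from the Genetics of Osteoarthritis
    meta-analysis scale (N ≈ 370,002).
``load_hoa_stroke_sensitivity``
    The reported sensitivity statistics (MR-Egger intercept and p,
    Cochran's Q and p) for hip osteoarthritis against the five stroke
    outcomes (AS, AIS, CES, LAS, SVS).
"""
from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .summary_io import SummaryDataset, is_palindromic

#: Exposure GWAS sample size behind the bundled instrument table.
HOA_SAMPLE_SIZE = 370_002


def _data_path(name: str):
    return resources.files("mrkit").joinpath("data", name)


def load_hoa_instruments_frame() -> pd.DataFrame:
    """The bundled instrument table as a DataFrame, verbatim."""
    with resources.as_file(_data_path("hoa_instruments.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_hoa_instruments(warn_palindromic: bool = True) -> SummaryDataset:
    """The bundled instrument table as a :class:`SummaryDataset`.

    The published table contains one palindromic variant (rs2268023, A/T)
    despite the study's stated palindrome-removal rule; it is kept
    verbatim and flagged with a warning rather than silently dropped.
    """
    frame = load_hoa_instruments_frame()
    ds = SummaryDataset.from_frame(
        frame.rename(columns={"samplesize": "n"}),
        trait_label="HOA",
        provenance="bundled hip-osteoarthritis instrument table",
    )
    if warn_palindromic:
        pal = [
            a.variant_id
            for a in ds.associations.values()
            if is_palindromic(a.effect_allele, a.other_allele)
        ]
        if pal:
            warnings.warn(
                f"bundled instrument table contains palindromic variant(s) "
                f"{', '.join(pal)} despite the palindrome-removal rule; kept verbatim",
                UserWarning,
                stacklevel=2,
            )
    return ds


def load_hoa_stroke_sensitivity() -> pd.DataFrame:
    """Reported per-outcome sensitivity statistics (intercept, Q, p-values)."""
    with resources.as_file(_data_path("hoa_stroke_sensitivity.tsv")) as p:
        return pd.read_csv(p, sep="\t")
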
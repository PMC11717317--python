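import numpy as np
import pytest

from mrkit import HarmonizedRecord, HarmonizedSet, SummaryDataset, VariantAssociation


def make_assoc(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3, pval=1e-9, **kw):
    return VariantAssociation(vid, ea, oa, beta, se, eaf, pval, **kw)


def make_dataset(rows, label="trait"):
    """rows: iterable of dicts accepted by make_assoc."""
    ds = SummaryDataset(label)
    for r in rows:
        ds.add(make_assoc(**r))
    return ds


def make_harmonized(bx, by, sy, sx=None, label_x="X", label_y="Y"):
    """A HarmonizedSet built directly from effect arrays (all 'kept')."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full_like(bx, 0.01, dtype=float) if sx is None else np.asarray(sx)
    recs = [
        HarmonizedRecord(
            variant_id=f"rs{j}",
            effect_allele="A",
            other_allele="G",
            beta_exposure=float(bx[j]),
            se_exposure=float(sx[j]),
            eaf_exposure=0.3,
            beta_outcome=float(by[j]),
            se_outcome=float(sy[j]),
            eaf_outcome=0.3,
            action="kept",
        )
        for j in range(len(bx))
    ]
    return HarmonizedSet(label_x, label_y, recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
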
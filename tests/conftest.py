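import numpy as np
import pytest

from netmr.harmonize import ALIGNED, HarmonizedRecord, HarmonizedSet
from netmr.io import SummaryDataset, VariantAssociation


def make_hset(beta_exp, beta_out, se_out, se_exp=None, binary=False, name="exp", out="out"):
    """Build a HarmonizedSet directly from effect arrays (already aligned)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    se_exp = np.full_like(beta_exp, 1e-4) if se_exp is None else np.asarray(se_exp, dtype=float)
    records = [
        HarmonizedRecord(f"rs{i + 1}", float(bx), float(sx), float(by), float(sy),
                         0.3, 0.3, ALIGNED)
        for i, (bx, sx, by, sy) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]
    return HarmonizedSet(name, out, records, outcome_binary=binary)


def make_dataset(rows, name="trait", trait_type="quantitative", n=10_000):
    """rows: iterable of (variant_id, ea, oa, beta, se, p[, eaf[, n]])."""
    records = {}
    for row in rows:
        rec = VariantAssociation(*row)
        records[rec.variant_id] = rec
    return SummaryDataset(name, trait_type, n, records)


@pytest.fixture
def three_record_set():
    """Three instruments with equal IVW weights 100 and ratios 0.5, 0.55, 0.47333."""
    return make_hset([0.10, 0.20, 0.15], [0.050, 0.110, 0.071], [0.01, 0.02, 0.015])


def random_hset(rng, k, binary=False):
    bx = rng.uniform(0.03, 0.2, k) * rng.choice([-1, 1], k)
    sy = rng.uniform(0.005, 0.05, k)
    by = 0.4 * bx + rng.normal(0, sy)
    sx = rng.uniform(0.002, 0.01, k)
    return make_hset(bx, by, sy, se_exp=sx, binary=binary)
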
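"""Instrument selection and strength: significance filter, LD clumping, R²/F.

Instruments are genome-wide-significant variants (p < 5e-8 by convention),
pruned to mutual independence by greedy p-ranked clumping against a pairwise
r² table.  Strength is quantified per SNP by the variance explained on a
standardized trait, R² = 2·EAF·(1−EAF)·β², with F = (n−2)·R²/(1−R²), and at
the genetic-risk-score level by F = ((n−k−1)/k)·R²/(1−R²) on the summed R².
Instruments with F < 10 are flagged as conventionally weak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io import LdTable, SummaryDataset

GENOME_WIDE_P = 5e-8
WEAK_F_THRESHOLD = 10.0


def select_significant(dataset: SummaryDataset, p_threshold: float = GENOME_WIDE_P) -> list[str]:
    """Ids with p below threshold, sorted by ascending p then id."""
    if not 0 < p_threshold < 1:
        raise ConfigurationError(f"p_threshold {p_threshold} outside (0, 1)")
    hits = [(r.pvalue, r.variant_id) for r in dataset.records.values() if r.pvalue < p_threshold]
    return [vid for _, vid in sorted(hits)]


def clump(candidates: list[str], ld: LdTable, r2_threshold: float = 0.001) -> list[str]:
    """Greedy p-ranked clumping: accept the best remaining candidate, discard
    everything correlated with it above ``r2_threshold``; repeat.

    ``candidates`` must already be sorted by ascending p-value (the order
    :func:`select_significant` produces)."""
    kept: list[str] = []
    for vid in candidates:
        if all(ld.r2(vid, k) <= r2_threshold for k in kept):
            kept.append(vid)
    return kept


def snp_strength(beta: float, eaf: float, n: float) -> tuple[float, float]:
    """Per-SNP (R², F) for a standardized quantitative trait."""
    if not 0 < eaf < 1:
        raise ValidationError(f"eaf {eaf} outside (0, 1)")
    if n <= 3:
        raise ValidationError(f"sample size {n} too small")
    r2 = 2.0 * eaf * (1.0 - eaf) * beta * beta
    if r2 >= 1:
        raise ValidationError(f"per-SNP R2 = {r2} >= 1: beta not on a standardized scale")
    f = (n - 2.0) * r2 / (1.0 - r2)
    return r2, f


def grs_strength(total_r2: float, k: int, n: float) -> float:
    """Joint F of a k-SNP genetic risk score explaining ``total_r2``."""
    if not 0 < total_r2 < 1:
        raise ValidationError(f"total_r2 {total_r2} outside (0, 1)")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n <= k + 1:
        raise ValidationError(f"n = {n} insufficient for k = {k} instruments")
    return ((n - k - 1.0) / k) * total_r2 / (1.0 - total_r2)


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP and score-level strength."""

    ids: list[str]
    per_snp_r2: list[float]
    per_snp_f: list[float]
    total_r2: float
    grs_f: float
    k: int
    n: float
    weak_ids: list[str] = field(default_factory=list)


def build_instrument_set(dataset: SummaryDataset, ids: list[str], n: float | None = None) -> InstrumentSet:
    """Compute strength statistics for an already-selected instrument list.

    ``total_r2`` is the plain sum of per-SNP R² (additive after clumping to
    independence).  For binary exposures the log-odds scale makes R²/F an
    approximation; results are still reported.  Variants lacking EAF are
    assigned R² = F = NaN-free zeros and flagged weak.
    """
    n = float(n if n is not None else dataset.sample_size)
    r2s, fs, weak = [], [], []
    for vid in ids:
        rec = dataset[vid]
        n_i = float(rec.n) if rec.n else n
        if rec.eaf is None:
            r2, f = 0.0, 0.0
        else:
            r2, f = snp_strength(rec.beta, rec.eaf, n_i)
        r2s.append(r2)
        fs.append(f)
        if f < WEAK_F_THRESHOLD:
            weak.append(vid)
    total_r2 = sum(r2s)
    grs_f = grs_strength(total_r2, len(ids), n) if 0 < total_r2 < 1 and n > len(ids) + 1 else 0.0
    return InstrumentSet(list(ids), r2s, fs, total_r2, grs_f, len(ids), n, weak)


def write_instrument_report(dataset: SummaryDataset, iset: InstrumentSet, path) -> None:
    rows = []
    for vid, r2, f in zip(iset.ids, iset.per_snp_r2, iset.per_snp_f):
        rec = dataset[vid]
        rows.append(
            (vid, rec.beta, rec.se, rec.pvalue, rec.eaf, r2, f, vid in set(iset.weak_ids))
        )
    pd.DataFrame(
        rows, columns=["variant_id", "beta", "se", "p", "eaf", "r2", "f", "flag_weak"]
    ).to_csv(path, sep="\t", index=False)
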
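"""Alignment of exposure and outcome summary statistics to a shared effect allele.

Two-sample MR needs the per-SNP exposure and outcome effects expressed on the
same effect allele.  Beyond trivial allele swaps, files may report opposite
genome strands (resolved by base complement), and palindromic variants (A/T,
C/G) are strand-ambiguous from alleles alone and must be resolved — or
dropped — using effect-allele frequency.  Instruments absent from the outcome
panel may be replaced by a high-LD proxy when an r² table is supplied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, HarmonizationError
from .io import LdTable, SummaryDataset, VariantAssociation, flip_record

__all__ = [
    "HarmonizedRecord",
    "HarmonizedSet",
    "harmonize",
    "flip_record",
    "write_audit",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# status labels
ALIGNED = "aligned"
FLIPPED = "flipped"
STRAND_CORRECTED = "strand_corrected"
PROXY_SUBSTITUTED = "proxy_substituted"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"
DROPPED_MISSING = "dropped_missing"

RETAINED_STATUSES = frozenset({ALIGNED, FLIPPED, STRAND_CORRECTED, PROXY_SUBSTITUTED})


def is_palindromic(a: str, b: str) -> bool:
    return COMPLEMENT[a] == b


@dataclass(frozen=True, slots=True)
class HarmonizedRecord:
    """Exposure and outcome effects for one instrument on a common effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    status: str
    proxy_id: str | None = None


@dataclass
class HarmonizedSet:
    """Retained harmonized records plus a per-status audit trail."""

    exposure_name: str
    outcome_name: str
    records: list[HarmonizedRecord]
    audit: Counter = field(default_factory=Counter)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)
    outcome_binary: bool = False

    @property
    def k(self) -> int:
        return len(self.records)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([r.beta_exp for r in self.records])
        sx = np.array([r.se_exp for r in self.records])
        by = np.array([r.beta_out for r in self.records])
        sy = np.array([r.se_out for r in self.records])
        return bx, sx, by, sy

    def subset(self, keep_ids) -> "HarmonizedSet":
        keep = set(keep_ids)
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            [r for r in self.records if r.variant_id in keep],
            audit=Counter(self.audit),
            dropped=list(self.dropped),
            outcome_binary=self.outcome_binary,
        )

    def ids(self) -> list[str]:
        return [r.variant_id for r in self.records]


def _align(exp: VariantAssociation, out: VariantAssociation, window: float):
    """Return (aligned outcome record, status) or (None, drop-status)."""
    ea, oa = exp.effect_allele, exp.other_allele
    if is_palindromic(ea, oa):
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return None, DROPPED_MISMATCH
        if exp.eaf is None or out.eaf is None:
            return None, DROPPED_PALINDROMIC
        lo, hi = 0.5 - window, 0.5 + window
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return None, DROPPED_PALINDROMIC
        # textual alignment first, then check minor-allele concordance:
        # a discordant frequency means the file is on the opposite strand,
        # which for a palindrome is equivalent to one further flip.
        cand = out if out.effect_allele == ea else flip_record(out)
        swapped = cand is not out
        if (exp.eaf < 0.5) == (cand.eaf < 0.5):
            return cand, (FLIPPED if swapped else ALIGNED)
        return flip_record(cand), STRAND_CORRECTED

    if (out.effect_allele, out.other_allele) == (ea, oa):
        return out, ALIGNED
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return flip_record(out), FLIPPED
    cea, coa = COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]
    if (cea, coa) == (ea, oa):
        return out, STRAND_CORRECTED
    if (cea, coa) == (oa, ea):
        return flip_record(out), STRAND_CORRECTED
    return None, DROPPED_MISMATCH


def _best_proxies(variant_id: str, outcome: SummaryDataset, ld: LdTable, r2_min: float):
    cands = [
        (r2, b) for b, r2 in ld.neighbors(variant_id).items() if r2 >= r2_min and b in outcome
    ]
    # highest r² first; lexicographic id breaks ties deterministically
    return [b for _, b in sorted(cands, key=lambda t: (-t[0], t[1]))]


def _orient_proxy(exp: VariantAssociation, proxy_out: VariantAssociation):
    """Orient a proxy's outcome record by frequency matching against the
    instrument's exposure EAF (alleles differ between the two variants, so
    allele logic cannot apply; at r² ≥ 0.8 the correlated alleles have nearly
    identical frequencies).  Returns None when frequencies are unavailable."""
    if exp.eaf is None or proxy_out.eaf is None:
        return None
    flipped = flip_record(proxy_out)
    return proxy_out if abs(proxy_out.eaf - exp.eaf) <= abs(flipped.eaf - exp.eaf) else flipped


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    instrument_ids,
    palindrome_window: float = 0.08,
    ld: LdTable | None = None,
    proxy_r2_min: float = 0.8,
) -> HarmonizedSet:
    """Align each instrument's outcome record to the exposure effect allele.

    Allele swaps negate the outcome beta; strand flips are complemented;
    palindromic variants are frequency-inferred inside
    ``[0.5 - palindrome_window, 0.5 + palindrome_window]``-excluded bands or
    dropped; instruments missing from the outcome are proxy-substituted when
    an LD table is supplied (best r² ≥ ``proxy_r2_min``).  Raises
    :class:`HarmonizationError` when nothing is retained.
    """
    if not 0 <= palindrome_window < 0.5:
        raise ConfigurationError(f"palindrome_window {palindrome_window} outside [0, 0.5)")
    missing = [i for i in instrument_ids if i not in exposure]
    if missing:
        raise ConfigurationError(f"instrument ids absent from exposure dataset: {missing[:5]}")

    records: list[HarmonizedRecord] = []
    audit: Counter = Counter()
    dropped: list[tuple[str, str, str]] = []

    for vid in instrument_ids:
        exp = exposure[vid]
        out = outcome.records.get(vid)
        if out is None:
            rec = None
            if ld is not None:
                for pid in _best_proxies(vid, outcome, ld, proxy_r2_min):
                    oriented = _orient_proxy(exp, outcome[pid])
                    if oriented is not None:
                        rec = HarmonizedRecord(
                            vid, exp.beta, exp.se, oriented.beta, oriented.se,
                            exp.eaf, oriented.eaf, PROXY_SUBSTITUTED, proxy_id=pid,
                        )
                        break
            if rec is None:
                audit[DROPPED_MISSING] += 1
                dropped.append((vid, DROPPED_MISSING, "absent from outcome, no usable proxy"))
            else:
                audit[PROXY_SUBSTITUTED] += 1
                records.append(rec)
            continue

        aligned, status = _align(exp, out, palindrome_window)
        if aligned is None:
            audit[status] += 1
            dropped.append((vid, status, "irreconcilable alleles" if status == DROPPED_MISMATCH
                            else "ambiguous palindrome"))
            continue
        audit[status] += 1
        records.append(
            HarmonizedRecord(
                vid, exp.beta, exp.se, aligned.beta, aligned.se, exp.eaf, aligned.eaf, status
            )
        )

    if not records:
        raise HarmonizationError(
            f"harmonization of {exposure.trait_name} vs {outcome.trait_name} retained 0 variants"
        )
    return HarmonizedSet(
        exposure.trait_name,
        outcome.trait_name,
        records,
        audit=audit,
        dropped=dropped,
        outcome_binary=(outcome.trait_type == "binary"),
    )


def write_audit(hset: HarmonizedSet, path) -> None:
    """Write the per-variant harmonization audit as a TSV."""
    rows = [(r.variant_id, r.status, r.proxy_id or "") for r in hset.records]
    rows += [(vid, status, reason) for vid, status, reason in hset.dropped]
    pd.DataFrame(rows, columns=["variant_id", "status", "reason"]).to_csv(
        path, sep="\t", index=False
    )
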
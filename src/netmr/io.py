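"""Reading, validation and writing of GWAS summary-statistics and LD tables.

The central containers are :class:`VariantAssociation` (one SNP's effect on
one trait), :class:`SummaryDataset` (a trait's full summary-statistics panel)
and :class:`LdTable` (a sparse, symmetric r-squared lookup).  Files are plain
tab-separated text with a header row; column names are mapped through a
configurable schema because consortium files disagree wildly on headers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .exceptions import EmptyInputError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical field -> default column header (SNP/effect_allele/.../pval/n)
DEFAULT_SCHEMA = {
    "variant_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

_MANDATORY = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")
_OPTIONAL = ("eaf", "n")


@dataclass(frozen=True, slots=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele estimate (log odds ratio for binary
    traits); ``eaf`` is the effect-allele frequency and may be missing, in
    which case the variant cannot take part in palindromic-strand inference.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None

    def is_valid(self) -> bool:
        if self.effect_allele not in VALID_ALLELES:
            return False
        if self.other_allele not in VALID_ALLELES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not (math.isfinite(self.beta) and math.isfinite(self.se) and self.se > 0):
            return False
        if not (0 < self.pvalue <= 1):
            return False
        if self.eaf is not None and not (0 < self.eaf < 1):
            return False
        if self.n is not None and not self.n > 0:
            return False
        return True


@dataclass
class SummaryDataset:
    """An ordered, id-keyed collection of variant associations for one trait."""

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    sample_size: int
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(
                f"trait_type must be 'quantitative' or 'binary', got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        return self.records[variant_id]

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.variant_id, r.effect_allele, r.other_allele, r.eaf, r.beta, r.se, r.pvalue, r.n)
            for r in self.records.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"],
        )


def _get(row, col, cast=float):
    if col is None:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return cast(v)


def read_summary_table(
    path,
    schema: dict[str, str] | None = None,
    trait_name: str = "trait",
    trait_type: str = "quantitative",
    sample_size: int = 0,
    sep: str = "\t",
) -> SummaryDataset:
    """Read a delimited summary-statistics file into a validated dataset.

    ``schema`` maps canonical field names (keys of :data:`DEFAULT_SCHEMA`) to
    the file's column headers.  Rows violating the data-model invariants are
    dropped with a logged count; alleles are upper-cased.  Raises
    :class:`SchemaError` if a mandatory mapped column is absent and
    :class:`EmptyInputError` if no valid row remains.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep, dtype={schema["variant_id"]: str})
    for fld in _MANDATORY:
        if schema[fld] not in df.columns:
            raise SchemaError(f"column {schema[fld]!r} (field {fld!r}) missing from {path}")
    optional_cols = {f: (schema[f] if schema.get(f) in df.columns else None) for f in _OPTIONAL}

    records: dict[str, VariantAssociation] = {}
    dropped = 0
    for row in df.to_dict("records"):
        try:
            rec = VariantAssociation(
                variant_id=str(row[schema["variant_id"]]),
                effect_allele=str(row[schema["effect_allele"]]).upper(),
                other_allele=str(row[schema["other_allele"]]).upper(),
                beta=float(row[schema["beta"]]),
                se=float(row[schema["se"]]),
                pvalue=float(row[schema["pvalue"]]),
                eaf=_get(row, optional_cols["eaf"]),
                n=_get(row, optional_cols["n"]),
            )
        except (TypeError, ValueError):
            dropped += 1
            continue
        if rec.is_valid() and rec.variant_id not in records:
            records[rec.variant_id] = rec
        else:
            dropped += 1
    if dropped:
        logger.warning("%s: dropped %d invalid/duplicate rows", path, dropped)
    if not records:
        raise EmptyInputError(f"no valid summary-statistics rows in {path}")
    return SummaryDataset(trait_name, trait_type, sample_size, records, n_dropped=dropped)


def write_summary_table(dataset: SummaryDataset, path, schema: dict[str, str] | None = None) -> None:
    """Write a dataset as TSV; round-trips through :func:`read_summary_table`."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = dataset.to_frame()
    df.columns = [schema[c] for c in df.columns]
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


class LdTable:
    """Sparse symmetric pairwise r-squared table.

    Absent pairs are treated as r² = 0; r²(x, x) is implicitly 1.
    """

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, a: str) -> dict[str, float]:
        return self._adj.get(a, {})

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    @classmethod
    def from_pairs(cls, pairs) -> "LdTable":
        t = cls()
        for a, b, r2 in pairs:
            t.set(str(a), str(b), float(r2))
        return t


def read_ld_table(path, sep: str = "\t") -> LdTable:
    """Read a three-column (id_a, id_b, r2) TSV with a header row."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise SchemaError(f"LD table {path} needs three columns (id_a, id_b, r2)")
    return LdTable.from_pairs(df.iloc[:, :3].itertuples(index=False))


def write_ld_table(table: LdTable, path) -> None:
    seen = set()
    rows = []
    for a, nbrs in table._adj.items():
        for b, r2 in nbrs.items():
            key = (a, b) if a < b else (b, a)
            if key not in seen:
                seen.add(key)
                rows.append((key[0], key[1], r2))
    pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep="\t", index=False)


def flip_record(record: VariantAssociation) -> VariantAssociation:
    """Swap alleles, negate beta, complement the frequency; an involution."""
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
    )
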
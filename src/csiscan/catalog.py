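"""The packaged catalog of 41 rodent/Glires conserved signature indels.

Records are transcribed verbatim from the study's three summary tables
(clade-level CSIs; Rodentia-suborder CSIs; Myomorpha-family CSIs), including
internal inconsistencies, which carry explicit flags rather than silent
corrections.  Combined-clade specificities ("Myomorpha and Castorimorpha",
"Muridae and Cricetidae", "Glires and Scandentia") are single composite
labels and are never double-counted.  Records are keyed by
``(accession, location)`` since protein names recur across clades.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

_CATALOG_PATH = Path(__file__).parent / "data" / "csi_catalog.tsv"

_VALID_KINDS = {"Ins", "Del"}


class CatalogPackagingError(ValueError):
    """Packaged catalog data fails its schema."""


@dataclass(frozen=True)
class CatalogRecord:
    """One catalog row: a published CSI."""

    protein_name: str
    accession: str
    figure: str
    indel_size_aa: int
    indel_kind: str  # "Ins" or "Del"
    location: str  # 1-based residue range, exactly as printed
    specificity: str
    source_table: int
    flags: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, str]:
        return (self.accession, self.location)

    @property
    def location_range(self) -> tuple[int, int] | None:
        """Parsed (start, end); abbreviated printed ranges (e.g. 1326-28)
        are expanded for the parsed view only."""
        m = re.fullmatch(r"(\d+)-(\d+)", self.location)
        if not m:
            return None
        start, end = int(m.group(1)), int(m.group(2))
        if end < start:  # abbreviated form: trailing digits replaced
            expanded = int(str(start)[: len(str(start)) - len(m.group(2))]
                           + m.group(2))
            if expanded > start:
                end = expanded
        return (start, end)


def load_catalog() -> list[CatalogRecord]:
    """Load all packaged records (7 + 24 + 10 rows), schema-checked."""
    df = pd.read_csv(_CATALOG_PATH, sep="\t", dtype=str).fillna("")
    records: list[CatalogRecord] = []
    for _, row in df.iterrows():
        try:
            size = int(row["indel_size_aa"])
        except ValueError as exc:
            raise CatalogPackagingError(
                f"bad indel size {row['indel_size_aa']!r}") from exc
        rec = CatalogRecord(
            protein_name=row["protein_name"],
            accession=row["accession"],
            figure=row["figure"],
            indel_size_aa=size,
            indel_kind=row["indel_kind"],
            location=row["location"],
            specificity=row["specificity"],
            source_table=int(row["source_table"]),
            flags=tuple(f for f in row["flags"].split(";") if f),
        )
        if rec.indel_size_aa < 1:
            raise CatalogPackagingError(f"record {rec.key}: size < 1")
        if rec.indel_kind not in _VALID_KINDS:
            raise CatalogPackagingError(
                f"record {rec.key}: kind {rec.indel_kind!r}")
        if not rec.specificity:
            raise CatalogPackagingError(f"record {rec.key}: empty specificity")
        records.append(rec)
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        raise CatalogPackagingError("duplicate (accession, location) keys")
    return records


def count_by_clade(records: list[CatalogRecord], clade_label: str) -> int:
    """Exact count of records whose specificity equals ``clade_label``.

    Unknown labels count 0 with a warning.
    """
    known = {r.specificity for r in records}
    if clade_label not in known:
        logger.warning("clade label %r not present in the catalog", clade_label)
        return 0
    return sum(1 for r in records if r.specificity == clade_label)


def tally_summary(records: list[CatalogRecord]) -> pd.DataFrame:
    """Per-clade CSI counts plus the grand total (one row per specificity
    label, ordered by first appearance, then a ``Total`` row)."""
    order: list[str] = []
    for r in records:
        if r.specificity not in order:
            order.append(r.specificity)
    rows = [{"clade": label,
             "n_csis": sum(1 for r in records if r.specificity == label)}
            for label in order]
    rows.append({"clade": "Total", "n_csis": len(records)})
    return pd.DataFrame(rows, columns=["clade", "n_csis"])
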
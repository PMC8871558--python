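"""Protein alignment and clade-partition I/O.

Alignments are gapped amino-acid matrices keyed by taxon identifier
("Genus_species" strings).  The clade partition is a hierarchical taxonomy
(order / suborder / family / ...) with designated outgroups and a list of
candidate clades eligible for CSI specificity assignment.

Coordinate convention: columns are 0-based half-open internally; every
coordinate shown to a user is 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: permitted alignment symbols: the 20 residues, ambiguity 'X', and the gap
ALPHABET = frozenset(AMINO_ACIDS) | {"X", "-"}

UNPLACED = "unplaced"


class AlignmentShapeError(ValueError):
    """Rows of an alignment have unequal lengths."""


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the amino-acid alphabet."""


class EmptyInputError(ValueError):
    """An alignment file or alignment object contains no records."""


class PartitionConfigError(ValueError):
    """The clade-partition configuration is internally inconsistent."""


class UnknownTaxonError(PartitionConfigError):
    """A clade references a taxon that is not declared in the partition."""


@dataclass
class ProteinAlignment:
    """A gapped protein multiple sequence alignment.

    Parameters
    ----------
    id
        Protein-family identifier.
    taxa
        Ordered taxon identifiers, unique within the alignment.
    rows
        Mapping taxon -> gapped sequence over the 20 amino acids, ``X``
        and ``-``.  All rows share one length and no column is all-gap.
    metadata
        Optional per-taxon annotations (e.g. sequence accessions).
    """

    id: str
    taxa: list[str]
    rows: dict[str, str]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def length(self) -> int:
        return len(self.rows[self.taxa[0]])

    def column(self, j: int) -> list[str]:
        """Characters of column ``j`` in taxon order."""
        return [self.rows[t][j] for t in self.taxa]

    def validate(self) -> None:
        if not self.taxa:
            raise EmptyInputError(f"alignment {self.id!r} has no sequences")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise PartitionConfigError(
                f"duplicate taxon identifiers in alignment {self.id!r}: {dupes}"
            )
        lengths = {t: len(self.rows[t]) for t in self.taxa}
        if len(set(lengths.values())) != 1:
            raise AlignmentShapeError(
                f"alignment {self.id!r} rows have unequal lengths: {lengths}"
            )
        n = next(iter(lengths.values()))
        if n < 1:
            raise EmptyInputError(f"alignment {self.id!r} has zero columns")
        for t in self.taxa:
            for j, ch in enumerate(self.rows[t]):
                if ch not in ALPHABET:
                    raise AlphabetError(
                        f"alignment {self.id!r}: invalid symbol {ch!r} in row "
                        f"{t!r} at column {j + 1} (1-based)"
                    )
        for j in range(n):
            if all(self.rows[t][j] == "-" for t in self.taxa):
                raise AlignmentShapeError(
                    f"alignment {self.id!r}: column {j + 1} (1-based) is all-gap"
                )

    def subset(self, taxa: Iterable[str]) -> "ProteinAlignment":
        """Restrict to ``taxa``, dropping columns left all-gap (logged)."""
        keep = [t for t in self.taxa if t in set(taxa)]
        if not keep:
            raise EmptyInputError(f"subset of alignment {self.id!r} is empty")
        n = len(self.rows[keep[0]])
        cols = [j for j in range(n) if any(self.rows[t][j] != "-" for t in keep)]
        if len(cols) < n:
            logger.warning(
                "alignment %s: dropping %d all-gap columns after taxon subset",
                self.id,
                n - len(cols),
            )
        rows = {t: "".join(self.rows[t][j] for j in cols) for t in keep}
        return ProteinAlignment(id=self.id, taxa=keep, rows=rows,
                                metadata={t: self.metadata.get(t, {}) for t in keep})


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
        else:
            raise EmptyInputError(f"{path} is empty")
    if first.startswith(">"):
        return "fasta"
    if first.upper().startswith("CLUSTAL"):
        return "clustal"
    raise AlphabetError(f"{path}: cannot auto-detect format from first line {first!r}")


def read_alignment(path: str | Path, format: str = "auto",
                   id: str | None = None) -> ProteinAlignment:
    """Read a FASTA or Clustal protein alignment into a :class:`ProteinAlignment`.

    Lowercase residues are normalised to uppercase; ``format='auto'`` sniffs
    the file content.  The alignment id defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"{path} is empty")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Biopython raises plain ValueError both for empty files and for
        # records of unequal length; distinguish by message.
        msg = str(exc)
        if "No records" in msg or "Empty file" in msg:
            raise EmptyInputError(f"{path}: no alignment records") from exc
        raise AlignmentShapeError(f"{path}: {msg}") from exc
    taxa = [rec.id for rec in msa]
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    return ProteinAlignment(id=id or path.stem, taxa=taxa, rows=rows)


def write_alignment(aln: ProteinAlignment, path: str | Path,
                    format: str = "fasta") -> None:
    """Write the alignment as FASTA or Clustal; re-readable by :func:`read_alignment`."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    aln.validate()
    records = [SeqRecord(Seq(aln.rows[t]), id=t, description="") for t in aln.taxa]
    msa = MultipleSeqAlignment(records)
    AlignIO.write(msa, str(path), format)


@dataclass
class CladePartition:
    """Hierarchical taxon -> clade labelling with outgroups and candidate clades.

    ``levels`` maps a level name (e.g. ``suborder``) to a taxon -> label
    mapping; taxa without a label at a level carry the sentinel ``unplaced``.
    ``outgroups`` are never assignable as CSI carriers and never intersect a
    candidate clade.  ``candidate_clades`` lists the ``(level, label)`` pairs
    eligible for specificity assignment.
    """

    taxa: set[str]
    levels: dict[str, dict[str, str]]
    outgroups: set[str]
    candidate_clades: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for level, mapping in self.levels.items():
            labels: dict[str, str] = {}
            for taxon in mapping:
                if taxon not in self.taxa:
                    raise UnknownTaxonError(
                        f"level {level!r} labels unknown taxon {taxon!r}"
                    )
            for taxon in self.taxa:
                mapping.setdefault(taxon, UNPLACED)
            del labels
        missing = self.outgroups - self.taxa
        if missing:
            raise UnknownTaxonError(f"outgroups not in taxa: {sorted(missing)}")
        seen: set[tuple[str, str]] = set()
        for level, label in self.candidate_clades:
            if level not in self.levels:
                raise PartitionConfigError(
                    f"candidate clade ({level!r}, {label!r}) references unknown level"
                )
            if (level, label) in seen:
                raise PartitionConfigError(
                    f"duplicate candidate clade ({level!r}, {label!r})"
                )
            seen.add((level, label))
            members = self.members(level, label)
            if not members:
                raise PartitionConfigError(
                    f"candidate clade ({level!r}, {label!r}) has no members"
                )
            bad = members & self.outgroups
            if bad:
                raise PartitionConfigError(
                    f"candidate clade ({level!r}, {label!r}) contains outgroup "
                    f"taxa {sorted(bad)}"
                )

    def members(self, level: str, label: str) -> set[str]:
        """Taxa labelled ``label`` at ``level``."""
        mapping = self.levels.get(level)
        if mapping is None:
            raise PartitionConfigError(f"unknown level {level!r}")
        return {t for t, lab in mapping.items() if lab == label}


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate clade labels)."""


def _strict_mapping(loader: _StrictLoader, node: yaml.nodes.MappingNode):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=True)
        if key in seen:
            raise PartitionConfigError(f"duplicate key {key!r} in config mapping")
        seen.add(key)
    return loader.construct_mapping(node, deep=True)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def load_clade_partition(path: str | Path) -> CladePartition:
    """Load a clade-partition config (YAML with ``levels``, ``outgroups``,
    ``candidate_clades`` sections).

    Each level maps clade label -> list of taxa.  A taxon may appear under at
    most one label per level; unlisted taxa are treated as unplaced at that
    level.  The full taxon set may be given explicitly under ``taxa`` or is
    otherwise the union of all labelled taxa and outgroups.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(cfg, Mapping):
        raise PartitionConfigError(f"{path}: config is not a mapping")
    for key in ("levels", "outgroups", "candidate_clades"):
        if key not in cfg:
            raise PartitionConfigError(f"{path}: missing {key!r} section")

    levels: dict[str, dict[str, str]] = {}
    all_taxa: set[str] = set(cfg.get("taxa") or [])
    for level, groups in cfg["levels"].items():
        mapping: dict[str, str] = {}
        if not isinstance(groups, Mapping):
            raise PartitionConfigError(f"{path}: level {level!r} is not a mapping")
        for label, taxa in groups.items():
            for taxon in taxa:
                if taxon in mapping:
                    raise PartitionConfigError(
                        f"{path}: taxon {taxon!r} appears under both "
                        f"{mapping[taxon]!r} and {label!r} at level {level!r}"
                    )
                mapping[taxon] = label
        levels[level] = mapping
        all_taxa |= set(mapping)

    outgroups = set(cfg["outgroups"] or [])
    all_taxa |= outgroups

    candidates: list[tuple[str, str]] = []
    for item in cfg["candidate_clades"]:
        if isinstance(item, Mapping):
            candidates.append((item["level"], item["label"]))
        else:
            level, label = item
            candidates.append((level, label))

    if "taxa" in cfg and cfg["taxa"]:
        declared = set(cfg["taxa"])
        extra = all_taxa - declared
        if extra:
            raise UnknownTaxonError(
                f"{path}: taxa used but not declared: {sorted(extra)}"
            )
        all_taxa = declared

    return CladePartition(
        taxa=all_taxa,
        levels=levels,
        outgroups=outgroups,
        candidate_clades=candidates,
    )


def default_partition_path() -> Path:
    """Path of the shipped Glires taxonomy config (the study's clade labels)."""
    return Path(__file__).parent / "data" / "glires_partition.yaml"


def load_default_partition() -> CladePartition:
    """Load the shipped 35-taxon Glires clade partition."""
    return load_clade_partition(default_partition_path())
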
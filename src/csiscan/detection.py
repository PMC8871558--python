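"""Conserved-signature-indel (CSI) detection in protein alignments.

The scan proceeds in stages, mirroring how signature indels are identified by
comparative inspection of alignments:

1. :func:`profile_columns` — per-column conservation: a column is *conserved*
   when the majority residue (over non-gap, non-``X`` rows) reaches the
   conservation threshold and the column's gap fraction is small.
2. :func:`find_indel_candidates` — maximal runs of columns sharing one
   constant, nonempty, proper gap-taxon set: the fixed-length indel
   candidates.  Ragged gap patterns break into several shorter candidates.
3. :func:`assess_flanks` — an indel is only a reliable marker when flanked on
   both sides by sufficiently many conserved positions within a window.
4. :func:`classify_specificity` — which candidate clade (if any) the indel
   demarcates, tolerating a bounded number of clade members lacking it
   (*exceptions*) and a bounded number of *foreign* carriers outside the
   clade; indels carried by only one or two isolated taxa are rejected.
5. :func:`infer_polarity` — insertion vs. deletion, polarised by near-unanimous
   outgroup character states.
6. Reference-coordinate mapping and query-region extraction for reporting.

Columns are 0-based half-open internally; user-facing coordinates are 1-based
inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from csiscan.alignment_io import CladePartition, ProteinAlignment

logger = logging.getLogger(__name__)

INSERTION = "insertion"
DELETION = "deletion"
UNDETERMINED = "undetermined"


class ReferenceError_(ValueError):
    """The chosen reference taxon is gapped across the entire display region."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable thresholds of the CSI scan.

    flank_window
        Columns examined on each side of a candidate (per-side window).
    min_conserved_flank
        Conserved columns required within the window on *each* side.
    conservation_threshold
        Fraction of non-gap, non-X rows that must share the majority residue
        for a column to count as conserved.
    max_column_gap_fraction
        Maximum gap fraction a conserved column may have.
    min_carriers
        Minimum number of taxa sharing the indel state (excludes signatures
        confined to one or two isolated taxa).
    max_exceptions
        Clade members allowed to lack the CSI (e.g. a single deep-branching
        lineage that secondarily lost it).
    max_foreign
        Non-clade, non-outgroup taxa allowed to share the CSI (0 = strict
        clade exclusivity; shared presence outside the clade suggests
        homoplasy).
    outgroup_unanimity
        Fraction of outgroup taxa that must agree for polarity to be called.
    """

    flank_window: int = 45
    min_conserved_flank: int = 5
    conservation_threshold: float = 0.8
    max_column_gap_fraction: float = 0.1
    min_carriers: int = 3
    max_exceptions: int = 1
    max_foreign: int = 0
    outgroup_unanimity: float = 0.9

    def __post_init__(self) -> None:
        if not (self.flank_window >= self.min_conserved_flank >= 1):
            raise ValueError("require flank_window >= min_conserved_flank >= 1")
        for name in ("conservation_threshold", "max_column_gap_fraction",
                     "outgroup_unanimity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0) and name != "max_column_gap_fraction":
                raise ValueError(f"{name} must be in (0, 1], got {v}")
            if name == "max_column_gap_fraction" and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")
        if self.max_exceptions < 0 or self.max_foreign < 0:
            raise ValueError("max_exceptions and max_foreign must be >= 0")


@dataclass(frozen=True)
class ColumnProfile:
    """Conservation summary of one alignment column."""

    index: int
    majority_residue: str | None
    majority_fraction: float
    gap_fraction: float
    conserved: bool


@dataclass(frozen=True)
class IndelCandidate:
    """A maximal fixed-length indel candidate.

    ``gap_taxa`` are gapped in *every* column of ``[start, end)``; all other
    taxa (``residue_taxa``) are gapped in none of them.  Extending the
    interval in either direction changes the gap set.
    """

    protein_id: str
    start: int
    end: int
    gap_taxa: frozenset[str]
    residue_taxa: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FlankAssessment:
    """Conserved-column counts in the windows flanking a candidate."""

    left_conserved: int
    right_conserved: int
    passed: bool


@dataclass(frozen=True)
class CladeAssignment:
    level: str
    label: str
    carriers: frozenset[str]
    exceptions: frozenset[str]
    foreign: frozenset[str]
    carrier_side: str  # "gap" or "residue"


@dataclass
class CSICall:
    """A detected conserved signature indel."""

    protein_id: str
    candidate: IndelCandidate
    clade_level: str
    clade_label: str
    carriers: frozenset[str]
    exceptions: frozenset[str]
    foreign: frozenset[str]
    polarity: str
    flanks: FlankAssessment
    reference_taxon: str | None = None
    reference_range: tuple[int, int] | None = None
    query_region: str | None = None
    indel_reference_range: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.candidate.length


def profile_columns(aln: ProteinAlignment,
                    params: DetectionParams) -> list[ColumnProfile]:
    """Per-column conservation profiles.

    The majority fraction is computed over non-gap, non-``X`` rows (``X`` is
    never counted toward a majority); the gap fraction over all rows.
    """
    profiles: list[ColumnProfile] = []
    n_rows = len(aln.taxa)
    for j in range(aln.length):
        col = aln.column(j)
        gaps = col.count("-")
        counts: dict[str, int] = {}
        for ch in col:
            if ch not in ("-", "X"):
                counts[ch] = counts.get(ch, 0) + 1
        informative = n_rows - gaps - col.count("X")
        if counts and informative > 0:
            majority_residue = max(sorted(counts), key=counts.get)
            majority_fraction = counts[majority_residue] / informative
        else:
            majority_residue = None
            majority_fraction = 0.0
        gap_fraction = gaps / n_rows
        conserved = (
            majority_residue is not None
            and majority_fraction >= params.conservation_threshold
            and gap_fraction <= params.max_column_gap_fraction
        )
        profiles.append(ColumnProfile(j, majority_residue, majority_fraction,
                                      gap_fraction, conserved))
    return profiles


def find_indel_candidates(aln: ProteinAlignment) -> list[IndelCandidate]:
    """All maximal column intervals with a constant nonempty, proper gap set.

    Consecutive columns are grouped by their gap-taxon set; each maximal run
    whose set is nonempty and not the whole taxon set is one candidate.  A
    ragged pattern (the gap set changes inside the run) therefore yields
    several shorter candidates, never one merged candidate.
    """
    taxa = set(aln.taxa)
    out: list[IndelCandidate] = []
    start = 0
    prev: frozenset[str] | None = None
    for j in range(aln.length + 1):
        if j < aln.length:
            cur = frozenset(t for t in aln.taxa if aln.rows[t][j] == "-")
        else:
            cur = None
        if cur != prev:
            if prev:  # nonempty; all-gap columns are impossible by invariant
                out.append(IndelCandidate(
                    protein_id=aln.id, start=start, end=j,
                    gap_taxa=prev,
                    residue_taxa=frozenset(taxa - prev),
                ))
            start = j
            prev = cur
    return out


def assess_flanks(cand: IndelCandidate, profiles: list[ColumnProfile],
                  params: DetectionParams) -> FlankAssessment:
    """Count conserved columns in the per-side windows around a candidate.

    Windows exclude the indel columns themselves and are clipped at the
    alignment edges.
    """
    left_lo = max(0, cand.start - params.flank_window)
    left = sum(1 for p in profiles[left_lo:cand.start] if p.conserved)
    right_hi = min(len(profiles), cand.end + params.flank_window)
    right = sum(1 for p in profiles[cand.end:right_hi] if p.conserved)
    passed = (left >= params.min_conserved_flank
              and right >= params.min_conserved_flank)
    return FlankAssessment(left, right, passed)


def classify_specificity(cand: IndelCandidate, partition: CladePartition,
                         params: DetectionParams) -> CladeAssignment | None:
    """Assign the most specific candidate clade the indel demarcates, or reject.

    For each side of the candidate (gapped taxa / residue taxa) and each
    candidate clade C the following must hold, with ``A`` the clade members
    present in the alignment:

    * ``|side ∩ A| >= |A| - max_exceptions``  (nearly all members carry it),
    * ``|side \\ A \\ outgroups| <= max_foreign``  (essentially exclusive),
    * ``|side| >= min_carriers``  (not an isolated-taxon pattern).

    Among all passing ``(side, clade)`` pairs the clade with the fewest
    aligned members wins (most specific).  A size tie between distinct clades
    is ambiguous and rejected with a log entry.
    """
    if not partition.candidate_clades:
        raise ValueError("partition declares no candidate clades")
    aln_taxa = cand.gap_taxa | cand.residue_taxa
    unknown = aln_taxa - partition.taxa
    if unknown:
        raise ValueError(f"alignment taxa not in partition: {sorted(unknown)}")

    passing: list[tuple[int, CladeAssignment]] = []
    for side_name, side in (("gap", cand.gap_taxa), ("residue", cand.residue_taxa)):
        if len(side) < params.min_carriers:
            continue
        for level, label in partition.candidate_clades:
            members = partition.members(level, label) & aln_taxa
            if not members:
                continue
            carriers = side & members
            if len(carriers) < len(members) - params.max_exceptions:
                continue
            foreign = side - members - partition.outgroups
            if len(foreign) > params.max_foreign:
                continue
            passing.append((len(members), CladeAssignment(
                level=level, label=label,
                carriers=frozenset(carriers),
                exceptions=frozenset(members - carriers),
                foreign=frozenset(foreign),
                carrier_side=side_name,
            )))
    if not passing:
        return None
    passing.sort(key=lambda item: item[0])
    best_size, best = passing[0]
    ties = {(a.level, a.label) for size, a in passing if size == best_size}
    if len(ties) > 1:
        logger.info(
            "candidate %s[%d:%d): ambiguous specificity among equally small "
            "clades %s; rejected", cand.protein_id, cand.start, cand.end,
            sorted(ties))
        return None
    return best


def infer_polarity(cand: IndelCandidate, partition: CladePartition,
                   carriers: frozenset[str],
                   params: DetectionParams = DetectionParams()) -> str:
    """Insertion or deletion, polarised by outgroup states at the indel columns.

    If nearly all outgroups (>= ``outgroup_unanimity``) hold residues there
    while the carriers are gapped, the event was a deletion in the carriers'
    ancestor; in the mirrored case, an insertion.  Mixed outgroups (possible
    homoplasy) or no outgroup in the alignment give ``undetermined``.
    """
    aln_taxa = cand.gap_taxa | cand.residue_taxa
    out_present = partition.outgroups & aln_taxa
    if not out_present:
        logger.warning(
            "candidate %s[%d:%d): no outgroup taxon present; polarity "
            "undetermined", cand.protein_id, cand.start, cand.end)
        return UNDETERMINED
    out_residue = len(out_present & cand.residue_taxa) / len(out_present)
    out_gapped = len(out_present & cand.gap_taxa) / len(out_present)
    if out_residue >= params.outgroup_unanimity and carriers <= cand.gap_taxa:
        return DELETION
    if out_gapped >= params.outgroup_unanimity and carriers <= cand.residue_taxa:
        return INSERTION
    return UNDETERMINED


def _display_columns(cand: IndelCandidate, profiles: list[ColumnProfile],
                     params: DetectionParams) -> tuple[int, int]:
    """Columns of the displayed region: the indel plus, per side, the nearest
    ``min_conserved_flank`` conserved columns (clipped at the edges)."""
    lo = cand.start
    need = params.min_conserved_flank
    while lo > 0 and need > 0:
        lo -= 1
        if profiles[lo].conserved:
            need -= 1
    hi = cand.end
    need = params.min_conserved_flank
    while hi < len(profiles) and need > 0:
        if profiles[hi].conserved:
            need -= 1
        hi += 1
    return lo, hi


def _ref_positions(aln: ProteinAlignment, reference_taxon: str) -> list[int]:
    """1-based ungapped residue position per column (0 where reference gapped)."""
    row = aln.rows[reference_taxon]
    pos = 0
    out = []
    for ch in row:
        if ch != "-":
            pos += 1
            out.append(pos)
        else:
            out.append(0)
    return out


def map_to_reference_coords(csi: CSICall, aln: ProteinAlignment,
                            reference_taxon: str,
                            profiles: list[ColumnProfile] | None = None,
                            params: DetectionParams = DetectionParams(),
                            ) -> tuple[int, int]:
    """1-based residue interval of the displayed region in the reference.

    The displayed region is the indel plus ``min_conserved_flank`` flanking
    conserved columns on each side; the interval spans the reference's
    ungapped residues inside it.  Gap columns in the reference do not shift
    the numbering.
    """
    if reference_taxon not in aln.rows:
        raise ReferenceError_(f"reference taxon {reference_taxon!r} not in alignment")
    if profiles is None:
        profiles = profile_columns(aln, params)
    lo, hi = _display_columns(csi.candidate, profiles, params)
    positions = _ref_positions(aln, reference_taxon)
    covered = [positions[j] for j in range(lo, hi) if positions[j] > 0]
    if not covered:
        raise ReferenceError_(
            f"reference {reference_taxon!r} is gapped across the entire "
            f"display region [{lo}, {hi})")
    return (min(covered), max(covered))


def extract_query_region(csi: CSICall, aln: ProteinAlignment,
                         reference_taxon: str, flank_aa: int = 60,
                         ) -> str:
    """Ungapped reference residues covering the indel region ± ``flank_aa``.

    This is the sequence one would submit to a similarity search to verify
    group specificity externally; it is clipped at the sequence ends, so its
    length is at most ``indel length + 2 * flank_aa``.
    """
    if reference_taxon not in aln.rows:
        raise ReferenceError_(f"reference taxon {reference_taxon!r} not in alignment")
    positions = _ref_positions(aln, reference_taxon)
    cand = csi.candidate
    covered = [positions[j] for j in range(cand.start, cand.end) if positions[j] > 0]
    degapped = aln.rows[reference_taxon].replace("-", "")
    if covered:
        first, last = min(covered), max(covered)
    else:
        # reference gapped across the indel (it lacks the insert): anchor on
        # the residues bracketing the interval
        before = [p for p in positions[:cand.start] if p > 0]
        after = [p for p in positions[cand.end:] if p > 0]
        if not before and not after:
            raise ReferenceError_(
                f"reference {reference_taxon!r} has no residues around the indel")
        first = before[-1] if before else after[0]
        last = after[0] if after else before[-1]
    lo = max(1, first - flank_aa)
    hi = min(len(degapped), last + flank_aa)
    return degapped[lo - 1:hi]


def _choose_reference(aln: ProteinAlignment, cand: IndelCandidate) -> str | None:
    """Display reference: the first taxon holding residues across the indel
    columns (so the full region is visible), else the first taxon with any
    residue near the indel."""
    for t in aln.taxa:
        if t in cand.residue_taxa:
            return t
    return aln.taxa[0] if aln.taxa else None


def _clean_boundaries(cand: IndelCandidate, aln: ProteinAlignment) -> bool:
    """Fixed-length guard: no gap-set taxon may be gapped in the column
    immediately adjacent to the interval.

    A length-varying ("ragged") indel cluster that an aligner renders
    flush-left shares a fixed-length core flanked by columns where some of
    the same taxa are still gapped; such cores are not fixed-length events
    and are rejected here.
    """
    for j in (cand.start - 1, cand.end):
        if 0 <= j < aln.length:
            for t in cand.gap_taxa:
                if aln.rows[t][j] == "-":
                    return False
    return True


def detect_csis(aln: ProteinAlignment, partition: CladePartition,
                params: DetectionParams = DetectionParams(),
                reference_taxon: str | None = None,
                query_flank_aa: int = 60) -> list[CSICall]:
    """Run the full CSI scan on one alignment.

    Stages: candidate enumeration -> fixed-length boundary guard -> flank
    conservation filter -> clade-specificity classification -> polarity
    inference -> reference-coordinate mapping.  Output is deterministic and
    sorted by start column.
    """
    unknown = set(aln.taxa) - partition.taxa
    if unknown:
        raise ValueError(f"alignment taxa not in partition: {sorted(unknown)}")
    profiles = profile_columns(aln, params)
    calls: list[CSICall] = []
    for cand in find_indel_candidates(aln):
        if not _clean_boundaries(cand, aln):
            continue
        flanks = assess_flanks(cand, profiles, params)
        if not flanks.passed:
            continue
        assignment = classify_specificity(cand, partition, params)
        if assignment is None:
            continue
        polarity = infer_polarity(cand, partition, assignment.carriers, params)
        call = CSICall(
            protein_id=aln.id,
            candidate=cand,
            clade_level=assignment.level,
            clade_label=assignment.label,
            carriers=assignment.carriers,
            exceptions=assignment.exceptions,
            foreign=assignment.foreign,
            polarity=polarity,
            flanks=flanks,
        )
        ref = reference_taxon or _choose_reference(aln, cand)
        if ref is not None:
            try:
                call.reference_taxon = ref
                call.reference_range = map_to_reference_coords(
                    call, aln, ref, profiles, params)
                call.query_region = extract_query_region(
                    call, aln, ref, flank_aa=query_flank_aa)
                positions = _ref_positions(aln, ref)
                hit = [positions[j] for j in range(cand.start, cand.end)
                       if positions[j] > 0]
                if hit:
                    call.indel_reference_range = (min(hit), max(hit))
            except ReferenceError_ as exc:
                logger.warning("reference mapping failed: %s", exc)
        calls.append(call)
    calls.sort(key=lambda c: c.candidate.start)
    return calls


def calls_to_table(calls: list[CSICall]) -> list[dict]:
    """Flatten calls into report rows (tab-separated friendly)."""
    rows = []
    for c in calls:
        rows.append({
            "protein": c.protein_id,
            "clade": c.clade_label,
            "level": c.clade_level,
            "size_aa": c.length,
            "type": {INSERTION: "Ins", DELETION: "Del"}.get(c.polarity, "Indel"),
            "columns": f"{c.candidate.start + 1}-{c.candidate.end}",
            "reference": c.reference_taxon or "",
            "reference_range": (f"{c.reference_range[0]}-{c.reference_range[1]}"
                                if c.reference_range else ""),
            "indel_range": (f"{c.indel_reference_range[0]}-{c.indel_reference_range[1]}"
                            if c.indel_reference_range else ""),
            "carriers": ",".join(sorted(c.carriers)),
            "exceptions": ",".join(sorted(c.exceptions)),
            "foreign": ",".join(sorted(c.foreign)),
        })
    return rows
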
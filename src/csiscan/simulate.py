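"""Synthetic protein-family alignments with planted, ground-truthed indels.

The generator emulates the study system: a labelled species tree over a
Glires-like taxon set (rodent suborders, nested Myomorpha families, a tree
shrew, and primate/dermopteran outgroups), per-branch substitution noise on
an ancestral sequence, and clade-ancestral fixed-length indels planted on
internal branches.  It can additionally plant three confounders:

* a *loss* taxon — one clade member whose terminal branch reverts the event
  (the pattern of a deep lineage secondarily lacking an otherwise
  clade-universal signature);
* a *homoplastic* distractor — the same-coordinate indel planted
  independently on one non-clade terminal branch, which should defeat strict
  clade exclusivity;
* a *ragged* decoy — the indel length varies among clade members, violating
  the fixed-length requirement.

No realignment is performed: the simulator emits the true alignment, so
detection behaviour is isolated from aligner artifacts.  Everything is
deterministic under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from csiscan.alignment_io import AMINO_ACIDS, CladePartition, ProteinAlignment, \
    load_default_partition
from csiscan.detection import CSICall, DetectionParams

logger = logging.getLogger(__name__)

_AA = np.array(list(AMINO_ACIDS))


class PlanError(ValueError):
    """An indel plan is out of bounds or overlaps another plan."""


#: Species-tree topology matching the shipped Glires partition: 4 rodent
#: suborders, nested Myomorpha families (Muroidea = Muridae + Cricetidae +
#: Spalacidae), Lagomorpha, Tupaia (Scandentia) sister to Glires, and 4
#: primate/dermopteran outgroup taxa.
_TREE_TOPOLOGY = (
    (
        (("Homo_sapiens", "Pan_troglodytes"), "Macaca_mulatta"),
        "Galeopterus_variegatus",
    ),
    (
        "Tupaia_chinensis",
        (
            # Lagomorpha
            (("Oryctolagus_cuniculus", "Lepus_europaeus"), "Ochotona_princeps"),
            # Rodentia
            (
                # Sciuromorpha
                (("Ictidomys_tridecemlineatus", "Urocitellus_parryii"),
                 ("Marmota_marmota", "Sciurus_carolinensis")),
                (
                    # Hystricomorpha
                    (("Cavia_porcellus", "Octodon_degus"),
                     ("Chinchilla_lanigera",
                      ("Heterocephalus_glaber", "Fukomys_damarensis"))),
                    (
                        # Castorimorpha
                        ("Castor_canadensis",
                         ("Dipodomys_ordii", "Dipodomys_spectabilis")),
                        # Myomorpha: Dipodoidea + Muroidea
                        (
                            ("Jaculus_jaculus", "Zapus_hudsonius"),
                            ("Nannospalax_galili",
                             (
                                 # Muridae
                                 (("Mus_musculus",
                                   ("Rattus_norvegicus", "Rattus_rattus")),
                                  (("Mastomys_coucha", "Arvicanthis_niloticus"),
                                   "Grammomys_surdaster")),
                                 # Cricetidae
                                 (("Peromyscus_maniculatus", "Onychomys_torridus"),
                                  (("Microtus_ochrogaster", "Ondatra_zibethicus"),
                                   ("Mesocricetus_auratus", "Cricetulus_griseus"))),
                             )),
                        ),
                    ),
                ),
            ),
        ),
    ),
)


def _topology_to_newick(node, terminal: float = 0.05,
                        internal: float = 0.02) -> str:
    if isinstance(node, str):
        return f"{node}:{terminal}"
    inner = ",".join(_topology_to_newick(ch, terminal, internal) for ch in node)
    return f"({inner}):{internal}"


DEFAULT_TREE_NEWICK = (
    "(" + ",".join(_topology_to_newick(ch) for ch in _TREE_TOPOLOGY) + ");"
)


@dataclass
class SpeciesScenario:
    """A labelled species tree plus the matching clade partition."""

    tree: dendropy.Tree
    partition: CladePartition

    def __post_init__(self) -> None:
        # clade-ancestral events need a direction of time
        self.tree.is_rooted = True
        leaves = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        if leaves != self.partition.taxa:
            raise ValueError(
                "tree leaves and partition taxa differ: "
                f"only-in-tree={sorted(leaves - self.partition.taxa)}, "
                f"only-in-partition={sorted(self.partition.taxa - leaves)}")
        for level, label in self.partition.candidate_clades:
            members = self.partition.members(level, label)
            mrca = self.tree.mrca(taxon_labels=sorted(members))
            below = {lf.taxon.label for lf in mrca.leaf_iter()}
            if below != members:
                raise ValueError(
                    f"candidate clade ({level!r}, {label!r}) is not "
                    f"monophyletic on the tree")

    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass(frozen=True)
class IndelPlan:
    """One event to plant in one family.

    ``position`` is in ancestral-sequence (root) coordinates; insertions add
    ``length`` columns before that position, deletions gap the columns
    ``[position, position + length)``.  ``loss_taxa`` revert the event on
    their terminal branches.  ``ragged_lengths`` maps clade members to
    per-member lengths (decoy); ``homoplastic_extra_taxon`` plants the same
    event independently on one non-clade terminal.
    """

    family: str
    clade_level: str
    clade_label: str
    position: int
    length: int
    kind: str  # "insertion" or "deletion"
    loss_taxa: frozenset[str] = frozenset()
    homoplastic_extra_taxon: str | None = None
    ragged_lengths: tuple[tuple[str, int], ...] = ()

    @property
    def is_decoy(self) -> bool:
        return bool(self.ragged_lengths) or self.homoplastic_extra_taxon is not None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise PlanError("indel length must be >= 1")
        if self.kind not in ("insertion", "deletion"):
            raise PlanError(f"unknown indel kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationParams:
    """Family-level simulation settings.

    sequence_length
        Ancestral (root) sequence length in residues.
    substitution_prob
        Per-site, per-branch substitution probability at mutable sites.
    conserved_fraction
        Fraction of sites that never substitute (guarantees conserved
        flanking regions, as real signature-bearing proteins have).
    """

    families: int = 50
    sequence_length: int = 600
    substitution_prob: float = 0.02
    conserved_fraction: float = 0.5
    indel_prob: tuple[float, float, float] = (0.2, 0.5, 0.3)  # P(0,1,2 events)
    max_indel_length: int = 5
    loss_prob: float = 0.15
    ragged_decoy_prob: float = 0.15
    homoplasy_decoy_prob: float = 0.15
    min_locus_separation: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_prob < 1):
            raise ValueError("substitution_prob must be in [0, 1)")
        if not (0 <= self.conserved_fraction <= 1):
            raise ValueError("conserved_fraction must be in [0, 1]")
        if self.sequence_length < 2 * 45 + self.max_indel_length:
            raise ValueError("sequence_length too short for flank windows")


def _evolve_sequences(tree: dendropy.Tree, L: int, sub_prob: float,
                      conserved: np.ndarray,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Root sequence + per-branch substitutions down the tree; conserved
    sites never change.  Returns leaf label -> residue index array."""
    root_seq = rng.integers(0, 20, size=L)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            seq = root_seq
        else:
            parent = seqs[id(node.parent_node)]
            seq = parent.copy()
            hit = (rng.random(L) < sub_prob) & ~conserved
            idx = np.flatnonzero(hit)
            if idx.size:
                # substitute to a uniformly random *different* residue
                shift = rng.integers(1, 20, size=idx.size)
                seq[idx] = (seq[idx] + shift) % 20
        seqs[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = seq
    return out


def _event_carriers(plan: IndelPlan, partition: CladePartition,
                    taxa: list[str]) -> set[str]:
    members = partition.members(plan.clade_level, plan.clade_label) & set(taxa)
    carriers = members - plan.loss_taxa
    if plan.homoplastic_extra_taxon:
        carriers |= {plan.homoplastic_extra_taxon}
    return carriers


def evolve_family(scenario: SpeciesScenario, params: SimulationParams,
                  plans: list[IndelPlan], seed: int,
                  family_id: str = "fam") -> tuple[ProteinAlignment, pd.DataFrame]:
    """Simulate one family alignment with the given planted events.

    Returns the true alignment (no realignment) and a truth table with one
    row per plan: family, final alignment columns ``[start, end)``, length,
    kind, clade, loss taxa, decoy flag.
    """
    rng = np.random.default_rng(seed)
    L = params.sequence_length
    taxa = scenario.taxa

    n_cons = int(round(params.conserved_fraction * L))
    conserved = np.zeros(L, dtype=bool)
    conserved[rng.choice(L, size=n_cons, replace=False)] = True

    leaf_seqs = _evolve_sequences(scenario.tree, L, params.substitution_prob,
                                  conserved, rng)

    # validate and order the plans; no two events may overlap
    intervals = []
    for plan in plans:
        width = max([plan.length] + [ln for _, ln in plan.ragged_lengths])
        if plan.kind == "deletion":
            if plan.position + width > L:
                raise PlanError(
                    f"deletion at {plan.position}+{width} exceeds sequence "
                    f"length {L}")
            intervals.append((plan.position, plan.position + width, plan))
        else:
            if not (0 <= plan.position <= L):
                raise PlanError(f"insertion position {plan.position} out of bounds")
            intervals.append((plan.position, plan.position, plan))
    intervals.sort(key=lambda iv: (iv[0], iv[1]))
    for (a0, a1, _), (b0, b1, _) in zip(intervals, intervals[1:]):
        if b0 < a1 or (a0 == b0):
            raise PlanError("planted events overlap")

    # final column layout: root coordinates plus inserted blocks
    insert_width: dict[int, int] = {}
    for lo, hi, plan in intervals:
        if plan.kind == "insertion":
            width = max([plan.length] + [ln for _, ln in plan.ragged_lengths])
            insert_width[lo] = insert_width.get(lo, 0) + width

    col_offset = np.zeros(L + 1, dtype=int)  # root position -> leading inserts
    acc = 0
    for p in range(L + 1):
        acc += insert_width.get(p, 0)
        col_offset[p] = acc
    total_cols = L + acc

    def final_col(root_pos: int) -> int:
        return root_pos + col_offset[root_pos]

    rows = {t: np.full(total_cols, "-", dtype="<U1") for t in taxa}
    for t in taxa:
        res = _AA[leaf_seqs[t]]
        for p in range(L):
            rows[t][final_col(p)] = res[p]

    truth_rows = []
    for lo, hi, plan in intervals:
        carriers = _event_carriers(plan, scenario.partition, taxa)
        if plan.kind == "deletion":
            if plan.ragged_lengths:
                lengths = dict(plan.ragged_lengths)
                for t, ln in lengths.items():
                    for p in range(plan.position, plan.position + ln):
                        rows[t][final_col(p)] = "-"
            else:
                for t in carriers:
                    for p in range(plan.position, plan.position + plan.length):
                        rows[t][final_col(p)] = "-"
            start = final_col(plan.position)
            end = start + plan.length
        else:
            width = insert_width[plan.position]
            start = plan.position + col_offset[plan.position] - width
            end = start + plan.length
            block = rng.integers(0, 20, size=width)
            if plan.ragged_lengths:
                lengths = dict(plan.ragged_lengths)
                for t, ln in lengths.items():
                    rows[t][start:start + ln] = _AA[block[:ln]]
            else:
                for t in carriers:
                    if t == plan.homoplastic_extra_taxon:
                        # independent origin: same coordinates, its own residues
                        extra = rng.integers(0, 20, size=plan.length)
                        rows[t][start:end] = _AA[extra]
                    else:
                        rows[t][start:end] = _AA[block[:plan.length]]
        truth_rows.append({
            "family": family_id,
            "start": int(start),
            "end": int(end),
            "length": plan.length,
            "kind": plan.kind,
            "clade_level": plan.clade_level,
            "clade_label": plan.clade_label,
            "losses": ",".join(sorted(plan.loss_taxa)),
            "decoy": plan.is_decoy,
            "decoy_kind": ("ragged" if plan.ragged_lengths else
                           "homoplasy" if plan.homoplastic_extra_taxon else ""),
        })

    aln = ProteinAlignment(
        id=family_id, taxa=list(taxa),
        rows={t: "".join(rows[t]) for t in taxa})
    truth = pd.DataFrame(truth_rows, columns=[
        "family", "start", "end", "length", "kind", "clade_level",
        "clade_label", "losses", "decoy", "decoy_kind"])
    return aln, truth


def default_scenario() -> SpeciesScenario:
    """The shipped 35-taxon Glires-like scenario."""
    tree = dendropy.Tree.get(data=DEFAULT_TREE_NEWICK, schema="newick",
                             preserve_underscores=True)
    return SpeciesScenario(tree=tree, partition=load_default_partition())


def _side_is_callable(side: set[str], partition: CladePartition,
                      det: DetectionParams) -> bool:
    """Would this carrier set satisfy any candidate clade's specificity test?"""
    if len(side) < det.min_carriers:
        return False
    for level, label in partition.candidate_clades:
        members = partition.members(level, label)
        if len(side & members) < len(members) - det.max_exceptions:
            continue
        if len(side - members - partition.outgroups) > det.max_foreign:
            continue
        return True
    return False


def _plantable_clades(scenario: SpeciesScenario,
                      det: DetectionParams) -> list[tuple[str, str]]:
    return [
        (level, label)
        for level, label in scenario.partition.candidate_clades
        if len(scenario.partition.members(level, label)) >= det.min_carriers
    ]


def generate_scenario(n_families: int,
                      params: SimulationParams = SimulationParams(),
                      seed: int | None = None,
                      scenario: SpeciesScenario | None = None,
                      detection_params: DetectionParams = DetectionParams(),
                      ) -> tuple[list[ProteinAlignment], pd.DataFrame,
                                 CladePartition, dendropy.Tree]:
    """Generate a family set with planted events, decoys and ground truth.

    Each family receives 0-2 clade-ancestral events at well-separated loci,
    plus (at configured frequency) a ragged decoy and/or a homoplastic
    distractor.  Loss taxa are only planted where the depleted carrier set
    cannot be mistaken for a different candidate clade.  Returns
    ``(alignments, truth table, partition, tree)``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if scenario is None:
        scenario = default_scenario()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    partition = scenario.partition
    det = detection_params
    clades = _plantable_clades(scenario, det)
    L = params.sequence_length
    margin = 80

    all_truth: list[pd.DataFrame] = []
    families: list[ProteinAlignment] = []
    family_seeds = np.random.SeedSequence(seed).spawn(n_families)

    for fi in range(n_families):
        fam = f"fam{fi:04d}"
        n_events = int(rng.choice(3, p=list(params.indel_prob)))
        want_ragged = rng.random() < params.ragged_decoy_prob
        want_homoplasy = rng.random() < params.homoplasy_decoy_prob
        n_loci = n_events + int(want_ragged) + int(want_homoplasy)

        positions: list[int] = []
        attempts = 0
        while len(positions) < n_loci and attempts < 1000:
            p = int(rng.integers(margin, L - margin))
            if all(abs(p - q) >= params.min_locus_separation for q in positions):
                positions.append(p)
            attempts += 1
        positions = positions[:n_loci]

        plans: list[IndelPlan] = []
        pos_iter = iter(positions)

        for _ in range(n_events):
            try:
                p = next(pos_iter)
            except StopIteration:
                break
            level, label = clades[int(rng.integers(len(clades)))]
            members = partition.members(level, label)
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            length = int(rng.integers(1, params.max_indel_length + 1))
            loss: frozenset[str] = frozenset()
            if (rng.random() < params.loss_prob
                    and len(members) > det.min_carriers):
                for cand_loss in rng.permutation(sorted(members)):
                    depleted = members - {cand_loss}
                    # the depleted carrier set must still point to this clade
                    # only (no other candidate clade may equally explain it)
                    safe = True
                    for lvl2, lab2 in partition.candidate_clades:
                        if (lvl2, lab2) == (level, label):
                            continue
                        m2 = partition.members(lvl2, lab2)
                        ok_exc = len(depleted & m2) >= len(m2) - det.max_exceptions
                        ok_for = len(depleted - m2 - partition.outgroups) <= det.max_foreign
                        if ok_exc and ok_for and len(m2) <= len(members):
                            safe = False
                            break
                    if safe:
                        loss = frozenset({str(cand_loss)})
                        break
            plans.append(IndelPlan(
                family=fam, clade_level=level, clade_label=label,
                position=p, length=length, kind=kind, loss_taxa=loss))

        if want_ragged:
            try:
                p = next(pos_iter)
            except StopIteration:
                p = None
            if p is not None:
                level, label = clades[int(rng.integers(len(clades)))]
                members = sorted(partition.members(level, label))
                lengths = {t: int(rng.integers(1, 4)) for t in members}
                if len(set(lengths.values())) == 1:  # force true raggedness
                    lengths[members[0]] = lengths[members[0]] % 3 + 1
                width = max(lengths.values())
                plans.append(IndelPlan(
                    family=fam, clade_level=level, clade_label=label,
                    position=p, length=width, kind="deletion",
                    ragged_lengths=tuple(sorted(lengths.items()))))

        if want_homoplasy:
            try:
                p = next(pos_iter)
            except StopIteration:
                p = None
            if p is not None:
                for _ in range(20):
                    level, label = clades[int(rng.integers(len(clades)))]
                    members = partition.members(level, label)
                    pool = sorted(partition.taxa - members - partition.outgroups)
                    # neither the carrier set nor its complement may satisfy
                    # any candidate clade, else the distractor would be called
                    safe = [
                        t for t in pool
                        if not _side_is_callable(set(members) | {t}, partition, det)
                        and not _side_is_callable(
                            partition.taxa - set(members) - {t}, partition, det)
                    ]
                    if safe:
                        extra = str(safe[int(rng.integers(len(safe)))])
                        kind = "deletion" if rng.random() < 0.5 else "insertion"
                        plans.append(IndelPlan(
                            family=fam, clade_level=level, clade_label=label,
                            position=p, length=int(rng.integers(1, 4)),
                            kind=kind, homoplastic_extra_taxon=extra))
                        break

        fam_seed = int(family_seeds[fi].generate_state(1)[0] % (2**31))
        aln, truth = evolve_family(scenario, params, plans, seed=fam_seed,
                                   family_id=fam)
        families.append(aln)
        all_truth.append(truth)

    truth = (pd.concat(all_truth, ignore_index=True) if all_truth
             else pd.DataFrame())
    return families, truth, partition, scenario.tree


@dataclass
class DetectionScore:
    precision: float
    recall: float
    polarity_accuracy: float
    confusion: pd.DataFrame
    n_calls: int
    n_truth: int
    zero_call_denominator: bool = False
    zero_truth_denominator: bool = False


def score_detection(calls: list[tuple[str, CSICall]],
                    truth: pd.DataFrame) -> DetectionScore:
    """Score detected CSIs against the planted ground truth.

    A call matches a truth record iff it is in the same family, its columns
    overlap the record's, its length equals the planted length, and its clade
    label equals the planted clade.  Decoy records are excluded from the
    truth set (they must never be matched).  Empty denominators score 1.0
    with an explicit flag.
    """
    real = truth[~truth["decoy"].astype(bool)] if len(truth) else truth
    matched_truth: set[int] = set()
    matched_calls = 0
    polarity_ok = 0
    pairs = []
    for fam, call in calls:
        hit_idx = None
        for idx, rec in real[real["family"] == fam].iterrows():
            if idx in matched_truth:
                continue
            overlap = (call.candidate.start < rec["end"]
                       and rec["start"] < call.candidate.end)
            if (overlap and call.length == rec["length"]
                    and call.clade_label == rec["clade_label"]):
                hit_idx = idx
                break
        if hit_idx is not None:
            matched_truth.add(hit_idx)
            matched_calls += 1
            rec = real.loc[hit_idx]
            if call.polarity == rec["kind"]:
                polarity_ok += 1
            pairs.append((rec["clade_label"], call.clade_label))
        else:
            pairs.append(("(none)", call.clade_label))
    for idx, rec in real.iterrows():
        if idx not in matched_truth:
            pairs.append((rec["clade_label"], "(missed)"))

    n_calls = len(calls)
    n_truth = len(real)
    precision = matched_calls / n_calls if n_calls else 1.0
    recall = len(matched_truth) / n_truth if n_truth else 1.0
    pol_acc = polarity_ok / matched_calls if matched_calls else 1.0
    confusion = (pd.crosstab(
        pd.Series([a for a, _ in pairs], name="truth"),
        pd.Series([b for _, b in pairs], name="called"))
        if pairs else pd.DataFrame())
    return DetectionScore(
        precision=precision, recall=recall, polarity_accuracy=pol_acc,
        confusion=confusion, n_calls=n_calls, n_truth=n_truth,
        zero_call_denominator=(n_calls == 0),
        zero_truth_denominator=(n_truth == 0),
    )
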
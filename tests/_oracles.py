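"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity from first principles, by exhaustive
enumeration or direct counting, without sharing code with the implementation
it checks.
"""

from __future__ import annotations

import math

import numpy as np

from csiscan.alignment_io import CladePartition, ProteinAlignment
from csiscan.detection import DetectionParams
from csiscan.phylogeny import Supermatrix, TrimParams


def column_tally(aln: ProteinAlignment, threshold: float, max_gap_frac: float):
    """Per-column (majority residue, majority fraction, gap fraction,
    conserved) by direct counting."""
    out = []
    n = len(aln.taxa)
    for j in range(aln.length):
        col = [aln.rows[t][j] for t in aln.taxa]
        residues = [c for c in col if c not in ("-", "X")]
        gap_frac = col.count("-") / n
        if residues:
            best = sorted(set(residues),
                          key=lambda r: (-residues.count(r), r))[0]
            frac = residues.count(best) / len(residues)
        else:
            best, frac = None, 0.0
        conserved = (best is not None and frac >= threshold
                     and gap_frac <= max_gap_frac)
        out.append((best, frac, gap_frac, conserved))
    return out


def enumerate_indel_intervals(aln: ProteinAlignment):
    """All maximal [s, e) intervals with a constant nonempty proper gap set,
    found by checking every interval exhaustively."""

    def gapset(j):
        return frozenset(t for t in aln.taxa if aln.rows[t][j] == "-")

    n = aln.length
    found = []
    for s in range(n):
        g = gapset(s)
        if not g or len(g) == len(aln.taxa):
            continue
        for e in range(s + 1, n + 1):
            if any(gapset(j) != g for j in range(s, e)):
                break
            left_ok = s == 0 or gapset(s - 1) != g
            right_ok = e == n or gapset(e) != g
            if left_ok and right_ok:
                found.append((s, e, g))
    return sorted(set(found))


def flank_counts(aln: ProteinAlignment, start: int, end: int,
                 params: DetectionParams):
    """Conserved-column counts in the two windows, by direct tally."""
    cons = [c[3] for c in column_tally(aln, params.conservation_threshold,
                                       params.max_column_gap_fraction)]
    left = sum(1 for j in range(max(0, start - params.flank_window), start)
               if cons[j])
    right = sum(1 for j in range(end, min(aln.length, end + params.flank_window))
                if cons[j])
    return left, right


def score_all_clade_sides(gap_taxa: set, residue_taxa: set,
                          partition: CladePartition,
                          params: DetectionParams):
    """Exhaustively score every (side, candidate clade) pair; return the
    passing assignments as (clade size, level, label, side name) tuples."""
    aln_taxa = gap_taxa | residue_taxa
    passing = []
    for side_name, side in (("gap", gap_taxa), ("residue", residue_taxa)):
        if len(side) < params.min_carriers:
            continue
        for level, label in partition.candidate_clades:
            members = partition.members(level, label) & aln_taxa
            if not members:
                continue
            if len(side & members) < len(members) - params.max_exceptions:
                continue
            if len(side - members - partition.outgroups) > params.max_foreign:
                continue
            passing.append((len(members), level, label, side_name))
    return sorted(passing)


def map_indel_to_reference(aln: ProteinAlignment, ref: str, start: int,
                           end: int, params: DetectionParams):
    """Displayed-region residue interval by walking the reference row
    gap-aware, column by column."""
    cons = [c[3] for c in column_tally(aln, params.conservation_threshold,
                                       params.max_column_gap_fraction)]
    lo, need = start, params.min_conserved_flank
    while lo > 0 and need > 0:
        lo -= 1
        need -= int(cons[lo])
    hi, need = end, params.min_conserved_flank
    while hi < aln.length and need > 0:
        need -= int(cons[hi])
        hi += 1
    pos, hits = 0, []
    for j, ch in enumerate(aln.rows[ref]):
        if ch != "-":
            pos += 1
            if lo <= j < hi:
                hits.append(pos)
    return (min(hits), max(hits)) if hits else None


def gblocks_rules(sm: Supermatrix, params: TrimParams):
    """Kept column intervals by literal rule-by-rule application."""
    n_rows = len(sm.taxa)
    states = []
    for j in range(sm.length):
        col = [sm.rows[t][j] for t in sm.taxa]
        if "-" in col and not params.allow_gap_columns:
            states.append(0)
            continue
        best = max((col.count(c) for c in set(col) if c != "-"), default=0)
        frac = best / n_rows
        states.append(2 if frac >= params.high_threshold
                      else 1 if frac > params.majority_threshold else 0)
    keep = [True] * sm.length
    j = 0
    while j < sm.length:
        if states[j] == 0:
            k = j
            while k < sm.length and states[k] == 0:
                k += 1
            if k - j > params.max_nonconserved_run:
                for m in range(j, k):
                    keep[m] = False
            j = k
        else:
            j += 1
    intervals = []
    j = 0
    while j < sm.length:
        if not keep[j]:
            j += 1
            continue
        k = j
        while k < sm.length and keep[k]:
            k += 1
        lo, hi = j, k
        while lo < hi and states[lo] != 2:
            lo += 1
        while hi > lo and states[hi - 1] != 2:
            hi -= 1
        if hi - lo >= params.min_block_length:
            intervals.append((lo, hi))
        j = k
    return intervals


def coverage_kept_columns(sm: Supermatrix, min_coverage: float):
    n = len(sm.taxa)
    return [j for j in range(sm.length)
            if sum(1 for t in sm.taxa if sm.rows[t][j] != "-") / n >= min_coverage]


def pairwise_poisson(sm: Supermatrix):
    """Two-pass Poisson distances: first collect shared columns, then count
    mismatches."""
    n = len(sm.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = sm.rows[sm.taxa[i]], sm.rows[sm.taxa[j]]
            shared = [k for k in range(sm.length)
                      if ri[k] != "-" and rj[k] != "-"]
            mism = sum(1 for k in shared
                       if ri[k] != rj[k] or ri[k] == "X" or rj[k] == "X")
            p = mism / len(shared)
            D[i, j] = D[j, i] = -math.log(1 - p)
    return D


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree and its exact leaf distance matrix.

    Built by sequential leaf attachment; returns (leaf labels, distance
    matrix, bipartitions as frozensets of leaf labels, edge lengths keyed by
    bipartition)."""
    import dendropy

    labels = [f"L{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    # start from a 3-leaf star
    for lab in labels[:3]:
        ch = tree.seed_node.add_child(dendropy.Node())
        ch.taxon = tns.require_taxon(label=lab)
        ch.edge.length = float(rng.uniform(0.1, 1.0))
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
        edge = edges[int(rng.integers(len(edges)))]
        head = edge.head_node
        parent = head.parent_node
        old_len = edge.length
        split = float(rng.uniform(0.2, 0.8)) * old_len
        mid = dendropy.Node()
        parent.remove_child(head)
        parent.add_child(mid)
        mid.edge.length = split
        mid.add_child(head)
        head.edge.length = old_len - split
        leaf = mid.add_child(dendropy.Node())
        leaf.taxon = tns.require_taxon(label=lab)
        leaf.edge.length = float(rng.uniform(0.1, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(n_leaves):
            if i != j:
                D[i, j] = pdm.distance(tns.get_taxon(labels[i]),
                                       tns.get_taxon(labels[j]))
    return labels, D, tree


def edge_lengths_by_split(tree):
    """Edge length keyed by the edge's bipartition (smaller side; leaf edges
    keyed by the singleton leaf)."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = min(below, leaves - below, key=lambda s: (len(s), sorted(s)))
        out[key] = node.edge.length
    return out


def nj_bipartitions(D: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Independent neighbor joining that tracks only cluster label sets;
    returns the internal bipartitions of the resulting unrooted tree."""
    n = len(labels)
    clusters = {i: frozenset([labels[i]]) for i in range(n)}
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    nxt = n
    all_labels = frozenset(labels)
    splits = set()
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best, best_q = None, None
        for x in range(m):
            for y in range(x + 1, m):
                i, j = active[x], active[y]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        union = clusters[i] | clusters[j]
        if 1 < len(union) < n - 1:
            splits.add(min(union, all_labels - union,
                           key=lambda s: (len(s), sorted(s))))
        for k in active:
            if k not in (i, j):
                dist[nxt, k] = dist[k, nxt] = 0.5 * (
                    dist[i, k] + dist[j, k] - dist[i, j])
        clusters[nxt] = union
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return splits


def tree_bipartitions(tree, leaf_labels=None):
    """Non-trivial bipartitions as frozensets of the smaller side's labels."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            other = leaves - below
            out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return out
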
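"""Supermatrix phylogeny: concatenation, block trimming, coverage filtering,
Poisson-corrected distances, neighbor joining with bootstrap, outgroup rooting.

This is a desk-scale stand-in for a full maximum-likelihood analysis: per-
protein alignments are concatenated into a supermatrix, poorly conserved
blocks are removed by three explicit rules (a simplified form of the
conserved-block selection performed by Gblocks-like programs), columns with
insufficient site coverage are dropped, and the tree is built by neighbor
joining on Poisson-corrected pairwise distances, with column-resampling
bootstrap support and rooting on a designated outgroup.

Trees are :class:`dendropy.Tree` objects; bootstrap supports (0-100) are
stored as internal-node labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from csiscan.alignment_io import ProteinAlignment

logger = logging.getLogger(__name__)


class CoverageError(ValueError):
    """A taxon pair shares no ungapped column."""


class NewickParseError(ValueError):
    """Malformed newick input."""


@dataclass
class Supermatrix:
    """Concatenated, partitioned protein alignment.

    ``partition_map`` maps protein id -> 0-based half-open column interval;
    intervals are disjoint and cover all columns in order.
    """

    taxa: list[str]
    rows: dict[str, str]
    partition_map: dict[str, tuple[int, int]]

    @property
    def length(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0

    def column(self, j: int) -> list[str]:
        return [self.rows[t][j] for t in self.taxa]

    def to_array(self) -> np.ndarray:
        """(n_taxa, n_columns) array of single characters."""
        return np.array([list(self.rows[t]) for t in self.taxa])

    def select_columns(self, cols: list[int]) -> "Supermatrix":
        """New supermatrix with the given columns (order preserved),
        partition map remapped."""
        rows = {t: "".join(self.rows[t][j] for j in cols) for t in self.taxa}
        pmap: dict[str, tuple[int, int]] = {}
        pos = 0
        for pid, (lo, hi) in self.partition_map.items():
            kept = sum(1 for j in cols if lo <= j < hi)
            pmap[pid] = (pos, pos + kept)
            pos += kept
        return Supermatrix(taxa=list(self.taxa), rows=rows, partition_map=pmap)


@dataclass(frozen=True)
class TrimParams:
    """Thresholds of the simplified conserved-block trimmer.

    A column is *nonconserved* unless its majority-residue fraction (over all
    rows, gaps counting against) strictly exceeds ``majority_threshold``;
    *highly conserved* when it reaches ``high_threshold``.  Gap-containing
    columns are nonconserved unless ``allow_gap_columns``.  Runs of more than
    ``max_nonconserved_run`` nonconserved columns are removed; surviving
    blocks are trimmed to highly conserved end columns and kept only when at
    least ``min_block_length`` long.
    """

    majority_threshold: float = 0.5
    high_threshold: float = 0.85
    max_nonconserved_run: int = 8
    min_block_length: int = 10
    allow_gap_columns: bool = False
    min_site_coverage: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.majority_threshold <= 1 and 0 < self.high_threshold <= 1):
            raise ValueError("thresholds must be in (0, 1]")
        if self.max_nonconserved_run < 1 or self.min_block_length < 1:
            raise ValueError("run/block lengths must be >= 1")


@dataclass
class DistanceMatrix:
    """Symmetric taxon distance matrix with per-pair effective column counts."""

    taxa: list[str]
    matrix: np.ndarray
    n_effective: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError("entries must be finite and nonnegative")
        if self.n_effective is None:
            self.n_effective = np.zeros((n, n), dtype=int)


def concatenate(alignments: list[ProteinAlignment],
                taxa: list[str]) -> Supermatrix:
    """Concatenate per-protein alignments over a common ordered taxon list.

    Proteins appear as blocks in input order; a taxon missing from a protein
    gets an all-gap row across that block.
    """
    seen: set[str] = set()
    rows = {t: [] for t in taxa}
    pmap: dict[str, tuple[int, int]] = {}
    pos = 0
    for aln in alignments:
        if aln.id in seen:
            raise ValueError(f"duplicate protein id {aln.id!r}")
        seen.add(aln.id)
        extra = set(aln.taxa) - set(taxa)
        if extra:
            raise ValueError(
                f"protein {aln.id!r} has taxa outside the supermatrix taxon "
                f"list: {sorted(extra)}")
        n = aln.length
        for t in taxa:
            rows[t].append(aln.rows.get(t, "-" * n))
        pmap[aln.id] = (pos, pos + n)
        pos += n
    return Supermatrix(taxa=list(taxa),
                       rows={t: "".join(parts) for t, parts in rows.items()},
                       partition_map=pmap)


def _column_states(sm: Supermatrix, params: TrimParams) -> list[int]:
    """0 = nonconserved, 1 = conserved, 2 = highly conserved (per column)."""
    n_rows = len(sm.taxa)
    states = []
    for j in range(sm.length):
        col = sm.column(j)
        if "-" in col and not params.allow_gap_columns:
            states.append(0)
            continue
        counts: dict[str, int] = {}
        for ch in col:
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        frac = (max(counts.values()) / n_rows) if counts else 0.0
        if frac >= params.high_threshold:
            states.append(2)
        elif frac > params.majority_threshold:
            states.append(1)
        else:
            states.append(0)
    return states


def trim_blocks(sm: Supermatrix, params: TrimParams = TrimParams()
                ) -> tuple[Supermatrix, list[tuple[int, int]]]:
    """Remove poorly conserved regions; return the trimmed matrix and the
    kept column intervals (original coordinates).

    Rules, applied in order: (1) delete every run of more than
    ``max_nonconserved_run`` consecutive nonconserved columns; (2) trim each
    remaining block inward so both end columns are highly conserved;
    (3) keep only blocks of at least ``min_block_length`` columns.
    """
    if sm.length == 0:
        return sm.select_columns([]), []
    states = _column_states(sm, params)
    n = len(states)

    removed = [False] * n
    j = 0
    while j < n:
        if states[j] == 0:
            k = j
            while k < n and states[k] == 0:
                k += 1
            if k - j > params.max_nonconserved_run:
                for m in range(j, k):
                    removed[m] = True
            j = k
        else:
            j += 1

    kept_intervals: list[tuple[int, int]] = []
    j = 0
    while j < n:
        if removed[j]:
            j += 1
            continue
        k = j
        while k < n and not removed[k]:
            k += 1
        lo, hi = j, k
        while lo < hi and states[lo] != 2:
            lo += 1
        while hi > lo and states[hi - 1] != 2:
            hi -= 1
        if hi - lo >= params.min_block_length:
            kept_intervals.append((lo, hi))
        j = k

    cols = [c for lo, hi in kept_intervals for c in range(lo, hi)]
    if not cols:
        logger.warning("trim_blocks removed every column")
    return sm.select_columns(cols), kept_intervals


def filter_site_coverage(sm: Supermatrix, min_coverage: float = 0.95
                         ) -> Supermatrix:
    """Drop columns whose non-gap fraction is below ``min_coverage``."""
    if not (0 < min_coverage <= 1):
        raise ValueError("min_coverage must be in (0, 1]")
    n_rows = len(sm.taxa)
    cols = [j for j in range(sm.length)
            if (n_rows - sm.column(j).count("-")) / n_rows >= min_coverage]
    return sm.select_columns(cols)


def poisson_distance(sm: Supermatrix) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) from pairwise mismatch
    fractions over pairwise-ungapped columns.

    ``X`` counts as a mismatch to every residue (including another ``X``).
    """
    n = len(sm.taxa)
    arr = sm.to_array()
    gap = arr == "-"
    unknown = arr == "X"
    D = np.zeros((n, n))
    eff = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            m = int(shared.sum())
            if m == 0:
                raise CoverageError(
                    f"taxa {sm.taxa[i]!r} and {sm.taxa[j]!r} share no "
                    f"ungapped column")
            mism = int((shared & ((arr[i] != arr[j]) | unknown[i] | unknown[j])).sum())
            p = mism / m
            if p >= 1.0:
                raise CoverageError(
                    f"taxa {sm.taxa[i]!r} and {sm.taxa[j]!r} are saturated "
                    f"(mismatch fraction {p})")
            d = -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
            eff[i, j] = eff[j, i] = m
    return DistanceMatrix(taxa=list(sm.taxa), matrix=D, n_effective=eff)


def _clamp(x: float, context: str) -> float:
    if x < 0:
        logger.debug("negative branch length %.4g clamped to 0 (%s)", x, context)
        return 0.0
    return x


def neighbor_joining(dm: DistanceMatrix,
                     taxon_namespace: dendropy.TaxonNamespace | None = None
                     ) -> dendropy.Tree:
    """Neighbor joining via the Q-criterion; returns an unrooted tree
    (trifurcating seed node).

    Ties in Q are broken by taxon-pair order, so the agglomeration is
    deterministic.  Negative branch lengths are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: dict[int, dendropy.Node] = {}
    for i, name in enumerate(dm.taxa):
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=name)
        nodes[i] = node

    D = {(i, j): float(dm.matrix[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        u = dendropy.Node()
        ci = u.add_child(nodes[i])
        ci.edge.length = _clamp(li, f"join {i},{j}")
        cj = u.add_child(nodes[j])
        cj.edge.length = _clamp(lj, f"join {i},{j}")
        for k in active:
            if k in (i, j):
                continue
            D[next_id, k] = D[k, next_id] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D[next_id, next_id] = 0.0
        nodes[next_id] = u
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = tree.seed_node
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        ch = root.add_child(nodes[idx])
        ch.edge.length = _clamp(ln, "final join")
    tree.is_rooted = False
    return tree


def _bipartition_keys(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Internal (non-trivial) bipartitions as frozensets of the smaller-side
    leaf labels, mapped to the child node under the corresponding edge."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        other = leaves - below
        key = min(below, other, key=lambda s: (len(s), sorted(s)))
        out[key] = node
    return out


def bootstrap_support(sm: Supermatrix, n_reps: int = 100, seed: int = 0
                      ) -> dendropy.Tree:
    """NJ tree of the supermatrix with column-resampling bootstrap supports.

    Each replicate resamples columns of the (final, filtered) supermatrix
    with replacement, rebuilds the NJ tree, and the support of each internal
    bipartition of the full-data tree is the percentage of replicates
    containing it.  Supports are stored as internal-node labels; the run is
    fully reproducible from ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = neighbor_joining(poisson_distance(sm))
    keys = _bipartition_keys(full)
    counts = {k: 0 for k in keys}
    rng = np.random.RandomState(seed)
    ncols = sm.length
    for _ in range(n_reps):
        cols = [int(c) for c in rng.randint(0, ncols, size=ncols)]
        rep_sm = sm.select_columns(cols)
        rep_tree = neighbor_joining(poisson_distance(rep_sm))
        rep_keys = _bipartition_keys(rep_tree)
        for k in counts:
            if k in rep_keys:
                counts[k] += 1
    for k, node in keys.items():
        node.label = str(int(round(100.0 * counts[k] / n_reps)))
    return full


def root_tree(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the midpoint of the edge subtending the outgroup leaf.

    Leaf-to-leaf path lengths and the unrooted bipartition set are unchanged.
    """
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup taxon {outgroup!r} not in tree")
    edge = leaf.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise to newick; internal-node labels carry bootstrap supports."""
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip() + "\n"


def read_newick(text: str,
                taxon_namespace: dendropy.TaxonNamespace | None = None
                ) -> dendropy.Tree:
    """Parse newick text (branch lengths and internal support labels kept)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return tree


def build_tree_pipeline(alignments: list[ProteinAlignment], taxa: list[str],
                        outgroup: str | None = None,
                        trim_params: TrimParams = TrimParams(),
                        n_bootstrap: int = 100, seed: int = 0
                        ) -> tuple[dendropy.Tree, Supermatrix, list[tuple[int, int]]]:
    """Full stage: concatenate -> trim -> coverage filter -> NJ + bootstrap
    -> (optional) outgroup rooting.  Deterministic for fixed inputs + seed."""
    sm = concatenate(alignments, taxa)
    trimmed, report = trim_blocks(sm, trim_params)
    filtered = filter_site_coverage(trimmed, trim_params.min_site_coverage)
    tree = bootstrap_support(filtered, n_reps=n_bootstrap, seed=seed)
    if outgroup is not None:
        tree = root_tree(tree, outgroup)
    return tree, filtered, report
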
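"""Tree algorithms on a fixed topology.

The topology is always an input — nothing here searches tree space.  A
dendropy tree is compiled once into flat arrays (:class:`CompiledTree`) and
all per-column work (Fitch parsimony, Felsenstein pruning under JC69) is
vectorized across alignment columns with numpy.

Per-gene evolutionary rate is defined operationally: with reference branch
lengths estimated once on the pseudogene-masked concatenated alignment, each
gene's rate scaler ``c_g`` is the maximum-likelihood multiplier of all
reference branch lengths under JC69 for that gene's columns, and the
relative rate is ``c_g`` normalized to mean 1 over genes.  Fitch steps per
ungapped column are kept as an independent parsimony cross-check track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import SequenceRecord

_BASE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 15, "-": 15, "?": 15}
_MISSING = 15


class PhyloError(ValueError):
    pass


@dataclass
class CompiledTree:
    """Flat-array view of a rooted tree for vectorized algorithms."""

    taxa: list[str]                 # leaf labels; leaf i is node i
    parent: np.ndarray              # parent node index, -1 at root
    lengths: np.ndarray             # branch length above each node (root: 0)
    children: list[list[int]]
    postorder: list[int]            # every node, children before parents
    labels: list[str]               # per-node label ('' for unnamed internals)

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    def leaf_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise PhyloError(f"taxon {label!r} not a leaf of the tree") from None

    def with_lengths(self, lengths: np.ndarray) -> "CompiledTree":
        return CompiledTree(self.taxa, self.parent, np.asarray(lengths, float),
                            self.children, self.postorder, self.labels)

    def scaled(self, c: float) -> "CompiledTree":
        return self.with_lengths(self.lengths * c)


def compile_tree(tree: dendropy.Tree) -> CompiledTree:
    """Index leaves 0..n_leaves-1 (Newick order), internals after, root last."""
    leaves = [nd for nd in tree.leaf_node_iter()]
    internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    nodes = leaves + internals
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        for ch in nd.child_nodes():
            children[i].append(index[id(ch)])
    postorder = [index[id(nd)] for nd in tree.postorder_node_iter()]
    taxa = [lf.taxon.label for lf in leaves]
    labels = [lf.taxon.label for lf in leaves] + ["" for _ in internals]
    return CompiledTree(taxa, parent, lengths, children, postorder, labels)


def branch_names(ctree: CompiledTree) -> list[str]:
    """Stable human-readable name per node's parent branch (leaf label or
    sorted leaf-set signature for internal branches)."""
    below: list[list[str]] = [[] for _ in range(ctree.n_nodes)]
    for i in ctree.postorder:
        if not ctree.children[i]:
            below[i] = [ctree.taxa[i]]
        else:
            for ch in ctree.children[i]:
                below[i].extend(below[ch])
    names = []
    for i in range(ctree.n_nodes):
        leaves = sorted(below[i])
        names.append(leaves[0] if len(leaves) == 1 else f"anc({leaves[0]}+{len(leaves)-1})")
    return names


# ---------------------------------------------------------------------------
# Fitch parsimony (4-state, vectorized across columns)
# ---------------------------------------------------------------------------

def leaf_state_masks(rows: dict[str, str], ctree: CompiledTree) -> np.ndarray:
    """(n_leaves, n_cols) uint8 bitmasks; gaps/N are the universal set."""
    widths = {len(s) for s in rows.values()}
    if len(widths) != 1:
        raise PhyloError("alignment rows differ in length")
    n_cols = widths.pop()
    masks = np.full((ctree.n_leaves, n_cols), _MISSING, dtype=np.uint8)
    for label, seq in rows.items():
        i = ctree.leaf_index(label)
        masks[i] = [_BASE_MASK.get(ch, _MISSING) for ch in seq]
    return masks


def fitch_steps_matrix(ctree: CompiledTree, leaf_masks: np.ndarray) -> np.ndarray:
    """Per-column minimum substitution counts by Fitch's algorithm.

    Multifurcating nodes are folded child-by-child (the standard
    generalization).  Columns whose leaves are all missing score 0.
    """
    n_cols = leaf_masks.shape[1]
    node_masks: list[np.ndarray | None] = [None] * ctree.n_nodes
    steps = np.zeros(n_cols, dtype=np.int64)
    for i in ctree.postorder:
        if not ctree.children[i]:
            node_masks[i] = leaf_masks[i]
            continue
        acc = node_masks[ctree.children[i][0]]
        for ch in ctree.children[i][1:]:
            m = node_masks[ch]
            inter = acc & m
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | m, inter)
        node_masks[i] = acc
    return steps


def fitch_steps(tree: dendropy.Tree | CompiledTree, column_states: dict[str, str]) -> int:
    """Minimum number of state changes for one nucleotide column."""
    ctree = tree if isinstance(tree, CompiledTree) else compile_tree(tree)
    rows = {k: v for k, v in column_states.items()}
    for label in rows:
        ctree.leaf_index(label)  # raises if absent
    masks = leaf_state_masks(rows, ctree)
    return int(fitch_steps_matrix(ctree, masks)[0])


# ---------------------------------------------------------------------------
# Generic set-Fitch (used with 61 codon states)
# ---------------------------------------------------------------------------

def fitch_sets(ctree: CompiledTree, leaf_sets: list[frozenset], universe: frozenset):
    """Bottom-up Fitch state sets for one character with arbitrary state space.

    ``leaf_sets[i]`` is the state set of leaf ``i``; missing leaves pass the
    full ``universe``.  Returns (per-node sets, step count).
    """
    node_sets: list[frozenset | None] = [None] * ctree.n_nodes
    steps = 0
    for i in ctree.postorder:
        if not ctree.children[i]:
            s = leaf_sets[i]
            node_sets[i] = s if s else universe
            continue
        acc = node_sets[ctree.children[i][0]]
        for ch in ctree.children[i][1:]:
            inter = acc & node_sets[ch]
            if inter:
                acc = inter
            else:
                acc = acc | node_sets[ch]
                steps += 1
        node_sets[i] = acc
    return node_sets, steps


# ---------------------------------------------------------------------------
# JC69 pruning likelihood
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _leaf_partials(rows: dict[str, str], ctree: CompiledTree) -> np.ndarray:
    """(n_leaves, n_cols, 4) conditional likelihoods; gaps/N -> all ones."""
    widths = {len(s) for s in rows.values()}
    if len(widths) != 1:
        raise PhyloError("alignment rows differ in length")
    n_cols = widths.pop()
    part = np.ones((ctree.n_leaves, n_cols, 4))
    for label, seq in rows.items():
        i = ctree.leaf_index(label)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for base, k in _BASE_INDEX.items():
            hit = arr == ord(base)
            part[i, hit] = 0.0
            part[i, hit, k] = 1.0
    return part


def _jc_probs(t: float) -> np.ndarray:
    """4x4 JC69 transition probability matrix for branch length t."""
    e = np.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def jc69_loglik(ctree: CompiledTree, rows: dict[str, str],
                leaf_partials: np.ndarray | None = None,
                lengths: np.ndarray | None = None) -> float:
    """Log-likelihood of an alignment under JC69 by Felsenstein pruning.

    Gaps and N are missing data (partial likelihood 1 for every state).
    ``leaf_partials`` may be precomputed once and reused across calls that
    differ only in branch lengths (the rate-scaler optimization).
    """
    if lengths is None:
        lengths = ctree.lengths
    if np.any(lengths < 0):
        raise PhyloError("negative branch length")
    if leaf_partials is None:
        leaf_partials = _leaf_partials(rows, ctree)
    n_cols = leaf_partials.shape[1]
    partial: list[np.ndarray | None] = [None] * ctree.n_nodes
    log_scale = np.zeros(n_cols)
    for i in ctree.postorder:
        if not ctree.children[i]:
            partial[i] = leaf_partials[i]
            continue
        acc = np.ones((n_cols, 4))
        for ch in ctree.children[i]:
            acc = acc * (partial[ch] @ _jc_probs(lengths[ch]).T)
        # rescale to avoid underflow on deep trees
        mx = acc.max(axis=1)
        mx[mx == 0] = 1.0
        acc /= mx[:, None]
        log_scale += np.log(mx)
        partial[i] = acc
    root = partial[ctree.root]
    site_lik = 0.25 * root.sum(axis=1)
    return float(np.sum(np.log(site_lik) + log_scale))


def optimize_branch_lengths(ctree: CompiledTree, rows: dict[str, str],
                            tol: float = 1e-4, max_passes: int = 20,
                            bound: float = 10.0) -> CompiledTree:
    """Coordinate-wise Brent optimization of all branch lengths under JC69.

    Passes over branches repeat until the log-likelihood improves by less
    than ``tol``.  The topology is never altered.
    """
    lp = _leaf_partials(rows, ctree)
    lengths = ctree.lengths.copy()
    best = jc69_loglik(ctree, rows, leaf_partials=lp, lengths=lengths)
    nodes = [i for i in range(ctree.n_nodes) if ctree.parent[i] >= 0]
    for _ in range(max_passes):
        prev = best
        for i in nodes:
            def neg(t: float, i=i) -> float:
                trial = lengths.copy()
                trial[i] = t
                return -jc69_loglik(ctree, rows, leaf_partials=lp, lengths=trial)

            res = minimize_scalar(neg, bounds=(0.0, bound), method="bounded",
                                  options={"xatol": 1e-7})
            if -res.fun > best:
                best = -res.fun
                lengths[i] = res.x
        if best - prev < tol:
            break
    return ctree.with_lengths(lengths)


# ---------------------------------------------------------------------------
# Per-gene rate scalers
# ---------------------------------------------------------------------------

@dataclass
class GeneRateResult:
    gene: str
    rate_scaler: float | None       # ML multiplier of reference branch lengths
    relative_rate: float | None = None   # rate_scaler / mean over genes
    parsimony_rate: float | None = None  # Fitch steps per ungapped column
    flag: str = ""                  # 'no_signal' | 'all_gap' | ''


_SCALER_BOUNDS = (1e-4, 50.0)


def fit_gene_rate(ctree: CompiledTree, gene: str, rows: dict[str, str],
                  tol: float = 1e-6) -> GeneRateResult:
    """ML branch-length multiplier for one gene against reference lengths.

    All reference branch lengths are multiplied by a single scalar ``c`` and
    ``c`` is optimized by bounded Brent search.  An all-gap alignment has no
    defined rate (returned as None); a gene with no variation drives ``c``
    to the lower bound and is flagged ``no_signal``.
    """
    if all(set(seq) <= {"-", "N"} for seq in rows.values()):
        return GeneRateResult(gene=gene, rate_scaler=None, flag="all_gap")
    lp = _leaf_partials(rows, ctree)

    def neg(c: float) -> float:
        return -jc69_loglik(ctree, rows, leaf_partials=lp, lengths=ctree.lengths * c)

    res = minimize_scalar(neg, bounds=_SCALER_BOUNDS, method="bounded",
                          options={"xatol": tol})
    c = float(res.x)
    flag = "no_signal" if c <= _SCALER_BOUNDS[0] * 2 else ""
    # parsimony cross-check: Fitch steps per column with any non-gap data
    masks = leaf_state_masks(rows, ctree)
    steps = fitch_steps_matrix(ctree, masks)
    informative = (masks != _MISSING).any(axis=0)
    n_cols = int(informative.sum())
    pars = float(steps[informative].sum() / n_cols) if n_cols else None
    return GeneRateResult(gene=gene, rate_scaler=c, parsimony_rate=pars, flag=flag)


def normalize_relative_rates(results: list[GeneRateResult]) -> list[GeneRateResult]:
    """Fill ``relative_rate`` = scaler / mean scaler (mean over defined genes)."""
    vals = [r.rate_scaler for r in results if r.rate_scaler is not None]
    if vals:
        mean = float(np.mean(vals))
        for r in results:
            r.relative_rate = None if r.rate_scaler is None else r.rate_scaler / mean
    return results


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

@dataclass
class Supermatrix:
    """Concatenated alignment with a gene -> column-interval partition map."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def gene_rows(self, gene: str) -> dict[str, str]:
        start, end = self.partitions[gene]
        return {t: self.rows[t][start:end] for t in self.taxa}

    def partition_table(self):
        import pandas as pd

        return pd.DataFrame(
            [(g, s, e) for g, (s, e) in self.partitions.items()],
            columns=["gene", "start", "end"],
        )


def concatenate(gene_alignments, gene_order: list[str] | None = None,
                pad_missing: bool = True) -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix with partition map.

    ``gene_alignments`` maps gene name -> alignment (any object with
    ``.records`` of :class:`SequenceRecord`, or a plain dict taxon->row).
    Taxa absent from a gene are padded with all-gap rows when
    ``pad_missing`` (otherwise a mismatch raises).
    """
    if not gene_alignments:
        raise PhyloError("empty gene list")
    order = gene_order if gene_order is not None else list(gene_alignments)
    per_gene_rows: dict[str, dict[str, str]] = {}
    all_taxa: list[str] = []
    for gene in order:
        aln = gene_alignments[gene]
        rows = (dict(aln) if isinstance(aln, dict)
                else {r.id: r.residues for r in aln.records})
        per_gene_rows[gene] = rows
        for t in rows:
            if t not in all_taxa:
                all_taxa.append(t)
    cat = {t: [] for t in all_taxa}
    partitions: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene in order:
        rows = per_gene_rows[gene]
        width = len(next(iter(rows.values())))
        missing = [t for t in all_taxa if t not in rows]
        if missing and not pad_missing:
            raise PhyloError(f"gene {gene} missing taxa {missing} and padding disabled")
        for t in all_taxa:
            cat[t].append(rows.get(t, "-" * width))
        partitions[gene] = (offset, offset + width)
        offset += width
    return Supermatrix(taxa=all_taxa, rows={t: "".join(v) for t, v in cat.items()},
                       partitions=partitions)
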
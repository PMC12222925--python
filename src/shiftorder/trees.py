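"""Rooted, dated phylogenies and species-table alignment.

The central container is :class:`Phylogeny`, an array-backed rooted tree with
branch lengths in millions of years (Myr).  Nodes are indexed ``0..n_nodes-1``
in postorder with tips first (``0..n_tips-1``) and the root last, which lets
the likelihood code in :mod:`shiftorder.markov` run Felsenstein pruning as a
single forward sweep over the node index.

Newick parsing and serialization are delegated to :mod:`dendropy`; this module
adds the validation, pruning and taxon-alignment behavior the downstream
analyses rely on (unique tip labels, non-negative branch lengths, preserved
root-to-tip distances under pruning, polytomy support).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYNDROMES = ("bee", "generalist", "nectar_vertebrate", "foodbody_vertebrate")
THECAL_WALLS = ("smooth", "ruminate")

TRAIT_COLUMNS = [
    "species",
    "syndrome",
    "petal_length_mm",
    "pore_height_mm",
    "pore_width_mm",
    "thecal_wall",
]


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass
class Phylogeny:
    """Array-backed rooted tree.

    Attributes
    ----------
    parent : (n_nodes,) int array; parent index of each node, -1 at the root.
    children : list of child-index lists, one per node (empty for tips).
    blen : (n_nodes,) float array; length of the edge above each node in Myr
        (0.0 at the root).
    tip_labels : tip names; ``tip_labels[i]`` labels node ``i`` for
        ``i < n_tips``.
    """

    parent: np.ndarray
    children: list[list[int]]
    blen: np.ndarray
    tip_labels: list[str]

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.blen = np.asarray(self.blen, dtype=float)
        self.validate()
        self._depths: np.ndarray | None = None

    def validate(self) -> None:
        if (self.parent == -1).sum() != 1 or self.parent[-1] != -1:
            raise NewickError("tree must have exactly one root, stored last")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dups = sorted({x for x in self.tip_labels if self.tip_labels.count(x) > 1})
            raise NewickError(f"duplicate tip labels: {dups}")
        if np.any(self.blen < 0):
            bad = int(np.argmax(self.blen < 0))
            raise NewickError(f"negative branch length at node {bad}: {self.blen[bad]}")
        # postorder contract: every child index below its parent
        for v in range(self.n_nodes - 1):
            if self.parent[v] <= v:
                raise NewickError("nodes are not in postorder (child >= parent)")

    # -- geometry ----------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for v in range(self.n_nodes - 2, -1, -1):
                d[v] = d[self.parent[v]] + self.blen[v]
            self._depths = d
        return self._depths

    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def ages(self) -> np.ndarray:
        """Node ages (Myr before present), using max tip depth as the present."""
        return self.height() - self.depths()

    def is_ultrametric(self, rtol: float = 1e-4) -> bool:
        d = self.depths()[: self.n_tips]
        h = d.max()
        return bool(h == 0 or (d.max() - d.min()) <= rtol * h)

    def total_length(self) -> float:
        return float(self.blen.sum())

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def mrca(self, nodes: list[int]) -> int:
        """Most recent common ancestor of a set of node indices."""
        paths = []
        for v in nodes:
            anc = []
            while v != -1:
                anc.append(v)
                v = self.parent[v]
            paths.append(set(anc))
        common = set.intersection(*paths)
        return min(common)  # postorder: smallest common index is deepest

    def subtree_tips(self) -> list[np.ndarray]:
        """Tip indices below each node (tips map to themselves)."""
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            out[i] = [i]
        for v in range(self.n_tips, self.n_nodes):
            acc: list[int] = []
            for c in self.children[v]:
                acc.extend(out[c])
            out[v] = acc
        return [np.asarray(t, dtype=int) for t in out]

    def patristic(self, a: str, b: str) -> float:
        idx = self.tip_index()
        i, j = idx[a], idx[b]
        d = self.depths()
        m = self.mrca([i, j])
        return float(d[i] + d[j] - 2 * d[m])

    # -- zero-length terminal guard ---------------------------------------
    def with_positive_terminals(self, eps_frac: float = 1e-8) -> "Phylogeny":
        """Replace zero-length terminal branches by ``eps_frac * height``.

        Zero pendant edges make tip transition matrices singular in the
        likelihood code; the replacement is tiny relative to tree height and
        emits a warning.
        """
        blen = self.blen.copy()
        zero = np.flatnonzero(blen[: self.n_tips] == 0.0)
        if zero.size:
            eps = eps_frac * max(self.height(), 1.0)
            blen[zero] = eps
            warnings.warn(
                f"replaced {zero.size} zero-length terminal branch(es) with {eps:g}",
                stacklevel=2,
            )
        return Phylogeny(self.parent.copy(), [list(c) for c in self.children],
                         blen, list(self.tip_labels))


# -- Newick I/O ------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.postorder_node_iter())
    tips = [nd for nd in nodes if nd.is_leaf()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    order = tips + internals  # tips first, root (last postorder internal) last
    index = {id(nd): i for i, nd in enumerate(order)}
    parent = np.full(len(order), -1, dtype=int)
    blen = np.zeros(len(order))
    children: list[list[int]] = [[] for _ in order]
    labels = []
    for nd in tips:
        tax = nd.taxon.label if nd.taxon is not None else nd.label
        if tax is None:
            raise NewickError("unlabeled tip in Newick input")
        labels.append(str(tax).replace(" ", "_"))
    for nd in order:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            children[index[id(nd.parent_node)]].append(i)
            if nd.edge.length is None:
                raise NewickError(f"missing branch length above node {i}")
            blen[i] = float(nd.edge.length)
    # internal nodes keep postorder among themselves but parents must follow
    # children in the merged ordering; dendropy postorder guarantees this.
    return Phylogeny(parent, children, blen, labels)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Raises :class:`NewickError` for unbalanced parentheses, duplicate tip
    labels, missing or negative branch lengths.
    """
    if text.count("(") != text.count(")"):
        raise NewickError("unbalanced parentheses in Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickError(f"could not parse Newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric (rel. tol 1e-4)", stacklevel=2)
    return tree


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path=None, precision: int = 12) -> str:
    """Serialize to Newick; round-trips lengths to ~1e-9 relative."""

    def render(v: int) -> str:
        if v < tree.n_tips:
            core = tree.tip_labels[v]
        else:
            core = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return core
        return f"{core}:{tree.blen[v]:.{precision}g}"

    text = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def topology_hash(tree: Phylogeny) -> str:
    """Canonical topology string: sorted nested tip-label sets."""

    def render(v: int) -> str:
        if v < tree.n_tips:
            return tree.tip_labels[v]
        return "(" + ",".join(sorted(render(c) for c in tree.children[v])) + ")"

    return render(tree.root)


# -- pruning ---------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict the tree to tip set ``keep``.

    Unary internal nodes created by the pruning are suppressed with their
    branch lengths summed, so patristic distances among retained tips are
    preserved exactly.  The original root is kept (even if left with a single
    child) so root-to-tip depths are preserved too.
    """
    keep = set(keep)
    idx = tree.tip_index()
    missing = sorted(keep - set(tree.tip_labels))
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least two tips to prune to")

    keep_node = np.zeros(tree.n_nodes, dtype=bool)
    for lab in keep:
        keep_node[idx[lab]] = True
    for v in range(tree.n_tips, tree.n_nodes):
        keep_node[v] = any(keep_node[c] for c in tree.children[v])

    # rebuild: effective children = kept children; suppress unary chains
    new_children: dict[int, list[int]] = {}
    new_blen: dict[int, float] = {}

    def build(v: int, extra: float) -> int | None:
        """Return representative old-node id for v's subtree, or None."""
        if v < tree.n_tips:
            new_blen[v] = tree.blen[v] + extra
            return v
        kids = [c for c in tree.children[v] if keep_node[c]]
        if len(kids) == 1 and v != tree.root:
            # suppress this unary node: its own edge length rides along
            return build(kids[0], extra + tree.blen[v])
        reps = [build(c, 0.0) for c in kids]
        new_children[v] = [r for r in reps if r is not None]
        new_blen[v] = (tree.blen[v] + extra) if v != tree.root else 0.0
        return v

    root_rep = build(tree.root, 0.0)
    assert root_rep == tree.root

    # re-index: tips of the new tree in original order, then internals postorder
    new_tips = [i for i in range(tree.n_tips) if keep_node[i]]
    order: list[int] = []

    def post(v: int) -> None:
        for c in new_children.get(v, []):
            post(c)
        if v >= tree.n_tips:
            order.append(v)

    post(tree.root)
    merged = new_tips + order
    remap = {old: new for new, old in enumerate(merged)}
    parent = np.full(len(merged), -1, dtype=int)
    blen = np.zeros(len(merged))
    children: list[list[int]] = [[] for _ in merged]
    for old in merged:
        new = remap[old]
        blen[new] = new_blen[old]
        for c in new_children.get(old, []):
            parent[remap[c]] = new
            children[new].append(remap[c])
    labels = [tree.tip_labels[i] for i in new_tips]
    return Phylogeny(parent, children, blen, labels)


# -- trait tables ----------------------------------------------------------

def read_trait_table(path) -> pd.DataFrame:
    """Read the species trait CSV and validate its categorical columns."""
    df = pd.read_csv(path)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dups}")
    bad = set(df["syndrome"].dropna()) - set(SYNDROMES)
    if bad:
        raise ValueError(f"unknown syndrome values: {sorted(bad)}")
    if df["syndrome"].isna().any():
        raise ValueError("syndrome is required for every species")
    bad = set(df["thecal_wall"].dropna()) - set(THECAL_WALLS)
    if bad:
        raise ValueError(f"unknown thecal wall values: {sorted(bad)}")
    return df


def align_tree_and_traits(
    tree: Phylogeny, traits: pd.DataFrame
) -> tuple[Phylogeny, pd.DataFrame]:
    """Restrict tree and trait table to their common species set.

    Dropped names on each side are logged, never guessed at: name matching
    between published trees and trait matrices is a curation step, so the
    aligner reports what it removed and proceeds on the intersection.
    """
    tree_set = set(tree.tip_labels)
    trait_set = set(traits["species"])
    common = tree_set & trait_set
    if not common:
        raise ValueError("tree and trait table share no species names")
    dropped_tree = sorted(tree_set - common)
    dropped_traits = sorted(trait_set - common)
    if dropped_tree:
        logger.info("align: dropping %d tree tips without traits: %s",
                    len(dropped_tree), dropped_tree)
    if dropped_traits:
        logger.info("align: dropping %d trait rows not in tree: %s",
                    len(dropped_traits), dropped_traits)
    out_tree = prune_to_taxa(tree, common) if dropped_tree else tree
    out_traits = traits[traits["species"].isin(common)].reset_index(drop=True)
    return out_tree, out_traits
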
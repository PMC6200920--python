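"""Distance phylogenetics for short C-terminally conserved peptides.

The peptide tree is built from a C-terminus-anchored (right-anchored)
alignment: RFamide peptides are conserved at their amidated C-terminus, so
rows are padded with gaps on the left only.  An externally computed aligned
FASTA may be supplied instead.  Distances are proportions of different
sites (p-distance) under pairwise deletion by default, with complete
deletion available; trees come from the canonical Saitou-Nei neighbor
joining agglomeration with deterministic tie-breaking, and clade support
from seeded bootstrap resampling of alignment columns.

Trees are :class:`skbio.TreeNode` objects rooted at a trifurcating root,
i.e. unrooted binary trees; internal nodes carry a ``support`` attribute
after bootstrapping.  The Newick dialect written here uses branch lengths
with six decimals, supports as internal node labels, and single-quoted
labels when a label contains Newick metacharacters or spaces; it
round-trips losslessly through :func:`read_newick`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "PhyloError",
    "PeptideAlignment",
    "right_anchor_align",
    "alignment_from_rows",
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "clade_concordance",
    "write_newick",
    "read_newick",
    "write_distance_tsv",
]

logger = logging.getLogger(__name__)

GAP = "-"


class PhyloError(ValueError):
    """Raised for invalid alignments, matrices or trees."""


@dataclass(frozen=True)
class PeptideAlignment:
    """Equal-length gapped rows over labeled peptides."""

    labels: tuple[str, ...]
    rows: tuple[str, ...]
    anchoring: str = "right-anchored"  # or "external"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise PhyloError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise PhyloError("duplicate labels in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise PhyloError("alignment rows have unequal lengths")
        if self.anchoring == "right-anchored":
            for label, row in zip(self.labels, self.rows):
                if GAP in row.lstrip(GAP):
                    raise PhyloError(
                        f"right-anchored row {label!r} has interior gaps"
                    )

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, label: str) -> str:
        return self.rows[self.labels.index(label)].replace(GAP, "")


def right_anchor_align(
    peptides: Mapping[str, str] | Sequence[tuple[str, str]],
) -> PeptideAlignment:
    """Left-pad every sequence with gaps to the maximum length.

    Order is preserved; at least two peptides are required.
    """
    items = list(peptides.items()) if isinstance(peptides, Mapping) else list(peptides)
    if len(items) < 2:
        raise PhyloError("need at least 2 peptides to align")
    width = max(len(s) for _, s in items)
    labels = tuple(label for label, _ in items)
    rows = tuple(s.rjust(width, GAP) for _, s in items)
    return PeptideAlignment(labels=labels, rows=rows)


def alignment_from_rows(
    labels: Sequence[str], rows: Sequence[str], anchoring: str = "external"
) -> PeptideAlignment:
    """Wrap externally aligned rows (e.g. from an aligned FASTA)."""
    return PeptideAlignment(tuple(labels), tuple(rows), anchoring)


def _char_matrix(aln: PeptideAlignment) -> np.ndarray:
    return np.array([list(r) for r in aln.rows], dtype="<U1")


def p_distance(
    alignment: PeptideAlignment,
    deletion: str = "pairwise",
    min_shared: int = 3,
    on_undefined: str | float = "error",
) -> DistanceMatrix:
    """Proportion-of-different-sites distance matrix.

    Under pairwise deletion each pair is scored over the columns where both
    rows are residues; under complete deletion every column containing any
    gap is removed first.  A pair sharing fewer than ``min_shared``
    scoreable columns raises an error naming the pair, unless
    ``on_undefined`` is a number to substitute (used by the bootstrap,
    where resampling can leave barely-overlapping short peptides).
    """
    if deletion not in ("pairwise", "complete"):
        raise PhyloError(f"unknown deletion policy {deletion!r}")
    A = _char_matrix(alignment)
    if deletion == "complete":
        keep = (A != GAP).all(axis=0)
        if not keep.any():
            raise PhyloError(
                "complete deletion removed every column; use pairwise deletion"
            )
        A = A[:, keep]
    nongap = A != GAP
    shared = (nongap[:, None, :] & nongap[None, :, :])
    n_shared = shared.sum(axis=2)
    n_diff = ((A[:, None, :] != A[None, :, :]) & shared).sum(axis=2)
    n = len(alignment.labels)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if n_shared[i, j] < min_shared:
                if on_undefined == "error":
                    raise PhyloError(
                        f"pair ({alignment.labels[i]!r}, {alignment.labels[j]!r}) "
                        f"shares only {n_shared[i, j]} scoreable columns "
                        f"(< {min_shared})"
                    )
                values[i, j] = values[j, i] = float(on_undefined)
            else:
                d = n_diff[i, j] / n_shared[i, j]
                values[i, j] = values[j, i] = d
    return DistanceMatrix(values, ids=list(alignment.labels))


def _as_matrix(D) -> tuple[list[str], np.ndarray]:
    if isinstance(D, DistanceMatrix):
        return list(D.ids), np.asarray(D.data, dtype=float)
    raise PhyloError("expected a skbio DistanceMatrix")


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``
    is joined; ties break to the lowest (row, column) index in the current
    matrix order (new nodes are appended at the end).  Branch lengths use
    the standard two-point formulas, the final three nodes the three-point
    formulas; negative lengths are clamped to zero with the original value
    logged.  The result is an unrooted binary tree represented with a
    trifurcating root.
    """
    ids, M = _as_matrix(D)
    n = len(ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(M).all():
        raise PhyloError("distance matrix contains non-finite values")
    if not np.allclose(M, M.T, atol=0):
        raise PhyloError("distance matrix is not symmetric")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    M = M.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = M.sum(axis=1)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        mask = np.full_like(Q, np.inf)
        mask[iu] = Q[iu]
        i, j = np.unravel_index(int(np.argmin(mask)), mask.shape)
        d_ij = M[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = _clamp(li, a.name)
        b.length = _clamp(lj, b.name)
        parent.append(a)
        parent.append(b)
        d_new = 0.5 * (M[i, :] + M[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        M2 = np.empty((m - 1, m - 1), dtype=float)
        M2[: m - 2, : m - 2] = M[np.ix_(keep, keep)]
        M2[: m - 2, m - 2] = M2[m - 2, : m - 2] = d_new[keep]
        M2[m - 2, m - 2] = 0.0
        M = M2
        nodes = [nodes[k] for k in keep] + [parent]
    # resolve the last three nodes with the three-point formulas
    d01, d02, d12 = M[0, 1], M[0, 2], M[1, 2]
    root = TreeNode()
    for node, length in zip(
        nodes,
        (
            0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01),
        ),
    ):
        node.length = _clamp(length, node.name)
        root.append(node)
    return root


def _clamp(length: float, name) -> float:
    if length < 0:
        logger.info(
            "clamped negative branch length %g to 0 (node %s)", length, name
        )
        return 0.0
    return float(length)


def _tipset(node: TreeNode) -> frozenset[str]:
    return frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset(
        {node.name}
    )


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (internal edges) in canonical form.

    The canonical side of a split is the one not containing the
    lexicographically smallest leaf label.  An unrooted binary tree on n
    leaves yields exactly n - 3 of these.
    """
    full = frozenset(t.name for t in tree.tips())
    ref = min(full)
    splits = set()
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        side = _tipset(node)
        if ref in side:
            side = full - side
        if len(side) >= 2 and len(full) - len(side) >= 2:
            splits.add(side)
    return splits


def _edge_sides(tree: TreeNode) -> list[frozenset[str]]:
    """Tip sets below every edge (one per non-root node, pendant included)."""
    return [_tipset(node) for node in tree.preorder(include_self=False)]


def bootstrap_support(
    alignment: PeptideAlignment,
    replicates: int = 50,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> TreeNode:
    """Attach bootstrap supports to the point-estimate NJ tree.

    Columns are resampled with replacement per replicate using a seeded
    generator; the support of an internal edge is the fraction of
    replicate trees containing the same bipartition.  Supports are
    invariant to leaf order and reproducible for a fixed seed.
    """
    if replicates < 1:
        raise PhyloError("replicates must be >= 1")
    if seed is None:
        raise PhyloError("bootstrap requires an explicit seed")
    if alignment.width < 1:
        raise PhyloError("alignment too short to resample")
    tree = neighbor_joining(p_distance(alignment, deletion=deletion))
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    width = alignment.width
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        rows = tuple(
            "".join(row[c] for c in cols) for row in alignment.rows
        )
        rep_aln = PeptideAlignment(alignment.labels, rows, anchoring="external")
        rep_dm = p_distance(
            rep_aln, deletion=deletion, min_shared=1, on_undefined=1.0
        )
        rep_splits = bipartitions(neighbor_joining(rep_dm))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    full = frozenset(t.name for t in tree.tips())
    ref = min(full)
    for node in tree.preorder(include_self=False):
        if node.is_tip():
            continue
        side = _tipset(node)
        if ref in side:
            side = full - side
        if side in counts:
            node.support = counts[side] / replicates
    return tree


def clade_concordance(
    tree: TreeNode, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group monophyly report for a leaf-labeled unrooted tree.

    For each group the report states whether its leaves form one side of
    some edge of the tree and, if not, the minimum number of leaves whose
    removal makes the group monophyletic (exact, via a scan over all
    edges: removing leaves cannot create a separating edge that does not
    correspond to an edge of the original tree).
    """
    leaves = [t.name for t in tree.tips()]
    unlabeled = [l for l in leaves if l not in labels]
    if unlabeled:
        raise PhyloError(f"unlabeled leaves: {unlabeled[:5]}")
    full = frozenset(leaves)
    sides = _edge_sides(tree)
    rows = []
    for group in sorted(set(labels[l] for l in leaves)):
        members = frozenset(l for l in leaves if labels[l] == group)
        if members == full:
            rows.append(
                {"group": group, "n_leaves": len(members),
                 "monophyletic": True, "removal_count": 0}
            )
            continue
        best = len(leaves)
        for side in sides:
            for s in (side, full - side):
                cost = len(members - s) + len(s - members)
                if cost < best:
                    best = cost
        rows.append(
            {
                "group": group,
                "n_leaves": len(members),
                "monophyletic": best == 0,
                "removal_count": best,
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "n_leaves", "monophyletic", "removal_count"]
    )


# ---------------------------------------------------------------------------
# Newick IO (fixed dialect: 6-decimal branch lengths, supports as internal
# labels, single-quoted labels where needed)

_NEEDS_QUOTE = set(" \t(),:;[]'\"")


def _format_label(label: str) -> str:
    if any(c in _NEEDS_QUOTE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _write_node(node: TreeNode, is_root: bool) -> str:
    if node.is_tip():
        body = _format_label(str(node.name))
    else:
        inner = ",".join(_write_node(c, False) for c in node.children)
        support = getattr(node, "support", None)
        label = f"{support:.6f}" if support is not None else (
            _format_label(str(node.name)) if node.name else ""
        )
        body = f"({inner}){label}"
    if is_root:
        return body
    length = node.length if node.length is not None else 0.0
    return f"{body}:{length:.6f}"


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to the package's Newick dialect."""
    return _write_node(tree, True) + ";"


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        c = self.peek()
        self.pos += 1
        return c

    def label(self) -> str:
        if self.peek() == "'":
            self.take()
            out = []
            while True:
                c = self.take()
                if c == "'":
                    if self.peek() == "'":
                        out.append(self.take())
                    else:
                        break
                elif not c:
                    raise PhyloError("unterminated quoted label")
                else:
                    out.append(c)
            return "".join(out)
        out = []
        while self.peek() and self.peek() not in " \t(),:;":
            out.append(self.take())
        return "".join(out)


def _parse_node(sc: _Scanner) -> TreeNode:
    node = TreeNode()
    if sc.peek() == "(":
        sc.take()
        while True:
            node.append(_parse_node(sc))
            c = sc.take()
            if c == ")":
                break
            if c != ",":
                raise PhyloError(f"unexpected {c!r} in Newick string")
        label = sc.label()
        if label:
            try:
                value = float(label)
            except ValueError:
                node.name = label
            else:
                if 0.0 <= value <= 1.0:
                    node.support = value
                else:
                    node.name = label
    else:
        name = sc.label()
        if not name:
            raise PhyloError("empty leaf label in Newick string")
        node.name = name
    if sc.peek() == ":":
        sc.take()
        out = []
        while sc.peek() and sc.peek() not in ",();":
            out.append(sc.take())
        node.length = float("".join(out))
    return node


def read_newick(text: str) -> TreeNode:
    """Parse the package's Newick dialect back into a tree."""
    sc = _Scanner(text.strip())
    tree = _parse_node(sc)
    if sc.take() != ";":
        raise PhyloError("Newick string must end with ';'")
    return tree


def write_distance_tsv(dm: DistanceMatrix, path, style: str = "tsv") -> None:
    """Write a square distance matrix: labeled TSV or square PHYLIP."""
    ids = list(dm.ids)
    data = np.asarray(dm.data)
    with open(path, "w", encoding="utf-8") as fh:
        if style == "tsv":
            fh.write("\t" + "\t".join(ids) + "\n")
            for i, label in enumerate(ids):
                fh.write(
                    label
                    + "\t"
                    + "\t".join(f"{x:.6f}" for x in data[i])
                    + "\n"
                )
        elif style == "phylip":
            fh.write(f"{len(ids)}\n")
            for i, label in enumerate(ids):
                fh.write(
                    label.replace(" ", "_")[:10].ljust(10)
                    + " "
                    + " ".join(f"{x:.6f}" for x in data[i])
                    + "\n"
                )
        else:
            raise PhyloError(f"unknown style {style!r}")
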
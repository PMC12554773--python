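"""CDR3 sequence homology: trimming, Levenshtein distances, and
neighbor-joining trees.

The first ``trim_left`` and last ``trim_right`` residues (default 3 and 3)
of each CDR3 are removed before comparison: the flanks are germline-encoded
and nearly invariant, so homology is assessed on the non-redundant core.
Pairwise Levenshtein (unit-cost edit) distances over the pooled
spike-specific cores feed a neighbor-joining tree whose leaves carry
participant and group labels; clades of interest are exported as distance
submatrices.

Edit distances are computed with edlib; tree topology search is a
neighbor-joining implementation with lexicographic tie-breaking so the
Newick output is reproducible, emitting scikit-bio ``TreeNode`` objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
from skbio import TreeNode

from .model import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrimmedCdr3:
    seq_id: str
    original: str
    core: str
    owner: str = ""
    group: str = ""


def trim_cdr3(seq: str, trim_left: int = 3, trim_right: int = 3) -> str:
    """Remove the first ``trim_left`` and last ``trim_right`` residues.

    Raises :class:`ValidationError` for sequences too short to retain at
    least one core residue; batch callers exclude those with a warning.
    """
    if len(seq) <= trim_left + trim_right:
        raise ValidationError(
            f"CDR3 {seq!r} (length {len(seq)}) is too short to trim "
            f"{trim_left}+{trim_right} residues"
        )
    return seq[trim_left: len(seq) - trim_right]


def trim_pool(
    seqs: list[tuple[str, str, str, str]], trim_left: int = 3, trim_right: int = 3
) -> list[TrimmedCdr3]:
    """Trim a pooled list of (seq_id, cdr3, owner, group) tuples.

    Sequences too short for the trimming rule are excluded with a logged
    warning rather than padded — the rule is undefined for them.
    """
    out = []
    for seq_id, cdr3, owner, group in seqs:
        try:
            core = trim_cdr3(cdr3, trim_left, trim_right)
        except ValidationError:
            logger.warning(
                "excluding CDR3 %s (%s): too short for %d+%d trimming",
                cdr3, seq_id, trim_left, trim_right,
            )
            continue
        out.append(TrimmedCdr3(seq_id=seq_id, original=cdr3, core=core,
                               owner=owner, group=group))
    return out


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b``."""
    return int(edlib.align(a, b, task="distance")["editDistance"])


@dataclass
class DistanceMatrix:
    """Labeled square matrix of pairwise CDR3 core edit distances."""

    ids: list[str]
    matrix: np.ndarray
    owners: list[str] | None = None
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if len(set(self.ids)) != n:
            raise ValidationError("sequence ids must be unique")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValidationError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(
            ids=list(ids),
            matrix=self.matrix[np.ix_(idx, idx)],
            owners=[self.owners[i] for i in idx] if self.owners else None,
            groups=[self.groups[i] for i in idx] if self.groups else None,
        )


def pairwise_distance_matrix(seqs: list[TrimmedCdr3]) -> DistanceMatrix:
    """Full symmetric Levenshtein distance matrix over trimmed cores.

    Duplicate cores are kept as separate leaves at distance 0 — shared
    sequences between owners/groups are exactly what the homology analysis
    looks for.
    """
    if len(seqs) < 2:
        raise ValidationError("need at least 2 sequences for a distance matrix")
    n = len(seqs)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein_distance(seqs[i].core, seqs[j].core)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(
        ids=[s.seq_id for s in seqs],
        matrix=m,
        owners=[s.owner for s in seqs],
        groups=[s.group for s in seqs],
    )


def build_unrooted_tree(dm: DistanceMatrix, method: str = "nj") -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    The tree is unrooted, represented with a trifurcating root.  Ties in the
    Q criterion break toward the lexicographically smallest label pair, and
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch (the pair's total length is preserved), so the Newick
    serialization is stable for a fixed input order.
    """
    if method != "nj":
        raise ValueError(f"unknown tree method {method!r}")
    if dm.n < 3:
        raise ValidationError("need at least 3 leaves to build an unrooted tree")

    # active nodes: label -> TreeNode; distances: frozenset pair -> float
    nodes: dict[str, TreeNode] = {
        label: TreeNode(name=label) for label in dm.ids
    }
    dist: dict[frozenset, float] = {}
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            dist[frozenset((dm.ids[i], dm.ids[j]))] = float(dm.matrix[i, j])

    internal_counter = 0
    while len(nodes) > 3:
        labels = sorted(nodes)
        n = len(labels)
        r = {
            a: sum(dist[frozenset((a, b))] for b in labels if b != a)
            for a in labels
        }
        best = None
        for ai in range(n):
            for bi in range(ai + 1, n):
                a, b = labels[ai], labels[bi]
                q = (n - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
                # lexicographic tie-break is implicit: label pairs are
                # visited in sorted order and strict improvement is required
        _, a, b = best
        d_ab = dist[frozenset((a, b))]
        la = d_ab / 2.0 + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = d_ab - la
        if la < 0:
            lb, la = d_ab, 0.0
        if lb < 0:
            la, lb = d_ab, 0.0
        internal_counter += 1
        new_label = f"n{internal_counter}"
        parent = TreeNode(name=new_label)
        nodes[a].length = la
        nodes[b].length = lb
        parent.extend([nodes[a], nodes[b]])
        for c in labels:
            if c in (a, b):
                continue
            d_new = 0.5 * (dist[frozenset((a, c))] + dist[frozenset((b, c))] - d_ab)
            dist[frozenset((new_label, c))] = max(d_new, 0.0)
        del nodes[a], nodes[b]
        nodes[new_label] = parent

    (x, y, z) = sorted(nodes)
    dxy = dist[frozenset((x, y))]
    dxz = dist[frozenset((x, z))]
    dyz = dist[frozenset((y, z))]
    nodes[x].length = max((dxy + dxz - dyz) / 2.0, 0.0)
    nodes[y].length = max((dxy + dyz - dxz) / 2.0, 0.0)
    nodes[z].length = max((dxz + dyz - dxy) / 2.0, 0.0)
    root = TreeNode(name="root")
    root.extend([nodes[x], nodes[y], nodes[z]])
    return root


def tree_to_newick(tree: TreeNode) -> str:
    import io as _io

    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def internal_node_ids(tree: TreeNode) -> list[str]:
    return [n.name for n in tree.non_tips(include_self=True) if n.name]


def extract_clade(
    tree: TreeNode, node_id: str, dm: DistanceMatrix, side: str = "auto"
) -> tuple[list[str], DistanceMatrix, dict]:
    """Leaves under the edge above ``node_id`` plus their distance submatrix.

    ``side='auto'`` takes the smaller side of the bipartition induced by the
    edge; ``'below'``/``'above'`` force the subtree below the node or its
    complement.  The returned metadata records the color-scale range of the
    *full* matrix, so heatmaps rendered from several clades share one fixed
    scale.
    """
    try:
        node = tree.find(node_id)
    except Exception:
        valid = internal_node_ids(tree) + [t.name for t in tree.tips()]
        raise ValidationError(
            f"unknown node id {node_id!r}; valid ids: {valid}"
        ) from None
    below = [t.name for t in node.tips()] or [node.name]
    all_leaves = [t.name for t in tree.tips()]
    above = [l for l in all_leaves if l not in set(below)]
    if side == "below" or (side == "auto" and (len(below) <= len(above) or not above)):
        chosen = below
    elif side in ("above", "auto"):
        chosen = above
    else:
        raise ValueError(f"unknown side {side!r}")
    sub = dm.submatrix(chosen)
    meta = {
        "node_id": node_id,
        "side": side,
        "color_scale_min": float(dm.matrix.min()),
        "color_scale_max": float(dm.matrix.max()),
    }
    return chosen, sub, meta
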
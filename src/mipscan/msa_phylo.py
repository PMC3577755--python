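"""Protein alignment, distance matrices and neighbor-joining trees.

The pairwise aligner is a deterministic affine-gap Gotoh DP (BLOSUM62,
gap open 10 / extend 0.5 by default, ClustalX-like).  The progressive MSA
builds a UPGMA guide tree from quick k-mer distances and merges profiles
leaf-to-root with the same DP kernel.  Neighbor joining is the standard
Saitou–Nei agglomeration with rate-corrected branch lengths; trees are
scikit-bio ``TreeNode`` objects, so Newick round-trips go through a
battle-tested serializer.
"""

from __future__ import annotations

import io
import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from ._dp import gotoh_align

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """Rows of (id, gapped sequence); all rows the same length."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.rows)

    def degapped(self, row_id: str) -> str:
        for i, s in self.rows:
            if i == row_id:
                return s.replace("-", "")
        raise KeyError(row_id)

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.rows)


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 21x21 substitution matrix over ACDEFGHIKLMNPQRSTVWYX."""
    blosum = substitution_matrices.load(name)
    mat = np.zeros((21, 21))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = blosum[a][b]
    return mat


def simple_matrix(match: float = 1.0, mismatch: float = -1.0) -> np.ndarray:
    mat = np.full((21, 21), mismatch)
    np.fill_diagonal(mat, match)
    return mat


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise AlignmentError(f"non-amino-acid character {exc} in sequence") from exc


def _resolve_matrix(matrix) -> np.ndarray:
    if matrix is None:
        return load_matrix()
    if isinstance(matrix, str):
        return load_matrix(matrix)
    return np.asarray(matrix, dtype=float)


def global_align(a, b, *, matrix=None, gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> tuple[Alignment, float]:
    """Optimal affine-gap global alignment of two protein records.

    Returns the alignment and its score.  Traceback ties resolve
    diagonal > up > left, so the result is deterministic.
    """
    if not a.sequence or not b.sequence:
        raise AlignmentError("cannot align an empty sequence")
    mat = _resolve_matrix(matrix)
    ia, ib = _encode(a.sequence), _encode(b.sequence)
    score, ops = gotoh_align(mat[np.ix_(ia, ib)], gap_open, gap_extend)
    ga, gb = [], []
    pa = pb = 0
    for op in ops:
        if op == 0:
            ga.append(a.sequence[pa]); gb.append(b.sequence[pb])
            pa += 1; pb += 1
        elif op == 1:
            ga.append(a.sequence[pa]); gb.append("-")
            pa += 1
        else:
            ga.append("-"); gb.append(b.sequence[pb])
            pb += 1
    aln = Alignment(rows=((a.id, "".join(ga)), (b.id, "".join(gb))))
    return aln, float(score)


# ---------------------------------------------------------------------------
# Progressive MSA


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    """Quick guide distances: 1 - fraction of shared k-mers (ClustalW-style)."""
    counters = [Counter(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = min(sum(counters[i].values()), sum(counters[j].values()))
            d[i, j] = d[j, i] = 1.0 - shared / denom if denom else 1.0
    return d


def _upgma_order(d: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA merge schedule; each merge references cluster indices, with new
    clusters numbered n, n+1, ... in merge order."""
    n = d.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        (i, j), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[i] + active[j]
        del active[i], active[j]
        # average linkage over original leaf distances
        newd = {}
        for k in list(active):
            pair_sum = sum(d[x, y] for x in members for y in active[k])
            newd[k] = pair_sum / (len(members) * len(active[k]))
        dist = {
            (min(a, b), max(a, b)): v
            for (a, b), v in dist.items()
            if a in active and b in active
        }
        for k, v in newd.items():
            dist[(min(nxt, k), max(nxt, k))] = v
        active[nxt] = members
        merges.append((i, j))
        nxt += 1
    return merges


def _profile(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies (gaps give columns reduced weight)."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                prof[j, _AA_INDEX[c]] += 1
    return prof / len(rows)


def _merge(rows_a: list[tuple[str, str]], rows_b: list[tuple[str, str]],
           mat: np.ndarray, gap_open: float, gap_extend: float):
    pa = _profile([s for _, s in rows_a])
    pb = _profile([s for _, s in rows_b])
    S = pa @ mat @ pb.T
    _, ops = gotoh_align(S, gap_open, gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 0:
            for r, (_, s) in enumerate(rows_a):
                out_a[r] += s[ia]
            for r, (_, s) in enumerate(rows_b):
                out_b[r] += s[ib]
            ia += 1; ib += 1
        elif op == 1:
            for r, (_, s) in enumerate(rows_a):
                out_a[r] += s[ia]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, (_, s) in enumerate(rows_b):
                out_b[r] += s[ib]
            ib += 1
    return (
        [(rid, out_a[r]) for r, (rid, _) in enumerate(rows_a)]
        + [(rid, out_b[r]) for r, (rid, _) in enumerate(rows_b)]
    )


def progressive_msa(records, *, matrix=None, gap_open: float = 10.0,
                    gap_extend: float = 0.5) -> Alignment:
    """Progressive multiple alignment guided by a UPGMA tree on k-mer
    distances, profiles merged leaf-to-root."""
    records = list(records)
    if len(records) < 2:
        raise AlignmentError("progressive MSA needs at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate record ids")
    mat = _resolve_matrix(matrix)
    guide = _kmer_distance([r.sequence for r in records])
    merges = _upgma_order(guide)
    clusters: dict[int, list[tuple[str, str]]] = {
        i: [(r.id, r.sequence)] for i, r in enumerate(records)
    }
    nxt = len(records)
    for i, j in merges:
        clusters[nxt] = _merge(clusters.pop(i), clusters.pop(j), mat,
                               gap_open, gap_extend)
        nxt += 1
    (final,) = clusters.values()
    order = {rid: k for k, rid in enumerate(ids)}
    final.sort(key=lambda row: order[row[0]])
    return Alignment(rows=tuple(final))


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(aln: Alignment, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances from an alignment with pairwise gap deletion.

    ``model`` is "p-distance" or "poisson" (d = -ln(1 - p)).
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(aln.rows) < 2:
        raise AlignmentError("need at least two rows")
    seqs = np.array([list(s) for _, s in aln.rows])
    gap = seqs == "-"
    n = len(aln.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            ncomp = int(ok.sum())
            if ncomp == 0:
                raise AlignmentError(
                    f"rows {aln.rows[i][0]!r} and {aln.rows[j][0]!r} share no "
                    "comparable columns"
                )
            p = float((seqs[i, ok] != seqs[j, ok]).sum()) / ncomp
            if model == "poisson":
                if p >= 1.0:
                    raise AlignmentError("p-distance 1.0: Poisson correction undefined")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=list(aln.ids))


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic lowest-index tie-break.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge (the pair's total is preserved).  The returned tree is
    unrooted in the usual sense: the root trifurcates.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    idx = list(range(n))

    while len(idx) > 3:
        m = len(idx)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a, b in itertools.combinations(range(m), 2):
            if best is None or q[a, b] < q[best]:
                best = (a, b)
        a, b = best
        i, j = idx[a], idx[b]
        vi = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        vj = sub[a, b] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = TreeNode()
        nodes[i].length = max(vi, 0.0)
        nodes[j].length = max(vj, 0.0)
        parent.extend([nodes[i], nodes[j]])
        # new node reuses slot i
        new_row = 0.5 * (d[i] + d[j] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        idx.remove(j)

    a, b, c = idx
    root = TreeNode()
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node_i, v in ((a, va), (b, vb), (c, vc)):
        nodes[node_i].length = max(v, 0.0)
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree."""
    return tree.tip_tip_distances()


def write_newick(tree: TreeNode, path=None) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    """Read Newick from a path or a literal string."""
    text = None
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, TypeError):
        text = str(source)
    return TreeNode.read(io.StringIO(text), format="newick")


def smallest_clade(tree: TreeNode, leaf_names) -> set[str]:
    """Leaf set of the smallest clade containing all the given leaves
    (monophyly check helper)."""
    lca = tree.lca([tree.find(name) for name in leaf_names])
    return {tip.name for tip in lca.tips()} or {lca.name}


def is_unrooted_cluster(tree: TreeNode, leaf_names) -> bool:
    """True iff some edge of the (unrooted) tree separates exactly these
    leaves from the rest.

    The NJ root is an arbitrary trifurcation, so rooted monophyly can fail
    spuriously when the root falls inside the group; the bipartition test
    is the correct unrooted criterion (a group is also a cluster when its
    complement hangs below one edge).
    """
    target = set(leaf_names)
    all_tips = {tip.name for tip in tree.tips()}
    if not target <= all_tips:
        raise ValueError("leaf names missing from tree")
    complement = all_tips - target
    for node in tree.traverse(include_self=False):
        below = {tip.name for tip in node.tips()} or {node.name}
        if below == target or below == complement:
            return True
    return False
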
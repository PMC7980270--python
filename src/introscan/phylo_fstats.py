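"""p-distance matrices, neighbour-joining trees, IBS checks and the f3 test.

Individual-level distances use genotype dosages (allele sharing): for
diploid dosages ``g in {0, 1, 2}``, ``d_ij`` is the mean of ``|g_i - g_j| / 2``
over co-called sites, and IBS = 1 - d.  Trees are built with the
Saitou-Nei neighbour-joining agglomeration using the Studier-Keppler
criterion, which is exact on additive distance matrices.

The three-population test follows the Reich/Patterson formulation with the
target-heterozygosity bias correction and a delete-one block jackknife
standard error over contiguous genomic blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel import GenomicInterval, HaplotypePanel

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "F3Result",
    "p_distance_matrix",
    "flag_high_ibs_pairs",
    "nj_tree",
    "region_tree",
    "f3_test",
]


# ------------------------------------------------------------- distances

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair site counts."""

    labels: list[str]
    d: np.ndarray
    n_sites: np.ndarray

    @property
    def ibs(self) -> np.ndarray:
        """Identity-by-state matrix, 1 - d."""
        return 1.0 - self.d

    def __post_init__(self) -> None:
        m = len(self.labels)
        if self.d.shape != (m, m):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")


def p_distance_matrix(
    panel: HaplotypePanel,
    interval: GenomicInterval | None = None,
    samples: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Genotype-dosage p-distance between individuals.

    ``d_ij = mean over co-called sites of |g_i - g_j| / 2`` with dosages
    ``g in {0, 1, 2}``.  Restricted to ``interval`` when given (for
    region-induced trees).  Pairs with zero co-called sites get NaN
    (fatal downstream in tree building).
    """
    if samples is None:
        samples = list(panel.sample_ids)
    idx = [panel.sample_ids.index(s) for s in samples]
    parts = []
    for chrom in panel.chrom_names:
        if interval is not None and chrom != interval.chrom:
            continue
        if interval is None:
            mat = panel.alleles[chrom]
        else:
            lo, hi = panel.site_range(chrom, interval.start, interval.end)
            mat = panel.alleles[chrom][lo:hi]
        if len(mat):
            parts.append(mat)
    m = len(samples)
    if not parts:
        return DistanceMatrix(
            labels=list(samples),
            d=np.full((m, m), np.nan),
            n_sites=np.zeros((m, m), dtype=int),
        )
    mat = np.vstack(parts)
    g = np.empty((mat.shape[0], m))
    for j, i in enumerate(idx):
        a, b = mat[:, 2 * i], mat[:, 2 * i + 1]
        called = (a >= 0) & (b >= 0)
        g[:, j] = np.where(called, a + b, np.nan)
    d = np.zeros((m, m))
    n = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
            n[i, j] = n[j, i] = int(ok.sum())
            if n[i, j] == 0:
                d[i, j] = d[j, i] = np.nan
            else:
                val = np.abs(g[ok, i] - g[ok, j]).mean() / 2.0
                d[i, j] = d[j, i] = val
    return DistanceMatrix(labels=list(samples), d=d, n_sites=n)


def flag_high_ibs_pairs(
    matrix: DistanceMatrix, threshold: float = 0.9
) -> list[tuple[str, str, float]]:
    """Pairs with IBS >= threshold: potential relatives or duplicates."""
    ibs = matrix.ibs
    out = []
    m = len(matrix.labels)
    for i in range(m):
        for j in range(i + 1, m):
            if not np.isnan(ibs[i, j]) and ibs[i, j] >= threshold:
                out.append((matrix.labels[i], matrix.labels[j], float(ibs[i, j])))
    return out


# ------------------------------------------------------------------ trees

class TreeNode:
    """A (possibly unrooted) tree node; internal nodes hold children with
    branch lengths, leaves hold a label."""

    __slots__ = ("label", "children")

    def __init__(
        self,
        label: str | None = None,
        children: list[tuple["TreeNode", float]] | None = None,
    ):
        self.label = label
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, decimals: int = 6) -> str:
        return self._newick(decimals) + ";"

    def _newick(self, decimals: int) -> str:
        if self.is_leaf:
            return self.label
        inner = ",".join(
            f"{c._newick(decimals)}:{bl:.{decimals}f}" for c, bl in self.children
        )
        return f"({inner})"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions as frozensets of leaf labels (one side).

        Each internal edge contributes the leaf set of its child subtree;
        both orientations are returned so comparisons can be made directly
        against another tree's splits over the same leaf set.
        """
        all_leaves = frozenset(self.leaves())
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset()
            for c, _ in node.children:
                side = walk(c)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(side)
                    out.add(all_leaves - side)
                below = below | side
            return below

        walk(self)
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic (path-length) distances between all leaf pairs."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, 0.0)]
            sub = []
            for c, bl in node.children:
                sub.append([(lab, d + bl) for lab, d in walk(c)])
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i]:
                        for lb, db in sub[j]:
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            return [x for part in sub for x in part]

        walk(self)
        return dists


def nj_tree(
    matrix: DistanceMatrix, outgroup: str | None = None
) -> TreeNode:
    """Neighbour-joining tree (Saitou-Nei with Studier-Keppler criterion).

    Tie-breaking is deterministic: the minimal-Q pair with the smallest
    (i, j) index pair wins.  The result is unrooted (final 3-way node);
    with ``outgroup`` the tree is rooted on the outgroup's edge, splitting
    it in half, for display.  Negative branch lengths are kept but warned
    about.  Exact (topology and branch lengths) on additive matrices.
    """
    m = len(matrix.labels)
    if m < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if np.isnan(matrix.d).any():
        raise ValueError("distance matrix has missing entries")
    if outgroup is not None and outgroup not in matrix.labels:
        raise ValueError(f"outgroup {outgroup!r} not among labels")

    D = matrix.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=l) for l in matrix.labels]
    active = list(range(m))
    negative = False

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        Q[np.tril_indices(k)] = np.inf
        flat = int(np.argmin(Q))  # row-major: smallest i then j on ties
        qi, qj = divmod(flat, k)
        i, j = active[qi], active[qj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[qi] - r[qj]) / (2.0 * (k - 2))
        vj = dij - vi
        negative |= vi < 0 or vj < 0
        new = TreeNode(children=[(nodes[i], float(vi)), (nodes[j], float(vj))])
        # distances from the new node to every other active node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(dnew)] = dnew
        D[: len(dnew), -1] = dnew
        D[-1, -1] = 0.0
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    ia, ib, ic = active
    dab, dac, dbc = D[ia, ib], D[ia, ic], D[ib, ic]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    negative |= min(va, vb, vc) < 0
    root = TreeNode(
        children=[
            (nodes[ia], float(va)),
            (nodes[ib], float(vb)),
            (nodes[ic], float(vc)),
        ]
    )
    if negative:
        warnings.warn(
            "NJ produced negative branch length(s); kept unclamped", stacklevel=2
        )
    if outgroup is not None:
        root = _root_on_leaf_edge(root, outgroup)
    return root


def _root_on_leaf_edge(tree: TreeNode, leaf: str) -> TreeNode:
    """Re-root an unrooted tree on the edge above the given leaf."""
    # build parent map
    parent: dict[int, tuple[TreeNode, float]] = {}

    def walk(node: TreeNode) -> None:
        for c, bl in node.children:
            parent[id(c)] = (node, bl)
            walk(c)

    walk(tree)
    target = next(
        (n for n in _iter_nodes(tree) if n.is_leaf and n.label == leaf), None
    )
    if target is None:
        raise ValueError(f"leaf {leaf!r} not found")
    par, bl = parent[id(target)]

    def hang(node: TreeNode, exclude: TreeNode | None) -> TreeNode:
        """Rebuild ``node`` as seen from its new parent, reversing edges."""
        kids = [(c, b) for c, b in node.children if c is not exclude]
        if id(node) in parent:
            p, pb = parent[id(node)]
            kids.append((hang(p, node), pb))
        if not kids:
            return node
        return TreeNode(children=kids)

    other = hang(par, target)
    return TreeNode(children=[(target, bl / 2.0), (other, bl / 2.0)])


def _iter_nodes(tree: TreeNode):
    yield tree
    for c, _ in tree.children:
        yield from _iter_nodes(c)


def region_tree(
    panel: HaplotypePanel,
    interval: GenomicInterval,
    samples: Sequence[str] | None = None,
    outgroup: str | None = None,
) -> TreeNode:
    """NJ tree induced by one genomic region.

    Used to check whether recipient individuals cluster with the donor
    inside candidate introgression regions.  Warns (but still builds) when
    the region holds fewer than 5 sites.
    """
    lo, hi = panel.site_range(interval.chrom, interval.start, interval.end)
    if hi - lo < 5:
        warnings.warn(
            f"region {interval} holds only {hi - lo} sites; tree may be unstable",
            stacklevel=2,
        )
    dm = p_distance_matrix(panel, interval=interval, samples=samples)
    return nj_tree(dm, outgroup=outgroup)


# --------------------------------------------------------------------- f3

@dataclass(frozen=True)
class F3Result:
    """f3(target; src1, src2) with block-jackknife uncertainty."""

    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    block_sizes: tuple[int, ...] = field(repr=False, default=())


def f3_test(
    panel: HaplotypePanel,
    target: str | Sequence[str],
    src1: str | Sequence[str],
    src2: str | Sequence[str],
    block_size_bp: int = 5_000_000,
) -> F3Result:
    """Three-population test: significantly negative f3 implies admixture.

    Per usable site (>= 2 called target haplotypes, >= 1 per source) with
    sample frequencies a (target), b, c:
    ``t = (a - b)(a - c) - a(1 - a) / (n_a - 1)``, the second term being
    the target finite-sample heterozygosity correction.  f3 is the mean of
    t; the SE comes from a delete-one jackknife over contiguous
    ``block_size_bp`` blocks (>= 10 non-empty blocks required).
    """
    t_set = {target} if isinstance(target, str) else set(target)
    s1_set = {src1} if isinstance(src1, str) else set(src1)
    s2_set = {src2} if isinstance(src2, str) else set(src2)
    if (t_set & s1_set) or (t_set & s2_set) or (s1_set & s2_set):
        raise ValueError("target and source populations must be disjoint")

    ht = panel.hap_indices(target)
    h1 = panel.hap_indices(src1)
    h2 = panel.hap_indices(src2)
    t_vals: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    for chrom in panel.chrom_names:
        mat = panel.alleles[chrom]
        pos = panel.positions[chrom]
        if not len(pos):
            continue
        na, da = _counts(mat[:, ht])
        n1, d1 = _counts(mat[:, h1])
        n2, d2 = _counts(mat[:, h2])
        ok = (na >= 2) & (n1 >= 1) & (n2 >= 1)
        a = da[ok] / na[ok]
        b = d1[ok] / n1[ok]
        c = d2[ok] / n2[ok]
        corr = a * (1.0 - a) / (na[ok] - 1.0)
        t_vals.append((a - b) * (a - c) - corr)
        blocks.append(
            np.char.add(chrom + ":", ((pos[ok] - 1) // block_size_bp).astype(str))
        )
    if not t_vals:
        raise ValueError("no usable sites for f3")
    t_all = np.concatenate(t_vals)
    block_all = np.concatenate(blocks)
    uniq, inv = np.unique(block_all, return_inverse=True)
    n_blocks = len(uniq)
    if n_blocks < 10:
        raise ValueError(
            f"only {n_blocks} non-empty jackknife blocks; need >= 10 "
            "(reduce block_size_bp or simulate a longer genome)"
        )
    total = t_all.sum()
    n = len(t_all)
    block_sums = np.bincount(inv, weights=t_all)
    block_n = np.bincount(inv)
    loo = (total - block_sums) / (n - block_n)  # delete-one estimates
    f3 = total / n
    loo_mean = loo.mean()
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo_mean) ** 2).sum()))
    if se == 0.0:
        raise ValueError("degenerate jackknife: zero variance across blocks")
    return F3Result(
        f3=float(f3),
        se=se,
        z=float(f3 / se),
        n_blocks=n_blocks,
        n_sites=n,
        block_sizes=tuple(int(x) for x in block_n),
    )


def _counts(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = mat >= 0
    return called.sum(axis=1).astype(float), (mat == 1).sum(axis=1).astype(float)
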
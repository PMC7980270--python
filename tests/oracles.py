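"""Independent brute-force oracles.

Everything here is deliberately written the slow, literal way — explicit
loops over haplotype pairs and direct textbook formulas — and stays
independent of the implementation paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def pi_sum_pair_loop(mat: np.ndarray) -> float:
    """Sum over sites of the mean pairwise difference among called pairs."""
    total = 0.0
    for row in np.asarray(mat):
        called = [a for a in row if a >= 0]
        n = len(called)
        if n < 2:
            continue
        diffs = 0
        pairs = 0
        for i in range(n):
            for j in range(i + 1, n):
                pairs += 1
                diffs += called[i] != called[j]
        total += diffs / pairs
    return total


def dxy_sum_pair_loop(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Sum over sites of the mean difference across all A×B called pairs."""
    total = 0.0
    for row_a, row_b in zip(np.asarray(mat_a), np.asarray(mat_b)):
        ca = [a for a in row_a if a >= 0]
        cb = [b for b in row_b if b >= 0]
        if not ca or not cb:
            continue
        diffs = sum(1 for a in ca for b in cb if a != b)
        total += diffs / (len(ca) * len(cb))
    return total


def tajima_d_direct(n: int, s: int, k_hat: float) -> float | None:
    """Tajima's D by direct evaluation of the 1989 constants a1..e2."""
    if s == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def tajima_from_matrix(mat: np.ndarray) -> tuple[int, int, float, float | None]:
    """(n, S, k_hat, D) from a hap matrix, pair-counting k_hat.

    Only sites fully called across all haplotypes are used, mirroring the
    constant-n assumption of the statistic.
    """
    mat = np.asarray(mat)
    n = mat.shape[1]
    full = [row for row in mat if (row >= 0).all()]
    s = 0
    k_sum = 0.0
    pairs = n * (n - 1) // 2
    for row in full:
        d = int((row == 1).sum())
        if 0 < d < n:
            s += 1
        diffs = 0
        for i in range(n):
            for j in range(i + 1, n):
                diffs += row[i] != row[j]
        k_sum += diffs / pairs
    return n, s, k_sum, tajima_d_direct(n, s, k_sum)


def wc_abc_direct(groups: list[list[tuple[int, int]]]):
    """Weir & Cockerham (a, b, c) for one site, scalar textbook coding.

    ``groups`` is a list (one per population) of diploid genotypes as
    (allele, allele) tuples; individuals with a missing allele are dropped.
    Returns None when any population has no called individual or the mean
    sample size is 1.
    """
    r = len(groups)
    n_i, p_i, h_i = [], [], []
    for g in groups:
        called = [(a, b) for a, b in g if a >= 0 and b >= 0]
        if not called:
            return None
        n = len(called)
        p = sum(a + b for a, b in called) / (2.0 * n)
        h = sum(1 for a, b in called if a != b) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_bar = sum(n_i) / r
    if n_bar <= 1:
        return None
    n_c = (r * n_bar - sum(n * n for n in n_i) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2 * n_bar - 1) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    return a, b, c


def confusion_hand_count(truth, called, windows):
    """Window confusion matrix by literal double loops."""
    tp = fp = fn = tn = 0
    for w in windows:
        in_truth = any(
            w.chrom == t.chrom and w.start < t.end and t.start < w.end for t in truth
        )
        in_call = any(
            w.chrom == c.chrom and w.start < c.end and c.start < w.end for c in called
        )
        if in_truth and in_call:
            tp += 1
        elif in_call:
            fp += 1
        elif in_truth:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


# ------------------------------------------------------------ random trees

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree: returns (labels, distance matrix, split set).

    Built by sequential random joins with positive branch lengths; the
    returned matrix holds exact leaf-to-leaf path lengths, hence is
    additive by construction.
    """
    labels = [chr(ord("A") + i) for i in range(n_taxa)]
    # node: (set of (leaf, depth)) pairs
    nodes = [[(lab, 0.0)] for lab in labels]
    splits: list[frozenset] = []
    D = np.zeros((n_taxa, n_taxa))
    idx = {lab: i for i, lab in enumerate(labels)}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bi = float(rng.uniform(0.5, 3.0))
        bj = float(rng.uniform(0.5, 3.0))
        a = [(lab, d + bi) for lab, d in nodes[i]]
        b = [(lab, d + bj) for lab, d in nodes[j]]
        for la, da in a:
            for lb, db in b:
                D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db
        merged = a + b
        side = frozenset(lab for lab, _ in merged)
        if 1 < len(side) < n_taxa - 1:
            splits.append(side)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    # final 3-way join
    center = []
    for k in range(3):
        bk = float(rng.uniform(0.5, 3.0))
        center.append([(lab, d + bk) for lab, d in nodes[k]])
    for x in range(3):
        for y in range(x + 1, 3):
            for la, da in center[x]:
                for lb, db in center[y]:
                    D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db
    full = frozenset(labels)
    split_set = set()
    for s in splits:
        split_set.add(s)
        split_set.add(full - s)
    return labels, D, split_set
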
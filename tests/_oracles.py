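"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: connected components
come from networkx, additive trees are built by direct random construction,
quartet topologies are resolved by the four-point condition, and the
pairwise aligner is an exhaustive affine-gap dynamic program written
independently of the package's profile aligner.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random binary tree over taxa t0..t{n-1} with branch lengths in
    [0.1, 2.0]; returns (newick string, patristic distance matrix)."""
    labels = [f"t{i}" for i in range(n)]

    def split(group):
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        bl_l = rng.uniform(0.1, 2.0)
        bl_r = rng.uniform(0.1, 2.0)
        return f"({split(left)}:{bl_l:.6f},{split(right)}:{bl_r:.6f})"

    order = list(rng.permutation(labels))
    newick = split(order) + ";"

    # patristic matrix by parsing the newick independently (simple stack parser)
    children: dict[int, list] = {}
    lengths: dict[int, float] = {}
    leaf_of: dict[int, str] = {}
    counter = [0]

    def parse(s: str, i: int) -> tuple[int, int]:
        node = counter[0]
        counter[0] += 1
        children[node] = []
        if s[i] == "(":
            i += 1
            while True:
                child, i = parse(s, i)
                children[node].append(child)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
        else:
            j = i
            while s[j] not in ":,();":
                j += 1
            leaf_of[node] = s[i:j]
            i = j
        if i < len(s) and s[i] == ":":
            j = i + 1
            while s[j] not in ",();":
                j += 1
            lengths[node] = float(s[i + 1 : j])
            i = j
        return node, i

    root, _ = parse(newick, 0)

    # distances from each leaf by DFS
    leaves = {node: lab for node, lab in leaf_of.items()}
    parent = {}
    for node, ch in children.items():
        for c in ch:
            parent[c] = node

    def path_to_root(node):
        out = []
        while node in parent:
            out.append(node)
            node = parent[node]
        return out

    D = np.zeros((n, n))
    index = {lab: k for k, lab in enumerate(labels)}
    leaf_nodes = list(leaves)
    for a, b in itertools.combinations(leaf_nodes, 2):
        pa, pb = path_to_root(a), path_to_root(b)
        common = set(pa) & set(pb)
        d = sum(lengths[x] for x in pa if x not in common)
        d += sum(lengths[x] for x in pb if x not in common)
        D[index[leaves[a]], index[leaves[b]]] = d
        D[index[leaves[b]], index[leaves[a]]] = d
    return newick, labels, D


def four_point_quartet(D: np.ndarray, i: int, j: int, k: int, l: int):
    """The quartet split minimizing the four-point sum: returns a frozenset
    pair like {frozenset({i,j}), frozenset({k,l})}."""
    sums = {
        (frozenset((i, j)), frozenset((k, l))): D[i, j] + D[k, l],
        (frozenset((i, k)), frozenset((j, l))): D[i, k] + D[j, l],
        (frozenset((i, l)), frozenset((j, k))): D[i, l] + D[j, k],
    }
    return frozenset(min(sums, key=sums.get))


def tree_quartets(tree, labels):
    """Quartet splits induced by tree bipartitions, as {(pair, pair): ...}."""
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
    all_leaves = frozenset(labels)
    sides = [s for n, s in sets.items() if 2 <= len(s) <= len(all_leaves) - 2]
    idx = {lab: i for i, lab in enumerate(labels)}
    out = {}
    for quad in itertools.combinations(labels, 4):
        split = None
        for side in sides:
            inside = [q for q in quad if q in side]
            if len(inside) == 2:
                outside = [q for q in quad if q not in side]
                split = frozenset(
                    (
                        frozenset(idx[x] for x in inside),
                        frozenset(idx[x] for x in outside),
                    )
                )
                break
        out[tuple(idx[q] for q in quad)] = split
    return out


def exhaustive_affine_nw(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal global alignment score under BLOSUM62 with affine gaps
    (first gap residue costs gap_open, each further one gap_extend),
    computed by an explicit three-state DP independent of the package."""
    na, nb = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (nb + 1) for _ in range(na + 1)]
    X = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in b
    Y = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, na + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, nb + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(na + 1):
        for j in range(nb + 1):
            if i > 0 and j > 0:
                s = _B62[a[i - 1]][b[j - 1]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            if i > 0:
                X[i][j] = max(X[i][j], M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            if j > 0:
                Y[i][j] = max(Y[i][j], M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
    return max(M[na][nb], X[na][nb], Y[na][nb])


def msa_pair_score(row_a: str, row_b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Score of an aligned pair of rows under the same affine scheme."""
    score = 0.0
    in_gap = False
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        if x == "-" or y == "-":
            score -= gap_extend if in_gap else gap_open
            in_gap = True
        else:
            score += _B62[x][y]
            in_gap = False
    return score
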
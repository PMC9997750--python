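"""Contact tracing of transposase families shared between symbiont genomes.

Insertion-sequence transposases shared by two or more co-resident symbionts
carry a phylogenetic signature of how they came to be shared: near-identical
copies across genomes indicate a recent horizontal transfer, while
per-genome clades joined as well-supported sisters indicate an ancient
common source (co-residence in a shared niche in the past). This module
finds shared transposase families, removes terminally degraded
(pseudogenized) copies, aligns and trims each family, infers bootstrapped
neighbor-joining trees, and classifies each cross-genome pair as
recent / ancient_sister / unresolved.

Tree inference here is distance-based (Poisson-corrected p-distances +
neighbor joining): the classification target is topological — sister clades
and near-zero cross-genome distances — so externally computed
maximum-likelihood trees in Newick can be dropped into
:func:`classify_sharing` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import GeneFeature, SequenceRecord, read_newick, write_newick

__all__ = [
    "MSA",
    "TEFamily",
    "TransferCall",
    "DegradationResult",
    "find_shared_te_families",
    "flag_degraded",
    "build_msa",
    "trim_alignment",
    "protein_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "classify_sharing",
    "midpoint_root",
    "trace_family",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_GAP = "-"

_B62 = substitution_matrices.load("BLOSUM62")
_S20 = np.array([[_B62[a][b] for b in _AA] for a in _AA], dtype=float)

_GAP_OPEN = 11.0
_GAP_EXTEND = 1.0


@dataclass
class MSA:
    """A multiple sequence alignment: parallel ids and equal-length rows."""

    ids: list
    rows: list

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(_GAP, "")

    def to_array(self) -> np.ndarray:
        return np.array([bytearray(r.encode()) for r in self.rows], dtype=np.uint8)

    def select_columns(self, cols) -> "MSA":
        arr = self.to_array()[:, cols]
        return MSA(list(self.ids), [bytes(row).decode() for row in arr])

    def subset(self, keep_ids) -> "MSA":
        keep = [i for i, x in enumerate(self.ids) if x in set(keep_ids)]
        return MSA([self.ids[i] for i in keep], [self.rows[i] for i in keep])


@dataclass
class TEFamily:
    """A transposase gene family with per-genome member sequences."""

    family_id: str
    members: list  # (genome_id, SequenceRecord)
    is_family_label: str | None = None

    @property
    def genomes(self) -> set:
        return {g for g, _ in self.members}

    @property
    def is_shared(self) -> bool:
        return len(self.genomes) >= 2


@dataclass
class TransferCall:
    family_id: str
    genome_pair: tuple
    classification: str  # recent | ancient_sister | unresolved
    min_cross_genome_patristic: float
    monophyletic: tuple  # (bool, bool) for the two genomes
    sister_support: float | None


@dataclass
class DegradationResult:
    kept: list
    removed: list
    testable: bool  # False when < 3 members survive (no tree built)


# ---------------------------------------------------------------------------
# family discovery


def find_shared_te_families(families, features, min_genomes: int = 2) -> list[TEFamily]:
    """Transposase families spanning at least ``min_genomes`` genomes.

    ``families`` are ortholog families (members as (protein_id, genome_id));
    members are restricted to proteins annotated as transposases in
    ``features``. Sequences are taken from the features' proteins.
    """
    feat = {f.feature_id: f for f in features}
    out = []
    for fam in families:
        te_members = []
        for pid, genome in fam.members:
            f = feat.get(pid)
            if f is None or f.feature_class != "transposase" or not f.protein:
                continue
            te_members.append((genome or f.genome_id, SequenceRecord(pid, f.product, f.protein)))
        if len({g for g, _ in te_members}) >= min_genomes:
            out.append(
                TEFamily(family_id=fam.family_id, members=sorted(te_members, key=lambda m: m[1].id))
            )
    return out


# ---------------------------------------------------------------------------
# progressive alignment


def _profile(rows: list) -> np.ndarray:
    """(n_cols, 20) residue frequency profile; gaps contribute zero mass."""
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, 20))
    for r in rows:
        for j, ch in enumerate(r):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                prof[j, idx] += 1.0
    return prof / len(rows)


def _profile_align(rows_a: list, rows_b: list) -> tuple[list, list]:
    """Global profile-profile alignment with affine gaps (BLOSUM62, 11/1).

    Returns the two row groups expanded to a common set of columns.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    na, nb = pa.shape[0], pb.shape[0]
    C = pa @ _S20 @ pb.T  # (na, nb) column-pair scores

    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    Ix = np.full((na + 1, nb + 1), NEG)  # gap columns in B (consume A)
    Iy = np.full((na + 1, nb + 1), NEG)  # gap columns in A (consume B)
    M[0, 0] = 0.0
    i_idx = np.arange(1, na + 1)
    j_idx = np.arange(1, nb + 1)
    Ix[1:, 0] = -_GAP_OPEN - (i_idx - 1) * _GAP_EXTEND
    Iy[0, 1:] = -_GAP_OPEN - (j_idx - 1) * _GAP_EXTEND

    jj = np.arange(nb + 1, dtype=float)
    for i in range(1, na + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = C[i - 1, :] + prev_best[:-1]
        Ix[i] = np.maximum(M[i - 1] - _GAP_OPEN, Ix[i - 1] - _GAP_EXTEND)
        # Iy within-row prefix-max: Iy[i,j] = max_{k<j} M[i,k] - open - (j-1-k)ext
        A = np.maximum(M[i], Iy[i]) + jj * _GAP_EXTEND  # Iy[i,0] boundary included
        P = np.maximum.accumulate(A)
        Iy[i, 1:] = P[:-1] - _GAP_OPEN - (jj[1:] - 1) * _GAP_EXTEND

    # traceback
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = na, nb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    eps = 1e-6
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i - 1])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j - 1])
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i - 1])
            for r in range(len(rows_b)):
                out_b[r].append(_GAP)
            if abs(Ix[i, j] - (M[i - 1, j] - _GAP_OPEN)) < eps:
                state = 0
            i -= 1
        elif state == 2 and j > 0:
            for r in range(len(rows_a)):
                out_a[r].append(_GAP)
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j - 1])
            if abs(Iy[i, j] - (M[i, j - 1] - _GAP_OPEN)) < eps:
                state = 0
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    return (
        ["".join(reversed(r)) for r in out_a],
        ["".join(reversed(r)) for r in out_b],
    )


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(0, len(a) - k + 1))}
    kb = {b[i : i + k] for i in range(max(0, len(b) - k + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _guide_order(names: list, seqs: list) -> list:
    """Merge schedule from an NJ guide tree on k-mer distances.

    Returns a list of (left_indices, right_indices) merges in postorder;
    falls back to sequential joining when the guide tree degenerates
    (e.g. all distances zero).
    """
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(seqs[i], seqs[j])
    labels = [f"t{i}" for i in range(n)]
    try:
        tree = nj_tree(labels, D)
        tree = midpoint_root(tree)
        merges = []

        def collect(node) -> list:
            children = node.child_nodes()
            if not children:
                return [int(node.taxon.label[1:])]
            groups = [collect(c) for c in children]
            if node.taxon is not None:  # rerooting can leave a taxon on the root
                groups.append([int(node.taxon.label[1:])])
            acc = groups[0]
            for g in groups[1:]:
                merges.append((list(acc), list(g)))
                acc = acc + g
            return acc

        total = collect(tree.seed_node)
        if sorted(total) != list(range(n)) or not merges:
            raise ValueError("degenerate guide tree")
        return merges
    except Exception:
        merges = []
        acc = [0]
        for i in range(1, n):
            merges.append((list(acc), [i]))
            acc.append(i)
        return merges


def build_msa(sequences: list) -> MSA:
    """Progressive multiple alignment of protein sequences.

    ``sequences`` is a list of SequenceRecord (or (id, seq) pairs). Pairwise
    k-mer distances give an NJ guide tree; profiles are merged bottom-up by
    global profile-profile alignment under BLOSUM62 with affine gap
    penalties (open 11, extend 1). Every input residue appears in the
    output; the alignment has at least as many columns as the longest
    input.
    """
    seqs = []
    names = []
    for s in sequences:
        if isinstance(s, SequenceRecord):
            names.append(s.id)
            seqs.append(s.residues.upper())
        else:
            names.append(s[0])
            seqs.append(s[1].upper())
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences to align")

    merges = _guide_order(names, seqs)
    aligned: dict[int, list] = {i: [seqs[i]] for i in range(len(seqs))}
    groups: dict[int, list] = {i: [i] for i in range(len(seqs))}
    for left, right in merges:
        rows_a = []
        for i in left:
            rows_a = aligned[left[0]]
            break
        rows_b = aligned[right[0]]
        new_a, new_b = _profile_align(rows_a, rows_b)
        members = groups[left[0]] + groups[right[0]]
        rows = new_a + new_b
        for idx in members:
            aligned[idx] = rows
            groups[idx] = members
    final_members = groups[0]
    rows = aligned[0]
    order = np.argsort(final_members)
    return MSA([names[final_members[i]] for i in order], [rows[i] for i in order])


# ---------------------------------------------------------------------------
# degradation filter


def flag_degraded(
    family: TEFamily,
    msa: MSA,
    max_terminal_missing: float = 0.15,
    min_identity: float = 0.90,
) -> DegradationResult:
    """Remove terminally truncated (pseudogenized) copies.

    A member is removed iff (a) it is missing at least
    ``max_terminal_missing`` of the consensus-span columns contiguously at
    either alignment terminus, and (b) over its aligned span it is at least
    ``min_identity`` identical to its nearest neighbor — i.e. the copy is
    truncated, not merely divergent. Families reduced below 3 members are
    marked untestable (no tree is built for them).
    """
    arr = msa.to_array()
    gap = arr == ord(_GAP)
    span = np.flatnonzero((~gap).mean(axis=0) >= 0.5)  # consensus span
    if span.size == 0:
        span = np.arange(msa.n_cols)
    removed = []
    for i, rid in enumerate(msa.ids):
        row_gap = gap[i][span]
        lead = 0
        while lead < row_gap.size and row_gap[lead]:
            lead += 1
        trail = 0
        while trail < row_gap.size and row_gap[row_gap.size - 1 - trail]:
            trail += 1
        frac = max(lead, trail) / row_gap.size
        if frac < max_terminal_missing:
            continue
        # nearest-neighbor identity over this member's aligned span
        best = 0.0
        for j in range(msa.n_rows):
            if j == i:
                continue
            both = ~gap[i] & ~gap[j]
            n = int(both.sum())
            if n == 0:
                continue
            ident = float((arr[i][both] == arr[j][both]).sum()) / n
            best = max(best, ident)
        if best >= min_identity:
            removed.append(rid)
    kept = [x for x in msa.ids if x not in set(removed)]
    return DegradationResult(kept=kept, removed=removed, testable=len(kept) >= 3)


# ---------------------------------------------------------------------------
# trimming and distances


def trim_alignment(msa: MSA, max_gap_fraction: float = 0.5, max_entropy: float = 0.6) -> MSA:
    """Remove gappy and high-entropy columns (BMGE-style).

    A column is removed when its gap fraction exceeds ``max_gap_fraction``
    or its Shannon entropy over residues, normalized to base 20, exceeds
    ``max_entropy``. Column order is preserved; trimming is idempotent.
    """
    if msa.n_rows < 2:
        raise ValueError("need >= 2 rows")
    arr = msa.to_array()
    gap = arr == ord(_GAP)
    gap_frac = gap.mean(axis=0)
    keep = []
    for j in range(msa.n_cols):
        if gap_frac[j] > max_gap_fraction:
            continue
        col = arr[~gap[:, j], j]
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        entropy = float(-(p * np.log(p)).sum() / np.log(20.0))
        if entropy > max_entropy:
            continue
        keep.append(j)
    if not keep:
        raise ValueError(
            "all columns removed by trimming; relax max_gap_fraction/max_entropy"
        )
    return msa.select_columns(keep)


def protein_distance_matrix(msa: MSA, min_overlap: int = 30) -> tuple[list, np.ndarray]:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the proportion of mismatches over mutually ungapped columns; pairs
    overlapping in fewer than ``min_overlap`` columns, or with p >= 1, are
    errors.
    """
    arr = msa.to_array()
    gap = arr == ord(_GAP)
    n = msa.n_rows
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            overlap = int(both.sum())
            if overlap < min_overlap:
                raise ValueError(
                    f"pair ({msa.ids[i]}, {msa.ids[j]}) overlaps in only "
                    f"{overlap} columns (< {min_overlap})"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / overlap
            if p >= 1.0:
                raise ValueError(
                    f"pair ({msa.ids[i]}, {msa.ids[j]}): p-distance >= 1, "
                    "Poisson correction undefined"
                )
            D[i, j] = D[j, i] = -np.log(1.0 - p)
    return list(msa.ids), D


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(labels: list, D: np.ndarray) -> dendropy.Tree:
    """Neighbor joining on a symmetric zero-diagonal distance matrix.

    Ties in the Q criterion are broken toward the lexicographically
    smallest label pair; negative branch lengths are clamped to zero with
    the deficit shifted to the sister branch. Returns an unrooted dendropy
    tree whose patristic distances reproduce the input exactly when the
    matrix is additive.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if n < 3:
        raise ValueError("need >= 3 taxa for neighbor joining")

    nodes = [(str(lab), str(lab)) for lab in labels]  # (newick, min label)
    D = D.copy()

    def _clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] <= qmin + 1e-9:
                    key = tuple(sorted((nodes[i][1], nodes[j][1])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp(li, lj)
        newick = f"({nodes[i][0]}:{li:.12g},{nodes[j][0]}:{lj:.12g})"
        minlab = min(nodes[i][1], nodes[j][1])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = du[keep]
        D_new[:-1, -1] = du[keep]
        nodes = [nodes[k] for k in keep] + [(newick, minlab)]
        D = D_new

    # closed-form three-point join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    newick = (
        f"({nodes[0][0]}:{l0:.12g},{nodes[1][0]}:{l1:.12g},{nodes[2][0]}:{l2:.12g});"
    )
    return read_newick(newick)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-rooted copy of a tree (display convenience only)."""
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)
    return t


# ---------------------------------------------------------------------------
# bootstrap


def _leafsets(tree: dendropy.Tree) -> dict:
    """Map each non-root node to the frozenset of leaf labels below it."""
    sets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset([node.taxon.label])
        else:
            acc = frozenset()
            for c in node.child_nodes():
                acc = acc | sets[c]
            sets[node] = acc
    return sets


def _internal_bipartitions(tree: dendropy.Tree) -> dict:
    """Normalized internal bipartitions: frozenset(side w/o reference leaf) -> node."""
    sets = _leafsets(tree)
    all_leaves = sets[tree.seed_node]
    ref = min(all_leaves)
    out = {}
    for node, side in sets.items():
        if node is tree.seed_node or node.parent_node is tree.seed_node and len(tree.seed_node.child_nodes()) <= 2:
            continue
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def bootstrap_support(
    msa: MSA,
    n_replicates: int = 100,
    seed: int = 0,
    min_overlap: int = 30,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate alignment yields a distance matrix and NJ tree, and the
    support of an internal branch of the full-alignment tree is the
    percentage of replicates containing its bipartition. Supports are
    stored on ``node.support`` and as internal node labels.
    """
    if n_replicates < 10:
        raise ValueError("n_replicates must be >= 10")
    labels, D = protein_distance_matrix(msa, min_overlap=min_overlap)
    tree = nj_tree(labels, D)
    bips = _internal_bipartitions(tree)
    counts = {side: 0 for side in bips}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep = msa.select_columns(cols)
        try:
            rlabels, rD = protein_distance_matrix(rep, min_overlap=1)
            rtree = nj_tree(rlabels, rD)
        except ValueError:
            continue
        rep_bips = set(_internal_bipartitions(rtree))
        for side in counts:
            if side in rep_bips:
                counts[side] += 1
    for side, node in bips.items():
        support = 100.0 * counts[side] / n_replicates
        node.support = support
        node.label = f"{support:.4g}"
    return tree


# ---------------------------------------------------------------------------
# classification


def _edge_support(node) -> float:
    sup = getattr(node, "support", None)
    if sup is not None:
        return float(sup)
    if node.label:
        try:
            return float(node.label)
        except ValueError:
            pass
    return 100.0  # terminal or unannotated branches count as present


def classify_sharing(
    tree: dendropy.Tree,
    genome_of: dict,
    recent_threshold: float = 0.02,
    support_threshold: float = 95.0,
) -> list[TransferCall]:
    """Classify cross-genome TE sharing for every genome pair on the tree.

    recent: minimum patristic distance between members of the two genomes
    is at most ``recent_threshold`` substitutions/site (near-identical
    copies on both sides of a genome boundary).
    ancient_sister: each genome's members form a clade (singletons allowed)
    and the two clades are joined as sisters with bootstrap support of the
    joining branch >= ``support_threshold``.
    unresolved: anything else.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    leaves = [t.label for t in tree.taxon_namespace if t.label in genome_of]
    genomes = sorted({genome_of[x] for x in leaves})
    members = {g: sorted(x for x in leaves if genome_of[x] == g) for g in genomes}

    sets = _leafsets(tree)
    all_leaves = sets[tree.seed_node]
    sides = {}
    for node, side in sets.items():
        if node is tree.seed_node:
            continue
        sides.setdefault(side, node)
        sides.setdefault(all_leaves - side, node)

    def support_for_bipartition(side: frozenset) -> float | None:
        """Support of the edge realizing this bipartition; None when the
        only realization is a terminal edge seen from its complement (no
        internal joining branch exists)."""
        node = sides.get(side)
        if node is None:
            return None
        if node.is_leaf() and sets[node] != side:
            return None
        return _edge_support(node)

    calls = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            gx, gy = genomes[i], genomes[j]
            X, Y = frozenset(members[gx]), frozenset(members[gy])
            dmin = min(
                pdm.patristic_distance(taxa[a], taxa[b]) for a in X for b in Y
            )
            mono_x = X in sides
            mono_y = Y in sides
            if dmin <= recent_threshold:
                cls, support = "recent", None
            else:
                support = None
                sisters = False
                if mono_x and mono_y:
                    union = X | Y
                    if union == all_leaves:
                        # only these two genomes on the tree: the joining
                        # branch is the X|Y bipartition itself
                        sisters = True
                        support = support_for_bipartition(X)
                        if support is None:
                            support = support_for_bipartition(Y)
                        if support is None:  # two-leaf family
                            support = 100.0
                    elif union in sides:
                        sisters = True
                        support = support_for_bipartition(union)
                        if support is None:
                            # joining edge is terminal (single outgroup):
                            # fall back to the weaker of the clade supports
                            sx = support_for_bipartition(X) if len(X) > 1 else 100.0
                            sy = support_for_bipartition(Y) if len(Y) > 1 else 100.0
                            support = min(sx or 0.0, sy or 0.0)
                cls = (
                    "ancient_sister"
                    if sisters and support is not None and support >= support_threshold
                    else "unresolved"
                )
            calls.append(
                TransferCall(
                    family_id="",
                    genome_pair=(gx, gy),
                    classification=cls,
                    min_cross_genome_patristic=float(dmin),
                    monophyletic=(mono_x, mono_y),
                    sister_support=support,
                )
            )
    return calls


def trace_family(
    family: TEFamily,
    n_bootstrap: int = 100,
    seed: int = 0,
    recent_threshold: float = 0.02,
    support_threshold: float = 95.0,
    max_gap_fraction: float = 0.5,
    max_entropy: float = 0.6,
) -> tuple[MSA | None, dendropy.Tree | None, list]:
    """Full per-family pipeline: align, degrade-filter, trim, tree, classify.

    Returns (trimmed msa, tree, calls); (None, None, []) for untestable
    families (< 3 members after the degradation filter, or < 2 genomes).
    """
    if len(family.members) < 3:
        return None, None, []
    msa = build_msa([rec for _, rec in family.members])
    deg = flag_degraded(family, msa)
    if not deg.testable:
        return None, None, []
    genome_of = {rec.id: g for g, rec in family.members}
    msa = msa.subset(deg.kept)
    if len({genome_of[x] for x in msa.ids}) < 2:
        return None, None, []
    trimmed = trim_alignment(msa, max_gap_fraction=max_gap_fraction, max_entropy=max_entropy)
    tree = bootstrap_support(trimmed, n_replicates=n_bootstrap, seed=seed)
    calls = classify_sharing(
        tree,
        genome_of,
        recent_threshold=recent_threshold,
        support_threshold=support_threshold,
    )
    for c in calls:
        c.family_id = family.family_id
    return trimmed, tree, calls
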
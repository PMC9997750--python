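"""Ortholog families, core/accessory partition, and ANI/AAI delimitation.

Protein families are connected components of an all-against-all local
alignment graph thresholded on e-value, identity and overlap (single
linkage, as in SiLiX-style de novo clustering). The accessory genome of a
comparison is the set of families private to one genome after removing
proteins shorter than 100 aa (ghost CDSs and transposase remnants).
Species delimitation uses fragment-based average nucleotide identity
(1020-nt fragments, 30% identity over 70% alignable, Goris-style) and
reciprocal-best-hit average amino-acid identity, both against a >= 95%
same-species convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

__all__ = [
    "SimilarityEdge",
    "OrthologFamily",
    "PangenomePartition",
    "IdentityResult",
    "all_vs_all_protein_similarity",
    "cluster_families",
    "partition_pangenome",
    "summarize_accessory_cog",
    "ani",
    "aai",
    "species_call",
]

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX")


@dataclass
class SimilarityEdge:
    """One undirected similarity edge between two proteins."""

    query_id: str
    subject_id: str
    identity: float  # % identical over alignment columns
    query_coverage: float  # % of query residues aligned
    subject_coverage: float
    score: float
    evalue_proxy: float


@dataclass
class OrthologFamily:
    """A gene family: proteins joined by single-linkage clustering."""

    family_id: str
    members: list  # (protein_id, genome_id)

    @property
    def member_ids(self) -> list:
        return [m[0] for m in self.members]

    @property
    def genomes_present(self) -> set:
        return {m[1] for m in self.members}


@dataclass
class PangenomePartition:
    """Shared vs per-genome accessory families after the length filter."""

    shared_families: set
    accessory: dict  # genome_id -> set of family ids
    surviving_members: dict  # family_id -> [(protein_id, genome_id)]


@dataclass
class IdentityResult:
    genome_pair: tuple
    ani: float | None = None
    ani_fragments_used: int = 0
    aai: float | None = None
    aai_orthologs_used: int = 0
    same_species_call: bool | None = None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _validate_protein(rec: SequenceRecord) -> None:
    bad = set(rec.residues) - _VALID_AA
    if bad:
        raise ValueError(
            f"protein {rec.id!r} contains non-amino-acid characters: {sorted(bad)}"
        )


def _kmer_set(seq: str, k: int = 5) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_stats(aln, a: str, b: str) -> tuple[float, float, float]:
    """(identity %, query coverage %, subject coverage %) of a local alignment."""
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_a = 0
    aligned_b = 0
    columns = 0
    prev = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev is not None:
            columns += (a0 - prev[0]) + (b0 - prev[1])  # gap columns
        seg_a = a[a0:a1]
        seg_b = b[b0:b1]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
        aligned_a += a1 - a0
        aligned_b += b1 - b0
        columns += a1 - a0
        prev = (a1, b1)
    if columns == 0:
        return 0.0, 0.0, 0.0
    return (
        100.0 * matches / columns,
        100.0 * aligned_a / len(a),
        100.0 * aligned_b / len(b),
    )


def _pair_edge(
    rec_a: SequenceRecord,
    rec_b: SequenceRecord,
    aligner: Align.PairwiseAligner,
    db_residues: int,
    max_evalue: float,
) -> SimilarityEdge | None:
    score = aligner.score(rec_a.residues, rec_b.residues)
    if score <= 0:
        return None
    evalue = _KA_K * len(rec_a.residues) * db_residues * math.exp(-_KA_LAMBDA * score)
    if evalue > max_evalue:
        return None
    aln = aligner.align(rec_a.residues, rec_b.residues)[0]
    identity, cov_a, cov_b = _alignment_stats(aln, rec_a.residues, rec_b.residues)
    return SimilarityEdge(
        query_id=rec_a.id,
        subject_id=rec_b.id,
        identity=identity,
        query_coverage=cov_a,
        subject_coverage=cov_b,
        score=float(score),
        evalue_proxy=float(evalue),
    )


def all_vs_all_protein_similarity(
    proteins: list[SequenceRecord],
    max_evalue: float = 10.0,
    prescreen_kmer: int = 5,
    max_proteins: int = 5000,
    allow_large: bool = False,
) -> list[SimilarityEdge]:
    """All-against-all local protein alignment (BLOSUM62, affine 11/1).

    One undirected edge per protein pair with a positive-scoring local
    alignment whose Karlin-Altschul e-value (database size = total residues)
    is at most ``max_evalue``. Pairs sharing no ``prescreen_kmer``-mer are
    skipped, which prunes the quadratic alignment cost for unrelated pairs
    without touching pairs that could pass any clustering threshold.
    """
    if len(proteins) < 2:
        raise ValueError("need >= 2 proteins")
    if len(proteins) > max_proteins and not allow_large:
        raise ValueError(
            f"{len(proteins)} proteins exceeds the all-vs-all guard "
            f"({max_proteins}); pass allow_large=True to override"
        )
    for rec in proteins:
        _validate_protein(rec)
    aligner = _make_aligner()
    db_residues = sum(len(r.residues) for r in proteins)
    kmers = [_kmer_set(r.residues, prescreen_kmer) for r in proteins]
    edges: list[SimilarityEdge] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if not (kmers[i] & kmers[j]):
                continue
            edge = _pair_edge(proteins[i], proteins[j], aligner, db_residues, max_evalue)
            if edge is not None:
                edges.append(edge)
    return edges


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_families(
    edges: list[SimilarityEdge],
    protein_ids: list[str],
    genome_of: dict | None = None,
    evalue_cutoff: float = 1e-3,
    min_identity: float = 35.0,
    min_overlap: float = 80.0,
) -> list[OrthologFamily]:
    """Single-linkage ortholog families: connected components of the edge
    graph after thresholding on e-value, identity, and overlap (the smaller
    of the two coverages). Isolated proteins become singleton families.
    Family ids are the lexicographically smallest member id; output order
    is deterministic and independent of edge order.
    """
    genome_of = genome_of or {}
    uf = _UnionFind(protein_ids)
    known = set(protein_ids)
    for e in edges:
        if e.query_id not in known or e.subject_id not in known:
            raise ValueError(f"edge references unknown protein: {e.query_id}/{e.subject_id}")
        if (
            e.evalue_proxy < evalue_cutoff
            and e.identity >= min_identity
            and min(e.query_coverage, e.subject_coverage) >= min_overlap
        ):
            uf.union(e.query_id, e.subject_id)
    groups: dict[str, list[str]] = {}
    for pid in protein_ids:
        groups.setdefault(uf.find(pid), []).append(pid)
    families = []
    for members in groups.values():
        members = sorted(members)
        families.append(
            OrthologFamily(
                family_id=members[0],
                members=[(m, genome_of.get(m, "")) for m in members],
            )
        )
    families.sort(key=lambda f: f.family_id)
    return families


def partition_pangenome(
    families: list[OrthologFamily],
    protein_lengths: dict,
    genomes: set | list,
    min_protein_length: int = 100,
) -> PangenomePartition:
    """Partition families into shared vs per-genome accessory content.

    Proteins shorter than ``min_protein_length`` aa (ghost CDSs, transposase
    remnants) are removed first; a family is accessory to genome g iff all
    remaining members belong to g, shared iff members span >= 2 genomes.
    Families with no surviving member drop out entirely.
    """
    genomes = set(genomes)
    shared: set = set()
    accessory: dict = {g: set() for g in genomes}
    surviving: dict = {}
    remaining_per_genome: dict = {g: 0 for g in genomes}
    for fam in families:
        keep = [
            (pid, g)
            for pid, g in fam.members
            if protein_lengths.get(pid, 0) >= min_protein_length
        ]
        if not keep:
            continue
        surviving[fam.family_id] = keep
        present = {g for _, g in keep}
        for _, g in keep:
            if g in remaining_per_genome:
                remaining_per_genome[g] += 1
        if len(present) >= 2:
            shared.add(fam.family_id)
        else:
            (only,) = present
            if only in accessory:
                accessory[only].add(fam.family_id)
    for g, n in remaining_per_genome.items():
        if n == 0:
            warnings.warn(f"genome {g} has no proteins left after the length filter")
    return PangenomePartition(
        shared_families=shared, accessory=accessory, surviving_members=surviving
    )


def summarize_accessory_cog(
    partition: PangenomePartition,
    annotations: dict,
    pool_threshold: int = 2,
) -> dict:
    """Per-genome COG-category counts of accessory families, with pooling.

    A family's category is the most common unambiguous single-letter COG
    annotation among its members; multi-letter (ambiguous) annotations are
    ignored; families with no unambiguous annotation count as
    "de novo OGs". Categories with counts <= ``pool_threshold`` are pooled
    into "Other categories".
    """
    out: dict = {}
    for genome, fams in partition.accessory.items():
        counts: dict[str, int] = {}
        de_novo = 0
        for fam in sorted(fams):
            cats = [
                annotations[pid]
                for pid, _ in partition.surviving_members.get(fam, [])
                if pid in annotations
                and len(annotations[pid]) == 1
                and annotations[pid].isalpha()
            ]
            if not cats:
                de_novo += 1
                continue
            vals, freq = np.unique(cats, return_counts=True)
            counts[vals[np.argmax(freq)]] = counts.get(vals[np.argmax(freq)], 0) + 1
        pooled: dict[str, int] = {}
        other = 0
        for cat in sorted(counts):
            if counts[cat] <= pool_threshold:
                other += counts[cat]
            else:
                pooled[cat] = counts[cat]
        if other:
            pooled["Other categories"] = other
        if de_novo:
            pooled["de novo OGs"] = de_novo
        out[genome] = pooled
    return out


# ---------------------------------------------------------------------------
# ANI / AAI

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """(identity %, alignment columns) from an edlib extended cigar."""
    matches = 0
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return (100.0 * matches / columns if columns else 0.0), columns


def _one_way_ani(
    a: str,
    b: str,
    b_kmers: set,
    fragment_length: int,
    min_identity: float,
    min_aligned_fraction: float,
    seed_size: int,
) -> tuple[float | None, int]:
    identities = []
    n_frags = len(a) // fragment_length
    for i in range(n_frags):
        frag = a[i * fragment_length : (i + 1) * fragment_length]
        candidates = []
        for query in (frag, _revcomp(frag)):
            seeded = any(
                query[j : j + seed_size] in b_kmers
                for j in range(0, len(query) - seed_size + 1)
            )
            if not seeded:
                continue
            res = edlib.align(query, b, mode="HW", task="path")
            if res["editDistance"] < 0 or not res.get("cigar"):
                continue
            identity, _ = _cigar_identity(res["cigar"])
            candidates.append(identity)
        if not candidates:
            continue
        identity = max(candidates)
        aligned_fraction = 100.0  # infix alignment places the full fragment
        if identity >= min_identity and aligned_fraction >= min_aligned_fraction:
            identities.append(identity)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def ani(
    genome_a: SequenceRecord,
    genome_b: SequenceRecord,
    fragment_length: int = 1020,
    min_identity: float = 30.0,
    min_aligned_fraction: float = 70.0,
    seed_size: int = 20,
) -> IdentityResult:
    """Fragment-based average nucleotide identity (Goris-style).

    Genome A is cut into consecutive ``fragment_length``-nt fragments; each
    fragment sharing an exact ``seed_size``-mer with B (either strand) is
    placed by infix alignment and contributes its percent identity if it
    passes the identity/alignable-fraction cutoffs. The reported ANI is the
    mean of the two one-way values; it is undefined (None) when no fragment
    passes in either direction.
    """
    a, b = genome_a.residues.upper(), genome_b.residues.upper()
    if len(a) < fragment_length or len(b) < fragment_length:
        raise ValueError("genome shorter than one ANI fragment")

    def kmers(seq: str) -> set:
        return {seq[i : i + seed_size] for i in range(len(seq) - seed_size + 1)}

    ab, n_ab = _one_way_ani(
        a, b, kmers(b), fragment_length, min_identity, min_aligned_fraction, seed_size
    )
    ba, n_ba = _one_way_ani(
        b, a, kmers(a), fragment_length, min_identity, min_aligned_fraction, seed_size
    )
    vals = [v for v in (ab, ba) if v is not None]
    return IdentityResult(
        genome_pair=(genome_a.id, genome_b.id),
        ani=float(np.mean(vals)) if vals else None,
        ani_fragments_used=n_ab + n_ba,
    )


def aai(
    proteome_a: list[SequenceRecord],
    proteome_b: list[SequenceRecord],
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    min_orthologs: int = 10,
    prescreen_kmer: int = 5,
) -> IdentityResult:
    """Reciprocal-best-hit average amino-acid identity.

    Best hits by alignment score in both directions; an RBH pair
    contributes if it passes the identity and coverage cutoffs. AAI is the
    unweighted mean identity over contributing pairs, undefined (None) with
    fewer than ``min_orthologs`` of them.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    for rec in list(proteome_a) + list(proteome_b):
        _validate_protein(rec)
    aligner = _make_aligner()
    db_residues = sum(len(r.residues) for r in proteome_b)
    kmers_a = [_kmer_set(r.residues, prescreen_kmer) for r in proteome_a]
    kmers_b = [_kmer_set(r.residues, prescreen_kmer) for r in proteome_b]

    pair_stats: dict[tuple[int, int], tuple[float, float, float, float]] = {}
    for i, ra in enumerate(proteome_a):
        for j, rb in enumerate(proteome_b):
            if not (kmers_a[i] & kmers_b[j]):
                continue
            score = aligner.score(ra.residues, rb.residues)
            if score <= 0:
                continue
            pair_stats[(i, j)] = (float(score), np.nan, np.nan, np.nan)
    if not pair_stats:
        return IdentityResult(genome_pair=("", ""), aai=None, aai_orthologs_used=0)

    best_a: dict[int, tuple[float, int]] = {}
    best_b: dict[int, tuple[float, int]] = {}
    for (i, j), (score, *_rest) in pair_stats.items():
        if i not in best_a or score > best_a[i][0]:
            best_a[i] = (score, j)
        if j not in best_b or score > best_b[j][0]:
            best_b[j] = (score, i)

    identities = []
    for i, (_, j) in sorted(best_a.items()):
        if best_b.get(j, (None, None))[1] != i:
            continue
        ra, rb = proteome_a[i], proteome_b[j]
        aln = aligner.align(ra.residues, rb.residues)[0]
        identity, cov_a, cov_b = _alignment_stats(aln, ra.residues, rb.residues)
        if identity >= min_identity and min(cov_a, cov_b) >= min_coverage:
            identities.append(identity)
    aai_value = float(np.mean(identities)) if len(identities) >= min_orthologs else None
    return IdentityResult(
        genome_pair=("", ""), aai=aai_value, aai_orthologs_used=len(identities)
    )


def species_call(
    identity: IdentityResult, ani_threshold: float = 95.0, aai_threshold: float = 95.0
) -> bool:
    """Same-species call: every defined metric must reach its threshold.

    With ANI and AAI both undefined the call cannot be made (error). The
    strict-AND rule is a convention of this package; calls near the
    thresholds should be inspected alongside the raw values.
    """
    if identity.ani is None and identity.aai is None:
        raise ValueError("species call impossible: both ANI and AAI undefined")
    ok = True
    if identity.ani is not None:
        ok = ok and identity.ani >= ani_threshold
    if identity.aai is not None:
        ok = ok and identity.aai >= aai_threshold
    return ok
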
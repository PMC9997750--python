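"""Synthetic multi-symbiont sequencing study generator.

Emulates the data layout of a census of maternally transmitted bacterial
endosymbionts co-infecting one arthropod host: several symbiont genomes with
core/accessory gene-family structure (including a near-identical "confounded"
strain pair whose shared genes attract cross-mapped reads), per-sample
per-base depth tracks driven by true per-host-cell symbiont loads, shared
transposase families with vertical, recently transferred, or anciently
diverged histories, and variant tables with fixed and polymorphic calls
inside and outside excluded feature classes.

Depth is simulated directly as per-base Poisson counts rather than via read
simulation and mapping: the statistic under study (median symbiont depth
normalized by mean host single-copy-marker depth) operates downstream of
mapping, and cross-mapping between the two near-identical strains is modeled
explicitly as additive depth on their shared genes.

Every generator draws from child streams of one root seed, so a fixed
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DepthTrack, GeneFeature, SequenceRecord

__all__ = [
    "SimulationConfig",
    "TEHistorySpec",
    "VariantSpec",
    "TruthTable",
    "TESimResult",
    "simulate_genomes",
    "simulate_depth",
    "simulate_te_families",
    "simulate_variant_table",
    "simulate_pileup",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# standard codon table inverted, stops excluded
_CODONS: dict[str, list[str]] = {}
_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
for _c, _a in _TABLE.items():
    _CODONS.setdefault(_a, []).append(_c)


def _rng(seed: int, *key: str) -> np.random.Generator:
    """Deterministic child stream of the root seed, named by string key."""
    spawn = tuple(zlib.crc32(k.encode()) for k in key)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn))


@dataclass
class TEHistorySpec:
    """Histories to simulate for shared-transposase families.

    ``divergence`` is the total expected substitutions/site separating the
    two per-genome clades of an "ancient" family; recently transferred
    copies differ by at most one substitution. ``degradation_rate`` is the
    fraction of copies per family truncated at the 5' or 3' terminus by
    20-40% of their length, emulating pseudogenized IS copies.
    """

    n_recent: int = 3
    n_ancient: int = 3
    n_vertical: int = 2
    divergence: float = 0.3
    te_length: int = 300
    degradation_rate: float = 0.0
    copies_per_genome: int = 3
    within_clade_divergence: float = 0.005

    @property
    def n_families(self) -> int:
        return self.n_recent + self.n_ancient + self.n_vertical

    def validate(self) -> None:
        if self.te_length < 50:
            raise ValueError("te_length < 50 aa: too short to classify")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if not 0 <= self.degradation_rate <= 1:
            raise ValueError("degradation_rate must lie in [0, 1]")


@dataclass
class VariantSpec:
    """Per-(sample, genome) composition of the simulated variant table."""

    n_fixed_outside: int = 20
    n_fixed_excluded: int = 10
    n_polymorphic: int = 15
    type_weights: dict = field(
        default_factory=lambda: {
            "SNP": 0.7,
            "insertion": 0.1,
            "deletion": 0.1,
            "substitution": 0.1,
        }
    )


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests, keyed like the outputs."""

    true_loads: dict
    family_membership: dict
    te_event_labels: dict
    true_variant_density: dict
    family_genomes: dict
    pair_shared_features: dict
    pair_accessory_features: dict
    ghost_features: set
    genome_lengths: dict


@dataclass
class TESimResult:
    families: dict  # family_id -> list of (genome_id, SequenceRecord)
    labels: dict  # family_id -> {recent, ancient, none}
    degraded: set  # ids of truncated copies


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the shape of the motivating field study: a handful of
    host individuals, four co-infecting symbionts of which the first two are
    a near-identical strain pair sharing most of their genes, per-host-cell
    loads spanning roughly 0.1-5, a diploid host, and a single-copy host
    marker sequenced to ~30x mean depth. ``host_marker_depth_mean`` is the
    observed mean depth on the marker; a symbiont at per-host-cell load L is
    covered at L x marker x ploidy reads/base.
    """

    seed: int = 0
    n_symbionts: int = 4
    genome_length: int = 50_000
    n_gene_families: int = 120
    core_fraction: float = 0.3
    ghost_cds_fraction: float = 0.05
    host_marker_depth_mean: float = 30.0
    symbiont_loads: dict | None = None  # sample -> symbiont -> load/host cell
    ploidy: int = 2
    shared_fraction_confounded_pair: float = 0.8
    n_samples: int = 6
    infection_probability: float = 0.75
    n_transposases_per_genome: int = 4
    n_introns_per_genome: int = 2
    mean_protein_length: int = 230
    spacer_length: int = 100
    host_marker_length: int = 1200
    te_history: TEHistorySpec = field(default_factory=TEHistorySpec)
    variant_spec: VariantSpec = field(default_factory=VariantSpec)

    def __post_init__(self) -> None:
        for name in ("core_fraction", "ghost_cds_fraction",
                     "shared_fraction_confounded_pair"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.host_marker_depth_mean <= 0:
            raise ValueError("host_marker_depth_mean must be > 0")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        self.te_history.validate()
        if self.symbiont_loads is None:
            self.symbiont_loads = self._default_loads()

    @property
    def symbionts(self) -> list[str]:
        return [f"symb{i + 1:02d}" for i in range(self.n_symbionts)]

    @property
    def confounded_pair(self) -> tuple[str, str]:
        return (self.symbionts[0], self.symbionts[1])

    @property
    def samples(self) -> list[str]:
        return sorted(self.symbiont_loads)

    def _default_loads(self) -> dict:
        rng = _rng(self.seed, "loads")
        loads: dict = {}
        for i in range(self.n_samples):
            sample = f"S{i + 1:02d}"
            loads[sample] = {}
            for s in self.symbionts:
                infected = rng.random() < self.infection_probability
                loads[sample][s] = (
                    float(np.round(rng.uniform(0.1, 5.0), 3)) if infected else 0.0
                )
        return loads

    def host_marker_feature(self) -> GeneFeature:
        return GeneFeature(
            feature_id="host_marker_gene",
            genome_id="host",
            contig_id="host_marker",
            start=1,
            end=self.host_marker_length,
            strand="+",
            feature_class="CDS",
            product="elongation factor 1-alpha (single-copy host marker)",
        )


# ---------------------------------------------------------------------------
# sequence helpers


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def _backtranslate(protein: str, rng: np.random.Generator) -> str:
    codons = [ _CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein ]
    return "".join(codons) + "TAA"


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Apply Poisson(divergence x length) substitutions, uniform over sites
    and over the 19 alternative residues (multiple hits allowed)."""
    chars = list(seq)
    n_events = rng.poisson(divergence * len(chars))
    for _ in range(n_events):
        i = int(rng.integers(len(chars)))
        alt = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = alt[int(rng.integers(19))]
    return "".join(chars)


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    n_events = rng.poisson(rate * len(chars))
    for _ in range(n_events):
        i = int(rng.integers(len(chars)))
        alt = [n for n in NUCLEOTIDES if n != chars[i]]
        chars[i] = alt[int(rng.integers(3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# genomes and gene content


def _allocate_families(config: SimulationConfig) -> tuple[dict, dict]:
    """Assign gene families to genomes.

    Returns (family_genomes, pair_shared_extra): family -> set of genomes,
    and per pair-genome lists of families converted from private accessory
    to pair-shared so that each confounded-pair genome shares exactly the
    requested fraction of its families with its sister strain.
    """
    symbionts = config.symbionts
    n_core = int(round(config.core_fraction * config.n_gene_families))
    n_acc_total = config.n_gene_families - n_core
    fam_ids = [f"fam{i + 1:04d}" for i in range(config.n_gene_families)]
    core = fam_ids[:n_core]
    accessory = fam_ids[n_core:]

    per_genome: dict[str, list[str]] = {s: [] for s in symbionts}
    for i, fam in enumerate(accessory):
        per_genome[symbionts[i % len(symbionts)]].append(fam)

    g1, g2 = config.confounded_pair
    f = config.shared_fraction_confounded_pair
    a = min(len(per_genome[g1]), len(per_genome[g2]))
    # each pair genome: n_core + a + x families of which n_core + 2x shared
    if f >= 1.0:
        x = a  # everything shared
    else:
        x = int(round((f * a - (1 - f) * n_core) / (2 - f)))
    if x < 0:
        x = 0  # core alone already exceeds the requested sharing
    if x > a:
        raise ValueError(
            "shared_fraction_confounded_pair unattainable: accessory pool of the "
            "confounded pair too small relative to the core"
        )
    shared_extra = {g1: per_genome[g1][:x], g2: per_genome[g2][:x]}

    family_genomes: dict[str, set] = {fam: set(symbionts) for fam in core}
    for s in symbionts:
        for fam in per_genome[s]:
            family_genomes[fam] = {s}
    for g_from, g_to in ((g1, g2), (g2, g1)):
        for fam in shared_extra[g_from]:
            family_genomes[fam].add(g_to)
    return family_genomes, shared_extra


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[GeneFeature], TruthTable]:
    """Simulate symbiont genomes, gene annotations, and the truth table.

    Each genome carries all core families plus a private accessory set; the
    confounded strain pair additionally shares a block of families at
    >= 99% nucleotide identity (the cross-mapping substrate). A configured
    fraction of each genome's private genes are emitted as short "ghost"
    CDS fragments (< 100 aa). The first private accessory genes of each
    genome are annotated as transposases, and intergenic intron features
    are added, so downstream feature-class filters have substrate.
    """
    rng = _rng(config.seed, "genomes")
    family_genomes, shared_extra = _allocate_families(config)
    symbionts = config.symbionts
    g1, g2 = config.confounded_pair

    # ancestral protein per family
    fam_protein: dict[str, str] = {}
    for fam in sorted(family_genomes):
        length = max(120, int(rng.normal(config.mean_protein_length, 30)))
        fam_protein[fam] = _random_protein(rng, length)

    # per-genome instances: protein + DNA
    pair_shared_all = {
        g1: sorted(f for f, gs in family_genomes.items() if gs >= {g1, g2} and g1 in gs),
        g2: sorted(f for f, gs in family_genomes.items() if gs >= {g1, g2}),
    }
    # DNA of pair-shared families is generated once and nearly copied
    pair_shared_dna: dict[str, tuple[str, str]] = {}
    for fam in pair_shared_all[g1]:
        dna = _backtranslate(fam_protein[fam], rng)
        pair_shared_dna[fam] = (dna, _mutate_dna(dna, 0.002, rng))

    genomes: list[SequenceRecord] = []
    features: list[GeneFeature] = []
    family_membership: dict[str, str] = {}
    ghost_features: set[str] = set()
    pair_shared_features: dict[str, list] = {g1: [], g2: []}
    pair_accessory_features: dict[str, list] = {g1: [], g2: []}
    genome_lengths: dict[str, int] = {}

    for s in symbionts:
        fams = sorted(f for f, gs in family_genomes.items() if s in gs)
        private = [f for f in fams if family_genomes[f] == {s}]
        n_ghost = int(round(config.ghost_cds_fraction * len(fams)))
        # ghosts and transposases drawn from the tail/head of the private set
        ghost_fams = set(private[-n_ghost:]) if n_ghost else set()
        te_fams = set(private[: config.n_transposases_per_genome])

        parts: list[str] = []
        pos = 0
        gene_count = 0
        for fam in fams:
            spacer = _random_dna(rng, config.spacer_length)
            parts.append(spacer)
            pos += len(spacer)
            is_pair_shared = s in (g1, g2) and family_genomes[fam] >= {g1, g2}
            if is_pair_shared:
                protein = fam_protein[fam]
                dna = pair_shared_dna[fam][0 if s == g1 else 1]
            elif len(family_genomes[fam]) > 1:
                protein = mutate_protein(fam_protein[fam], 0.08, rng)
                dna = _backtranslate(protein, rng)
            else:
                protein = mutate_protein(fam_protein[fam], 0.0, rng)
                dna = _backtranslate(protein, rng)
            if fam in ghost_fams:
                ghost_len = int(rng.integers(40, 80))
                protein = protein[:ghost_len]
                dna = dna[: 3 * ghost_len + 3]
            gene_count += 1
            fid = f"{s}_g{gene_count:04d}"
            product = (
                "IS256 family transposase" if fam in te_fams else f"protein of {fam}"
            )
            feat = GeneFeature(
                feature_id=fid,
                genome_id=s,
                contig_id=s,
                start=pos + 1,
                end=pos + len(dna),
                strand="+" if rng.random() < 0.5 else "-",
                feature_class="transposase" if fam in te_fams else "CDS",
                product=product,
                protein=protein,
            )
            features.append(feat)
            family_membership[fid] = fam
            if fam in ghost_fams:
                ghost_features.add(fid)
            if s in (g1, g2):
                if is_pair_shared:
                    pair_shared_features[s].append(fid)
                elif family_genomes[fam] == {s}:
                    pair_accessory_features[s].append(fid)
            parts.append(dna)
            pos += len(dna)

        if pos < config.genome_length:
            parts.append(_random_dna(rng, config.genome_length - pos))
            pos = config.genome_length
        seq = "".join(parts)
        genomes.append(SequenceRecord(s, f"synthetic symbiont genome {s}", seq))
        genome_lengths[s] = len(seq)

        # intergenic intron features in the tail padding
        tail_start = max(f.end for f in features if f.genome_id == s) + 50
        for i in range(config.n_introns_per_genome):
            start = tail_start + i * 300
            end = start + 149
            if end > len(seq):
                break
            features.append(
                GeneFeature(
                    feature_id=f"{s}_intron{i + 1:02d}",
                    genome_id=s,
                    contig_id=s,
                    start=start,
                    end=end,
                    strand="+",
                    feature_class="intron",
                    product="group II intron",
                )
            )

    truth = TruthTable(
        true_loads={s: dict(v) for s, v in config.symbiont_loads.items()},
        family_membership=family_membership,
        te_event_labels={},
        true_variant_density={},
        family_genomes={f: set(g) for f, g in family_genomes.items()},
        pair_shared_features=pair_shared_features,
        pair_accessory_features=pair_accessory_features,
        ghost_features=ghost_features,
        genome_lengths=genome_lengths,
    )
    return genomes, features, truth


# ---------------------------------------------------------------------------
# depth


def simulate_depth(
    config: SimulationConfig,
    genomes: list[SequenceRecord],
    features: list[GeneFeature],
    truth: TruthTable,
) -> list[DepthTrack]:
    """Per-base Poisson depth for every (sample, reference) pair.

    A symbiont at per-host-cell load L is covered at rate
    L x host_marker_depth_mean x ploidy. Genes shared by the confounded
    pair additionally receive an independent Poisson draw at the sister
    strain's rate (cross-mapping inflation). The host marker track is
    Poisson(host_marker_depth_mean).
    """
    rng = _rng(config.seed, "depth")
    m = config.host_marker_depth_mean
    p = config.ploidy
    g1, g2 = config.confounded_pair
    feat_by_id = {f.feature_id: f for f in features}

    tracks: list[DepthTrack] = []
    for sample in config.samples:
        loads = config.symbiont_loads[sample]
        for genome in genomes:
            s = genome.id
            length = len(genome.residues)
            lam = loads.get(s, 0.0) * m * p
            depth = (
                rng.poisson(lam, size=length)
                if lam > 0
                else np.zeros(length, dtype=np.int64)
            )
            if s in (g1, g2):
                sister = g2 if s == g1 else g1
                lam_sister = loads.get(sister, 0.0) * m * p
                if lam_sister > 0:
                    for fid in truth.pair_shared_features[s]:
                        f = feat_by_id[fid]
                        depth[f.start - 1 : f.end] += rng.poisson(
                            lam_sister, size=f.length
                        )
            tracks.append(DepthTrack(sample, s, depth.astype(np.int64)))
        tracks.append(
            DepthTrack(
                sample,
                "host_marker",
                rng.poisson(m, size=config.host_marker_length).astype(np.int64),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# transposase families


def _truncate(seq: str, rng: np.random.Generator) -> str:
    frac = rng.uniform(0.2, 0.4)
    n = int(round(frac * len(seq)))
    return seq[n:] if rng.random() < 0.5 else seq[: len(seq) - n]


def simulate_te_families(config: SimulationConfig) -> TESimResult:
    """Simulate shared-transposase families under three histories.

    recent: one genome carries a small clade of copies; a second genome
    carries one copy differing from a donor copy by at most one
    substitution (a fresh horizontal transfer).
    ancient: each of two genomes carries a clade; the clades diverged by
    ``divergence`` substitutions/site (an ancient sister-clade split).
    vertical ("none"): copies in a single genome only.

    ``degradation_rate`` truncates round(rate x copies) members per family
    at one terminus by 20-40% of their length.
    """
    spec = config.te_history
    spec.validate()
    rng = _rng(config.seed, "te")
    symbionts = config.symbionts
    if len(symbionts) < 2:
        raise ValueError("need >= 2 symbionts for TE history simulation")

    pairs = [
        (symbionts[i], symbionts[j])
        for i in range(len(symbionts))
        for j in range(i + 1, len(symbionts))
    ]
    families: dict[str, list[tuple[str, SequenceRecord]]] = {}
    labels: dict[str, str] = {}
    degraded: set[str] = set()
    fam_no = 0

    def _add_family(label: str, members: list[tuple[str, str]]) -> None:
        nonlocal fam_no
        fam_no += 1
        fam_id = f"tefam{fam_no:03d}"
        recs = []
        n_trunc = int(round(spec.degradation_rate * len(members)))
        trunc_idx = set(
            rng.choice(len(members), size=n_trunc, replace=False).tolist()
        ) if n_trunc else set()
        for i, (genome, seq) in enumerate(members):
            rid = f"{fam_id}_{genome}_c{i + 1}"
            if i in trunc_idx:
                seq = _truncate(seq, rng)
                degraded.add(rid)
            recs.append((genome, SequenceRecord(rid, f"transposase {fam_id}", seq)))
        families[fam_id] = recs
        labels[fam_id] = label

    for k in range(spec.n_recent):
        ga, gb = pairs[k % len(pairs)]
        base = _random_protein(rng, spec.te_length)
        donors = [
            mutate_protein(base, spec.within_clade_divergence, rng)
            for _ in range(spec.copies_per_genome)
        ]
        transferred = list(donors[0])
        if rng.random() < 0.5:  # at most one substitution
            i = int(rng.integers(len(transferred)))
            alt = [a for a in AMINO_ACIDS if a != transferred[i]]
            transferred[i] = alt[int(rng.integers(19))]
        members = [(ga, d) for d in donors] + [(gb, "".join(transferred))]
        _add_family("recent", members)

    for k in range(spec.n_ancient):
        ga, gb = pairs[k % len(pairs)]
        base = _random_protein(rng, spec.te_length)
        root_a = mutate_protein(base, spec.divergence / 2, rng)
        root_b = mutate_protein(base, spec.divergence / 2, rng)
        members = [
            (ga, mutate_protein(root_a, spec.within_clade_divergence, rng))
            for _ in range(spec.copies_per_genome)
        ] + [
            (gb, mutate_protein(root_b, spec.within_clade_divergence, rng))
            for _ in range(spec.copies_per_genome)
        ]
        _add_family("ancient", members)

    for k in range(spec.n_vertical):
        ga = symbionts[k % len(symbionts)]
        base = _random_protein(rng, spec.te_length)
        members = [
            (ga, mutate_protein(base, 0.05, rng))
            for _ in range(spec.copies_per_genome)
        ]
        _add_family("none", members)

    return TESimResult(families=families, labels=labels, degraded=degraded)


# ---------------------------------------------------------------------------
# variants


def _interval_mask(length: int, features, classes=("transposase", "intron")) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for f in features:
        if f.feature_class in classes:
            mask[f.start - 1 : f.end] = True
    return mask


def simulate_variant_table(
    config: SimulationConfig,
    genomes: list[SequenceRecord],
    features: list[GeneFeature],
) -> tuple[pd.DataFrame, dict]:
    """Emit a variant table plus true fixed-variant densities.

    For every (sample, genome) the table holds ``n_fixed_outside`` fixed
    (frequency 1.0) variants outside transposase/intron features,
    ``n_fixed_excluded`` fixed variants inside them, and ``n_polymorphic``
    variants at frequencies in (0.05, 0.95). The truth density counts only
    fixed variants outside excluded features, per kb of genome.
    """
    rng = _rng(config.seed, "variants")
    spec = config.variant_spec
    types = sorted(spec.type_weights)
    weights = np.array([spec.type_weights[t] for t in types], dtype=float)
    weights = weights / weights.sum()

    rows = []
    truth_density: dict = {}
    for sample in config.samples:
        for genome in genomes:
            s = genome.id
            length = len(genome.residues)
            feats = [f for f in features if f.genome_id == s]
            excluded = _interval_mask(length, feats)
            outside_pos = np.flatnonzero(~excluded) + 1
            inside_pos = np.flatnonzero(excluded) + 1

            n_out = min(spec.n_fixed_outside, len(outside_pos))
            n_in = min(spec.n_fixed_excluded, len(inside_pos))
            chosen_out = np.sort(rng.choice(outside_pos, size=n_out, replace=False))
            chosen_in = (
                np.sort(rng.choice(inside_pos, size=n_in, replace=False))
                if n_in
                else np.array([], dtype=int)
            )
            for pos in chosen_out:
                rows.append((sample, s, int(pos), types[int(rng.choice(len(types), p=weights))], 1.0))
            for pos in chosen_in:
                rows.append((sample, s, int(pos), types[int(rng.choice(len(types), p=weights))], 1.0))
            all_pos = rng.choice(length, size=spec.n_polymorphic, replace=False) + 1
            for pos in np.sort(all_pos):
                freq = float(np.round(rng.uniform(0.05, 0.95), 4))
                rows.append((sample, s, int(pos), types[int(rng.choice(len(types), p=weights))], freq))
            truth_density[(sample, s)] = n_out / (length / 1000.0)

    df = pd.DataFrame(rows, columns=["sample", "genome", "position", "type", "frequency"])
    return df, truth_density


def simulate_pileup(
    config: SimulationConfig,
    genome: SequenceRecord,
    variants: pd.DataFrame,
    depth_mean: float = 50.0,
) -> pd.DataFrame:
    """Per-position base counts for one (sample, genome) variant set.

    Produces the substrate for the toy pileup caller: at each variant
    position depth ~ Poisson(depth_mean), alt reads ~ Binomial(depth, f)
    (all reads alt for fixed variants); a margin of invariant positions is
    included with zero alt reads.
    """
    rng = _rng(config.seed, "pileup", genome.id)
    sub = variants[variants["genome"] == genome.id]
    rows = []
    for _, v in sub.iterrows():
        depth = int(rng.poisson(depth_mean))
        if v["frequency"] >= 1.0 - 1e-12:
            alt = depth
        else:
            alt = int(rng.binomial(depth, v["frequency"])) if depth else 0
        rows.append((int(v["position"]), depth - alt, alt, v["type"]))
    # invariant positions
    length = len(genome.residues)
    occupied = set(sub["position"].astype(int))
    free = [p for p in range(1, length + 1, max(1, length // 50)) if p not in occupied]
    for pos in free[:50]:
        depth = int(rng.poisson(depth_mean))
        rows.append((pos, depth, 0, "SNP"))
    df = pd.DataFrame(rows, columns=["position", "ref_count", "alt_count", "alt_type"])
    return df.sort_values("position", kind="stable").reset_index(drop=True)
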
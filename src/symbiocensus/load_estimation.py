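"""Coverage-normalized symbiont load estimation.

The abundance of each symbiont in a sample is its median per-base read
depth normalized by the mean depth of a single-copy host marker gene
(elongation factor 1-alpha); dividing by the number of host chromosome
copies yields the number of symbionts per host cell. For a pair of
near-identical strains whose shared genes attract cross-mapped reads, the
median is restricted to each strain's accessory genes, which are private
and therefore unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io_formats import DepthTrack, GeneFeature

__all__ = [
    "LoadConfig",
    "LoadProfile",
    "median_genome_coverage",
    "host_marker_mean_coverage",
    "symbiont_load",
    "accessory_restricted_coverage",
    "build_load_profiles",
    "cluster_samples",
    "dendrogram_newick",
    "coinfection_summary",
]


@dataclass
class LoadConfig:
    """Parameters of the load estimator.

    ``confounded_pairs`` maps each genome of a near-identical strain pair to
    its accessory gene features (private to that strain, proteins >= 100 aa);
    for those genomes the coverage median is computed over accessory genes
    only. ``presence_threshold`` is the per-host-cell load above which a
    symbiont is called present (0.01 by default: robust to cross-mapping
    noise yet far below any biologically discussed load).
    """

    ploidy: int = 2
    host_marker_feature: GeneFeature | None = None
    confounded_pairs: dict = field(default_factory=dict)  # genome_id -> [GeneFeature]
    presence_threshold: float = 0.01
    include_zero_depth: bool = True

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.presence_threshold < 0:
            raise ValueError("presence_threshold must be >= 0")


@dataclass
class LoadProfile:
    """Per-sample, per-symbiont normalized abundance and load."""

    sample_id: str
    median_coverage: dict
    normalized_abundance: dict
    load_per_host_cell: dict
    relative_abundance: dict
    present: dict

    @property
    def symbionts(self) -> list[str]:
        return sorted(self.median_coverage)


def _region_mask(track: DepthTrack, regions) -> np.ndarray:
    mask = np.zeros(len(track.depth), dtype=bool)
    for f in regions:
        if f.start < 1 or f.end > len(track.depth):
            raise ValueError(
                f"region {f.feature_id} ({f.start}..{f.end}) outside reference "
                f"{track.reference_id} (length {len(track.depth)})"
            )
        mask[f.start - 1 : f.end] = True
    return mask


def median_genome_coverage(
    track: DepthTrack, regions=None, include_zero_depth: bool = True
) -> float:
    """Median per-base depth over the whole genome, or over the union of
    region positions when ``regions`` is given.

    Zero-depth positions are included by default (the median is over the
    whole genome); with ``include_zero_depth=False`` only covered positions
    enter the median. An even position count yields the mean of the two
    central values.
    """
    if regions is not None:
        mask = _region_mask(track, regions)
        if not mask.any():
            raise ValueError("empty region union")
        depths = track.depth[mask]
    else:
        depths = track.depth
    if not include_zero_depth:
        depths = depths[depths > 0]
        if depths.size == 0:
            return 0.0
    return float(np.median(depths))


def host_marker_mean_coverage(track: DepthTrack, marker: GeneFeature) -> float:
    """Arithmetic mean depth over the single-copy host marker interval."""
    if marker.start < 1 or marker.end > len(track.depth):
        raise ValueError(
            f"marker {marker.feature_id} ({marker.start}..{marker.end}) outside "
            f"reference {track.reference_id} (length {len(track.depth)})"
        )
    return float(np.mean(track.slice(marker.start, marker.end)))


def symbiont_load(
    median_cov: float, host_marker_mean: float, ploidy: int
) -> tuple[float, float]:
    """Normalized abundance and per-host-cell load.

    abundance = median symbiont depth / mean marker depth; dividing by the
    number of host chromosome copies gives symbionts per host cell.
    """
    if host_marker_mean <= 0:
        raise ValueError(
            "host marker mean coverage <= 0: sample unusable for normalization"
        )
    normalized = median_cov / host_marker_mean
    return normalized, normalized / ploidy


def accessory_restricted_coverage(
    track: DepthTrack, accessory_genes, include_zero_depth: bool = True
) -> float:
    """Median depth over accessory-gene positions only.

    For the confounded strain pair a whole-genome median is biased upward by
    cross-mapping on shared genes; the accessory genes are private to each
    strain and estimate its depth without that bias. An empty accessory set
    is an error: whole-genome fallback is not permitted for confounded pairs.
    """
    if not accessory_genes:
        raise ValueError(
            "empty accessory gene set for a confounded genome; whole-genome "
            "median is not a permitted fallback (it is biased by cross-mapping)"
        )
    return median_genome_coverage(
        track, regions=accessory_genes, include_zero_depth=include_zero_depth
    )


def build_load_profiles(tracks, config: LoadConfig) -> list[LoadProfile]:
    """Build per-sample load profiles from depth tracks.

    ``tracks`` is a flat list of DepthTrack covering, per sample, one track
    per symbiont genome plus the host marker track (reference id equal to
    the marker feature's contig). Genomes configured in
    ``config.confounded_pairs`` use accessory-restricted medians.
    """
    if config.host_marker_feature is None:
        raise ValueError("LoadConfig.host_marker_feature is required")
    marker = config.host_marker_feature

    by_sample: dict[str, dict[str, DepthTrack]] = {}
    for t in tracks:
        by_sample.setdefault(t.sample_id, {})[t.reference_id] = t

    profiles: list[LoadProfile] = []
    for sample in sorted(by_sample):
        refs = by_sample[sample]
        if marker.contig_id not in refs:
            raise ValueError(f"missing host marker track for sample {sample}")
        marker_mean = host_marker_mean_coverage(refs[marker.contig_id], marker)
        med: dict[str, float] = {}
        for ref_id, track in refs.items():
            if ref_id == marker.contig_id:
                continue
            if ref_id in config.confounded_pairs:
                med[ref_id] = accessory_restricted_coverage(
                    track,
                    config.confounded_pairs[ref_id],
                    include_zero_depth=config.include_zero_depth,
                )
            else:
                med[ref_id] = median_genome_coverage(
                    track, include_zero_depth=config.include_zero_depth
                )
        norm: dict[str, float] = {}
        load: dict[str, float] = {}
        for ref_id, m in med.items():
            n, l = symbiont_load(m, marker_mean, config.ploidy)
            norm[ref_id], load[ref_id] = n, l
        present = {s: load[s] >= config.presence_threshold for s in load}
        denom = sum(load[s] for s in load if present[s])
        rel = {
            s: (load[s] / denom if present[s] and denom > 0 else 0.0) for s in load
        }
        profiles.append(
            LoadProfile(
                sample_id=sample,
                median_coverage=med,
                normalized_abundance=norm,
                load_per_host_cell=load,
                relative_abundance=rel,
                present=present,
            )
        )
    return profiles


def _abundance_matrix(profiles, on: str = "load_per_host_cell"):
    symbionts = sorted(profiles[0].load_per_host_cell)
    for p in profiles:
        if sorted(p.load_per_host_cell) != symbionts:
            raise ValueError("profiles do not share a common symbiont set")
    X = np.array([[getattr(p, on)[s] for s in symbionts] for p in profiles])
    return [p.sample_id for p in profiles], symbionts, X


def cluster_samples(profiles, linkage: str = "complete", on: str = "load_per_host_cell"):
    """Hierarchical clustering of samples on Euclidean abundance distances.

    Returns (sample_ids, scipy linkage matrix). Complete linkage by
    default; the distance is Euclidean between per-sample abundance
    vectors. Merge heights are invariant to sample input order.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 samples to cluster")
    samples, _, X = _abundance_matrix(profiles, on=on)
    dist = ssd.pdist(X, metric="euclidean")
    Z = sch.linkage(dist, method=linkage)
    return samples, Z


def dendrogram_newick(samples, Z) -> str:
    """Render a scipy linkage matrix as a Newick string with merge heights."""
    tree = sch.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist  # leaves have dist 0
        if node.is_leaf():
            return f"{samples[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def coinfection_summary(profiles) -> dict:
    """Per-sample count of present symbionts plus cohort counts.

    Returns {"per_sample": {sample: n_present}, "n_ge2": ..., "n_ge3": ...}.
    """
    per_sample = {
        p.sample_id: int(sum(1 for s in p.present if p.present[s])) for p in profiles
    }
    counts = list(per_sample.values())
    return {
        "per_sample": per_sample,
        "n_ge2": int(sum(1 for c in counts if c >= 2)),
        "n_ge3": int(sum(1 for c in counts if c >= 3)),
    }
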
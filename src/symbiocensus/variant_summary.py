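"""Fixed-variant filtering and per-sample mutation-density summaries.

Downstream of an external variant caller, samples are gated on symbiont
genome coverage (median depth >= 30) and on population (samples from the
population the reference genomes were assembled from are excluded, since
they would show zero divergence by construction). Variants are kept only
when fixed (frequency 1) and outside transposases and introns, and
summarized as mutations/kb and variant-type proportions. A toy pileup
caller is included so the synthetic cohort can exercise the filters
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import DepthTrack, GeneFeature
from .load_estimation import median_genome_coverage

__all__ = [
    "VariantRecord",
    "VariantSummary",
    "read_variant_tsv",
    "write_variant_tsv",
    "records_from_frame",
    "annotate_overlap",
    "gate_samples",
    "filter_variants",
    "summarize_variants",
    "aggregate_densities",
    "toy_pileup_caller",
]

_FREQ_TOL = 1e-9
EXCLUDED_CLASSES = ("transposase", "intron")
VARIANT_TYPES = ("SNP", "insertion", "deletion", "substitution")


@dataclass
class VariantRecord:
    sample_id: str
    genome_id: str
    position: int  # 1-based
    variant_type: str
    frequency: float
    overlapping_feature_class: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.frequency <= 1 + _FREQ_TOL:
            raise ValueError(
                f"frequency must lie in (0, 1], got {self.frequency} at "
                f"{self.genome_id}:{self.position}"
            )
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.variant_type!r}")


@dataclass
class VariantSummary:
    sample_id: str
    genome_id: str
    n_variants_kept: int
    mutations_per_kb: float
    type_proportions: dict
    sample_included: bool = True


def read_variant_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "genome", "position", "type", "frequency"}
    if not required.issubset(df.columns):
        raise ValueError(f"variant TSV must have columns {sorted(required)}")
    return [
        VariantRecord(
            sample_id=str(r["sample"]),
            genome_id=str(r["genome"]),
            position=int(r["position"]),
            variant_type=str(r["type"]),
            frequency=float(r["frequency"]),
        )
        for _, r in df.iterrows()
    ]


def write_variant_tsv(records, path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.genome_id, r.position, r.variant_type, r.frequency)
            for r in records
        ],
        columns=["sample", "genome", "position", "type", "frequency"],
    )
    df.to_csv(path, sep="\t", index=False)


def records_from_frame(df: pd.DataFrame) -> list[VariantRecord]:
    """Convert the simulator's variant table into records."""
    return [
        VariantRecord(
            sample_id=str(r["sample"]),
            genome_id=str(r["genome"]),
            position=int(r["position"]),
            variant_type=str(r["type"]),
            frequency=float(r["frequency"]),
        )
        for _, r in df.iterrows()
    ]


def _feature_trees(features) -> dict:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.genome_id, IntervalTree()).addi(
            f.start, f.end + 1, f.feature_class
        )
    return trees


def annotate_overlap(records, features) -> list[VariantRecord]:
    """Set each record's overlapping feature class from annotation intervals.

    Precedence when several features overlap one position:
    transposase > intron > CDS > other > none.
    """
    trees = _feature_trees(features)
    rank = {"transposase": 0, "intron": 1, "CDS": 2, "other": 3}
    for r in records:
        tree = trees.get(r.genome_id)
        hits = [iv.data for iv in tree[r.position]] if tree is not None else []
        r.overlapping_feature_class = (
            min(hits, key=lambda c: rank.get(c, 99)) if hits else "none"
        )
    return records


def gate_samples(
    depth_tracks,
    populations: dict,
    min_coverage: float = 30.0,
    excluded_populations=(),
) -> set:
    """(sample, genome) pairs passing the coverage and population gates.

    A pair is included iff the sample's median depth on that genome is at
    least ``min_coverage`` and the sample's population is not excluded
    (reference-source populations would contribute zero divergence).
    """
    excluded = set(excluded_populations)
    included = set()
    for t in depth_tracks:
        if populations.get(t.sample_id) in excluded:
            continue
        if median_genome_coverage(t) >= min_coverage:
            included.add((t.sample_id, t.reference_id))
    return included


def filter_variants(records, features=None) -> list[VariantRecord]:
    """Keep fixed variants outside transposases and introns.

    A record survives iff its frequency equals 1 (tolerance 1e-9) and its
    overlapping feature class is not transposase or intron. When
    ``features`` is given, overlap classes are (re)annotated first. The
    frequency and feature filters commute.
    """
    if features is not None:
        records = annotate_overlap(records, features)
    return [
        r
        for r in records
        if abs(r.frequency - 1.0) <= _FREQ_TOL
        and r.overlapping_feature_class not in EXCLUDED_CLASSES
    ]


def summarize_variants(
    kept_records, genome_length: int, sample_id: str = "", genome_id: str = ""
) -> VariantSummary:
    """Mutation density (mutations/kb of genome) and type proportions."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    n = len(kept_records)
    props: dict = {}
    if n:
        for r in kept_records:
            props[r.variant_type] = props.get(r.variant_type, 0) + 1
        props = {t: c / n for t, c in sorted(props.items())}
    return VariantSummary(
        sample_id=sample_id,
        genome_id=genome_id,
        n_variants_kept=n,
        mutations_per_kb=n / (genome_length / 1000.0),
        type_proportions=props,
    )


def aggregate_densities(summaries) -> dict:
    """Mean mutations/kb, both per sample (averaging a sample's genomes
    first) and over all (sample, genome) pairs."""
    if not summaries:
        return {"mean_over_pairs": 0.0, "mean_over_samples": 0.0}
    by_sample: dict[str, list] = {}
    for s in summaries:
        by_sample.setdefault(s.sample_id, []).append(s.mutations_per_kb)
    return {
        "mean_over_pairs": float(np.mean([s.mutations_per_kb for s in summaries])),
        "mean_over_samples": float(
            np.mean([np.mean(v) for v in by_sample.values()])
        ),
    }


def toy_pileup_caller(
    pileup: pd.DataFrame,
    sample_id: str = "",
    genome_id: str = "",
    min_alt_fraction: float = 0.95,
    min_depth: int = 10,
) -> list[VariantRecord]:
    """Call fixed variants from per-position base counts.

    ``pileup`` has columns position, ref_count, alt_count, alt_type. A
    variant is called where depth >= ``min_depth`` and the alt fraction is
    at least ``min_alt_fraction``; the reported frequency is the alt
    fraction. A stand-in for the external caller, sufficient to exercise
    the downstream filters on synthetic data.
    """
    out = []
    for _, row in pileup.iterrows():
        depth = int(row["ref_count"]) + int(row["alt_count"])
        if depth < min_depth:
            continue
        frac = int(row["alt_count"]) / depth
        if frac >= min_alt_fraction and frac > 0:
            out.append(
                VariantRecord(
                    sample_id=sample_id,
                    genome_id=genome_id,
                    position=int(row["position"]),
                    variant_type=str(row["alt_type"]),
                    frequency=frac,
                )
            )
    return out
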
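"""End-to-end orchestration: simulate -> pangenome -> load -> TE tracing -> variants.

Stages run in dependency order and only communicate through files in the
run directory; a machine-readable manifest records the package version,
seed, every threshold, and a SHA-256 hash of each stage output, so reruns
with the same configuration are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import write_depth_tsv, write_fasta, write_gff3
from .load_estimation import (
    LoadConfig,
    build_load_profiles,
    cluster_samples,
    coinfection_summary,
    dendrogram_newick,
)
from .pangenome_identity import (
    all_vs_all_protein_similarity,
    cluster_families,
    partition_pangenome,
)
from .synthetic_data import (
    SimulationConfig,
    simulate_depth,
    simulate_genomes,
    simulate_te_families,
    simulate_variant_table,
)
from .te_tracing import TEFamily, trace_family
from .io_formats import write_newick
from .variant_summary import (
    filter_variants,
    gate_samples,
    records_from_frame,
    summarize_variants,
    write_variant_tsv,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of every stage, with module defaults."""

    seed: int = 0
    out_dir: str = "symbiocensus_run"
    # load estimation
    ploidy: int = 2
    presence_threshold: float = 0.01
    include_zero_depth: bool = True
    linkage: str = "complete"
    # pangenome / identity
    evalue_cutoff: float = 1e-3
    min_identity: float = 35.0
    min_overlap: float = 80.0
    min_protein_length: int = 100
    ani_fragment_length: int = 1020
    ani_min_identity: float = 30.0
    ani_min_aligned_fraction: float = 70.0
    aai_min_identity: float = 30.0
    aai_min_coverage: float = 70.0
    # TE tracing
    recent_threshold: float = 0.02
    support_threshold: float = 95.0
    max_gap_fraction: float = 0.5
    max_entropy: float = 0.6
    bootstrap_replicates: int = 100
    te_min_genomes: int = 2
    # variants
    min_coverage: float = 30.0
    excluded_populations: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig, sim_config: SimulationConfig | None = None
) -> dict:
    """Run the full synthetic-cohort pipeline into ``config.out_dir``.

    Returns the manifest (also written as ``manifest.json``). When
    ``sim_config`` is omitted, the default synthetic study conditions are
    used with the pipeline seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "symbiocensus",
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config),
        "stages": {},
    }

    # --- stage: simulate -------------------------------------------------
    sim = sim_config or SimulationConfig(seed=config.seed)
    genomes, features, truth = simulate_genomes(sim)
    tracks = simulate_depth(sim, genomes, features, truth)
    variants_df, truth_density = simulate_variant_table(sim, genomes, features)
    te_sim = simulate_te_families(sim)

    write_fasta(genomes, out / "genomes.fna")
    write_gff3(features, out / "features.gff3")
    proteins = [
        f for f in features if f.protein
    ]
    from .io_formats import SequenceRecord

    write_fasta(
        [SequenceRecord(f.feature_id, f.product, f.protein) for f in proteins],
        out / "proteins.faa",
    )
    write_depth_tsv(tracks, out / "depth.tsv", omit_zero=True)
    variants_df.to_csv(out / "variants.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {
        "outputs": {
            p.name: _sha256(out / p.name)
            for p in [
                out / "genomes.fna",
                out / "features.gff3",
                out / "proteins.faa",
                out / "depth.tsv",
                out / "variants.tsv",
            ]
        }
    }

    # --- stage: pangenome -------------------------------------------------
    prot_records = [SequenceRecord(f.feature_id, "", f.protein) for f in proteins]
    genome_of = {f.feature_id: f.genome_id for f in proteins}
    edges = all_vs_all_protein_similarity(prot_records)
    families = cluster_families(
        edges,
        [r.id for r in prot_records],
        genome_of=genome_of,
        evalue_cutoff=config.evalue_cutoff,
        min_identity=config.min_identity,
        min_overlap=config.min_overlap,
    )
    lengths = {r.id: len(r.residues) for r in prot_records}
    partition = partition_pangenome(
        families,
        lengths,
        genomes={g.id for g in genomes},
        min_protein_length=config.min_protein_length,
    )
    fam_rows = [
        (fam.family_id, pid, g) for fam in families for pid, g in fam.members
    ]
    pd.DataFrame(fam_rows, columns=["family_id", "protein_id", "genome_id"]).to_csv(
        out / "families.tsv", sep="\t", index=False
    )
    part_rows = [("shared", fam, "") for fam in sorted(partition.shared_families)]
    for g in sorted(partition.accessory):
        part_rows += [("accessory", fam, g) for fam in sorted(partition.accessory[g])]
    pd.DataFrame(part_rows, columns=["class", "family_id", "genome_id"]).to_csv(
        out / "partition.tsv", sep="\t", index=False
    )
    manifest["stages"]["pangenome"] = {
        "n_families": len(families),
        "n_shared": len(partition.shared_families),
        "outputs": {
            "families.tsv": _sha256(out / "families.tsv"),
            "partition.tsv": _sha256(out / "partition.tsv"),
        },
    }

    # --- stage: load ------------------------------------------------------
    feat_by_id = {f.feature_id: f for f in features}
    confounded = {}
    for g in sim.confounded_pair:
        acc_feats = [
            feat_by_id[pid]
            for fam in partition.accessory.get(g, set())
            for pid, fg in partition.surviving_members[fam]
            if fg == g
        ]
        confounded[g] = acc_feats
    load_cfg = LoadConfig(
        ploidy=config.ploidy,
        host_marker_feature=sim.host_marker_feature(),
        confounded_pairs=confounded,
        presence_threshold=config.presence_threshold,
        include_zero_depth=config.include_zero_depth,
    )
    profiles = build_load_profiles(tracks, load_cfg)
    rows = []
    for p in profiles:
        for s in p.symbionts:
            rows.append(
                (
                    p.sample_id,
                    s,
                    p.median_coverage[s],
                    p.normalized_abundance[s],
                    p.load_per_host_cell[s],
                    p.relative_abundance[s],
                    p.present[s],
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "sample",
            "symbiont",
            "median_cov",
            "normalized_abundance",
            "load_per_host_cell",
            "relative_abundance",
            "present",
        ],
    ).to_csv(out / "loads.tsv", sep="\t", index=False)
    samples, Z = cluster_samples(profiles, linkage=config.linkage)
    (out / "samples.nwk").write_text(dendrogram_newick(samples, Z) + "\n")
    manifest["stages"]["load"] = {
        "coinfection": coinfection_summary(profiles),
        "outputs": {
            "loads.tsv": _sha256(out / "loads.tsv"),
            "samples.nwk": _sha256(out / "samples.nwk"),
        },
    }

    # --- stage: te-trace --------------------------------------------------
    te_rows = []
    tree_lines = []
    for fam_id in sorted(te_sim.families):
        fam = TEFamily(fam_id, te_sim.families[fam_id])
        if not fam.is_shared:
            continue
        _, tree, calls = trace_family(
            fam,
            n_bootstrap=config.bootstrap_replicates,
            seed=config.seed,
            recent_threshold=config.recent_threshold,
            support_threshold=config.support_threshold,
            max_gap_fraction=config.max_gap_fraction,
            max_entropy=config.max_entropy,
        )
        if tree is not None:
            tree_lines.append(f"{fam_id}\t{write_newick(tree)}")
        for c in calls:
            te_rows.append(
                (
                    c.family_id,
                    c.genome_pair[0],
                    c.genome_pair[1],
                    c.classification,
                    c.min_cross_genome_patristic,
                    c.sister_support if c.sister_support is not None else "",
                )
            )
    pd.DataFrame(
        te_rows,
        columns=["family", "genome_a", "genome_b", "classification", "min_patristic", "sister_support"],
    ).to_csv(out / "transfer_calls.tsv", sep="\t", index=False)
    (out / "te_trees.tsv").write_text("\n".join(tree_lines) + "\n")
    manifest["stages"]["te_trace"] = {
        "n_calls": len(te_rows),
        "outputs": {
            "transfer_calls.tsv": _sha256(out / "transfer_calls.tsv"),
            "te_trees.tsv": _sha256(out / "te_trees.tsv"),
        },
    }

    # --- stage: variants --------------------------------------------------
    populations = {s: "synthetic" for s in sim.samples}
    included = gate_samples(
        [t for t in tracks if t.reference_id != "host_marker"],
        populations,
        min_coverage=config.min_coverage,
        excluded_populations=config.excluded_populations,
    )
    records = records_from_frame(variants_df)
    kept = filter_variants(records, features)
    sum_rows = []
    for (sample, genome) in sorted(included):
        sub = [r for r in kept if r.sample_id == sample and r.genome_id == genome]
        summ = summarize_variants(
            sub, truth.genome_lengths[genome], sample_id=sample, genome_id=genome
        )
        sum_rows.append(
            (
                sample,
                genome,
                summ.n_variants_kept,
                summ.mutations_per_kb,
                json.dumps(summ.type_proportions),
            )
        )
    pd.DataFrame(
        sum_rows,
        columns=["sample", "genome", "n_kept", "mutations_per_kb", "type_proportions"],
    ).to_csv(out / "variant_summary.tsv", sep="\t", index=False)
    manifest["stages"]["variants"] = {
        "n_pairs_included": len(sum_rows),
        "outputs": {"variant_summary.tsv": _sha256(out / "variant_summary.tsv")},
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
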
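"""Readers and writers for the external formats the pipeline touches.

All coordinates at module boundaries are 1-based and inclusive, following
GFF3. Depth tracks are dense: every position of the declared reference is
represented, zero-depth positions included.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field

import dendropy
import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "GeneFeature",
    "DepthTrack",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_newick",
    "write_newick",
]


@dataclass
class SequenceRecord:
    """A named sequence (nucleotide or amino acid), residues uppercase."""

    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneFeature:
    """A located, stranded annotation interval with its feature class.

    ``feature_class`` is one of ``CDS``, ``transposase``, ``intron`` or
    ``other``; transposases are CDSs whose product mentions "transposase"
    (case-insensitive), mirroring reliance on annotation labels.
    ``protein`` may be empty (introns, or CDS without a matching protein).
    """

    feature_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # inclusive, end >= start
    strand: str
    feature_class: str = "CDS"
    product: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"feature {self.feature_id}: end ({self.end}) < start ({self.start})"
            )
        if self.start < 1:
            raise ValueError(f"feature {self.feature_id}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> np.ndarray:
        """1-based positions covered by this feature."""
        return np.arange(self.start, self.end + 1)


@dataclass
class DepthTrack:
    """Per-base read depth for one reference in one sample.

    ``depth[i]`` is the depth at 1-based position ``i + 1``; the array spans
    the whole reference, so zero-coverage positions are explicit.
    """

    sample_id: str
    reference_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if np.any(self.depth < 0):
            raise ValueError(
                f"negative depth in track {self.sample_id}/{self.reference_id}"
            )

    def __len__(self) -> int:
        return len(self.depth)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Depths over the 1-based inclusive interval [start, end]."""
        if start < 1 or end > len(self.depth):
            raise ValueError(
                f"interval {start}..{end} outside reference "
                f"{self.reference_id} (length {len(self.depth)})"
            )
        return self.depth[start - 1 : end]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order, residues uppercased.

    Raises ``ValueError`` on an empty file or on duplicate record ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, desc, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def _classify(ftype: str, product: str) -> str:
    if ftype.lower() == "intron":
        return "intron"
    if ftype == "CDS":
        if "transposase" in product.lower():
            return "transposase"
        return "CDS"
    return "other"


def read_gff3(path, protein_fasta_path=None, genome_id: str = "") -> list[GeneFeature]:
    """Read CDS/intron features from a GFF3 file.

    Feature classes are derived from the record type and the ``product``
    attribute: type ``intron`` -> intron; CDS whose product contains
    "transposase" (case-insensitive) -> transposase; other CDS -> CDS.
    Proteins are joined to CDS features by shared id from
    ``protein_fasta_path`` when given; a CDS without a matching protein is
    kept with an empty protein.
    """
    proteins: dict[str, str] = {}
    if protein_fasta_path is not None:
        proteins = {r.id: r.residues for r in read_fasta(protein_fasta_path)}

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneFeature] = []
    for f in db.all_features(order_by=("seqid", "start")):
        if f.featuretype not in ("CDS", "intron"):
            continue
        fid = f.attributes.get("ID", [f.id])[0]
        product = f.attributes.get("product", [""])[0]
        if f.end < f.start:
            raise ValueError(f"feature {fid}: end < start in {path}")
        out.append(
            GeneFeature(
                feature_id=fid,
                genome_id=genome_id or f.seqid,
                contig_id=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                feature_class=_classify(f.featuretype, product),
                product=product,
                protein=proteins.get(fid, ""),
            )
        )
    return out


def write_gff3(features, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = "intron" if f.feature_class == "intron" else "CDS"
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "symbiocensus",
                        ftype,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# depth TSV (samtools-depth dialect)


def read_depth_tsv(path, reference_lengths: dict, sample_id: str | None = None) -> list[DepthTrack]:
    """Read a 3- or 4-column depth TSV into dense tracks.

    Columns are (reference, position, depth[, sample]); positions are
    1-based; positions absent from the file have depth 0. Without a 4th
    column all rows belong to ``sample_id``. One track is returned per
    (sample, reference) pair present in ``reference_lengths`` (references
    with no rows at all yield all-zero tracks for each sample seen, or for
    ``sample_id`` if given).
    """
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=[0, 1, 2])
    if df.shape[1] == 3:
        df.columns = ["reference", "position", "depth"]
        df["sample"] = sample_id if sample_id is not None else "sample"
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["reference", "position", "depth", "sample"]
    else:
        raise ValueError(f"depth TSV {path} must have 3 or 4 columns")

    if len(df) and (df["depth"] < 0).any():
        raise ValueError(f"negative depth in {path}")

    samples = sorted(df["sample"].unique()) if len(df) else [sample_id or "sample"]
    tracks: list[DepthTrack] = []
    for samp in samples:
        sub = df[df["sample"] == samp]
        for ref, length in reference_lengths.items():
            rows = sub[sub["reference"] == ref]
            depth = np.zeros(int(length), dtype=np.int64)
            if len(rows):
                pos = rows["position"].to_numpy(dtype=np.int64)
                if pos.min() < 1 or pos.max() > length:
                    bad = pos[(pos < 1) | (pos > length)][0]
                    raise ValueError(
                        f"position {bad} outside reference {ref} (length {length})"
                    )
                depth[pos - 1] = rows["depth"].to_numpy(dtype=np.int64)
            tracks.append(DepthTrack(str(samp), str(ref), depth))
    return tracks


def write_depth_tsv(tracks, path, omit_zero: bool = False) -> None:
    """Write tracks as a 4-column TSV (reference, position, depth, sample)."""
    with open(path, "w") as fh:
        for t in tracks:
            for i, d in enumerate(t.depth):
                if omit_zero and d == 0:
                    continue
                fh.write(f"{t.reference_id}\t{i + 1}\t{int(d)}\t{t.sample_id}\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string into an (unrooted) dendropy tree.

    Raises ``ValueError`` with the reported position on malformed input.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick; branch lengths kept to 12 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
        unquoted_underscores=True,
    ).strip()
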
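"""Readers and writers for the package's plain-text exchange formats."""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .array import ArrayRecord
from .identity import ClusterSet
from .mining import ProteinRecord
from .prevalence import GeneCatalog, PresenceMatrix, RarefactionCurve, read_manifest

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_annotations",
    "write_domain_table",
    "write_catalogs",
    "load_catalogs",
    "write_array_csv",
    "write_clusters_tsv",
    "write_presence_tsv",
    "write_rarefaction_tsv",
]


def write_fasta(sequences: list[tuple[str, str]], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_annotations(records: list[ProteinRecord], path) -> None:
    """One row per domain (or one domain-less row per protein)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["accession", "reviewed", "description", "domain_id", "start", "end",
             "category"]
        )
        for rec in records:
            base = [rec.accession, str(rec.reviewed).lower(), rec.description]
            if not rec.domains:
                writer.writerow(base + ["", "", "", ""])
            for d in rec.domains:
                writer.writerow(base + [d.domain_id, d.start, d.end, d.category])


def write_domain_table(categories: dict[str, str], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["domain_id", "category", "name"])
        for dom in sorted(categories):
            writer.writerow([dom, categories[dom], dom])


def write_catalogs(catalogs: list[GeneCatalog], out_dir) -> Path:
    """One FASTA per sample plus a manifest TSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "body_site", "fasta_path"])
        for cat in catalogs:
            fasta = out_dir / f"{cat.sample_id}.fa"
            write_fasta(list(cat.genes), fasta)
            writer.writerow([cat.sample_id, cat.body_site, fasta.name])
    return manifest


def load_catalogs(manifest_path) -> list[GeneCatalog]:
    base = Path(manifest_path).parent
    catalogs = []
    for sample_id, body_site, fasta_path in read_manifest(manifest_path):
        path = Path(fasta_path)
        if not path.is_absolute():
            path = base / path
        catalogs.append(
            GeneCatalog(sample_id, body_site, tuple(read_fasta(path)))
        )
    return catalogs


def write_array_csv(records: list[ArrayRecord], path) -> None:
    n_reps = max(len(r.replicate_rfus) for r in records)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["glycan_id", "structure", "protein_id", "concentration"]
            + [f"rep{i + 1}" for i in range(n_reps)]
        )
        for r in records:
            writer.writerow(
                [r.glycan_id, r.structure.serialize(), r.protein_id, r.concentration]
                + [repr(v) for v in r.replicate_rfus]
            )


def write_clusters_tsv(clusters: ClusterSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cluster_id", "centroid", "member", "identity_to_centroid"])
        for i, cluster in enumerate(clusters.clusters, start=1):
            for member in cluster.members:
                writer.writerow(
                    [i, cluster.centroid, member,
                     f"{cluster.identities[member]:.6f}"]
                )


def write_presence_tsv(matrix: PresenceMatrix, path) -> None:
    df = matrix.data.astype(int)
    df.index.name = "lectin"
    df.to_csv(path, sep="\t", lineterminator="\n")


def write_rarefaction_tsv(curves: list[RarefactionCurve], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["body_site", "n", "expected_richness"]
        with_sd = any(c.sd is not None for c in curves)
        if with_sd:
            header.append("sd")
        writer.writerow(header)
        for curve in curves:
            for n in range(1, curve.n_samples + 1):
                row = [curve.body_site, n, repr(float(curve.points[n - 1]))]
                if with_sd:
                    row.append(
                        repr(float(curve.sd[n - 1])) if curve.sd is not None else ""
                    )
                writer.writerow(row)
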
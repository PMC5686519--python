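"""Reading, writing and merging BGC libraries.

BGCs travel as multi-record GenBank files in the dialect emitted by cluster
prediction tools: one record per cluster, a record-level ``cluster`` feature
whose ``product`` qualifier carries the class string, and CDS features with
``translation`` qualifiers.  Reference (characterized) clusters additionally
carry a ``compound`` qualifier.  Biopython performs all parsing and
serialization; in memory every coordinate is 0-based half-open, and the
1-based inclusive convention exists only inside the GenBank files
themselves.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import BGCRecord, GeneRecord, GenomeMeta, normalize_class_label

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import ClusterAssignment
    from .simulate import SyntheticCollection

logger = logging.getLogger(__name__)

_CLUSTER_FEATURE_TYPES = ("cluster", "region", "protocluster")


# ---------------------------------------------------------------------------
# GenBank


def _to_seqrecord(bgc: BGCRecord) -> SeqRecord:
    length = len(bgc.sequence) if bgc.sequence else max((g.interval[1] for g in bgc.genes), default=1)
    seq = Seq(bgc.sequence) if bgc.sequence else Seq("N" * length)
    rec = SeqRecord(seq, id=bgc.bgc_id, name=bgc.bgc_id[:30], description="")
    rec.annotations["molecule_type"] = "DNA"
    qualifiers = {
        "product": [bgc.class_label],
        "genome_id": [bgc.genome_id],
        "genome_start": [str(bgc.genome_interval[0])],
        "genome_end": [str(bgc.genome_interval[1])],
        "source_type": [bgc.source],
    }
    if bgc.compound:
        qualifiers["compound"] = [bgc.compound]
    rec.features.append(SeqFeature(FeatureLocation(0, length), type="cluster", qualifiers=qualifiers))
    for gene in bgc.genes:
        rec.features.append(
            SeqFeature(
                FeatureLocation(gene.interval[0], gene.interval[1], strand=1 if gene.strand == "+" else -1),
                type="CDS",
                qualifiers={"locus_tag": [gene.gene_id], "translation": [gene.translation]},
            )
        )
    return rec


def write_bgc_genbank(records: Iterable[BGCRecord], path: str | Path) -> Path:
    """Serialize BGC records as a multi-record GenBank file."""
    path = Path(path)
    SeqIO.write([_to_seqrecord(b) for b in records], str(path), "genbank")
    return path


def read_bgc_genbank(path: str | Path) -> list[BGCRecord]:
    """Parse a multi-record GenBank file into :class:`BGCRecord` objects.

    Every CDS feature with a ``translation`` qualifier becomes a gene;
    records lacking any translated CDS are skipped with a warning.  Unknown
    class strings map to ``"other"`` (with a warning from the vocabulary
    mapper).
    """
    out: list[BGCRecord] = []
    parser = SeqIO.parse(str(path), "genbank")
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except Exception as exc:  # malformed record
            raise ValueError(f"{path}: failed to parse GenBank record {index}: {exc}") from exc

        cluster_feat = next(
            (f for f in rec.features if f.type in _CLUSTER_FEATURE_TYPES and "product" in f.qualifiers),
            None,
        )
        raw_class = cluster_feat.qualifiers["product"][0] if cluster_feat else "other"
        q = cluster_feat.qualifiers if cluster_feat else {}
        genome_id = q.get("genome_id", ["unknown"])[0]
        try:
            genome_interval = (int(q["genome_start"][0]), int(q["genome_end"][0]))
        except (KeyError, ValueError):
            genome_interval = (0, len(rec.seq))
        source = q.get("source_type", ["predicted"])[0]
        compound = q.get("compound", [None])[0]

        genes: list[GeneRecord] = []
        for i, feat in enumerate(f for f in rec.features if f.type == "CDS"):
            if "translation" not in feat.qualifiers:
                continue
            genes.append(
                GeneRecord(
                    gene_id=feat.qualifiers.get("locus_tag", [f"{rec.id}_cds{i + 1}"])[0],
                    interval=(int(feat.location.start), int(feat.location.end)),
                    strand="-" if feat.location.strand == -1 else "+",
                    translation=feat.qualifiers["translation"][0],
                )
            )
        if not genes:
            logger.warning("%s: record %s has no translated CDS features; skipped", path, rec.id)
            index += 1
            continue
        genes.sort(key=lambda g: g.interval[0])
        seq = str(rec.seq) if len(rec.seq) and set(str(rec.seq)) != {"N"} else None
        out.append(
            BGCRecord(
                bgc_id=rec.id,
                genome_id=genome_id,
                class_label=normalize_class_label(raw_class),
                genome_interval=genome_interval,
                genes=genes,
                source=source if source in ("predicted", "reference") else "predicted",
                compound=compound,
                sequence=seq,
            )
        )
        index += 1
    return out


# ---------------------------------------------------------------------------
# FASTA / TSV


def write_genomes_fasta(genomes: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    recs = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in genomes.items()]
    SeqIO.write(recs, str(path), "fasta")
    return path


def read_genomes_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_metadata(metadata: Iterable[GenomeMeta], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "species", "group", "collection"])
        for m in metadata:
            w.writerow([m.genome_id, m.species, m.group, m.collection])
    return path


def read_metadata(path: str | Path) -> list[GenomeMeta]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(GenomeMeta(row["genome_id"], row["species"], row["group"], row["collection"]))
    return out


def write_collection(collection: "SyntheticCollection", outdir: str | Path) -> dict[str, Path]:
    """Write a simulated collection (FASTA, GenBank, metadata and truth TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": write_genomes_fasta(collection.genomes, outdir / "genomes.fasta"),
        "bgcs": write_bgc_genbank(collection.records, outdir / "bgcs.gbk"),
        "metadata": write_metadata(collection.metadata, outdir / "metadata.tsv"),
    }
    truth_path = outdir / "truth.tsv"
    collection.truth.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    paths["truth"] = truth_path
    if collection.reference_records:
        paths["reference"] = write_bgc_genbank(collection.reference_records, outdir / "reference.gbk")
    return paths


# ---------------------------------------------------------------------------
# library assembly


def merge_library(
    predicted: Iterable[BGCRecord],
    reference: Iterable[BGCRecord],
    prefix: str = "REF_",
) -> list[BGCRecord]:
    """Combine predicted and reference BGCs into one analysis library.

    Reference ids are prefixed to keep the id space disjoint; a collision
    after prefixing is an error.
    """
    merged = list(predicted)
    seen = {b.bgc_id for b in merged}
    if len(seen) != len(merged):
        raise ValueError("duplicate ids among predicted BGCs")
    for ref in reference:
        new_id = ref.bgc_id if ref.bgc_id.startswith(prefix) else prefix + ref.bgc_id
        if new_id in seen:
            raise ValueError(f"id collision after prefixing reference record: {new_id}")
        seen.add(new_id)
        merged.append(replace(ref, bgc_id=new_id))
    return merged


@dataclass(frozen=True)
class KnownLabel:
    """Known/unknown status of one DBSCAN cluster."""

    known: bool
    compounds: tuple[str, ...] = ()


def label_known_clusters(
    assignments: "Iterable[ClusterAssignment]",
    library: Iterable[BGCRecord],
) -> dict[tuple[str, int], KnownLabel]:
    """Mark each DBSCAN cluster known iff it contains a reference record.

    Keys are ``(class_label, cluster_id)``; compound names of member
    reference records are aggregated (sorted, deduplicated).
    """
    by_id = {b.bgc_id: b for b in library}
    out: dict[tuple[str, int], KnownLabel] = {}
    compounds: dict[tuple[str, int], set[str]] = {}
    for asg in assignments:
        for bgc_id, label in zip(asg.ids, asg.labels):
            if label < 0:
                continue
            key = (asg.class_label or "all", int(label))
            compounds.setdefault(key, set())
            rec = by_id.get(bgc_id)
            if rec is not None and rec.source == "reference" and rec.compound:
                compounds[key].add(rec.compound)
    for key, names in compounds.items():
        out[key] = KnownLabel(known=bool(names), compounds=tuple(sorted(names)))
    return out
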
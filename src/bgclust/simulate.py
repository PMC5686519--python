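"""Synthetic multi-genome collections with ground-truth BGC families.

The generator emulates the structure of a large single-genus genome-mining
collection: a handful of conserved gene-cluster families shared across
genomes (each derived from a family ancestor by amino-acid substitution,
occasional gene loss and adjacent-gene swaps), rare one-off singleton
clusters, species-group/collection metadata, and horizontally transferred
clusters embedded in sequence of atypical nucleotide composition.  Every
emitted BGC is logged in a truth table so downstream recovery (family
clustering, singleton detection, HGT flagging) can be scored exactly.

All randomness flows through one ``numpy`` generator seeded from
``SimConfig.seed``; a fixed seed yields byte-identical FASTA/GenBank/TSV
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .records import CLASS_VOCABULARY, SPECIES_GROUPS, BGCRecord, GeneRecord, GenomeMeta

SINGLETON = "SINGLETON"

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_DNA = np.array(list("ACGT"))

# aa -> list of synonymous codons (standard table), plus stop codons
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)

_SPECIES_BY_GROUP = {
    "cereus": ["Bacillus cereus", "Bacillus thuringiensis", "Bacillus mycoides"],
    "subtilis": ["Bacillus subtilis", "Bacillus amyloliquefaciens", "Bacillus atrophaeus"],
    "flexus": ["Bacillus flexus"],
    "coagulans": ["Bacillus coagulans"],
    "other": ["Bacillus megaterium", "Bacillus pseudomycoides"],
}

_MIN_GAP = 200  # minimum background bases between placed clusters
_ALIEN_FLANK = 1000  # alien-composition padding on each side of an HGT cluster


class PackingError(ValueError):
    """Raised when the configured clusters cannot fit inside a genome."""


@dataclass
class FamilySpec:
    """One conserved BGC family: class, size, prevalence and divergence."""

    family_id: str
    class_label: str
    n_genes: int
    prevalence: float | Mapping[str, float] = 1.0
    divergence: float = 0.1
    hgt: bool = False

    def prevalence_for(self, group: str) -> float:
        if isinstance(self.prevalence, Mapping):
            return float(self.prevalence.get(group, 0.0))
        return float(self.prevalence)


@dataclass
class SimConfig:
    """Configuration for one synthetic collection.

    Defaults define the package's standard recovery benchmark: 10 genomes,
    six families at full prevalence (60 family BGCs, two families per class
    so every per-class submatrix contains a real discrimination problem),
    divergence ≤ 0.15, one HGT family (10 alien-composition BGCs), and a low
    singleton rate.
    """

    n_genomes: int = 10
    group_spec: Sequence[tuple[str, float]] = (
        ("cereus", 0.5),
        ("subtilis", 0.3),
        ("other", 0.2),
    )
    family_spec: Sequence[FamilySpec] = field(
        default_factory=lambda: default_families()
    )
    reference_spec: Sequence[tuple[str, str]] = (("F1", "synthetic-compound-1"),)
    singleton_rate: float = 0.3
    singleton_classes: Sequence[str] | None = None
    genome_length: int = 100_000
    gc_background: float = 0.35
    gc_alien: float = 0.60
    public_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        total = sum(f for _, f in self.group_spec)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group fractions must sum to 1, got {total}")
        for g, _ in self.group_spec:
            if g not in SPECIES_GROUPS:
                raise ValueError(f"unknown species group {g!r}")
        for fam in self.family_spec:
            if fam.n_genes < 1:
                raise ValueError(f"family {fam.family_id}: gene count must be >= 1")
            if isinstance(fam.prevalence, Mapping):
                vals = fam.prevalence.values()
            else:
                vals = [fam.prevalence]
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"family {fam.family_id}: prevalence outside [0,1]")
            if not 0.0 <= fam.divergence <= 1.0:
                raise ValueError(f"family {fam.family_id}: divergence outside [0,1]")
            if fam.class_label not in CLASS_VOCABULARY:
                raise ValueError(f"family {fam.family_id}: unknown class {fam.class_label!r}")
        if not 0.0 < self.gc_background < 1.0 or not 0.0 < self.gc_alien < 1.0:
            raise ValueError("GC fractions must lie in (0,1)")
        if self.singleton_rate < 0:
            raise ValueError("singleton_rate must be >= 0")


def default_families(zero_divergence: bool = False) -> list[FamilySpec]:
    """The six-family layout of the default benchmark (two families per class)."""
    fams = [
        FamilySpec("F1", "NRPS", 6, 1.0, 0.05),
        FamilySpec("F2", "NRPS", 7, 1.0, 0.10),
        FamilySpec("F3", "PKS-I", 5, 1.0, 0.10),
        FamilySpec("F4", "PKS-I", 8, 1.0, 0.15),
        FamilySpec("F5", "bacteriocin", 4, 1.0, 0.05),
        FamilySpec("F6", "bacteriocin", 6, 1.0, 0.15, hgt=True),
    ]
    if zero_divergence:
        fams = [replace(f, divergence=0.0) for f in fams]
    return fams


def default_benchmark_config(seed: int = 11, zero_divergence: bool = False) -> SimConfig:
    """Standard recovery benchmark used throughout the test suite."""
    return SimConfig(seed=seed, family_spec=default_families(zero_divergence))


@dataclass
class SyntheticCollection:
    """In-memory result of :func:`simulate_collection`."""

    genomes: dict[str, str]
    records: list[BGCRecord]
    reference_records: list[BGCRecord]
    metadata: list[GenomeMeta]
    truth: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS, size=length).tolist())


def _mutate_protein(rng: np.random.Generator, protein: str, divergence: float) -> str:
    if divergence <= 0:
        return protein
    arr = np.array(list(protein))
    hit = rng.random(arr.size) < divergence
    # substitutions are drawn uniformly over the other 19 residues
    for i in np.flatnonzero(hit):
        choices = _AMINO_ACIDS[_AMINO_ACIDS != arr[i]]
        arr[i] = rng.choice(choices)
    return "".join(arr.tolist())


# Sharpness of the synonymous-codon GC bias.  Amino-acid composition caps
# how far coding sequence can drift from GC 0.5, so plain per-base weighting
# undershoots the target; cubing the weights makes the realized CDS GC track
# the configured gc_background/gc_alien closely enough that alien spans are
# compositionally separable at the configured contrast.
_CODON_BIAS_SHARPNESS = 3


def _codon_weights(gc: float) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per-residue synonymous-codon weights biased toward a target GC."""

    def weight(codon: str) -> float:
        g = sum(b in "GC" for b in codon)
        return (gc**g * (1 - gc) ** (3 - g)) ** _CODON_BIAS_SHARPNESS

    out: dict[str, tuple[list[str], np.ndarray]] = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.array([weight(c) for c in codons])
        out[aa] = (codons, w / w.sum())
    stop_w = np.array([weight(c) for c in _STOP_CODONS])
    out["*"] = (_STOP_CODONS, stop_w / stop_w.sum())
    return out


def _reverse_translate(rng: np.random.Generator, protein: str, weights) -> str:
    parts = []
    for aa in protein:
        codons, w = weights[aa]
        parts.append(codons[rng.choice(len(codons), p=w)])
    codons, w = weights["*"]
    parts.append(codons[rng.choice(len(codons), p=w)])
    return "".join(parts)


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_DNA, size=length, p=p).tolist())


# ---------------------------------------------------------------------------
# cluster and genome assembly


def _build_bgc_sequence(
    rng: np.random.Generator,
    proteins: Sequence[str],
    strands: Sequence[str],
    weights,
    gc: float,
) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate reverse-translated CDSs with random spacers.

    Returns the cluster nucleotide sequence and per-gene 0-based half-open
    intervals on it.
    """
    parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    for protein, strand in zip(proteins, strands):
        spacer = _random_dna(rng, int(rng.integers(50, 151)), gc)
        parts.append(spacer)
        pos += len(spacer)
        cds = _reverse_translate(rng, protein, weights)
        if strand == "-":
            cds = str(Seq(cds).reverse_complement())
        parts.append(cds)
        intervals.append((pos, pos + len(cds)))
        pos += len(cds)
    tail = _random_dna(rng, int(rng.integers(50, 151)), gc)
    parts.append(tail)
    return "".join(parts), intervals


def _derive_instance(
    rng: np.random.Generator, fam: FamilySpec, ancestor: list[tuple[str, str, str]]
) -> list[tuple[str, str, str]]:
    """Derive one family instance: substitution, gene loss, adjacent swaps."""
    genes = [(gid, _mutate_protein(rng, prot, fam.divergence), strand) for gid, prot, strand in ancestor]
    # gene loss with probability divergence/4, always keeping at least one gene
    keep = rng.random(len(genes)) >= fam.divergence / 4.0
    if not keep.any():
        keep[0] = True
    genes = [g for g, k in zip(genes, keep) if k]
    # one adjacent swap with probability divergence/4
    if len(genes) >= 2 and rng.random() < fam.divergence / 4.0:
        i = int(rng.integers(0, len(genes) - 1))
        genes[i], genes[i + 1] = genes[i + 1], genes[i]
    return genes


def simulate_collection(config: SimConfig) -> SyntheticCollection:
    """Generate genomes, BGC records, metadata and the truth table.

    Deterministic for a fixed ``config.seed``.  Raises :class:`PackingError`
    (naming the genome) if the configured clusters cannot fit into
    ``genome_length``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w_bg = _codon_weights(config.gc_background)
    w_alien = _codon_weights(config.gc_alien)

    # --- genome metadata -------------------------------------------------
    n = config.n_genomes
    counts = [int(np.floor(frac * n)) for _, frac in config.group_spec]
    i = 0
    while sum(counts) < n:
        counts[i % len(counts)] += 1
        i += 1
    metadata: list[GenomeMeta] = []
    for (group, _), cnt in zip(config.group_spec, counts):
        for _ in range(cnt):
            gid = f"g{len(metadata) + 1:04d}"
            species = str(rng.choice(_SPECIES_BY_GROUP[group]))
            collection = "public" if rng.random() < config.public_fraction else "proprietary"
            metadata.append(GenomeMeta(gid, species, group, collection))

    # --- family ancestors ------------------------------------------------
    ancestors: dict[str, list[tuple[str, str, str]]] = {}
    for fam in config.family_spec:
        genes = []
        for k in range(fam.n_genes):
            length = int(rng.integers(120, 251))
            strand = "+" if rng.random() < 0.7 else "-"
            genes.append((f"{fam.family_id}_g{k + 1}", _random_protein(rng, length), strand))
        ancestors[fam.family_id] = genes

    singleton_classes = list(
        config.singleton_classes
        if config.singleton_classes is not None
        else sorted({f.class_label for f in config.family_spec}) or ["other"]
    )

    # --- per-genome emission ---------------------------------------------
    genomes: dict[str, str] = {}
    records: list[BGCRecord] = []
    truth_rows: list[dict] = []

    for meta in metadata:
        gid = meta.genome_id
        planned: list[dict] = []  # one entry per BGC to place on this genome
        for fam in config.family_spec:
            if rng.random() >= fam.prevalence_for(meta.group):
                continue
            genes = _derive_instance(rng, fam, ancestors[fam.family_id])
            planned.append({"family": fam.family_id, "class": fam.class_label, "hgt": fam.hgt, "genes": genes})
        for _ in range(rng.poisson(config.singleton_rate)):
            n_genes = int(rng.integers(3, 9))
            genes = [
                (f"s_g{k + 1}", _random_protein(rng, int(rng.integers(80, 201))), "+" if rng.random() < 0.7 else "-")
                for k in range(n_genes)
            ]
            planned.append(
                {"family": SINGLETON, "class": str(rng.choice(singleton_classes)), "hgt": False, "genes": genes}
            )

        # build cluster sequences, then pack them with background gaps
        segments: list[dict] = []
        for item in planned:
            gc = config.gc_alien if item["hgt"] else config.gc_background
            weights = w_alien if item["hgt"] else w_bg
            seq, intervals = _build_bgc_sequence(
                rng, [p for _, p, _ in item["genes"]], [s for _, _, s in item["genes"]], weights, gc
            )
            flank = _ALIEN_FLANK if item["hgt"] else 0
            left = _random_dna(rng, flank, config.gc_alien) if flank else ""
            right = _random_dna(rng, flank, config.gc_alien) if flank else ""
            segments.append({**item, "seq": seq, "gene_intervals": intervals, "left": left, "right": right})

        total_span = sum(len(s["left"]) + len(s["seq"]) + len(s["right"]) for s in segments)
        n_gaps = len(segments) + 1
        remaining = config.genome_length - total_span
        if remaining < n_gaps * _MIN_GAP:
            raise PackingError(
                f"genome {gid}: clusters span {total_span} bases, cannot pack into "
                f"genome_length={config.genome_length}"
            )
        w = rng.random(n_gaps)
        extra = remaining - n_gaps * _MIN_GAP
        alloc = np.floor(extra * w / w.sum()).astype(int)
        alloc[-1] += extra - int(alloc.sum())
        gaps = _MIN_GAP + alloc

        parts: list[str] = []
        pos = 0
        for k, seg in enumerate(segments):
            gap = _random_dna(rng, int(gaps[k]), config.gc_background)
            parts.extend([gap, seg["left"]])
            pos += len(gap) + len(seg["left"])
            start = pos
            parts.append(seg["seq"])
            pos += len(seg["seq"])
            parts.append(seg["right"])
            pos += len(seg["right"])

            bgc_id = f"{gid}_bgc{len([r for r in records if r.genome_id == gid]) + 1}"
            genes = [
                GeneRecord(gene_id, interval, strand, protein)
                for (gene_id, protein, strand), interval in zip(seg["genes"], seg["gene_intervals"])
            ]
            records.append(
                BGCRecord(
                    bgc_id=bgc_id,
                    genome_id=gid,
                    class_label=seg["class"],
                    genome_interval=(start, start + len(seg["seq"])),
                    genes=genes,
                    source="predicted",
                    sequence=seg["seq"],
                )
            )
            truth_rows.append(
                {
                    "bgc_id": bgc_id,
                    "genome_id": gid,
                    "family_id": seg["family"],
                    "class_label": seg["class"],
                    "is_hgt": bool(seg["hgt"]),
                    "start": start,
                    "end": start + len(seg["seq"]),
                }
            )
        parts.append(_random_dna(rng, int(gaps[-1]), config.gc_background))
        genomes[gid] = "".join(parts)

    # --- reference library ------------------------------------------------
    reference_records: list[BGCRecord] = []
    fam_by_id = {f.family_id: f for f in config.family_spec}
    for family_id, compound in config.reference_spec:
        if family_id not in fam_by_id:
            raise ValueError(f"reference_spec names unknown family {family_id!r}")
        fam = fam_by_id[family_id]
        seq, intervals = _build_bgc_sequence(
            rng,
            [p for _, p, _ in ancestors[family_id]],
            [s for _, _, s in ancestors[family_id]],
            w_bg,
            config.gc_background,
        )
        genes = [
            GeneRecord(gene_id, interval, strand, protein)
            for (gene_id, protein, strand), interval in zip(ancestors[family_id], intervals)
        ]
        reference_records.append(
            BGCRecord(
                bgc_id=f"{family_id}_ref",
                genome_id="reference_library",
                class_label=fam.class_label,
                genome_interval=(0, len(seq)),
                genes=genes,
                source="reference",
                compound=compound,
                sequence=seq,
            )
        )

    truth = pd.DataFrame(
        truth_rows, columns=["bgc_id", "genome_id", "family_id", "class_label", "is_hgt", "start", "end"]
    )
    return SyntheticCollection(genomes, records, reference_records, metadata, truth, config)


# ---------------------------------------------------------------------------
# truth-table utilities


def truth_family_partition(truth: pd.DataFrame) -> list[frozenset]:
    """Reference partition of BGC ids: families as blocks, singletons as size-1 blocks."""
    if truth.empty:
        return []
    if truth["bgc_id"].duplicated().any():
        dup = truth.loc[truth["bgc_id"].duplicated(), "bgc_id"].iloc[0]
        raise ValueError(f"duplicate BGC id in truth table: {dup}")
    blocks: list[frozenset] = []
    for family_id, grp in truth.groupby("family_id", sort=True):
        if family_id == SINGLETON:
            blocks.extend(frozenset([b]) for b in grp["bgc_id"])
        else:
            blocks.append(frozenset(grp["bgc_id"]))
    return blocks


def truth_labels(truth: pd.DataFrame) -> dict[str, int]:
    """Integer labels per BGC id (each singleton gets its own label), for ARI."""
    labels: dict[str, int] = {}
    nxt = 0
    fam_label: dict[str, int] = {}
    for _, row in truth.iterrows():
        fam = row["family_id"]
        if fam == SINGLETON:
            labels[row["bgc_id"]] = nxt
            nxt += 1
        else:
            if fam not in fam_label:
                fam_label[fam] = nxt
                nxt += 1
            labels[row["bgc_id"]] = fam_label[fam]
    return labels
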
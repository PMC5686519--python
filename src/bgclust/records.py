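"""Core record types shared across the pipeline.

A biosynthetic gene cluster (BGC) is an ordered run of protein-coding genes
on a genome, annotated with one of the natural-product class labels used by
cluster-prediction tools (NRPS, the polyketide-synthase types, RiPP classes,
terpene, siderophore, ...).  All coordinates held in memory are 0-based
half-open; conversion to/from the 1-based inclusive GenBank convention
happens only at the file boundary (see :mod:`bgclust.catalog_io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Supported natural-product class vocabulary.
CLASS_VOCABULARY: tuple[str, ...] = (
    "NRPS",
    "PKS-I",
    "PKS-II",
    "PKS-III",
    "hybrid",
    "lanthipeptide-I",
    "lanthipeptide-II",
    "lanthipeptide-III",
    "lanthipeptide-IV",
    "thiopeptide",
    "bacteriocin",
    "terpene",
    "ectoine",
    "phosphonate",
    "siderophore",
    "other",
)

#: Species-group vocabulary used for prevalence stratification.
SPECIES_GROUPS: tuple[str, ...] = ("cereus", "subtilis", "flexus", "coagulans", "other")

#: Collection vocabulary (public archives vs a proprietary strain set).
COLLECTIONS: tuple[str, ...] = ("public", "proprietary")

# Product-string fragments mapped onto the fixed vocabulary.  Prediction
# tools emit many dialects ("t1pks", "transatpks", "lanthipeptide-class-ii",
# ...); anything unrecognised degrades to "other" with a warning rather than
# failing ingestion.
_PKS_TOKENS = {
    "t1pks": "PKS-I",
    "transatpks": "PKS-I",  # trans-AT systems are type I machinery
    "pks-i": "PKS-I",
    "pksi": "PKS-I",
    "t2pks": "PKS-II",
    "pks-ii": "PKS-II",
    "pksii": "PKS-II",
    "t3pks": "PKS-III",
    "pks-iii": "PKS-III",
    "pksiii": "PKS-III",
}

_LANTHI_SUFFIX = {
    "i": "lanthipeptide-I",
    "1": "lanthipeptide-I",
    "ii": "lanthipeptide-II",
    "2": "lanthipeptide-II",
    "iii": "lanthipeptide-III",
    "3": "lanthipeptide-III",
    "iv": "lanthipeptide-IV",
    "4": "lanthipeptide-IV",
}

_DIRECT = {
    "thiopeptide": "thiopeptide",
    "bacteriocin": "bacteriocin",
    "terpene": "terpene",
    "ectoine": "ectoine",
    "phosphonate": "phosphonate",
    "siderophore": "siderophore",
    "other": "other",
    "hybrid": "hybrid",
}


def normalize_class_label(raw: str) -> str:
    """Map a free-form product string onto the fixed class vocabulary.

    A string naming both NRPS and PKS machinery (e.g. ``"nrps-t1pks"``) is a
    hybrid.  trans-AT PKS maps into type I.  Unknown strings map to
    ``"other"`` with a logged warning.
    """
    s = raw.strip().lower()
    if not s:
        logger.warning("empty class string mapped to 'other'")
        return "other"
    has_nrps = "nrps" in s
    has_pks = "pks" in s or "polyketide" in s
    if has_nrps and has_pks:
        return "hybrid"
    if has_nrps:
        return "NRPS"
    for token, label in _PKS_TOKENS.items():
        if token in s:
            return label
    if "lanthipeptide" in s or "lantipeptide" in s or "lanthidin" in s:
        tail = s.rstrip().split("-")[-1].replace("class", "").strip()
        return _LANTHI_SUFFIX.get(tail, "lanthipeptide-I")
    if s in _DIRECT:
        return _DIRECT[s]
    for token, label in _DIRECT.items():
        if token in s:
            return label
    logger.warning("unknown class string %r mapped to 'other'", raw)
    return "other"


@dataclass
class GeneRecord:
    """A single protein-coding gene inside a BGC record.

    ``interval`` is 0-based half-open relative to the BGC record sequence.
    """

    gene_id: str
    interval: tuple[int, int]
    strand: str
    translation: str

    def __post_init__(self) -> None:
        start, end = self.interval
        if not start < end:
            raise ValueError(f"gene {self.gene_id}: interval start must be < end, got {self.interval}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.translation:
            raise ValueError(f"gene {self.gene_id}: empty translation")


@dataclass
class BGCRecord:
    """One biosynthetic gene cluster: an ordered gene list plus provenance."""

    bgc_id: str
    genome_id: str
    class_label: str
    genome_interval: tuple[int, int]
    genes: list[GeneRecord]
    source: str = "predicted"
    compound: str | None = None
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_VOCABULARY:
            raise ValueError(f"BGC {self.bgc_id}: class {self.class_label!r} not in vocabulary")
        if self.source not in ("predicted", "reference"):
            raise ValueError(f"BGC {self.bgc_id}: source must be 'predicted' or 'reference'")
        if self.source == "reference" and not self.compound:
            raise ValueError(f"reference BGC {self.bgc_id} must carry a compound name")
        starts = [g.interval[0] for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"BGC {self.bgc_id}: genes must be ordered by start coordinate")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class GenomeMeta:
    """Per-genome metadata: species name, species group, and collection."""

    genome_id: str
    species: str
    group: str
    collection: str

    def __post_init__(self) -> None:
        if self.group not in SPECIES_GROUPS:
            raise ValueError(f"genome {self.genome_id}: group {self.group!r} not in {SPECIES_GROUPS}")
        if self.collection not in COLLECTIONS:
            raise ValueError(f"genome {self.genome_id}: collection {self.collection!r} not in {COLLECTIONS}")
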
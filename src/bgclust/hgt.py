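"""Compositional detection of horizontally transferred regions.

Horizontally acquired DNA tends to retain the nucleotide composition of its
donor.  The detector slides a window along each genome, computes the
Kullback-Leibler divergence of the window's k-mer frequencies against the
whole-genome background, and flags windows whose divergence exceeds
``mean + z * sd`` over all windows; flagged windows are merged into maximal
alien intervals.  This is a deliberately simple fixed-order compositional
scan (the interpolated variable-order models of dedicated genomic-island
scanners are out of scope here and this stand-in is labelled as such).

Each BGC is then scored by the fraction of its span covered by the union of
alien intervals; a BGC is flagged as HGT-acquired when that fraction
reaches the cutoff (75% by default, boundary inclusive — the
``hgt_score`` is just the overlap percentage on a 0-100 scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import BGCRecord

_BASE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


@dataclass(frozen=True)
class AlienRegion:
    """A merged compositionally atypical interval (0-based half-open)."""

    genome_id: str
    start: int
    end: int
    atypicality: float


@dataclass(frozen=True)
class HGTAnnotation:
    """Per-BGC overlap with alien regions and the cutoff flag."""

    bgc_id: str
    overlap_fraction: float
    flagged: bool

    @property
    def hgt_score(self) -> float:
        return 100.0 * self.overlap_fraction


def _kmer_indices(seq: str, k: int) -> np.ndarray:
    """Index of the k-mer starting at each position; -1 where ambiguous."""
    codes = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in range(k):
        chunk = codes[off : off + n]
        idx = idx * 4 + np.where(chunk >= 0, chunk, 0)
        valid &= chunk >= 0
    idx[~valid] = -1
    return idx


def _kl_divergence(counts: np.ndarray, background_p: np.ndarray, pseudo: float = 0.5) -> float:
    p = counts + pseudo
    p = p / p.sum()
    return float(np.sum(p * np.log(p / background_p)))


def detect_alien_regions(
    sequence: str,
    genome_id: str = "genome",
    k: int = 6,
    window: int = 5000,
    step: int = 2500,
    z: float = 2.0,
) -> list[AlienRegion]:
    """Sliding-window k-mer KL scan against the whole-genome background.

    Windows with divergence > mean + z*sd are alien; adjacent or
    overlapping alien windows are merged into maximal intervals whose
    atypicality is the maximum window divergence.  A sequence shorter than
    one window yields an empty result with a warning.
    """
    if len(sequence) < window:
        warnings.warn(f"{genome_id}: sequence ({len(sequence)} bp) shorter than window ({window} bp)")
        return []
    idx = _kmer_indices(sequence, k)
    valid = idx[idx >= 0]
    bg = np.bincount(valid, minlength=4**k).astype(float) + 0.5
    bg_p = bg / bg.sum()

    starts = list(range(0, len(sequence) - window + 1, step))
    scores = np.empty(len(starts))
    for w, s in enumerate(starts):
        win = idx[s : s + window - k + 1]
        win = win[win >= 0]
        counts = np.bincount(win, minlength=4**k).astype(float)
        scores[w] = _kl_divergence(counts, bg_p)

    threshold = scores.mean() + z * scores.std()
    flagged = [(s, min(s + window, len(sequence)), scores[w]) for w, s in enumerate(starts) if scores[w] > threshold]

    regions: list[AlienRegion] = []
    for s, e, sc in flagged:
        if regions and s <= regions[-1].end:
            prev = regions[-1]
            regions[-1] = AlienRegion(genome_id, prev.start, max(prev.end, e), max(prev.atypicality, sc))
        else:
            regions.append(AlienRegion(genome_id, s, e, sc))
    return regions


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals as a sorted disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def overlap_fraction(bgc_interval: tuple[int, int], regions: Sequence[AlienRegion | tuple[int, int]]) -> float:
    """Fraction of the BGC interval covered by the union of alien regions."""
    start, end = bgc_interval
    if end <= start:
        raise ValueError(f"zero-length BGC interval {bgc_interval}")
    ivs = [(r.start, r.end) if isinstance(r, AlienRegion) else tuple(r) for r in regions]
    covered = 0
    for s, e in merge_intervals(ivs):
        covered += max(0, min(e, end) - max(s, start))
    return covered / (end - start)


def flag_hgt(fractions: Mapping[str, float], cutoff: float = 75.0) -> list[HGTAnnotation]:
    """Apply the overlap cutoff (percent scale, boundary inclusive)."""
    out = []
    for bgc_id, frac in fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{bgc_id}: overlap fraction {frac} outside [0,1]")
        out.append(HGTAnnotation(bgc_id, float(frac), flagged=100.0 * frac >= cutoff))
    return out


def annotate_hgt(
    library: Iterable[BGCRecord],
    genomes: Mapping[str, str] | None = None,
    regions_by_genome: Mapping[str, Sequence[AlienRegion]] | None = None,
    cutoff: float = 75.0,
    k: int = 6,
    window: int = 5000,
    step: int = 2500,
    z: float = 2.0,
) -> tuple[list[HGTAnnotation], dict[str, list[AlienRegion]]]:
    """Scan genomes (unless regions are supplied) and annotate every BGC.

    BGCs whose genome has no sequence (e.g. reference-library entries) get
    an overlap of 0.
    """
    if regions_by_genome is None:
        if genomes is None:
            raise ValueError("either genomes or regions_by_genome is required")
        regions_by_genome = {
            gid: detect_alien_regions(seq, gid, k=k, window=window, step=step, z=z)
            for gid, seq in genomes.items()
        }
    fractions: dict[str, float] = {}
    for bgc in library:
        regions = regions_by_genome.get(bgc.genome_id, [])
        fractions[bgc.bgc_id] = overlap_fraction(bgc.genome_interval, regions)
    return flag_hgt(fractions, cutoff=cutoff), dict(regions_by_genome)


def write_bed(regions_by_genome: Mapping[str, Sequence[AlienRegion]], path: str | Path) -> Path:
    """Alien regions as BED (0-based half-open; score column = atypicality)."""
    path = Path(path)
    with open(path, "w") as fh:
        for gid in sorted(regions_by_genome):
            for i, r in enumerate(regions_by_genome[gid]):
                fh.write(f"{gid}\t{r.start}\t{r.end}\talien_{gid}_{i + 1}\t{r.atypicality:.6g}\n")
    return path


def write_hgt_table(annotations: Iterable[HGTAnnotation], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "bgc_id": a.bgc_id,
            "overlap_fraction": round(a.overlap_fraction, 6),
            "hgt_score": round(a.hgt_score, 4),
            "flagged": a.flagged,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=["bgc_id", "overlap_fraction", "hgt_score", "flagged"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
    return path
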
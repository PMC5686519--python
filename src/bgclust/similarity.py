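"""All-by-all syntenic similarity and the derived distance matrix.

The pairwise score follows the homology-plus-synteny recipe used by
gene-cluster comparison tools: for a pair of clusters ``(a, b)`` it is

    score = h + w * s

where ``h`` counts reciprocal-best-hit gene pairs whose global-alignment
identity and length compatibility pass the configured thresholds, and ``s``
counts unordered hit pairs whose two genes are adjacent in both clusters
(conserved adjacencies, i.e. local synteny).  A cluster against itself
scores ``n + w * (n - 1)``.

Directional scores are averaged, each column of the averaged matrix is
divided by its maximum, the result is re-symmetrized, and distance is
``1 - similarity`` — yielding a symmetric, zero-diagonal matrix in [0, 1]
ready for density-based clustering.

Protein identity uses ``edlib`` global (Needleman-Wunsch) alignment:
identity = matched columns / alignment columns, i.e. match = 1,
mismatch = 0, with gap columns counted in the alignment length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import BGCRecord

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ScoreParams:
    """Thresholds and weights for the pairwise score.

    min_identity: minimum global-alignment identity for a gene hit.
    min_coverage: minimum length ratio len(shorter)/len(longer) of the two
        proteins — a global alignment covers both sequences fully, so
        coverage acts as a length-compatibility gate.
    synteny_weight: weight ``w`` on conserved adjacencies.
    """

    min_identity: float = 0.30
    min_coverage: float = 0.25
    synteny_weight: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in [0,1]")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in [0,1]")
        if self.synteny_weight < 0:
            raise ValueError("synteny_weight must be >= 0")


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches = total = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        total += n
        if op == "=":
            matches += n
    return matches / total if total else 0.0


class _IdentityCache:
    """Memoizes pairwise protein identities across a matrix computation."""

    def __init__(self) -> None:
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        val = self._cache.get(key)
        if val is None:
            val = alignment_identity(*key)
            self._cache[key] = val
        return val


def _hit_identity(a: str, b: str, params: ScoreParams, cache) -> float:
    """Identity if the pair passes both thresholds, else -1 (no hit)."""
    la, lb = len(a), len(b)
    if min(la, lb) / max(la, lb) < params.min_coverage:
        return -1.0
    ident = cache(a, b) if cache is not None else alignment_identity(a, b)
    return ident if ident >= params.min_identity else -1.0


def score_pair(
    a: BGCRecord,
    b: BGCRecord,
    params: ScoreParams | None = None,
    _cache: _IdentityCache | None = None,
) -> float:
    """Syntenic similarity score ``h + w*s`` between two BGCs.

    Reciprocal-best-hit ties are broken by the lowest gene index in the
    partner cluster, which keeps the computation deterministic.
    """
    params = params or ScoreParams()
    params.validate()
    if not a.genes or not b.genes:
        empty = a.bgc_id if not a.genes else b.bgc_id
        raise ValueError(f"BGC {empty} has no genes")

    na, nb = len(a.genes), len(b.genes)
    ident = np.full((na, nb), -1.0)
    for i, ga in enumerate(a.genes):
        for j, gb in enumerate(b.genes):
            ident[i, j] = _hit_identity(ga.translation, gb.translation, params, _cache)

    # best hit of each a-gene in b and vice versa; ties -> lowest index
    best_a = np.where(ident.max(axis=1) >= 0, ident.argmax(axis=1), -1)
    best_b = np.where(ident.max(axis=0) >= 0, ident.argmax(axis=0), -1)
    pairs = [(i, int(best_a[i])) for i in range(na) if best_a[i] >= 0 and best_b[best_a[i]] == i]
    h = len(pairs)

    s = 0
    for x in range(h):
        for y in range(x + 1, h):
            (i1, j1), (i2, j2) = pairs[x], pairs[y]
            if abs(i1 - i2) == 1 and abs(j1 - j2) == 1:
                s += 1
    return float(h + params.synteny_weight * s)


def score_matrix(library: Sequence[BGCRecord], params: ScoreParams | None = None) -> pd.DataFrame:
    """Raw directional score matrix over the library (rows: query, cols: subject)."""
    params = params or ScoreParams()
    cache = _IdentityCache()
    ids = [b.bgc_id for b in library]
    n = len(library)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            values[i, j] = score_pair(library[i], library[j], params, _cache=cache)
    return pd.DataFrame(values, index=ids, columns=ids)


def average_directional(scores: pd.DataFrame) -> pd.DataFrame:
    """Average the two directions of each comparison: (M + Mᵀ) / 2."""
    values = scores.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("score matrix must be square")
    avg = (values + values.T) / 2.0
    return pd.DataFrame(avg, index=scores.index, columns=scores.columns)


def normalize_columns(avg: pd.DataFrame) -> pd.DataFrame:
    """Divide each column by its maximum, then re-symmetrize by averaging.

    All-zero columns are left at zero.  The result lies in [0, 1].
    """
    values = avg.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("column normalization requires nonnegative entries")
    colmax = values.max(axis=0)
    scaled = np.divide(values, colmax, out=np.zeros_like(values), where=colmax > 0)
    sym = (scaled + scaled.T) / 2.0
    return pd.DataFrame(sym, index=avg.index, columns=avg.columns)


def to_distance(similarity: pd.DataFrame) -> pd.DataFrame:
    """Invert normalized similarity: d = 1 - v, with an exactly-zero diagonal."""
    values = similarity.to_numpy(dtype=float)
    if (values < -1e-12).any() or (values > 1 + 1e-12).any():
        raise ValueError("similarity values must lie in [0,1]")
    dist = 1.0 - np.clip(values, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=similarity.index, columns=similarity.columns)


def compute_distance(library: Sequence[BGCRecord], params: ScoreParams | None = None) -> pd.DataFrame:
    """Full pipeline: score -> average -> column-normalize -> invert."""
    return to_distance(normalize_columns(average_directional(score_matrix(library, params))))


def split_by_class(
    dist: pd.DataFrame, library: Iterable[BGCRecord] | Mapping[str, str]
) -> dict[str, pd.DataFrame]:
    """Restrict the distance matrix to one submatrix per BGC class."""
    if isinstance(library, Mapping):
        class_of = dict(library)
    else:
        class_of = {b.bgc_id: b.class_label for b in library}
    missing = [i for i in dist.index if i not in class_of]
    if missing:
        raise ValueError(f"ids without a class label: {missing[:5]}")
    out: dict[str, pd.DataFrame] = {}
    for cls in sorted(set(class_of[i] for i in dist.index)):
        ids = [i for i in dist.index if class_of[i] == cls]
        out[cls] = dist.loc[ids, ids]
    return out


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


class SyntenyDistance(TransformerMixin, BaseEstimator):
    """Transformer from a BGC library to its pairwise distance matrix.

    Parameters mirror :class:`ScoreParams`.  ``fit`` computes the raw
    directional score matrix; ``transform`` returns the symmetric
    column-normalized distance matrix as an ndarray (``distance_`` holds the
    labelled DataFrame).
    """

    def __init__(self, min_identity: float = 0.30, min_coverage: float = 0.25, synteny_weight: float = 0.5):
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.synteny_weight = synteny_weight

    def _params(self) -> ScoreParams:
        return ScoreParams(self.min_identity, self.min_coverage, self.synteny_weight)

    def fit(self, X: Sequence[BGCRecord], y=None):
        self._params().validate()
        self.ids_ = [b.bgc_id for b in X]
        self.score_matrix_ = score_matrix(X, self._params())
        self.distance_ = to_distance(normalize_columns(average_directional(self.score_matrix_)))
        self.n_features_in_ = len(self.ids_)
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "distance_"):
            raise AttributeError("SyntenyDistance is not fitted yet")
        return self.distance_.to_numpy()

    def fit_transform(self, X: Sequence[BGCRecord], y=None) -> np.ndarray:
        return self.fit(X).transform(X)
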
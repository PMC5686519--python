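"""Pairwise score semantics and the matrix transform chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.base import clone

from bgclust import (
    ScoreParams,
    SyntenyDistance,
    average_directional,
    compute_distance,
    normalize_columns,
    score_pair,
    split_by_class,
    to_distance,
)
from bgclust.simulate import SINGLETON

from ._utils import make_bgc, random_protein

nonneg_matrices = arrays(
    np.float64,
    st.integers(2, 8).map(lambda n: (n, n)),
    elements=st.floats(0, 100, allow_nan=False),
)


def test_self_score_is_n_plus_w_times_adjacencies():
    rng = np.random.default_rng(0)
    bgc = make_bgc("a", [random_protein(rng) for _ in range(3)])
    assert score_pair(bgc, bgc, ScoreParams(synteny_weight=0.5)) == pytest.approx(4.0)
    five = make_bgc("b", [random_protein(rng) for _ in range(5)])
    assert score_pair(five, five, ScoreParams(synteny_weight=0.5)) == pytest.approx(5 + 0.5 * 4)


def test_unrelated_pair_scores_zero():
    rng = np.random.default_rng(1)
    a = make_bgc("a", [random_protein(rng) for _ in range(3)])
    b = make_bgc("b", [random_protein(rng) for _ in range(3)])
    assert score_pair(a, b) == 0.0


def test_rearranged_shared_genes():
    """Two shared genes that stay adjacent after a swap: h=2, s=1 -> 2.5."""
    rng = np.random.default_rng(2)
    f1, f2, f3, f4 = (random_protein(rng) for _ in range(4))
    a = make_bgc("a", [f1, f2, f3])
    b = make_bgc("b", [f2, f1, f4])
    assert score_pair(a, b, ScoreParams(synteny_weight=0.5)) == pytest.approx(2.5)


def test_empty_gene_list_is_an_error():
    rng = np.random.default_rng(3)
    a = make_bgc("a", [random_protein(rng)])
    empty = make_bgc("e", [random_protein(rng)])
    empty.genes = []
    with pytest.raises(ValueError, match="no genes"):
        score_pair(a, empty)


def test_score_symmetric_when_identities_distinct():
    rng = np.random.default_rng(4)
    shared = [random_protein(rng) for _ in range(4)]
    a = make_bgc("a", shared)
    b = make_bgc("b", [shared[1], shared[0], shared[3], random_protein(rng)])
    assert score_pair(a, b) == pytest.approx(score_pair(b, a))


def test_raising_min_identity_never_raises_score():
    rng = np.random.default_rng(5)
    base = [random_protein(rng, 120) for _ in range(5)]

    def mutate(p, k):
        arr = list(p)
        for i in rng.choice(len(arr), size=k, replace=False):
            arr[i] = "W" if arr[i] != "W" else "Y"
        return "".join(arr)

    a = make_bgc("a", base)
    b = make_bgc("b", [mutate(p, k) for p, k in zip(base, [5, 20, 45, 70, 100])])
    scores = [
        score_pair(a, b, ScoreParams(min_identity=t)) for t in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    ]
    assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))
    assert scores[0] > scores[-1]  # the gradient of divergence actually bites


@given(nonneg_matrices)
def test_average_directional_is_the_symmetric_part(values):
    df = pd.DataFrame(values)
    out = average_directional(df).to_numpy()
    np.testing.assert_allclose(out, (values + values.T) / 2, atol=1e-12)


@given(nonneg_matrices)
def test_column_normalization_properties(values):
    avg = (values + values.T) / 2
    out = normalize_columns(pd.DataFrame(avg)).to_numpy()
    colmax = avg.max(axis=0)
    scaled = np.divide(avg, colmax, out=np.zeros_like(avg), where=colmax > 0)
    # pre-symmetrization: every nonzero column peaks at exactly 1
    assert np.allclose(scaled.max(axis=0)[colmax > 0], 1.0)
    np.testing.assert_allclose(out, (scaled + scaled.T) / 2, atol=1e-12)
    assert out.min() >= 0 and out.max() <= 1 + 1e-12


@given(nonneg_matrices)
def test_distance_matrix_invariants(values):
    sim = normalize_columns(average_directional(pd.DataFrame(values)))
    dist = to_distance(sim).to_numpy()
    assert np.allclose(dist, dist.T)
    assert np.allclose(np.diag(dist), 0.0)
    assert dist.min() >= 0 and dist.max() <= 1


def test_to_distance_endpoints_and_domain():
    ids = ["a", "b"]
    sim = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=ids, columns=ids)
    dist = to_distance(sim)
    assert dist.loc["a", "b"] == 1.0 and dist.loc["a", "a"] == 0.0
    with pytest.raises(ValueError, match=r"\[0,1\]"):
        to_distance(pd.DataFrame([[0.0, 1.5], [1.5, 0.0]], index=ids, columns=ids))


def test_families_are_separated_in_distance(benchmark_collection, benchmark_distance):
    truth = benchmark_collection.truth
    fam_of = dict(zip(truth["bgc_id"], truth["family_id"]))
    ids = [i for i in benchmark_distance.index if fam_of.get(i, SINGLETON) != SINGLETON]
    within, between = [], []
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            d = benchmark_distance.loc[ids[x], ids[y]]
            (within if fam_of[ids[x]] == fam_of[ids[y]] else between).append(d)
    assert np.mean(within) < np.mean(between)


def test_zero_divergence_gives_perfect_separation(zerodiv_collection, zerodiv_clustered):
    """At divergence 0 every within-family distance < every between-family distance."""
    _, dist, _ = zerodiv_clustered
    truth = zerodiv_collection.truth
    fam_of = dict(zip(truth["bgc_id"], truth["family_id"]))
    ids = [i for i in dist.index if fam_of.get(i, SINGLETON) != SINGLETON]
    within, between = [], []
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            d = dist.loc[ids[x], ids[y]]
            (within if fam_of[ids[x]] == fam_of[ids[y]] else between).append(d)
    assert max(within) < min(between)


def test_split_by_class_sizes_and_identity():
    ids = [f"b{i}" for i in range(5)]
    classes = {"b0": "NRPS", "b1": "NRPS", "b2": "NRPS", "b3": "terpene", "b4": "terpene"}
    rng = np.random.default_rng(6)
    m = rng.random((5, 5))
    dist = pd.DataFrame((m + m.T) / 2, index=ids, columns=ids)
    np.fill_diagonal(dist.values, 0)
    subs = split_by_class(dist, classes)
    assert {cls: len(sub) for cls, sub in subs.items()} == {"NRPS": 3, "terpene": 2}
    single = split_by_class(dist, {i: "NRPS" for i in ids})
    pd.testing.assert_frame_equal(single["NRPS"], dist)
    with pytest.raises(ValueError, match="without a class"):
        split_by_class(dist, {"b0": "NRPS"})


def test_split_by_class_matches_truth_counts(benchmark_collection, benchmark_library, benchmark_distance):
    subs = split_by_class(benchmark_distance, benchmark_library)
    truth_counts = benchmark_collection.truth["class_label"].value_counts().to_dict()
    ref_classes = [b.class_label for b in benchmark_library if b.source == "reference"]
    for cls in ref_classes:
        truth_counts[cls] = truth_counts.get(cls, 0) + 1
    assert {cls: len(sub) for cls, sub in subs.items()} == truth_counts
    assert sum(len(sub) for sub in subs.values()) == len(benchmark_library)


def test_estimator_api_matches_functional_path(benchmark_library, benchmark_distance):
    est = SyntenyDistance()
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    out = est.fit_transform(benchmark_library)
    np.testing.assert_allclose(out, benchmark_distance.to_numpy(), atol=1e-12)
    np.testing.assert_allclose(out, compute_distance(benchmark_library).to_numpy(), atol=1e-12)
    assert est.ids_ == list(benchmark_distance.index)
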
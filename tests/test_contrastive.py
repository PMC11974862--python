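"""Contrastive losses against independent scalar-loop oracles, plus
neighbourhood selection, gradients and invariances."""

import warnings

import numpy as np
import pytest

from elastoage._tensor import Tensor
from elastoage.contrastive import (EmbeddingBatch, NeighbourhoodSchedule,
                                   age_kernel_weights, loss_adaptive,
                                   loss_exponential, loss_yaware,
                                   select_neighbours, similarity_matrix)


def _unit(rng, n, d):
    f = rng.normal(size=(n, d))
    return f / np.linalg.norm(f, axis=1, keepdims=True)


def _weights(ages, sigma):
    w = np.exp(-(np.subtract.outer(ages, ages)) ** 2 / (2 * sigma**2))
    np.fill_diagonal(w, 0.0)
    return w


# --- brute-force oracles: plain scalar double loops, no vectorisation -----

def _brute_yaware(f, ages, sigma):
    n = len(ages)
    S = f @ f.T
    w = _weights(ages, sigma)
    total = 0.0
    for i in range(n):
        for k in range(n):
            if k == i:
                continue
            den = sum(np.exp(S[i, t]) for t in range(n) if t not in (i, k))
            total -= w[i, k] * np.log(np.exp(S[i, k]) / den)
    return total


def _brute_exponential(f, ages, sigma):
    n = len(ages)
    S = f @ f.T
    w = _weights(ages, sigma)
    total = 0.0
    for i in range(n):
        for k in range(n):
            if k == i:
                continue
            den = sum(np.exp(S[i, t] * (1 - w[i, t])) for t in range(n)
                      if t not in (i, k))
            total -= w[i, k] * np.log(np.exp(S[i, k]) / den)
    return total


def _brute_adaptive(f, ages, sigma, nn_sets):
    n = len(ages)
    S = f @ f.T
    w = _weights(ages, sigma)
    total = 0.0
    for i in range(n):
        wsum = sum(w[i, t] for t in range(n))
        for k in range(n):
            if k == i:
                continue
            pool = [t for t in nn_sets[i] if t != k]
            if not pool:
                continue
            den = sum(np.exp(S[i, t] * (1 - w[i, t])) for t in pool)
            total -= w[i, k] / wsum * np.log(np.exp(S[i, k]) / den)
    return total


# --------------------------------------------------------------------------

def test_kernel_weights_closed_form():
    w = age_kernel_weights([30.0, 30.0, 35.0], sigma=5.0)
    assert w[0, 1] == pytest.approx(1.0)                   # age twins
    assert w[0, 2] == pytest.approx(np.exp(-0.5), abs=1e-12)  # delta = sigma
    assert np.all(np.diag(w) == 0.0)
    assert np.allclose(w, w.T)


def test_kernel_requires_positive_sigma():
    with pytest.raises(ValueError):
        age_kernel_weights([1.0, 2.0], sigma=0.0)


def test_similarity_matrix_limits():
    v = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    s = similarity_matrix(v)
    assert s[0, 1] == pytest.approx(1.0)
    assert s[0, 2] == pytest.approx(0.0)
    assert s[0, 3] == pytest.approx(-1.0)
    assert np.all(np.abs(s) <= 1 + 1e-12)


def test_similarity_normalizes_with_warning():
    with pytest.warns(UserWarning, match="unit-norm"):
        s = similarity_matrix(np.array([[2.0, 0.0], [0.0, 3.0]]))
    assert s[0, 0] == pytest.approx(1.0)


@pytest.mark.parametrize("n,d,seed", [(3, 4, 0), (4, 6, 1), (5, 3, 2)])
def test_loss_yaware_matches_brute_force(n, d, seed):
    rng = np.random.default_rng(seed)
    f = _unit(rng, n, d)
    ages = rng.uniform(20, 80, n)
    got = loss_yaware(EmbeddingBatch(f, ages), sigma=5.0).item()
    assert got == pytest.approx(_brute_yaware(f, ages, 5.0), abs=1e-10)


@pytest.mark.parametrize("n,d,seed", [(3, 4, 3), (5, 5, 4)])
def test_loss_exponential_matches_brute_force(n, d, seed):
    rng = np.random.default_rng(seed)
    f = _unit(rng, n, d)
    ages = rng.uniform(20, 80, n)
    got = loss_exponential(EmbeddingBatch(f, ages), sigma=4.0).item()
    assert got == pytest.approx(_brute_exponential(f, ages, 4.0), abs=1e-10)


@pytest.mark.parametrize("nn_size", [1, 2, 3])
def test_loss_adaptive_matches_brute_force(nn_size):
    rng = np.random.default_rng(7)
    f = _unit(rng, 4, 5)
    ages = rng.uniform(20, 80, 4)
    sched = NeighbourhoodSchedule(step=1, end_count=nn_size)
    nn = select_neighbours(f, epoch=10, schedule=sched)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        got = loss_adaptive(EmbeddingBatch(f, ages), 3.0, nn).item()
    assert got == pytest.approx(_brute_adaptive(f, ages, 3.0, nn), abs=1e-10)


def test_yaware_sigma_to_infinity_is_unweighted():
    """With sigma -> inf every weight -> 1; compare to the all-weights-one form."""
    rng = np.random.default_rng(5)
    f = _unit(rng, 4, 4)
    ages = rng.uniform(20, 80, 4)
    got = loss_yaware(EmbeddingBatch(f, ages), sigma=1e9).item()
    S = f @ f.T
    expect = 0.0
    for i in range(4):
        for k in range(4):
            if k == i:
                continue
            den = sum(np.exp(S[i, t]) for t in range(4) if t not in (i, k))
            expect -= np.log(np.exp(S[i, k]) / den)
    assert got == pytest.approx(expect, rel=1e-6)


def test_exponential_identical_ages_closed_form():
    """All w = 1 makes every denominator term exp(0): log term = s_ik - log(n-2)."""
    rng = np.random.default_rng(6)
    f = _unit(rng, 4, 4)
    ages = np.full(4, 50.0)
    got = loss_exponential(EmbeddingBatch(f, ages), sigma=2.0).item()
    S = f @ f.T
    expect = -sum(S[i, k] - np.log(4 - 2) for i in range(4) for k in range(4) if k != i)
    assert got == pytest.approx(expect, abs=1e-10)


def test_adaptive_with_full_neighbourhoods_is_normalized_exponential():
    rng = np.random.default_rng(8)
    n = 5
    f = _unit(rng, n, 6)
    ages = rng.uniform(20, 80, n)
    sigma = 3.0
    full = [np.array([t for t in range(n) if t != i]) for i in range(n)]
    got = loss_adaptive(EmbeddingBatch(f, ages), sigma, full).item()
    # normalized exponential: same loss with each anchor's weights divided by their sum
    S = f @ f.T
    w = _weights(ages, sigma)
    expect = 0.0
    for i in range(n):
        for k in range(n):
            if k == i:
                continue
            den = sum(np.exp(S[i, t] * (1 - w[i, t])) for t in range(n)
                      if t not in (i, k))
            expect -= w[i, k] / w[i].sum() * np.log(np.exp(S[i, k]) / den)
    assert got == pytest.approx(expect, abs=1e-10)


def test_losses_need_three_samples():
    f = np.eye(2)
    with pytest.raises(ValueError):
        loss_yaware(EmbeddingBatch(f, [20.0, 30.0]), 2.0)


# --- neighbourhood schedule and selection ---------------------------------

def test_schedule_clamp():
    sched = NeighbourhoodSchedule(step=2, end_count=3, start_count=11)
    sizes = [sched.size(e, n=12) for e in range(8)]
    assert sizes == [11, 9, 7, 5, 3, 3, 3, 3]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))  # non-increasing


def test_schedule_default_start_is_all_others():
    sched = NeighbourhoodSchedule(step=3, end_count=1)
    f = np.eye(6)
    nn = select_neighbours(f, epoch=0, schedule=sched)
    assert all(len(s) == 5 for s in nn)
    nn_late = select_neighbours(f, epoch=99, schedule=sched)
    assert all(len(s) == 1 for s in nn_late)


@pytest.mark.parametrize("metric", ["manhattan", "euclidean", "similarity"])
def test_neighbour_selection_brute_force_four_points(metric):
    rng = np.random.default_rng(11)
    f = _unit(rng, 4, 3)
    sched = NeighbourhoodSchedule(step=1, end_count=2, metric=metric)
    nn = select_neighbours(f, epoch=5, schedule=sched)
    for i in range(4):
        if metric == "similarity":
            score = {t: -(f[i] @ f[t]) for t in range(4) if t != i}
        elif metric == "manhattan":
            score = {t: np.abs(f[i] - f[t]).sum() for t in range(4) if t != i}
        else:
            score = {t: np.linalg.norm(f[i] - f[t]) for t in range(4) if t != i}
        expect = sorted(score, key=lambda t: score[t])[:2]
        assert sorted(nn[i].tolist()) == sorted(expect)
        assert i not in nn[i]


def test_points_on_line_nearest_is_unique_neighbour():
    # embed 4 collinear points on the unit circle (arc positions keep order)
    theta = np.array([0.0, 0.1, 0.35, 0.7])
    f = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    sched = NeighbourhoodSchedule(step=1, end_count=1, metric="euclidean")
    nn = select_neighbours(f, epoch=100, schedule=sched)
    assert [s[0] for s in nn] == [1, 0, 1, 2]


def test_end_count_must_be_below_batch():
    with pytest.raises(ValueError):
        select_neighbours(np.eye(3), 0, NeighbourhoodSchedule(step=1, end_count=3))


# --- gradients and geometry ------------------------------------------------

def _fd_grad(fun, x, eps=1e-6):
    g = np.zeros_like(x)
    for idx in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (fun(xp) - fun(xm)) / (2 * eps)
    return g


@pytest.mark.parametrize("which", ["yaware", "exponential", "adaptive"])
def test_finite_difference_gradients(which):
    """Autodiff gradients through L2-normalisation + loss match central differences."""
    rng = np.random.default_rng(21)
    n, d = 5, 4
    raw = rng.normal(size=(n, d))
    ages = rng.uniform(20, 80, n)
    sigma = 4.0
    nn = [np.array([t for t in range(n) if t != i][:3]) for i in range(n)]

    def value(x):
        f = x / np.linalg.norm(x, axis=1, keepdims=True)
        batch = EmbeddingBatch(f, ages)
        if which == "yaware":
            return loss_yaware(batch, sigma).item()
        if which == "exponential":
            return loss_exponential(batch, sigma).item()
        return loss_adaptive(batch, sigma, nn).item()

    t = Tensor(raw, requires_grad=True)
    f = t.l2_normalize()
    batch = EmbeddingBatch(f, ages)
    loss = {"yaware": lambda: loss_yaware(batch, sigma),
            "exponential": lambda: loss_exponential(batch, sigma),
            "adaptive": lambda: loss_adaptive(batch, sigma, nn)}[which]()
    loss.backward()
    fd = _fd_grad(value, raw)
    denom = max(np.abs(fd).max(), 1e-8)
    assert np.max(np.abs(t.grad - fd)) / denom < 1e-4


@pytest.mark.parametrize("loss_fn", [loss_yaware, loss_exponential])
def test_rotation_invariance(loss_fn):
    rng = np.random.default_rng(31)
    f = _unit(rng, 4, 3)
    ages = rng.uniform(20, 80, 4)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    a = loss_fn(EmbeddingBatch(f, ages), 3.0).item()
    b = loss_fn(EmbeddingBatch(f @ q, ages), 3.0).item()
    assert a == pytest.approx(b, rel=1e-10)


@pytest.mark.parametrize("which", ["yaware", "exponential", "adaptive"])
def test_attraction_moving_age_twins_together_lowers_loss(which):
    """Pulling the embeddings of an age-close pair together decreases the loss."""
    ages = np.array([30.0, 30.5, 75.0])
    far = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    theta = 0.15  # rotate sample 1 towards sample 0
    close = far.copy()
    close[1] = [np.sin(theta) * 0 + np.cos(np.pi / 2 - theta),
                np.sin(np.pi / 2 - theta)]
    close[1] /= np.linalg.norm(close[1])

    def val(f):
        batch = EmbeddingBatch(f, ages)
        if which == "yaware":
            return loss_yaware(batch, 2.0).item()
        if which == "exponential":
            return loss_exponential(batch, 2.0).item()
        nn = [np.array([t for t in range(3) if t != i]) for i in range(3)]
        return loss_adaptive(batch, 2.0, nn).item()

    assert val(close) < val(far)
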
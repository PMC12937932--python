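"""Tests for density estimation, Jensen-Shannon divergence and graph metrics."""

from __future__ import annotations

import numpy as np
import pytest

from _graph_oracles import oracle_metrics
from gaitnet.kinematics import MagnitudeSet
from gaitnet.simnet import (DegenerateSignalError, DiscretePDF, SubjectNetwork,
                            ThresholdGrid, build_network, estimate_pdf_pair,
                            global_metrics, js_divergence, local_metrics,
                            metrics_across_thresholds, threshold_graph)


def _pdf_from_function(fn, lo, hi, n=512) -> DiscretePDF:
    grid = np.linspace(lo, hi, n)
    dens = fn(grid)
    dens = dens / np.trapezoid(dens, grid)
    return DiscretePDF(grid=grid, density=dens)


def _gauss(mu, sd):
    return lambda x: np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def js_oracle(fn_p, fn_q, lo, hi, n=16385) -> float:
    """Dense-quadrature JS oracle on analytic densities (base 2)."""
    x = np.linspace(lo, hi, n)
    p, q = fn_p(x), fn_q(x)
    p /= np.trapezoid(p, x)
    q /= np.trapezoid(q, x)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        ip = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1) / m), 0.0)
        iq = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1) / m), 0.0)
    return 0.5 * float(np.trapezoid(ip, x)) + 0.5 * float(np.trapezoid(iq, x))


# ---------------------------------------------------------------------------
# DiscretePDF and KDE
# ---------------------------------------------------------------------------

def test_discrete_pdf_validation():
    grid = np.linspace(0, 1, 11)
    with pytest.raises(ValueError):
        DiscretePDF(grid=grid, density=np.ones(10))          # length mismatch
    with pytest.raises(ValueError):
        DiscretePDF(grid=grid[::-1], density=np.ones(11))    # decreasing grid
    with pytest.raises(ValueError):
        DiscretePDF(grid=grid, density=np.full(11, 7.0))     # not normalized
    dens = np.ones(11)
    DiscretePDF(grid=grid, density=dens)                     # uniform on [0,1]


def test_estimate_pdf_pair_contract():
    rng = np.random.default_rng(0)
    p, q = estimate_pdf_pair(rng.normal(0, 1, 4000), rng.normal(1, 1, 4000))
    assert np.array_equal(p.grid, q.grid)
    assert np.all(p.density >= 0)
    assert np.trapezoid(p.density, p.grid) == pytest.approx(1.0, abs=1e-9)
    # N(0,1) density at 0 is 1/sqrt(2 pi) ~ 0.3989
    at0 = np.interp(0.0, p.grid, p.density)
    assert at0 == pytest.approx(0.3989, abs=0.05)


def test_kde_matches_direct_kernel_sum():
    # the binned-convolution KDE must agree with the O(n*grid) direct sum
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 300)
    p, _ = estimate_pdf_pair(x, x + rng.normal(0, 1, 300))
    q1, q3 = np.percentile(x, [25, 75])
    h = 0.9 * min(x.std(ddof=1), (q3 - q1) / 1.349) * x.size ** (-1 / 5)
    direct = np.exp(-0.5 * ((p.grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1) \
        / (x.size * h * np.sqrt(2 * np.pi))
    direct /= np.trapezoid(direct, p.grid)
    assert np.max(np.abs(p.density - direct)) < 1e-3


def test_estimate_pdf_pair_rejects_degenerate_and_tiny():
    with pytest.raises(DegenerateSignalError):
        estimate_pdf_pair(np.full(100, 2.0), np.random.default_rng(0).normal(size=100))
    with pytest.raises(ValueError):
        estimate_pdf_pair(np.arange(4.0), np.arange(10.0))


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence
# ---------------------------------------------------------------------------

def test_js_identical_is_zero():
    p = _pdf_from_function(_gauss(0, 1), -6, 6)
    assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-9)


def test_js_symmetry():
    p = _pdf_from_function(_gauss(0, 1), -6, 9)
    q = _pdf_from_function(_gauss(3, 1.5), -6, 9)
    assert js_divergence(p, q) == pytest.approx(js_divergence(q, p), abs=1e-12)


def test_js_disjoint_supports_is_one():
    grid = np.linspace(0, 10, 2048)
    p = np.where(grid < 4, 1.0, 0.0)
    q = np.where(grid > 6, 1.0, 0.0)
    p_pdf = DiscretePDF(grid=grid, density=p / np.trapezoid(p, grid))
    q_pdf = DiscretePDF(grid=grid, density=q / np.trapezoid(q, grid))
    assert js_divergence(p_pdf, q_pdf) == pytest.approx(1.0, abs=1e-6)


def test_js_bounded_and_grid_checked():
    p = _pdf_from_function(_gauss(0, 0.5), -8, 8)
    q = _pdf_from_function(_gauss(5, 0.5), -8, 8)
    assert 0.0 <= js_divergence(p, q) <= 1.0
    other = _pdf_from_function(_gauss(0, 0.5), -7, 8)
    with pytest.raises(ValueError):
        js_divergence(p, other)


def test_js_against_dense_quadrature_oracle():
    rng = np.random.default_rng(42)
    for _ in range(10):
        mus = rng.uniform(-2, 2, size=4)
        sds = rng.uniform(0.4, 1.5, size=4)
        w1, w2 = rng.uniform(0.2, 0.8, size=2)
        fp = lambda x: w1 * _gauss(mus[0], sds[0])(x) + (1 - w1) * _gauss(mus[1], sds[1])(x)
        fq = lambda x: w2 * _gauss(mus[2], sds[2])(x) + (1 - w2) * _gauss(mus[3], sds[3])(x)
        lo, hi = mus.min() - 6 * sds.max(), mus.max() + 6 * sds.max()
        got = js_divergence(_pdf_from_function(fp, lo, hi),
                            _pdf_from_function(fq, lo, hi))
        assert got == pytest.approx(js_oracle(fp, fq, lo, hi), abs=1e-3)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _toy_mags(seed=0, n=400):
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 1, n)
    pos = {
        "Pelvis": 1.0 + 0.1 * base,
        "Head": 1.0 + 0.1 * base + rng.normal(0, 0.05, n),
        "Left Foot": 3.0 + 0.5 * rng.normal(0, 1, n),
    }
    return MagnitudeSet(fs=100.0, position=pos, speed={k: np.abs(v)
                                                       for k, v in pos.items()})


def test_build_network_contract():
    net = build_network(_toy_mags())
    A = net.A
    assert np.allclose(A, A.T)
    assert np.all(np.diag(A) == 0)
    off = A[~np.eye(len(net.nodes), dtype=bool)]
    assert np.all((off >= 0) & (off <= 1))
    # similar signals are closer than dissimilar ones
    assert net.edge_weight("Pelvis", "Head") > net.edge_weight("Pelvis", "Left Foot")


def test_build_network_identical_signals_give_one():
    x = np.random.default_rng(1).normal(0, 1, 500)
    mags = MagnitudeSet(fs=100.0, position={"Pelvis": x, "Head": x.copy()},
                        speed={})
    net = build_network(mags)
    assert net.edge_weight("Pelvis", "Head") == pytest.approx(1.0, abs=1e-6)


def test_build_network_flags_degenerate_segment():
    rng = np.random.default_rng(2)
    mags = MagnitudeSet(fs=100.0, position={
        "Pelvis": rng.normal(size=300), "Head": rng.normal(size=300),
        "Left Foot": np.full(300, 5.0)}, speed={})
    net = build_network(mags)
    assert net.missing == ["Left Foot"]
    k = net.nodes.index("Left Foot")
    assert np.all(np.isnan(np.delete(net.A[k], k)))
    assert np.isfinite(net.edge_weight("Pelvis", "Head"))


def test_build_network_node_relabel_equivariance():
    # feeding the same signals under permuted insertion order permutes A
    rng = np.random.default_rng(3)
    sig = {"Pelvis": rng.normal(size=300), "Head": rng.normal(1, 1, 300),
           "Neck": rng.normal(0.5, 1.2, 300)}
    net1 = build_network(MagnitudeSet(fs=1, position=dict(sig), speed={}))
    order = ["Neck", "Pelvis", "Head"]
    net2 = build_network(MagnitudeSet(
        fs=1, position={k: sig[k] for k in order}, speed={}))
    for u in sig:
        for v in sig:
            if u != v:
                assert net1.edge_weight(u, v) == pytest.approx(
                    net2.edge_weight(u, v), abs=1e-12)


# ---------------------------------------------------------------------------
# thresholding and metrics
# ---------------------------------------------------------------------------

def _net_from_adjacency(A, nodes=None):
    A = np.asarray(A, dtype=float)
    nodes = nodes or [f"n{i}" for i in range(A.shape[0])]
    return SubjectNetwork(nodes=list(nodes), A=A)


def test_threshold_grid_default_and_validation():
    grid = ThresholdGrid()
    assert grid.values == (0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60)
    with pytest.raises(ValueError):
        ThresholdGrid(values=(0.5, 0.4))
    with pytest.raises(ValueError):
        ThresholdGrid(values=(0.5, 1.2))


def test_threshold_graph_modes_and_distances():
    A = [[0, 0.9, 0.1], [0.9, 0, 0.5], [0.1, 0.5, 0]]
    net = _net_from_adjacency(A)
    G = threshold_graph(net, 0.4)
    assert G.number_of_edges() == 2
    assert G["n0"]["n1"]["weight"] == pytest.approx(0.9)
    assert G["n0"]["n1"]["length"] == pytest.approx(0.9)       # identity
    Gb = threshold_graph(net, 0.4, mode="binary")
    assert Gb["n0"]["n1"]["weight"] == 1.0
    Gm = threshold_graph(net, 0.4, distance="one_minus")
    assert Gm["n0"]["n1"]["length"] == pytest.approx(0.1)
    Gi = threshold_graph(net, 0.4, distance="inverse")
    assert Gi["n1"]["n2"]["length"] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        threshold_graph(net, 1.5)
    with pytest.raises(ValueError):
        threshold_graph(net, 0.4, mode="other")


def test_threshold_edge_count_non_increasing():
    rng = np.random.default_rng(7)
    n = 8
    W = rng.uniform(0, 1, (n, n))
    A = (W + W.T) / 2
    np.fill_diagonal(A, 0)
    net = _net_from_adjacency(A)
    counts = [threshold_graph(net, tau).number_of_edges()
              for tau in ThresholdGrid().values]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_local_metrics_path_graph_hand_example():
    # path a-b-c with unit weights: b is the only interior node
    A = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
    net = _net_from_adjacency(A, nodes=["a", "b", "c"])
    loc = local_metrics(threshold_graph(net, 0.5))
    assert loc["degree"] == {"a": 1.0, "b": 2.0, "c": 1.0}
    assert loc["strength"]["b"] == pytest.approx(2.0)
    assert loc["betweenness"] == pytest.approx({"a": 0.0, "b": 1.0, "c": 0.0})
    assert loc["closeness"]["b"] == pytest.approx(1.0)
    assert loc["closeness"]["a"] == pytest.approx(2.0 / 3.0)
    assert loc["clustering"]["b"] == 0.0
    assert sum(loc["pagerank"].values()) == pytest.approx(1.0)


def test_global_metrics_two_triangles_hand_example():
    A = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[i, j] = A[j, i] = 1.0
    net = _net_from_adjacency(A)
    glo = global_metrics(threshold_graph(net, 0.5))
    assert glo["global_n_components"] == 2.0
    assert glo["global_modularity"] == pytest.approx(0.5)
    assert glo["global_transitivity"] == pytest.approx(1.0)
    assert glo["global_avg_clustering"] == pytest.approx(1.0)
    assert glo["global_density"] == pytest.approx(6 / 15)
    assert glo["global_avg_strength"] == pytest.approx(2.0)
    # path length on the largest component (a triangle): all distances 1
    assert glo["global_path_length"] == pytest.approx(1.0)


def test_metrics_match_enumeration_oracle_on_random_graphs():
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = int(rng.integers(3, 6))
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.5:
                    A[i, j] = A[j, i] = 1.0
        net = _net_from_adjacency(A)
        G = threshold_graph(net, 0.5)
        loc = local_metrics(G)
        glo = global_metrics(G)
        oracle = oracle_metrics(net.nodes,
                                [(net.nodes[i], net.nodes[j])
                                 for i in range(n) for j in range(i + 1, n)
                                 if A[i, j] > 0])
        assert loc["degree"] == pytest.approx(oracle["degree"])
        assert loc["clustering"] == pytest.approx(oracle["clustering"])
        assert loc["betweenness"] == pytest.approx(oracle["betweenness"])
        assert loc["closeness"] == pytest.approx(oracle["closeness"])
        assert glo["global_density"] == pytest.approx(oracle["density"])
        assert glo["global_transitivity"] == pytest.approx(oracle["transitivity"])
        assert glo["global_n_components"] == oracle["n_components"]


def test_metrics_across_thresholds_averages_and_nan_policy():
    A = [[0, 0.9, 0.3], [0.9, 0, 0.3], [0.3, 0.3, 0]]
    net = _net_from_adjacency(A, nodes=["a", "b", "c"])
    grid = ThresholdGrid(values=(0.2, 0.5))
    gm = metrics_across_thresholds(net, grid)
    # degree of a: 2 at tau=0.2, 1 at tau=0.5 -> mean 1.5
    assert gm.local["degree"]["a"] == pytest.approx(1.5)
    # path length: defined at both thresholds (largest component size >= 2)
    assert np.isfinite(gm.global_["global_path_length"])
    assert set(gm.per_threshold) == {0.2, 0.5}
    # isolated node c at tau=0.5: global path length uses largest component
    assert gm.per_threshold[0.5]["n_edges"] == 1


def test_metrics_across_thresholds_permutation_equivariance():
    rng = np.random.default_rng(13)
    n = 5
    W = rng.uniform(0, 1, (n, n))
    A = (W + W.T) / 2
    np.fill_diagonal(A, 0)
    nodes = ["a", "b", "c", "d", "e"]
    perm = [2, 0, 4, 1, 3]
    A2 = A[np.ix_(perm, perm)]
    gm1 = metrics_across_thresholds(_net_from_adjacency(A, nodes))
    gm2 = metrics_across_thresholds(
        _net_from_adjacency(A2, [nodes[i] for i in perm]))
    for metric, per_node in gm1.local.items():
        for node, val in per_node.items():
            other = gm2.local[metric][node]
            if np.isnan(val):
                assert np.isnan(other)
            else:
                assert val == pytest.approx(other, abs=1e-9)
    for metric, val in gm1.global_.items():
        other = gm2.global_[metric]
        if np.isnan(val):
            assert np.isnan(other)
        else:
            assert val == pytest.approx(other, abs=1e-9)
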
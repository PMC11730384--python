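import heapq

import numpy as np
import pytest

import gliamass.connectivity as C
from gliamass.filters import bandpass_alpha, lowpass_slow


def _random_layer(n, seed, density=0.9, scale=0.9):
    rng = np.random.default_rng(seed)
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = 0.5 * (W + W.T) * scale
    np.fill_diagonal(W, 0.0)
    return W


def _multiplex(n=6, seeds=(0, 1, 2, 3), threshold=None):
    layers = []
    for name, s in zip(C.LAYER_NAMES, seeds):
        W = _random_layer(n, s)
        if threshold:
            W = C.threshold_top_fraction(W, threshold)
        layers.append(C.FunctionalLayer(name=name, weights=W))
    return C.MultiplexNetwork(layers=layers)


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------

def test_alpha_passband_and_stopband():
    fs = 1000.0
    t = np.arange(0, 20, 1 / fs)
    tone10 = np.sin(2 * np.pi * 10.5 * t)
    tone2 = np.sin(2 * np.pi * 2 * t)
    out10 = bandpass_alpha(tone10, fs)[2000:-2000]
    out2 = bandpass_alpha(tone2, fs)[2000:-2000]
    assert np.ptp(out10) / np.ptp(tone10[2000:-2000]) == pytest.approx(1.0, abs=0.01)
    atten_db = 20 * np.log10(np.ptp(out2) / np.ptp(tone2[2000:-2000]))
    assert atten_db <= -20


def test_alpha_zero_phase():
    fs = 1000.0
    t = np.arange(0, 10, 1 / fs)
    x = np.sin(2 * np.pi * 10 * t)
    y = bandpass_alpha(x, fs)
    mid = slice(2000, -2000)
    xc = np.correlate(x[mid], y[mid], mode="full")
    lag = np.argmax(xc) - (len(x[mid]) - 1)
    assert lag == 0


def test_lowpass_pass_and_stop():
    fs = 100.0
    t = np.arange(0, 100, 1 / fs)
    slow = np.sin(2 * np.pi * 0.1 * t)
    fast = np.sin(2 * np.pi * 5 * t)
    out_slow = lowpass_slow(slow, fs)[2000:-2000]
    out_fast = lowpass_slow(fast, fs)[2000:-2000]
    assert np.ptp(out_slow) / np.ptp(slow[2000:-2000]) == pytest.approx(1.0, abs=0.02)
    assert 20 * np.log10(np.ptp(out_fast) / np.ptp(fast[2000:-2000])) <= -20


def test_lowpass_preserves_dc():
    fs = 100.0
    x = np.full(2000, 3.7)
    assert np.allclose(lowpass_slow(x, fs), 3.7)


# ----------------------------------------------------------------------
# PLV and AEC
# ----------------------------------------------------------------------

def _narrowband(seed, n=20_000, fs=1000.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    return bandpass_alpha(x, fs)


def test_plv_self_and_constant_shift():
    fs = 1000.0
    t = np.arange(0, 20, 1 / fs)
    x = np.sin(2 * np.pi * 10 * t)
    y = np.sin(2 * np.pi * 10 * t - 0.8)
    assert C.plv(x, x) == pytest.approx(1.0, abs=1e-12)
    assert C.plv(x[2000:-2000], y[2000:-2000]) == pytest.approx(1.0, abs=1e-3)


def test_plv_null_for_independent_signals():
    # ~10^4 effective samples: 10 independent 200 s alpha-band noise pairs
    # (5 Hz bandwidth -> ~1000 effective samples each).
    vals = [C.plv(_narrowband(2 * s, n=200_000), _narrowband(2 * s + 1, n=200_000))
            for s in range(5)]
    assert np.mean(vals) < 0.1


def test_aec_identical_and_constructed_correlation():
    fs = 1000.0
    assert C.aec(_narrowband(3), _narrowband(3)) == pytest.approx(1.0)
    # Constructed envelope correlation of -0.8: two slow sinusoidal
    # modulators, orthogonal over integer cycles, mixed so that the sample
    # correlation is -0.8 by construction.
    t = np.arange(0, 120, 1 / fs)
    a = np.cos(2 * np.pi * 0.2 * t)
    b = np.sin(2 * np.pi * 0.4 * t)
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    m1 = a
    m2 = -0.8 * a + np.sqrt(1 - 0.64) * b
    carrier = np.sin(2 * np.pi * 10 * t)
    x = (4 + m1) * carrier
    y = (4 + m2) * carrier
    r = C.aec(bandpass_alpha(x, fs), bandpass_alpha(y, fs), fs=fs)
    assert r == pytest.approx(0.8, abs=0.1)


def test_aec_scale_invariance():
    x, y = _narrowband(5), _narrowband(6)
    assert C.aec(x, 4.2 * y) == pytest.approx(C.aec(x, y), abs=1e-12)


def test_layer_builders_match_pairwise_calls(short_run):
    fs = short_run.fs
    x = bandpass_alpha(short_run.lfp, fs)
    P = C.plv_layer(x, fs, trim_s=0.0)
    for (i, j) in [(0, 3), (2, 5)]:
        assert P[i, j] == pytest.approx(C.plv(x[:, i], x[:, j]), abs=1e-9)
    corr = C.correlation_layer(short_run.field("Glu_e"), fs=None, lowpass=False)
    g = short_run.field("Glu_e")
    brute = abs(np.corrcoef(g[:, 1], g[:, 4])[0, 1])
    assert corr[1, 4] == pytest.approx(brute, abs=1e-12)


def test_correlation_layer_null():
    rng = np.random.default_rng(7)
    x = rng.standard_normal((20_000, 4))
    Cm = C.correlation_layer(x, fs=None, lowpass=False)
    off = Cm[~np.eye(4, dtype=bool)]
    assert np.all(off < 0.1)


def test_correlation_layer_rejects_constant_series():
    x = np.ones((100, 3))
    x[:, 0] = np.random.default_rng(0).standard_normal(100)
    with pytest.raises(ValueError, match=r"\[1, 2\]|constant"):
        C.correlation_layer(x, fs=None, lowpass=False)


# ----------------------------------------------------------------------
# thresholding and Fisher mean
# ----------------------------------------------------------------------

def test_threshold_keeps_exact_count():
    W = _random_layer(5, 0)
    Wt = C.threshold_top_fraction(W, 0.25)
    assert np.count_nonzero(np.triu(Wt, 1)) == int(np.ceil(0.25 * 10))


def test_threshold_with_all_equal_weights_uses_tie_break():
    W = np.ones((5, 5)) * 0.5
    np.fill_diagonal(W, 0.0)
    Wt = C.threshold_top_fraction(W, 0.25)
    iu = np.triu_indices(5, 1)
    kept = [(i, j) for i, j in zip(*iu) if Wt[i, j] > 0]
    assert len(kept) == 3
    assert kept == sorted(kept)[:3]  # lexicographic tie-break


def test_threshold_order_statistic():
    W = _random_layer(8, 3)
    Wt = C.threshold_top_fraction(W, 0.25)
    kept = Wt[np.triu_indices(8, 1)]
    dropped = W[np.triu_indices(8, 1)][kept == 0]
    assert kept[kept > 0].min() >= dropped.max()


def test_fisher_mean_fixed_point_and_symmetry():
    assert C.fisher_mean([0.6, 0.6, 0.6]) == pytest.approx(0.6)
    assert C.fisher_mean([0.5, -0.5]) == pytest.approx(0.0, abs=1e-15)


def test_fisher_mean_high_precision_oracle():
    import mpmath
    mpmath.mp.dps = 50
    rs = ["0.3", "0.6", "0.9"]
    zbar = sum(mpmath.atanh(mpmath.mpf(r)) for r in rs) / 3
    expected = float(mpmath.tanh(zbar))
    assert C.fisher_mean([0.3, 0.6, 0.9]) == pytest.approx(expected, rel=1e-14)


def test_fisher_mean_rejects_unit_correlation():
    with pytest.raises(ValueError):
        C.fisher_mean([0.5, 1.0])


# ----------------------------------------------------------------------
# eigenvector versatility
# ----------------------------------------------------------------------

def test_versatility_replica_symmetry():
    # Four identical layers: versatility equals the single-layer
    # eigenvector centrality under the same max normalization.
    W = _random_layer(7, 8)
    m = C.MultiplexNetwork(layers=[
        C.FunctionalLayer(name=n, weights=W) for n in C.LAYER_NAMES])
    v = C.eigenvector_versatility(m)
    vals, vecs = np.linalg.eigh(W)
    single = np.abs(vecs[:, -1])
    single = single / single.max()
    assert np.max(np.abs(v - single)) < 1e-8


def test_star_hub_has_maximal_versatility():
    n = 6
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = 0.9
    m = C.MultiplexNetwork(layers=[
        C.FunctionalLayer(name=nm, weights=W) for nm in C.LAYER_NAMES])
    v = C.eigenvector_versatility(m)
    assert v[0] == 1.0
    assert np.all(v[1:] < 1.0)


def test_versatility_matches_power_iteration():
    m = _multiplex(n=6, threshold=0.6)
    S = m.supra_adjacency()
    x = np.ones(S.shape[0])
    for _ in range(10_000):
        x_new = S @ x
        x_new /= np.linalg.norm(x_new)
        if np.linalg.norm(x_new - x) < 1e-12:
            x = x_new
            break
        x = x_new
    node = np.abs(x).reshape(m.n_layers, m.n_nodes).sum(axis=0)
    node /= node.max()
    assert np.max(np.abs(C.eigenvector_versatility(m) - node)) < 1e-8


# ----------------------------------------------------------------------
# multilayer clustering / path length / overlap
# ----------------------------------------------------------------------

def test_clique_layers_cluster_to_one():
    n = 5
    W = np.ones((n, n)) - np.eye(n)
    m = C.MultiplexNetwork(layers=[
        C.FunctionalLayer(name=nm, weights=W) for nm in C.LAYER_NAMES])
    assert C.multilayer_clustering_coefficient(m) == pytest.approx(1.0)


def test_star_layers_have_zero_clustering():
    n = 5
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = 1.0
    m = C.MultiplexNetwork(layers=[
        C.FunctionalLayer(name=nm, weights=W) for nm in C.LAYER_NAMES])
    assert C.multilayer_clustering_coefficient(m) == 0.0


def test_clustering_matches_triad_enumeration():
    # Brute-force oracle over intra-layer triads (interlayer identity links
    # create no triangles in the multiplex block structure).
    m = _multiplex(n=5, threshold=0.8)
    N, L = m.n_nodes, m.n_layers
    S = np.zeros((N * L, N * L))
    for a in range(L):
        S[a * N:(a + 1) * N, a * N:(a + 1) * N] = m.layers[a].weights
    NL = S.shape[0]
    cc = []
    for i in range(NL):
        neigh = np.flatnonzero(S[i] > 0)
        k = len(neigh)
        if k < 2:
            cc.append(0.0)
            continue
        closed = 0.0
        for a in range(k):
            for b in range(k):
                ja, jb = neigh[a], neigh[b]
                if ja != jb and S[ja, jb] > 0:
                    closed += (S[i, ja] * S[ja, jb] * S[jb, i]) ** (1 / 3)
        cc.append(closed / (k * (k - 1)))
    assert C.multilayer_clustering_coefficient(m) == pytest.approx(
        float(np.mean(cc)), abs=1e-12)


def test_chain_path_length():
    # chain a-b-c with unit weights in one layer replicated: d(a,c) = 2
    n = 3
    W = np.zeros((n, n))
    W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
    m = C.MultiplexNetwork(layers=[
        C.FunctionalLayer(name=nm, weights=W) for nm in C.LAYER_NAMES])
    S = m.supra_adjacency()
    import scipy.sparse
    lengths = np.where(S > 0, 1.0 / np.where(S > 0, S, 1), 0.0)
    D = scipy.sparse.csgraph.shortest_path(
        scipy.sparse.csr_matrix(lengths), directed=False)
    assert D[0, 2] == pytest.approx(2.0)
    mean_d, _ = C.multilayer_path_length(m)
    assert mean_d > 0


def test_path_length_matches_dijkstra_oracle():
    m = _multiplex(n=5, threshold=0.5)
    S = m.supra_adjacency()
    NL = S.shape[0]

    def dijkstra(src):
        dist = np.full(NL, np.inf)
        dist[src] = 0.0
        heap = [(0.0, src)]
        seen = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in seen:
                continue
            seen.add(u)
            for v in range(NL):
                if S[u, v] > 0:
                    w = 1.0 if abs(u - v) % m.n_nodes == 0 and u != v else 1.0 / S[u, v]
                    # interlayer edges are exactly the replica links
                    if u % m.n_nodes == v % m.n_nodes and u != v:
                        w = 1.0
                    nd = d + w
                    if nd < dist[v]:
                        dist[v] = nd
                        heapq.heappush(heap, (nd, v))
        return dist

    dists = np.array([dijkstra(s) for s in range(NL)])
    iu = np.triu_indices(NL, 1)
    vals = dists[iu]
    expected = vals[np.isfinite(vals)].mean()
    got, _ = C.multilayer_path_length(m)
    assert got == pytest.approx(expected, rel=1e-12)


def test_edge_overlap_identical_layers():
    W = C.threshold_top_fraction(_random_layer(6, 1), 0.5)
    m = C.MultiplexNetwork(layers=[
        C.FunctionalLayer(name=nm, weights=W) for nm in C.LAYER_NAMES])
    assert C.edge_overlap(m) == pytest.approx(1.0)


def test_edge_overlap_single_layer_edge():
    n = 4
    W0 = np.zeros((n, n))
    W0[0, 1] = W0[1, 0] = 0.5
    empty = np.zeros((n, n))
    layers = [C.FunctionalLayer(name="LFP_PLV", weights=W0)]
    layers += [C.FunctionalLayer(name=nm, weights=empty)
               for nm in C.LAYER_NAMES[1:]]
    m = C.MultiplexNetwork(layers=layers)
    assert C.edge_overlap(m) == pytest.approx(0.25)


def test_edge_overlap_matches_pair_enumeration():
    m = _multiplex(n=6, threshold=0.4)
    L = m.n_layers
    counts = []
    for i in range(6):
        for j in range(i + 1, 6):
            c = sum(1 for l in m.layers if l.weights[i, j] > 0)
            if c:
                counts.append(c / L)
    assert C.edge_overlap(m) == pytest.approx(float(np.mean(counts)), abs=1e-12)


# ----------------------------------------------------------------------
# map equation
# ----------------------------------------------------------------------

def test_single_module_code_is_visit_rate_entropy():
    W = _random_layer(6, 9)
    strength = W.sum(axis=1)
    p = strength / strength.sum()
    entropy = -np.sum(p * np.log2(p))
    code = C.map_equation_code_length(W, np.zeros(6, dtype=int))
    assert code == pytest.approx(entropy, rel=1e-12)


def _two_cliques(n_per=5, bridge=0.05):
    n = 2 * n_per
    W = np.zeros((n, n))
    for block in (range(n_per), range(n_per, n)):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 1.0
    W[0, n_per] = W[n_per, 0] = bridge
    return W


def test_two_cliques_found_and_beat_one_module():
    W = _two_cliques()
    labels, code = C.map_equation_communities(W)
    truth = np.repeat([0, 1], 5)
    same = labels[truth == 0]
    other = labels[truth == 1]
    assert len(set(same)) == 1 and len(set(other)) == 1
    assert same[0] != other[0]
    one_code = C.map_equation_code_length(W, np.zeros(10, dtype=int))
    assert code < one_code


def test_two_module_code_beats_exhaustive_alternatives():
    # On the quotient of merge candidates the planted split is optimal:
    # compare against all 2^9 bipartitions of the 10 nodes (exhaustive).
    W = _two_cliques()
    truth = np.repeat([0, 1], 5)
    best = np.inf
    for mask in range(1, 2 ** 9):
        labels = np.zeros(10, dtype=int)
        for b in range(9):
            labels[b + 1] = (mask >> b) & 1
        best = min(best, C.map_equation_code_length(W, labels))
    planted = C.map_equation_code_length(W, truth)
    assert planted == pytest.approx(best, rel=1e-12)


def test_relabeling_invariance():
    W = _two_cliques()
    perm = np.random.default_rng(0).permutation(10)
    Wp = W[np.ix_(perm, perm)]
    _, code = C.map_equation_communities(W)
    _, code_p = C.map_equation_communities(Wp)
    assert code == pytest.approx(code_p, abs=1e-12)


def test_multiplex_majority_vote_over_replicas():
    W = _two_cliques()
    m = C.MultiplexNetwork(layers=[
        C.FunctionalLayer(name=nm, weights=W) for nm in C.LAYER_NAMES])
    labels, _ = C.map_equation_communities(m)
    truth = np.repeat([0, 1], 5)
    assert len(np.unique(labels[truth == 0])) == 1
    assert len(np.unique(labels[truth == 1])) == 1


# ----------------------------------------------------------------------
# Von Neumann entropy, QJSD, reducibility
# ----------------------------------------------------------------------

def test_single_edge_entropy_zero():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 0.7
    assert C.von_neumann_entropy(W) == pytest.approx(0.0, abs=1e-12)


def test_complete_graph_entropy_maximal():
    n = 6
    W = np.ones((n, n)) - np.eye(n)
    assert C.von_neumann_entropy(W) == pytest.approx(np.log2(n - 1), rel=1e-12)


def test_entropy_matches_high_precision_oracle():
    import mpmath
    mpmath.mp.dps = 50
    W = _random_layer(5, 10)
    Lap = np.diag(W.sum(axis=1)) - W
    rho = mpmath.matrix((Lap / np.trace(Lap)).tolist())
    evals = mpmath.mp.eigsy(rho, eigvals_only=True)
    ent = -sum(ev * mpmath.log(ev, 2) for ev in evals if ev > 1e-30)
    assert C.von_neumann_entropy(W) == pytest.approx(float(ent), abs=1e-10)


def test_qjsd_identity_and_symmetry():
    Wa, Wb = _random_layer(5, 11), _random_layer(5, 12)
    assert C.qjsd(Wa, Wa) == pytest.approx(0.0, abs=1e-8)
    assert C.qjsd(Wa, Wb) == pytest.approx(C.qjsd(Wb, Wa), abs=1e-12)


def test_qjsd_triangle_inequality_monte_carlo():
    rng = np.random.default_rng(13)
    for trial in range(200):
        seeds = rng.integers(0, 10_000, size=3)
        Wa, Wb, Wc = (_random_layer(4, int(s)) for s in seeds)
        dab, dbc, dac = C.qjsd(Wa, Wb), C.qjsd(Wb, Wc), C.qjsd(Wa, Wc)
        assert dac <= dab + dbc + 1e-12


def test_qjsd_bounded_by_one():
    for s in range(20):
        d = C.qjsd(_random_layer(5, s), _random_layer(5, s + 100))
        assert 0.0 <= d <= 1.0


def test_reducibility_identical_layers_fully_merge():
    W = C.threshold_top_fraction(_random_layer(6, 14), 0.5)
    red = C.structural_reducibility([W, W, W, W])
    assert len(red.reduced_layers) == 1
    assert red.best_n_merges == 3


def test_reducibility_merges_duplicate_pair_first():
    Wdup = C.threshold_top_fraction(_random_layer(8, 15), 0.4)
    Wx = C.threshold_top_fraction(_random_layer(8, 16), 0.4)
    Wy = C.threshold_top_fraction(_random_layer(8, 17), 0.4)
    red = C.structural_reducibility([Wdup, Wx, Wdup, Wy])
    # first merge joins the duplicate layers 0 and 2
    assert set(red.merge_sequence[0]) == {0, 2}


def test_reducibility_quality_contract():
    m = _multiplex(n=6, threshold=0.5)
    red = C.structural_reducibility(m)
    assert max(red.quality_curve) == pytest.approx(
        red.quality_curve[red.best_n_merges], abs=1e-12)
    assert red.quality_curve[red.best_n_merges] >= red.quality_curve[0] - 1e-12


def test_independent_layers_stay_unmerged():
    layers = [_random_layer(10, 20 + s, density=0.5) for s in range(4)]
    red = C.structural_reducibility(layers)
    assert red.best_n_merges == 0


# ----------------------------------------------------------------------
# layer/multiplex validation
# ----------------------------------------------------------------------

def test_functional_layer_validation():
    W = _random_layer(4, 0)
    W[0, 1] = 2.0  # out of [0, 1]
    W[1, 0] = 2.0
    with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
        C.FunctionalLayer(name="LFP_PLV", weights=W)
    bad = _random_layer(4, 0)
    bad[0, 1] += 0.5  # asymmetric
    with pytest.raises(ValueError, match="symmetric"):
        C.FunctionalLayer(name="LFP_PLV", weights=bad)


def test_build_multiplex_from_simulation(short_run):
    m = C.build_multiplex(short_run, threshold_fraction=0.25)
    assert [l.name for l in m.layers] == list(C.LAYER_NAMES)
    n = short_run.n_nodes
    expected_edges = int(np.ceil(0.25 * n * (n - 1) / 2))
    for l in m.layers:
        assert l.n_edges() == expected_edges
        assert np.allclose(l.weights, l.weights.T)
        assert np.all(np.diag(l.weights) == 0)
        assert l.weights.min() >= 0 and l.weights.max() <= 1
    S = m.supra_adjacency()
    # identity interlayer block structure
    blk = S[:n, n:2 * n]
    assert np.array_equal(blk, np.eye(n))


def test_coherent_pair_saturates_both_measures(short_run):
    # PLV and |r| on a perfectly coherent pair both give 1; on long
    # independent noise both fall below 0.1.
    fs = 1000.0
    t = np.arange(0, 30, 1 / fs)
    mod = 2 + lowpass_slow(np.random.default_rng(0).standard_normal(len(t)), fs, 0.3)
    x = mod * np.sin(2 * np.pi * 10 * t)
    xb = bandpass_alpha(x, fs)
    assert C.plv(xb, xb) == pytest.approx(1.0)
    assert C.aec(xb, xb, fs=fs) == pytest.approx(1.0)
    a, b = _narrowband(30), _narrowband(31)
    assert C.plv(a, b) < 0.1
    assert C.aec(a, b, fs=1000.0) < 0.35
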
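"""EEG dynamic-network features.

From a multichannel EEG recording this module builds a stack of windowed
functional-connectivity layers (|Pearson correlation| on band-passed,
z-scored windows), partitions the stack with a multilayer-modularity
Louvain heuristic, and computes five node-level network measures:

* **strength** — summed connection weight of a node within a layer;
* **search information** — for an ordered node pair, the surprisal (bits)
  that a random walker follows the shortest weighted path, a measure of
  communication efficiency;
* **temporal network flexibility** — the fraction of inter-layer
  transitions in which a node changes community;
* **recruitment / integration** — module-allegiance probabilities averaged
  within a node's own cortex and across the other cortices.

Each measure is averaged over the channels of four cortices (frontal,
parietal, occipital, temporal), yielding the 20-entry feature vector used
by the performance and learning-rate models.

The multilayer modularity being maximized is

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma k_il k_jl / 2m_l) delta_lr
                               + delta_ij omega_{lr} ] delta(g_il, g_jr)

with uniform ordinal coupling omega between temporally adjacent layers.
The optimizer is a generalized Louvain heuristic: randomized-order local
moves of node-layer states followed by greedy community merges, repeated
to convergence; ties in community choice break toward the lowest community
index so runs are reproducible under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .names import CORTICES

VARIANCE_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# containers


@dataclass
class EEGRecording:
    """Channels x samples signal matrix with a sampling rate and names."""

    signal: np.ndarray
    sampling_rate: float = 500.0
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.signal.shape[0])]
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match signal rows")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate


@dataclass
class CortexMap:
    """Channel-name -> cortex assignment; unassigned channels are excluded."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.assignment.values() if c not in CORTICES}
        if bad:
            raise ValueError(f"unknown cortex labels: {sorted(bad)}")

    def indices(self, channel_names: list[str]) -> dict[str, np.ndarray]:
        """Per-cortex channel indices for an ordered channel-name list."""
        out: dict[str, list[int]] = {c: [] for c in CORTICES}
        for i, name in enumerate(channel_names):
            cortex = self.assignment.get(name)
            if cortex is not None:
                out[cortex].append(i)
        return {c: np.asarray(idx, dtype=int) for c, idx in out.items()}

    def node_cortex(self, channel_names: list[str]) -> np.ndarray:
        """Per-channel cortex label ('' for unassigned)."""
        return np.asarray(
            [self.assignment.get(name, "") for name in channel_names], dtype=object
        )


@dataclass
class LayerStack:
    """Ordered symmetric nonnegative adjacency matrices, one per window."""

    layers: list[np.ndarray]
    window_length: float
    window_step: float

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty layer stack")
        n = self.layers[0].shape[0]
        for A in self.layers:
            if A.shape != (n, n):
                raise ValueError("all layers must share a dimension")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]

    def __len__(self) -> int:
        return len(self.layers)


@dataclass
class PartitionEnsemble:
    """Community labels with shape (n_runs, n_layers, n_nodes)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 3:
            raise ValueError("labels must have shape (runs, layers, nodes)")

    @property
    def n_runs(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[2]


# ---------------------------------------------------------------------------
# preprocessing and connectivity


def preprocess(
    recording: EEGRecording, band: tuple[float, float] = (4.0, 30.0), order: int = 4
) -> EEGRecording:
    """Zero-phase band-pass filter and per-channel z-scoring.

    Channels whose variance falls below the floor (e.g. flat channels)
    come out identically zero rather than NaN.
    """
    lo, hi = band
    nyq = recording.sampling_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=recording.sampling_rate, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, recording.signal, axis=1)
    mean = filtered.mean(axis=1, keepdims=True)
    var = filtered.var(axis=1, keepdims=True)
    flat = var[:, 0] < VARIANCE_FLOOR
    sd = np.sqrt(np.maximum(var, VARIANCE_FLOOR))
    z = (filtered - mean) / sd
    z[flat] = 0.0
    return EEGRecording(z, recording.sampling_rate, list(recording.channel_names))


def build_layers(
    recording: EEGRecording, window_length: float = 2.0, window_step: float = 2.0
) -> LayerStack:
    """Windowed |Pearson correlation| connectivity layers.

    One symmetric, zero-diagonal adjacency per window; weights in [0, 1].
    At least two windows are required (temporal flexibility is undefined
    on a single layer).
    """
    fs = recording.sampling_rate
    wlen = int(round(window_length * fs))
    wstep = int(round(window_step * fs))
    n_samp = recording.signal.shape[1]
    if wlen < 2 or wlen > n_samp:
        raise ValueError("window_length must give at least 2 samples and fit the recording")
    starts = range(0, n_samp - wlen + 1, wstep)
    layers = []
    for s in starts:
        seg = recording.signal[:, s : s + wlen]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(seg)
        C[np.isnan(C)] = 0.0
        C[sd < np.sqrt(VARIANCE_FLOOR), :] = 0.0
        C[:, sd < np.sqrt(VARIANCE_FLOOR)] = 0.0
        A = np.abs(C)
        np.fill_diagonal(A, 0.0)
        layers.append(np.clip(A, 0.0, 1.0))
    if len(layers) < 2:
        raise ValueError(
            f"recording yields {len(layers)} window(s); need >= 2 for a layer stack"
        )
    return LayerStack(layers, window_length, window_step)


# ---------------------------------------------------------------------------
# single-layer measures


def node_strength(layer: np.ndarray) -> np.ndarray:
    """Row sums of a symmetric nonnegative adjacency matrix."""
    layer = np.asarray(layer, dtype=float)
    if layer.ndim != 2 or layer.shape[0] != layer.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(layer, layer.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(layer < 0):
        raise ValueError("adjacency must be nonnegative")
    return layer.sum(axis=1)


def search_information(layer: np.ndarray, warn_disconnected: bool = True) -> np.ndarray:
    """Search information SI(i -> j) in bits for every ordered node pair.

    The shortest path between i and j is computed on edge lengths 1/w; the
    probability that a random walker starting at i follows that exact path
    is the product over its steps (u -> v) of w_uv / strength_u, and
    SI = -log2 of that product.  Among equal-length shortest paths the
    lexicographically smallest node sequence is used.  Unreachable pairs
    get +inf.  The diagonal is 0.
    """
    W = np.asarray(layer, dtype=float)
    n = W.shape[0]
    s = node_strength(W)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    graph = csr_matrix(np.where(np.isinf(L), 0.0, L))
    D = _dijkstra(graph, directed=False)

    if warn_disconnected and np.isinf(D).any():
        warnings.warn("graph is disconnected; unreachable pairs get infinite SI", stacklevel=2)

    # cost of step u -> v in bits: log2(s_u) - log2(w_uv)
    with np.errstate(divide="ignore", invalid="ignore"):
        step_cost = np.where(W > 0, np.log2(np.maximum(s, 1e-300))[:, None] - np.log2(W), np.inf)

    # next_hop[u, t]: lexicographically smallest v with L[u,v] + D[v,t] == D[u,t]
    next_hop = np.full((n, n), -1, dtype=int)
    for u in range(n):
        # slack[v, t] >= 0, zero iff v is on a shortest path from u to t
        with np.errstate(invalid="ignore"):
            slack = L[u][:, None] + D - D[u][None, :]
            tol = 1e-9 * np.maximum(1.0, np.abs(D[u]))[None, :]
            ok = slack <= tol
        ok[np.isinf(L[u])] = False
        any_ok = ok.any(axis=0)
        first = np.argmax(ok, axis=0)
        next_hop[u] = np.where(any_ok, first, -1)

    SI = np.full((n, n), np.inf)
    np.fill_diagonal(SI, 0.0)
    for t in range(n):
        order = np.argsort(D[:, t], kind="stable")
        for u in order:
            if u == t or np.isinf(D[u, t]):
                continue
            v = next_hop[u, t]
            SI[u, t] = step_cost[u, v] + SI[v, t]
    return SI


# ---------------------------------------------------------------------------
# multilayer community detection


def _modularity_matrices(layers: LayerStack, gamma: float) -> list[np.ndarray]:
    mats = []
    for A in layers.layers:
        k = A.sum(axis=1)
        two_m = k.sum()
        if two_m > 0:
            B = A - gamma * np.outer(k, k) / two_m
        else:
            B = A.copy()
        np.fill_diagonal(B, 0.0)
        mats.append(B)
    return mats


def _local_sweep(
    g: np.ndarray, B: list[np.ndarray], omega: float, order: np.ndarray, next_label: int
) -> tuple[bool, int]:
    """One randomized pass of single node-layer moves; mutates ``g``."""
    L, n = g.shape
    moved = False
    for flat in order:
        l, i = divmod(int(flat), n)
        size = next_label
        gains = np.bincount(g[l], weights=B[l][i], minlength=size)
        if l > 0:
            gains[g[l - 1, i]] += omega
        if l < L - 1:
            gains[g[l + 1, i]] += omega
        cur = g[l, i]
        # gain of leaving the current community (exclude self: B diag is 0)
        best = int(np.argmax(gains))  # argmax takes the lowest index on ties
        if gains[best] < 0.0:
            # a fresh singleton community beats every existing one
            if np.count_nonzero(g[l] == cur) > 1 or (
                (l > 0 and g[l - 1, i] == cur) or (l < L - 1 and g[l + 1, i] == cur)
            ):
                g[l, i] = next_label
                next_label += 1
                moved = True
            continue
        if best != cur and gains[best] > gains[cur] + 1e-12:
            g[l, i] = best
            moved = True
    return moved, next_label


def _merge_communities(g: np.ndarray, B: list[np.ndarray], omega: float) -> bool:
    """Greedy pairwise community merges with positive modularity gain."""
    L, n = g.shape
    labels = np.unique(g)
    k = labels.size
    remap = {lab: idx for idx, lab in enumerate(labels)}
    h = np.vectorize(remap.get)(g)
    # community-pair interaction: intralayer modularity + interlayer coupling
    M = np.zeros((k, k))
    for l in range(L):
        onehot = np.zeros((n, k))
        onehot[np.arange(n), h[l]] = 1.0
        M += onehot.T @ B[l] @ onehot
    for l in range(L - 1):
        for i in range(n):
            M[h[l, i], h[l + 1, i]] += omega
            M[h[l + 1, i], h[l, i]] += omega
    np.fill_diagonal(M, -np.inf)
    merged = False
    while True:
        a, b = np.unravel_index(np.argmax(M), M.shape)
        if not np.isfinite(M[a, b]) or M[a, b] <= 1e-12:
            break
        a, b = min(a, b), max(a, b)
        h[h == b] = a
        M[a, :] += M[b, :]
        M[:, a] += M[:, b]
        M[a, a] = -np.inf
        M[b, :] = -np.inf
        M[:, b] = -np.inf
        merged = True
    g[:] = h
    return merged


def multilayer_modularity(
    layers: LayerStack, g: np.ndarray, gamma: float = 1.0, omega: float = 1.0
) -> float:
    """Value of the (unnormalized) multilayer modularity of a partition."""
    B = _modularity_matrices(layers, gamma)
    L, n = g.shape
    q = 0.0
    for l in range(L):
        same = g[l][:, None] == g[l][None, :]
        q += B[l][same].sum()
    for l in range(L - 1):
        q += 2.0 * omega * np.count_nonzero(g[l] == g[l + 1])
    return float(q)


def multilayer_partition(
    layers: LayerStack,
    gamma: float = 1.0,
    omega: float = 1.0,
    n_runs: int = 100,
    seed: int | np.random.Generator | None = None,
    max_sweeps: int = 50,
) -> PartitionEnsemble:
    """Louvain-style multilayer community detection, ``n_runs`` restarts.

    Each run starts from singleton node-layer communities and alternates
    randomized local moves with greedy community merges until the partition
    stops changing.  The randomized node order is the only stochastic
    element; a seed makes the whole ensemble reproducible.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    B = _modularity_matrices(layers, gamma)
    L, n = len(layers), layers.n_nodes
    runs = np.empty((n_runs, L, n), dtype=int)
    for r in range(n_runs):
        g = np.tile(np.arange(n), (L, 1)) + (np.arange(L) * n)[:, None]
        next_label = L * n
        for _outer in range(10):
            for _ in range(max_sweeps):
                order = rng.permutation(L * n)
                moved, next_label = _local_sweep(g, B, omega, order, next_label)
                if not moved:
                    break
            # merge only once local moves stall, when few communities remain
            merged = _merge_communities(g, B, omega)
            next_label = int(g.max()) + 1
            if not merged:
                break
        _, canon = np.unique(g, return_inverse=True)
        runs[r] = (canon.reshape(L, n) + 1)
    return PartitionEnsemble(runs)


def flexibility(ensemble: PartitionEnsemble) -> np.ndarray:
    """Per-node temporal flexibility in [0, 1], averaged over runs.

    Within a run, a node's flexibility is the number of adjacent-layer
    transitions in which its community changes, divided by L - 1.
    """
    if ensemble.n_layers < 2:
        raise ValueError("flexibility is undefined with a single layer")
    changes = ensemble.labels[:, 1:, :] != ensemble.labels[:, :-1, :]
    return changes.mean(axis=(0, 1))


def allegiance(ensemble: PartitionEnsemble) -> np.ndarray:
    """Module-allegiance matrix P: co-assignment probability per node pair.

    P_ij is the fraction of (layer, run) slices in which nodes i and j
    carry the same community label; symmetric, unit diagonal.
    """
    n = ensemble.n_nodes
    P = np.zeros((n, n))
    flat = ensemble.labels.reshape(-1, n)
    for g in flat:
        P += g[:, None] == g[None, :]
    return P / flat.shape[0]


def recruitment_integration(
    P: np.ndarray, cortex_of_node: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node recruitment (within own cortex) and integration (across).

    ``cortex_of_node`` holds a cortex label per node ('' = unassigned;
    unassigned nodes get NaN and are excluded from the averages of
    assigned nodes).  A cortex with a single node has undefined
    recruitment, reported as NaN.
    """
    n = P.shape[0]
    cortex_of_node = np.asarray(cortex_of_node, dtype=object)
    assigned = cortex_of_node != ""
    rec = np.full(n, np.nan)
    integ = np.full(n, np.nan)
    for i in range(n):
        if not assigned[i]:
            continue
        same = assigned & (cortex_of_node == cortex_of_node[i])
        same[i] = False
        other = assigned & (cortex_of_node != cortex_of_node[i])
        if same.any():
            rec[i] = P[i, same].mean()
        if other.any():
            integ[i] = P[i, other].mean()
    return rec, integ


# ---------------------------------------------------------------------------
# default montage helpers


_PREFIX_RULES = (
    ("FP", "frontal"), ("AF", "frontal"), ("FC", "frontal"),
    ("FT", "temporal"), ("TP", "temporal"),
    ("CP", "parietal"), ("PO", "occipital"),
    ("F", "frontal"), ("T", "temporal"), ("P", "parietal"), ("O", "occipital"),
)


def cortex_from_label(label: str) -> str | None:
    """Map a 10-5-style electrode label to a cortex by its letter prefix.

    Central (C/Cz...) and other unmatched labels return None (unassigned).
    """
    head = "".join(ch for ch in label if ch.isalpha()).upper().rstrip("ZH")
    for prefix, cortex in _PREFIX_RULES:
        if head.startswith(prefix):
            return cortex
    return None


def default_cortex_map(channel_names: list[str]) -> CortexMap:
    """Build a CortexMap from electrode labels using 10-5 prefix rules."""
    assignment = {}
    for name in channel_names:
        cortex = cortex_from_label(name)
        if cortex is not None:
            assignment[name] = cortex
    return CortexMap(assignment)


def synthetic_channel_names(n_channels: int = 124) -> list[str]:
    """Round-robin synthetic electrode labels covering all four cortices.

    Labels follow the frontal/parietal/occipital/temporal prefix letters
    (F1, P1, O1, T1, F2, ...) so :func:`default_cortex_map` assigns every
    channel; they are not a physical montage.
    """
    prefixes = ("F", "P", "O", "T")
    return [f"{prefixes[i % 4]}{i // 4 + 1}" for i in range(n_channels)]


# ---------------------------------------------------------------------------
# feature vector


def extract_eeg_features(
    recording: EEGRecording,
    cortex_map: CortexMap,
    *,
    band: tuple[float, float] = (4.0, 30.0),
    window_length: float = 2.0,
    window_step: float = 2.0,
    gamma: float = 1.0,
    omega: float = 1.0,
    n_runs: int = 100,
    seed: int | np.random.Generator | None = None,
    do_preprocess: bool = True,
) -> dict[str, float]:
    """Compute the 20 cortex-averaged dynamic-network features.

    Strength and search information are computed per layer, averaged over
    layers, then over each cortex's channels (SI over ordered pairs with
    the source in the cortex and any other node as target); flexibility,
    recruitment and integration come from the multilayer partition
    ensemble and the allegiance matrix, averaged per cortex.
    """
    idx = cortex_map.indices(recording.channel_names)
    missing = [c for c in CORTICES if idx[c].size == 0]
    if missing:
        raise ValueError(f"cortex map covers no channels for: {', '.join(missing)}")

    rec = preprocess(recording, band) if do_preprocess else recording
    layers = build_layers(rec, window_length, window_step)

    n = layers.n_nodes
    strength_acc = np.zeros(n)
    si_acc = np.zeros((n, n))
    si_cnt = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for A in layers.layers:
            strength_acc += node_strength(A)
            SI = search_information(A, warn_disconnected=False)
            finite = np.isfinite(SI)
            si_acc[finite] += SI[finite]
            si_cnt += finite
    strength_node = strength_acc / len(layers)
    with np.errstate(invalid="ignore"):
        si_mean = np.where(si_cnt > 0, si_acc / np.maximum(si_cnt, 1), np.nan)

    ensemble = multilayer_partition(layers, gamma, omega, n_runs=n_runs, seed=seed)
    flex_node = flexibility(ensemble)
    P = allegiance(ensemble)
    rec_node, int_node = recruitment_integration(P, cortex_map.node_cortex(recording.channel_names))

    feats: dict[str, float] = {}
    offdiag = ~np.eye(n, dtype=bool)
    for cortex in CORTICES:
        ids = idx[cortex]
        si_rows = si_mean[ids][:, :]  # ordered pairs: source in cortex, any target
        mask = offdiag[ids]
        feats[f"flexibility_{cortex}"] = float(np.nanmean(flex_node[ids]))
        feats[f"integration_{cortex}"] = float(np.nanmean(int_node[ids]))
        feats[f"recruitment_{cortex}"] = float(np.nanmean(rec_node[ids]))
        feats[f"search_information_{cortex}"] = float(np.nanmean(si_rows[mask]))
        feats[f"strength_{cortex}"] = float(np.nanmean(strength_node[ids]))
    return feats
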
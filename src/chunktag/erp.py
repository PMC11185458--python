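"""Test-phase ERP analysis: filtering, epoching, cluster-permutation statistics."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats

from .synth import Recording

__all__ = [
    "EpochSet",
    "Cluster",
    "ClusterTestResult",
    "lowpass",
    "epoch_and_baseline",
    "cluster_permutation",
]


@dataclass
class EpochSet:
    """Trials x channels x samples with a shared epoch time axis.

    ``labels`` carries one row per trial (condition, role, ...). ``n_dropped``
    counts events whose epoch window fell outside the recording.
    """

    data: np.ndarray
    srate: float
    tmin: float
    tmax: float
    labels: pd.DataFrame | None = None
    subject: str | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        expected = int(round((self.tmax - self.tmin) * self.srate)) + 1
        if self.data.shape[2] != expected:
            raise ValueError(
                f"sample count {self.data.shape[2]} != round((tmax-tmin)*srate)+1 = {expected}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.srate


def lowpass(
    data: np.ndarray | Recording,
    cutoff: float = 25.0,
    srate: float | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase (forward-backward) IIR low-pass along the last axis."""
    if isinstance(data, Recording):
        srate = data.srate
        arr = data.data
    else:
        if srate is None:
            raise ValueError("srate is required for plain arrays")
        arr = np.asarray(data, dtype=float)
    if cutoff >= srate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {srate / 2} Hz")
    sos = scipy.signal.butter(order, cutoff, btype="low", fs=srate, output="sos")
    return scipy.signal.sosfiltfilt(sos, arr, axis=-1)


def epoch_and_baseline(
    recording: Recording,
    events: pd.DataFrame,
    roles: tuple[str, ...] = ("dep_second", "dep_second_violation"),
    tmin: float = -0.1,
    tmax: float = 0.3,
    subject: str | None = None,
) -> EpochSet:
    """Cut epochs around events with the given roles; baseline on [tmin, 0].

    Events whose window exceeds the recording bounds are dropped and counted
    in :attr:`EpochSet.n_dropped`.
    """
    sel = events[events["role"].isin(roles)]
    n_pre = int(round(-tmin * recording.srate))
    n_post = int(round(tmax * recording.srate))
    epochs, kept_rows = [], []
    n_dropped = 0
    for _, row in sel.iterrows():
        center = int(round(row["onset_s"] * recording.srate))
        lo, hi = center - n_pre, center + n_post + 1
        if lo < 0 or hi > recording.n_samples:
            n_dropped += 1
            continue
        epochs.append(recording.data[:, lo:hi])
        kept_rows.append(row)
    if epochs:
        data = np.stack(epochs)
        baseline = data[:, :, : n_pre + 1].mean(axis=2, keepdims=True)
        data = data - baseline
        labels = pd.DataFrame(kept_rows).reset_index(drop=True)
    else:
        data = np.empty((0, recording.n_channels, n_pre + n_post + 1))
        labels = sel.iloc[0:0].reset_index(drop=True)
    return EpochSet(
        data=data, srate=recording.srate, tmin=tmin, tmax=tmax,
        labels=labels, subject=subject, n_dropped=n_dropped,
    )


@dataclass
class Cluster:
    """Connected set of suprathreshold (channel, sample) points."""

    members: np.ndarray  # (m, 2) array of [channel, sample]
    mass: float
    sign: int
    p: float = np.nan


@dataclass
class ClusterTestResult:
    tmap: np.ndarray
    clusters: list[Cluster]
    null_distribution: np.ndarray
    alpha: float
    n_permutations: int
    t_threshold: float

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant_clusters(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": i,
                "n_points": len(c.members),
                "mass": c.mass,
                "sign": c.sign,
                "p": c.p,
                "channels": ",".join(map(str, sorted(set(c.members[:, 0])))),
                "sample_range": f"{c.members[:, 1].min()}-{c.members[:, 1].max()}",
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows,
            columns=["cluster", "n_points", "mass", "sign", "p", "channels", "sample_range"],
        )


def _tmaps(signs: np.ndarray, diffs_flat: np.ndarray) -> np.ndarray:
    """Paired t statistics for sign-flipped subject differences.

    ``signs``: (n_perm, n_subj) of +/-1; ``diffs_flat``: (n_subj, n_points).
    Uses the identity that per-subject squares are flip-invariant.
    """
    n = diffs_flat.shape[0]
    mean = signs @ diffs_flat / n
    sumsq = np.sum(diffs_flat**2, axis=0)
    var = (sumsq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _channel_edges(adjacency: np.ndarray) -> np.ndarray:
    i, j = np.nonzero(np.triu(adjacency, k=1))
    return np.column_stack([i, j])


def _find_clusters(
    tmap: np.ndarray,
    t_threshold: float,
    ch_edges: np.ndarray,
    eta: float,
) -> list[Cluster]:
    """Sign-homogeneous connected components of the suprathreshold map.

    Adjacency: same channel & consecutive samples, or adjacent channels &
    same sample.
    """
    n_ch, n_samp = tmap.shape
    mask = np.abs(tmap) > t_threshold
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        return []
    node_of = np.full(n_ch * n_samp, -1, dtype=np.int64)
    node_of[idx] = np.arange(idx.size)
    sign = np.sign(tmap)

    rows, cols = [], []
    # temporal edges
    tm = mask[:, :-1] & mask[:, 1:] & (sign[:, :-1] == sign[:, 1:])
    c, s = np.nonzero(tm)
    rows.append(c * n_samp + s)
    cols.append(c * n_samp + s + 1)
    # spatial edges
    for a, b in ch_edges:
        sm = mask[a] & mask[b] & (sign[a] == sign[b])
        s = np.flatnonzero(sm)
        rows.append(a * n_samp + s)
        cols.append(b * n_samp + s)
    rows = node_of[np.concatenate(rows)]
    cols = node_of[np.concatenate(cols)]

    graph = scipy.sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(idx.size, idx.size)
    )
    n_comp, comp = scipy.sparse.csgraph.connected_components(graph, directed=False)
    weights = np.abs(tmap.ravel()[idx]) ** eta
    masses = np.bincount(comp, weights=weights, minlength=n_comp)
    clusters = []
    for k in range(n_comp):
        members_flat = idx[comp == k]
        members = np.column_stack([members_flat // n_samp, members_flat % n_samp])
        csign = int(sign.ravel()[members_flat[0]])
        clusters.append(Cluster(members=members, mass=float(masses[k]), sign=csign))
    return clusters


def _max_mass(
    tmap: np.ndarray, t_threshold: float, ch_edges: np.ndarray, eta: float
) -> float:
    """Maximum cluster mass of a t map (fast path for sparse null maps)."""
    abs_t = np.abs(tmap)
    mask = abs_t > t_threshold
    if not mask.any():
        return 0.0
    sign = np.sign(tmap)
    has_edges = np.any(mask[:, :-1] & mask[:, 1:] & (sign[:, :-1] == sign[:, 1:]))
    if not has_edges:
        for a, b in ch_edges:
            if np.any(mask[a] & mask[b] & (sign[a] == sign[b])):
                has_edges = True
                break
    if not has_edges:  # all suprathreshold points are singleton clusters
        return float(np.max(abs_t[mask]) ** eta)
    clusters = _find_clusters(tmap, t_threshold, ch_edges, eta)
    return max((c.mass for c in clusters), default=0.0)


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
    eta: float = 1.0,
    exact: bool = False,
) -> ClusterTestResult:
    """Spatio-temporal cluster-permutation test for paired conditions.

    ``cond_a``/``cond_b`` are per-subject mean epochs (subjects x channels x
    samples). Pointwise dependent-sample t statistics are thresholded at the
    two-sided ``alpha_cluster`` level; connected sign-homogeneous clusters are
    scored by mass ``sum |t|**eta``; the null is the maximum cluster mass under
    within-subject condition swaps (sign flips of the paired difference).
    Cluster p is the proportion of null masses >= the observed mass.

    ``exact=True`` enumerates all ``2**n_subjects`` sign assignments instead of
    sampling ``n_perm`` random ones.
    """
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape or cond_a.ndim != 3:
        raise ValueError("cond_a and cond_b must be equal-shape (subjects, channels, samples)")
    n_subj, n_ch, n_samp = cond_a.shape
    if n_subj < 2:
        raise ValueError("at least 2 subjects are required")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency shape must match channel count")

    diffs = (cond_a - cond_b).reshape(n_subj, -1)
    ch_edges = _channel_edges(adjacency)
    t_threshold = float(scipy.stats.t.ppf(1 - alpha_cluster / 2, df=n_subj - 1))

    tmap = _tmaps(np.ones((1, n_subj)), diffs)[0].reshape(n_ch, n_samp)
    clusters = _find_clusters(tmap, t_threshold, ch_edges, eta)

    if exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_subj)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n_subj))
    null = np.empty(signs.shape[0])
    # tmaps for all permutations in one matmul; clustering per permutation
    perm_t = _tmaps(signs, diffs)
    any_supra = np.any(np.abs(perm_t) > t_threshold, axis=1)
    for i in range(signs.shape[0]):
        if not any_supra[i]:
            null[i] = 0.0
            continue
        null[i] = _max_mass(perm_t[i].reshape(n_ch, n_samp), t_threshold, ch_edges, eta)

    for c in clusters:
        c.p = float(np.mean(null >= c.mass))
    return ClusterTestResult(
        tmap=tmap,
        clusters=sorted(clusters, key=lambda c: -c.mass),
        null_distribution=null,
        alpha=alpha_cluster,
        n_permutations=signs.shape[0],
        t_threshold=t_threshold,
    )
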
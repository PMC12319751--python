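"""Sensor-level evaluation of artefact removal: RMSD maps and cluster tests.

The evaluation follows a fixed operation order: epochs are extracted
(0-1500 ms around picture onset), averaged into evoked responses, the two
planar gradiometers of each sensor element are combined by root mean square
(sqrt((a^2 + b^2)/2) per time point), the combined evoked is normalized by
its whole-head maximum, and the per-pair root-mean-square deviation

    RMSD_ch = sqrt( sum_i (EVhat_i,ch - EV_i,ch)^2 / t )

between original (EVhat) and cleaned (EV) responses quantifies the removed
signal.  Statistical differences are assessed with a nonparametric
cluster-based permutation test on pair-combined, per-epoch unit-scaled
epochs (two-sample t, spatio-temporal adjacency clusters, max-cluster-stat
null).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse, stats

from .core_data import (
    ChannelInfo,
    ChannelKind,
    EpochSet,
    Evoked,
    ValidationError,
    average_epochs,
    concat_task,
    extract_epochs,
    pick_channels,
)
from .decomposition import remove_components
from .mi_selection import SelectionOutcome
from .paradigm import Dataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gradiometer pair combination and normalization
# ---------------------------------------------------------------------------


def _pair_groups(channels: Sequence[ChannelInfo]) -> tuple[list[tuple[int, int]], list[ChannelInfo]]:
    by_pair: dict[int, list[int]] = {}
    for i, c in enumerate(channels):
        if c.kind is not ChannelKind.grad:
            raise ValidationError(f"non-gradiometer channel {c.name!r} in pair combination")
        if c.pair_id is None:
            raise ValidationError(f"unpaired gradiometer {c.name!r}")
        by_pair.setdefault(c.pair_id, []).append(i)
    pairs = []
    out_channels = []
    for pid in sorted(by_pair):
        idx = by_pair[pid]
        if len(idx) != 2:
            raise ValidationError(f"pair {pid} has {len(idx)} members")
        pairs.append((idx[0], idx[1]))
        c = channels[idx[0]]
        prefix = c.name[:-1] if c.name[:-1] else c.name
        out_channels.append(
            ChannelInfo(prefix, ChannelKind.grad, pair_id=pid, position=c.position)
        )
    return pairs, out_channels


def _pair_rms(data: np.ndarray, pairs: list[tuple[int, int]], axis: int) -> np.ndarray:
    a = np.take(data, [p[0] for p in pairs], axis=axis)
    b = np.take(data, [p[1] for p in pairs], axis=axis)
    return np.sqrt((a**2 + b**2) / 2.0)


def combine_grad_pairs(evoked: Evoked) -> Evoked:
    """Combine each planar-gradiometer pair by RMS: sqrt((a^2 + b^2)/2)."""
    pairs, out_channels = _pair_groups(evoked.channels)
    return Evoked(
        data=_pair_rms(evoked.data, pairs, axis=0),
        nave=evoked.nave,
        tmin=evoked.tmin,
        sfreq=evoked.sfreq,
        channels=out_channels,
    )


def combine_grad_pairs_epochs(epochs: EpochSet) -> EpochSet:
    """Pair-RMS combination applied epoch-wise (channel axis 1)."""
    pairs, out_channels = _pair_groups(epochs.channels)
    return EpochSet(
        data=_pair_rms(epochs.data, pairs, axis=1),
        tmin=epochs.tmin,
        tmax=epochs.tmax,
        sfreq=epochs.sfreq,
        channels=out_channels,
        event_refs=epochs.event_refs,
        baseline=epochs.baseline,
    )


def normalize_evoked(evoked: Evoked) -> Evoked:
    """Divide by the whole-head maximum (absolute value); idempotent and
    scale-invariant."""
    m = float(np.max(np.abs(evoked.data)))
    if m == 0:
        raise ValidationError("cannot normalize an all-zero evoked response")
    return Evoked(
        data=evoked.data / m,
        nave=evoked.nave,
        tmin=evoked.tmin,
        sfreq=evoked.sfreq,
        channels=list(evoked.channels),
    )


# ---------------------------------------------------------------------------
# RMSD map
# ---------------------------------------------------------------------------


@dataclass
class RmsdMap:
    """Per-gradiometer-pair RMSD between original and cleaned evoked maps."""

    values: np.ndarray
    pair_ids: tuple[int, ...]
    window: tuple[float, float]


def rmsd_map(
    evoked_orig: Evoked,
    evoked_clean: Evoked,
    window: tuple[float, float] = (0.0, 1.5),
) -> RmsdMap:
    """RMSD per channel over the in-window samples ``[window[0], window[1])``.

    Both inputs must already be pair-combined and normalized (the fixed
    evaluation order); channel sets and time grids must match.
    """
    if [c.name for c in evoked_orig.channels] != [c.name for c in evoked_clean.channels]:
        raise ValidationError("evoked channel sets differ")
    if evoked_orig.data.shape != evoked_clean.data.shape or (
        evoked_orig.sfreq != evoked_clean.sfreq
    ):
        raise ValidationError("evoked shapes or sampling rates differ")
    times = evoked_orig.times
    mask = (times >= window[0]) & (times < window[1])
    if not mask.any():
        raise ValidationError("evaluation window contains no samples")
    diff = evoked_orig.data[:, mask] - evoked_clean.data[:, mask]
    values = np.sqrt(np.mean(diff**2, axis=1))
    return RmsdMap(
        values=values,
        pair_ids=tuple(
            c.pair_id if c.pair_id is not None else i
            for i, c in enumerate(evoked_orig.channels)
        ),
        window=window,
    )


# ---------------------------------------------------------------------------
# Per-epoch unit scaling
# ---------------------------------------------------------------------------


def scale_epochs_unit(epochs: EpochSet) -> EpochSet:
    """Scale each epoch by its own maximum over all channels and times.

    Applied after pair combination, so values are >= 0 and each epoch's
    maximum becomes exactly 1.  Zero-maximum epochs are dropped with a
    warning.
    """
    maxima = np.max(np.abs(epochs.data), axis=(1, 2))
    keep = maxima > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-maximum epochs", int(np.sum(~keep)))
    data = epochs.data[keep] / maxima[keep][:, None, None]
    return EpochSet(
        data=data,
        tmin=epochs.tmin,
        tmax=epochs.tmax,
        sfreq=epochs.sfreq,
        channels=list(epochs.channels),
        event_refs=epochs.event_refs[keep],
        baseline=epochs.baseline,
    )


# ---------------------------------------------------------------------------
# Cluster-based permutation test
# ---------------------------------------------------------------------------


def adjacency_from_positions(
    channels: Sequence[ChannelInfo], max_dist: float = 1.5
) -> np.ndarray:
    """Boolean channel adjacency from 2-D layout positions (Euclidean <= max_dist)."""
    pos = np.array(
        [c.position if c.position is not None else (np.nan, np.nan) for c in channels]
    )
    if np.any(np.isnan(pos)):
        raise ValidationError("all channels need layout positions for adjacency")
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    adj = (d <= max_dist) & ~np.eye(len(channels), dtype=bool)
    return adj


@dataclass
class ClusterTestResult:
    """Spatio-temporal clusters with permutation p-values.

    ``clusters`` holds boolean masks [n_channels, n_times]; ``p_values``
    follow the (1 + #{null >= obs}) / (n_perm + 1) convention, so they lie
    in [1/(n_perm+1), 1].
    """

    clusters: list[np.ndarray]
    cluster_stats: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    alpha: float
    threshold: float
    channel_names: tuple[str, ...]
    times: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def any_significant(self) -> bool:
        return bool(np.any(self.significant))

    @property
    def significant_channels(self) -> tuple[str, ...]:
        names: set[str] = set()
        for mask, sig in zip(self.clusters, self.significant):
            if sig:
                names.update(
                    self.channel_names[i] for i in np.flatnonzero(mask.any(axis=1))
                )
        return tuple(sorted(names))

    @property
    def significant_time_range(self) -> tuple[float, float] | None:
        hit = np.zeros(len(self.times), dtype=bool)
        for mask, sig in zip(self.clusters, self.significant):
            if sig:
                hit |= mask.any(axis=0)
        if not hit.any():
            return None
        idx = np.flatnonzero(hit)
        return float(self.times[idx[0]]), float(self.times[idx[-1]])


def _connected_clusters(
    supra: np.ndarray, adjacency: np.ndarray
) -> list[np.ndarray]:
    """Connected components of supra-threshold (channel, time) nodes under
    channel adjacency x temporal contiguity."""
    n_ch, n_t = supra.shape
    flat = np.flatnonzero(supra.ravel())
    if len(flat) == 0:
        return []
    local = -np.ones(n_ch * n_t, dtype=np.int64)
    local[flat] = np.arange(len(flat))
    rows, cols = [], []
    # temporal edges
    tmask = supra[:, :-1] & supra[:, 1:]
    src = np.flatnonzero(np.pad(tmask, ((0, 0), (0, 1))).ravel())
    rows.extend(local[src])
    cols.extend(local[src + 1])
    # spatial edges
    ai, aj = np.nonzero(np.triu(adjacency, k=1))
    for c1, c2 in zip(ai, aj):
        both = supra[c1] & supra[c2]
        ts = np.flatnonzero(both)
        rows.extend(local[c1 * n_t + ts])
        cols.extend(local[c2 * n_t + ts])
    graph = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(flat), len(flat))
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    masks = []
    for c in range(n_comp):
        mask = np.zeros(n_ch * n_t, dtype=bool)
        mask[flat[labels == c]] = True
        masks.append(mask.reshape(n_ch, n_t))
    return masks


def _tmap(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Pooled two-sample t statistic from sufficient statistics."""
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    var_a = (sumsq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (sumsq_b - n_b * mean_b**2) / (n_b - 1)
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    denom = np.sqrt(np.maximum(pooled, 1e-300) * (1 / n_a + 1 / n_b))
    return (mean_a - mean_b) / denom


def cluster_permutation_test(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.001,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Two-sample cluster-based permutation test over (channel, time).

    Pointwise two-sample t maps are thresholded at the two-sided t quantile
    for ``cluster_alpha``; supra-threshold nodes are clustered under channel
    adjacency x temporal contiguity (positive and negative tails
    separately); the cluster statistic is the summed t; the null is the
    permutation distribution of the maximum |cluster statistic|.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if [c.name for c in epochs_a.channels] != [c.name for c in epochs_b.channels]:
        raise ValidationError("epoch channel sets differ")
    if epochs_a.data.shape[1:] != epochs_b.data.shape[1:]:
        raise ValidationError("epoch grids differ")
    n_ch, n_t = epochs_a.data.shape[1:]
    if adjacency.shape != (n_ch, n_ch):
        raise ValidationError("adjacency must cover all channels")
    n_a, n_b = epochs_a.n_epochs, epochs_b.n_epochs
    if n_a < 2 or n_b < 2:
        raise ValidationError("need at least 2 epochs per condition")

    X = np.concatenate([epochs_a.data, epochs_b.data]).reshape(n_a + n_b, -1)
    X2 = X**2
    df = n_a + n_b - 2
    threshold = float(stats.t.ppf(1 - cluster_alpha / 2, df))

    def max_cluster_stat(tmap_flat: np.ndarray) -> float:
        tmap = tmap_flat.reshape(n_ch, n_t)
        best = 0.0
        for sign in (1.0, -1.0):
            for mask in _connected_clusters(sign * tmap > threshold, adjacency):
                best = max(best, abs(float(tmap[mask].sum())))
        return best

    obs_t = _tmap(
        X[:n_a].sum(0), X2[:n_a].sum(0), n_a, X[n_a:].sum(0), X2[n_a:].sum(0), n_b
    ).reshape(n_ch, n_t)
    clusters: list[np.ndarray] = []
    cluster_stats: list[float] = []
    for sign in (1.0, -1.0):
        for mask in _connected_clusters(sign * obs_t > threshold, adjacency):
            clusters.append(mask)
            cluster_stats.append(float(obs_t[mask].sum()))

    rng = np.random.default_rng(seed)
    total, total2 = X.sum(0), X2.sum(0)
    null = np.empty(n_perm)
    for p in range(n_perm):
        idx = rng.permutation(n_a + n_b)[:n_a]
        sa, sa2 = X[idx].sum(0), X2[idx].sum(0)
        t_p = _tmap(sa, sa2, n_a, total - sa, total2 - sa2, n_b)
        null[p] = max_cluster_stat(t_p)

    stats_arr = np.asarray(cluster_stats)
    p_values = np.array(
        [(1 + np.sum(null >= abs(s))) / (n_perm + 1) for s in stats_arr]
    )
    return ClusterTestResult(
        clusters=clusters,
        cluster_stats=stats_arr,
        p_values=p_values,
        n_permutations=n_perm,
        alpha=alpha,
        threshold=threshold,
        channel_names=tuple(c.name for c in epochs_a.channels),
        times=epochs_a.times,
    )


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalParams:
    window: tuple[float, float] = (0.0, 1.5)
    n_perm: int = 1000
    alpha: float = 0.001
    cluster_alpha: float = 0.05
    adjacency_max_dist: float = 1.5
    seed: int = 0


@dataclass
class TaskEvaluation:
    task: str
    rmsd: RmsdMap
    test: ClusterTestResult
    evoked_orig: Evoked
    evoked_clean: Evoked
    n_epochs: int

    @property
    def significant(self) -> bool:
        return self.test.any_significant


@dataclass
class RemovalReport:
    """Evaluation of one selection on the vocal and silent naming tasks.

    The expected pattern of a successful removal is significant
    original-vs-cleaned differences in the vocal task and none in the
    silent task.
    """

    vocal: TaskEvaluation
    silent: TaskEvaluation
    selected_ics: tuple[int, ...]
    selection_warnings: tuple[str, ...]

    @property
    def expected_pattern(self) -> bool:
        return self.vocal.significant and not self.silent.significant

    def to_dict(self) -> dict:
        def task_dict(te: TaskEvaluation) -> dict:
            rng = te.test.significant_time_range
            return {
                "n_epochs": te.n_epochs,
                "rmsd_per_pair": te.rmsd.values.tolist(),
                "rmsd_max": float(te.rmsd.values.max()) if len(te.rmsd.values) else 0.0,
                "n_clusters": len(te.test.clusters),
                "n_significant_clusters": int(np.sum(te.test.significant)),
                "significant": te.significant,
                "significant_channels": list(te.test.significant_channels),
                "significant_time_range_s": list(rng) if rng else None,
                "p_values": te.test.p_values.tolist(),
            }

        return {
            "selected_ics": list(self.selected_ics),
            "selection_warnings": list(self.selection_warnings),
            "expected_pattern": self.expected_pattern,
            "vocal": task_dict(self.vocal),
            "silent": task_dict(self.silent),
        }


def evaluate_removal(
    dataset: Dataset,
    outcome: SelectionOutcome,
    params: EvalParams | None = None,
) -> RemovalReport:
    """Project out the elected components and evaluate on vocal and silent tasks.

    For each task: extract 0-1500 ms picture epochs from the original and
    cleaned naming data, average, pair-combine, normalize, compute the RMSD
    map, and run the cluster permutation test on pair-combined unit-scaled
    epochs (original vs cleaned).
    """
    params = params or EvalParams()
    segments = dataset.naming_segments
    if not segments:
        raise ValidationError("dataset has no naming runs")
    recording, events = concat_task(
        [s.recording for s in segments], [s.events for s in segments]
    )
    grad = pick_channels(recording, {ChannelKind.grad})
    cleaned = remove_components(grad, outcome.ica, set(outcome.selection.selected_ics))

    evaluations = {}
    for task in ("vocal", "silent"):
        ep_orig = extract_epochs(grad, events, *params.window, task=task)
        ep_clean = extract_epochs(cleaned, events, *params.window, task=task)
        if ep_orig.n_epochs == 0:
            raise ValidationError(f"no epochs for task {task!r}")
        ev_orig = normalize_evoked(combine_grad_pairs(average_epochs(ep_orig)))
        ev_clean = normalize_evoked(combine_grad_pairs(average_epochs(ep_clean)))
        rmsd = rmsd_map(ev_orig, ev_clean, window=params.window)
        pc_orig = scale_epochs_unit(combine_grad_pairs_epochs(ep_orig))
        pc_clean = scale_epochs_unit(combine_grad_pairs_epochs(ep_clean))
        adjacency = adjacency_from_positions(
            pc_orig.channels, params.adjacency_max_dist
        )
        test = cluster_permutation_test(
            pc_orig,
            pc_clean,
            adjacency,
            n_perm=params.n_perm,
            alpha=params.alpha,
            cluster_alpha=params.cluster_alpha,
            seed=params.seed,
        )
        evaluations[task] = TaskEvaluation(
            task=task,
            rmsd=rmsd,
            test=test,
            evoked_orig=ev_orig,
            evoked_clean=ev_clean,
            n_epochs=ep_orig.n_epochs,
        )
    return RemovalReport(
        vocal=evaluations["vocal"],
        silent=evaluations["silent"],
        selected_ics=outcome.selection.selected_ics,
        selection_warnings=outcome.selection.warnings,
    )
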
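"""Artefact-component selection by EMG/IC mutual information and k-means.

This is the heart of the pipeline.  For every pair of an ICA-decomposed MEG
source s_i and a task-restricted EMG principal component y_j, the mutual
information

    I(s_i; y_j) = integral p(s,y) log[ p(s,y) / (p(s) p(y)) ]

is estimated with the Kraskov-Stoegbauer-Grassberger k-nearest-neighbour
estimator (k = 3 by default) and normalized to the MI correlation
coefficient

    rho_I = 1 - exp(-2 I)  in [0, 1).

The per-IC rho profiles (one row per (task, EMG-PC) pair: 4 rows for the
naming-only variant, 8 for gesture+naming) are clustered with k-means
(k = 5); all ICs in the cluster with the highest mean MI sum are elected
for removal.  The elbow curve of k-means inertia over k supports choosing
the cluster count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import ndtri, psi
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .core_data import ChannelKind, ValidationError, concat_task, pick_channels
from .decomposition import EmgPcs, IcaModel, emg_pca, fit_ica, get_sources
from .paradigm import Dataset

logger = logging.getLogger(__name__)

#: elected cluster flagged oversize when it holds more than this fraction of ICs
OVERSIZE_FRACTION = 0.25
#: elected cluster flagged low-contrast when its mean MI sum does not exceed
#: the median per-IC MI sum by at least this much per matrix row
LOW_CONTRAST_MARGIN_PER_ROW = 0.1


# ---------------------------------------------------------------------------
# kNN mutual information (KSG algorithm 1)
# ---------------------------------------------------------------------------


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Map a sample to marginal normality via its ranks."""
    n = len(x)
    return ndtri(rankdata(x) / (n + 1))


def knn_mi(
    x: np.ndarray,
    y: np.ndarray,
    k_nn: int = 3,
    *,
    normalize_marginals: bool = True,
    seed: int = 0,
) -> float:
    """KSG (algorithm 1) mutual-information estimate in nats.

    I = psi(k) + psi(n) - < psi(n_x + 1) + psi(n_y + 1) >, where n_x/n_y
    count neighbours strictly inside the Chebyshev ball reaching the k-th
    joint neighbour.  Inputs are rank-transformed to marginal normality
    first (the estimate is invariant to strictly monotone marginal
    transforms, so this only improves numerical behaviour), and ties are
    broken by an infinitesimal seeded jitter.  The estimate is clipped
    below at 0.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValidationError("knn_mi inputs must have equal length")
    n = len(x)
    if n <= k_nn:
        raise ValidationError(f"need more than k_nn={k_nn} samples, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("knn_mi inputs must be finite")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        logger.warning("constant input to knn_mi; returning 0")
        return 0.0
    rng = np.random.default_rng(seed)
    x = x + 1e-10 * sx * rng.standard_normal(n)
    y = y + 1e-10 * sy * rng.standard_normal(n)
    if normalize_marginals:
        x = _rank_normalize(x)
        y = _rank_normalize(y)

    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k_nn + 1, p=np.inf)
    eps = dist[:, k_nn]
    xs, ys = np.sort(x), np.sort(y)
    # counts of |x_i - x_j| < eps_i include the point itself, i.e. n_x + 1
    nx1 = np.searchsorted(xs, x + eps, "left") - np.searchsorted(xs, x - eps, "right")
    ny1 = np.searchsorted(ys, y + eps, "left") - np.searchsorted(ys, y - eps, "right")
    mi = psi(k_nn) + psi(n) - float(np.mean(psi(nx1) + psi(ny1)))
    return max(mi, 0.0)


def mi_coefficient(mi: float) -> float:
    """MI correlation coefficient rho_I = 1 - exp(-2 I), strictly increasing
    in I with range [0, 1).  Negative estimates (estimator noise) are
    clipped to 0 with a warning."""
    if mi < 0:
        logger.warning("negative MI %.4g clipped to 0", mi)
        mi = 0.0
    return 1.0 - float(np.exp(-2.0 * mi))


# ---------------------------------------------------------------------------
# MI matrix
# ---------------------------------------------------------------------------


@dataclass
class MiMatrix:
    """Normalized MI values, rows = (task, EMG-PC) pairs, columns = ICs."""

    values: np.ndarray  # [n_rows, n_ic], entries in [0, 1)
    row_index: list[tuple[str, int]]
    ic_index: list[int]
    k_nn: int

    @property
    def n_ic(self) -> int:
        return self.values.shape[1]

    def mi_sum(self) -> np.ndarray:
        """Per-IC sum of rho over all rows."""
        return self.values.sum(axis=0)


TASK_ORDER = ("gesture", "vocal")


def build_mi_matrix(
    sources_by_task: Mapping[str, np.ndarray],
    emg_pcs_by_task: Mapping[str, EmgPcs],
    k_nn: int = 3,
    max_samples: int = 20000,
    seed: int = 0,
) -> MiMatrix:
    """MI matrix between task-restricted IC sources and EMG PCs.

    One value per (task, EMG-PC, IC) triple over the concatenated task
    samples; series longer than ``max_samples`` are uniformly subsampled
    (seeded) for tractability.  Only the gesture and vocal-naming tasks
    enter (silent naming and observation carry no informative EMG).
    """
    tasks = [t for t in TASK_ORDER if t in sources_by_task]
    if set(sources_by_task) - set(TASK_ORDER):
        raise ValidationError(
            f"unsupported tasks {sorted(set(sources_by_task) - set(TASK_ORDER))}"
        )
    if set(sources_by_task) != set(emg_pcs_by_task):
        raise ValidationError("tasks of sources and EMG PCs must match")
    rng = np.random.default_rng(seed)
    rows = []
    row_index: list[tuple[str, int]] = []
    n_ic = None
    for task in tasks:
        src = np.asarray(sources_by_task[task])
        pcs = emg_pcs_by_task[task]
        if src.shape[1] != pcs.components.shape[1]:
            raise ValidationError(
                f"task {task!r}: sources have {src.shape[1]} samples but EMG PCs "
                f"have {pcs.components.shape[1]}"
            )
        if n_ic is None:
            n_ic = src.shape[0]
        elif src.shape[0] != n_ic:
            raise ValidationError("IC count differs across tasks")
        n = src.shape[1]
        if n > max_samples:
            idx = np.sort(rng.choice(n, size=max_samples, replace=False))
            src = src[:, idx]
            comps = pcs.components[:, idx]
        else:
            comps = pcs.components
        for j in range(comps.shape[0]):
            row = np.empty(n_ic)
            for i in range(n_ic):
                row[i] = mi_coefficient(
                    knn_mi(src[i], comps[j], k_nn=k_nn, seed=seed)
                )
            rows.append(row)
            row_index.append((task, j))
    return MiMatrix(
        values=np.vstack(rows),
        row_index=row_index,
        ic_index=list(range(n_ic or 0)),
        k_nn=k_nn,
    )


# ---------------------------------------------------------------------------
# k-means selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Outcome of clustering the per-IC MI profiles.

    ``selected_ics`` are all ICs of the cluster with the highest mean MI
    sum.  ``warnings`` flags degenerate or suspicious selections
    ('oversize', 'degenerate', 'low_contrast'); a selection is confident
    when no warnings were raised.
    """

    k_clusters: int
    labels: np.ndarray
    mi_sum: np.ndarray
    selected_cluster: int
    selected_ics: tuple[int, ...]
    inertia_curve: dict[int, float]
    seed: int
    warnings: tuple[str, ...] = ()

    @property
    def confident(self) -> bool:
        return not self.warnings


def cluster_components(
    mi_matrix: MiMatrix, k_clusters: int = 5, seed: int = 0, n_init: int = 10
) -> SelectionResult:
    """K-means over the per-IC MI profile vectors; elect the cluster with the
    highest mean MI sum.

    Ties between clusters are broken by the higher maximum MI sum, then the
    lower cluster id.  The elected cluster is flagged 'oversize' beyond 25 %
    of the ICs, 'degenerate' when all profiles coincide, and 'low_contrast'
    when its mean MI sum barely exceeds the median IC's.
    """
    if k_clusters < 2:
        raise ValidationError("k_clusters must be >= 2")
    features = mi_matrix.values.T  # [n_ic, n_rows]
    n_ic = features.shape[0]
    if n_ic < k_clusters:
        raise ValidationError(f"need at least k_clusters={k_clusters} ICs, got {n_ic}")
    flags: list[str] = []
    if np.allclose(features, features[0], atol=1e-12):
        flags.append("degenerate")
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        km = KMeans(n_clusters=k_clusters, n_init=n_init, random_state=seed).fit(features)
    labels = km.labels_
    mi_sum = mi_matrix.mi_sum()
    means = np.full(k_clusters, -np.inf)
    maxes = np.full(k_clusters, -np.inf)
    for c in range(k_clusters):
        members = mi_sum[labels == c]
        if len(members):
            means[c] = members.mean()
            maxes[c] = members.max()
    order = sorted(
        range(k_clusters), key=lambda c: (-means[c], -maxes[c], c)
    )
    selected = order[0]
    selected_ics = tuple(int(i) for i in np.flatnonzero(labels == selected))
    if len(selected_ics) > OVERSIZE_FRACTION * n_ic:
        flags.append("oversize")
        logger.warning(
            "elected cluster holds %d of %d ICs (> %.0f%%); selection is suspect",
            len(selected_ics),
            n_ic,
            100 * OVERSIZE_FRACTION,
        )
    n_rows = mi_matrix.values.shape[0]
    if means[selected] - np.median(mi_sum) < LOW_CONTRAST_MARGIN_PER_ROW * n_rows:
        flags.append("low_contrast")
        logger.warning("elected cluster is not clearly separated from the bulk")
    return SelectionResult(
        k_clusters=k_clusters,
        labels=labels,
        mi_sum=mi_sum,
        selected_cluster=int(selected),
        selected_ics=selected_ics,
        inertia_curve={k_clusters: float(km.inertia_)},
        seed=seed,
        warnings=tuple(flags),
    )


def elbow_curve(
    mi_matrix: MiMatrix,
    k_range: Sequence[int] = tuple(range(2, 21)),
    seed: int = 0,
    n_init: int = 10,
) -> dict[int, float]:
    """K-means inertia (sum of squared distances to the closest center) per k."""
    features = mi_matrix.values.T
    if max(k_range) > features.shape[0]:
        raise ValidationError("max(k_range) exceeds the number of ICs")
    import warnings as _w

    curve: dict[int, float] = {}
    for k in k_range:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(features)
        curve[int(k)] = float(km.inertia_)
    return curve


# ---------------------------------------------------------------------------
# Variant orchestration
# ---------------------------------------------------------------------------

VARIANT_ALIASES = {
    "n": "N",
    "N": "N",
    "naming": "N",
    "gn": "GN",
    "GN": "GN",
    "gesture-naming": "GN",
}


@dataclass(frozen=True)
class SelectionParams:
    """Tunable parameters of the selection stage with their standard defaults."""

    var_threshold: float = 0.9999
    k_nn: int = 3
    k_clusters: int = 5
    max_mi_samples: int = 20000
    ica_max_iter: int = 1000
    ica_tol: float = 1e-4
    emg_highpass_hz: float | None = None
    seed: int = 0


@dataclass
class SelectionOutcome:
    """Full provenance of one selection run."""

    variant: str
    selection: SelectionResult
    ica: IcaModel
    mi_matrix: MiMatrix
    params: SelectionParams

    def report(self) -> str:
        """Human-readable per-IC summary."""
        lines = [
            f"variant: {self.variant}",
            f"n_ic: {self.ica.n_ic} (converged: {self.ica.converged})",
            f"selected cluster: {self.selection.selected_cluster}",
            f"selected ICs: {list(self.selection.selected_ics)}",
            f"warnings: {list(self.selection.warnings) or 'none'}",
            "",
            f"{'IC':>4} {'cluster':>8} {'mi_sum':>8}  selected",
        ]
        for i in range(self.ica.n_ic):
            mark = "*" if i in self.selection.selected_ics else ""
            lines.append(
                f"{i:>4} {self.selection.labels[i]:>8} "
                f"{self.selection.mi_sum[i]:>8.3f}  {mark}"
            )
        return "\n".join(lines)


def select_artefacts(
    dataset: Dataset,
    variant: str,
    params: SelectionParams | None = None,
) -> SelectionOutcome:
    """Run the full selection for one variant.

    The naming-only variant (N) fits the ICA on the concatenated naming runs
    and builds MI rows from the vocal-naming task; the gesture+naming
    variant (GN) prepends the gesture segment to the ICA fit and adds the
    gesture-task MI rows.  Observation and silent-naming samples never enter
    the MI estimation.
    """
    params = params or SelectionParams()
    try:
        variant = VARIANT_ALIASES[variant]
    except KeyError:
        raise ValidationError(
            f"unknown variant {variant!r}; use 'N' or 'GN'"
        ) from None

    segments = list(dataset.naming_segments)
    if not segments:
        raise ValidationError("dataset has no naming runs")
    if variant == "GN":
        gesture = dataset.gesture_segment
        if gesture is None:
            raise ValidationError("variant GN requires a gesture segment")
        segments = [gesture] + segments

    recording, events = concat_task(
        [s.recording for s in segments], [s.events for s in segments]
    )
    grad = pick_channels(recording, {ChannelKind.grad})
    emg = pick_channels(recording, {ChannelKind.emg})

    ica = fit_ica(
        grad,
        seed=params.seed,
        max_iter=params.ica_max_iter,
        tol=params.ica_tol,
        var_threshold=params.var_threshold,
    )
    sources = get_sources(ica, grad)

    tasks = ["vocal"] if variant == "N" else ["gesture", "vocal"]
    sources_by_task: dict[str, np.ndarray] = {}
    emg_pcs_by_task: dict[str, EmgPcs] = {}
    for task in tasks:
        mask = events.task_mask(task, recording.n_samples)
        if not mask.any():
            raise ValidationError(f"no samples for task {task!r}")
        sources_by_task[task] = sources[:, mask]
        from .core_data import Recording as _Recording

        emg_task = _Recording(
            sfreq=emg.sfreq, channels=list(emg.channels), data=emg.data[:, mask]
        )
        emg_pcs_by_task[task] = emg_pca(
            emg_task, task, highpass_hz=params.emg_highpass_hz
        )

    mi_matrix = build_mi_matrix(
        sources_by_task,
        emg_pcs_by_task,
        k_nn=params.k_nn,
        max_samples=params.max_mi_samples,
        seed=params.seed,
    )
    selection = cluster_components(
        mi_matrix, k_clusters=params.k_clusters, seed=params.seed
    )
    return SelectionOutcome(
        variant=variant,
        selection=selection,
        ica=ica,
        mi_matrix=mi_matrix,
        params=params,
    )
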
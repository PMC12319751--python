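"""PCA pre-whitening, FastICA decomposition, EMG PCA and component removal.

The MEG data (gradiometers only) are whitened by a PCA keeping the smallest
number of components explaining >= 99.99 % of the variance, then decomposed
with FastICA (log-cosh contrast, symmetric decorrelation).  The number of
independent components equals the number of retained PCs.  Facial EMG is
decomposed per task with an ordinary (rotation-only) PCA, keeping as many
components as channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .core_data import ChannelKind, Recording, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class Whitener:
    """PCA whitening transform: ``z = projection @ (x - mean)`` has identity
    covariance on the training data."""

    mean: np.ndarray  # [n_channels]
    projection: np.ndarray  # [n_pc, n_channels]
    explained_variance_ratio: np.ndarray  # full spectrum, not truncated
    n_pc: int

    def transform(self, data: np.ndarray) -> np.ndarray:
        return self.projection @ (data - self.mean[:, None])


def fit_whitener(data: np.ndarray, var_threshold: float = 0.9999) -> Whitener:
    """Fit a PCA whitener on ``[n_channels, n_samples]`` data.

    ``n_pc`` is the smallest count whose cumulative explained-variance ratio
    reaches ``var_threshold``.  If numerical rank-deficiency makes the
    threshold unreachable, the full numerical rank is kept with a warning.
    """
    data = np.asarray(data, dtype=np.float64)
    n_ch, n_samples = data.shape
    if n_samples <= n_ch:
        raise ValidationError("need more samples than channels to fit a whitener")
    mean = data.mean(axis=1)
    centered = data - mean[:, None]
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / (n_samples - 1)
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    rank = int(np.sum(var > var[0] * 1e-12)) if var[0] > 0 else 0
    if rank == 0:
        raise ValidationError("data has zero variance")
    reachable = np.flatnonzero(cum >= var_threshold - 1e-12)
    if len(reachable) == 0 or reachable[0] + 1 > rank:
        logger.warning(
            "variance threshold %.6f unreachable at numerical rank %d; keeping full rank",
            var_threshold,
            rank,
        )
        n_pc = rank
    else:
        n_pc = int(reachable[0]) + 1
    projection = (u[:, :n_pc] / np.sqrt(var[:n_pc])).T
    return Whitener(
        mean=mean, projection=projection, explained_variance_ratio=ratio, n_pc=n_pc
    )


@dataclass
class IcaModel:
    """Whitening + unmixing/mixing pair mapping sensors to independent
    components and back.  ``mixing`` is the pseudo-inverse sensor-space map;
    its columns are the component topographies."""

    whitener: Whitener
    unmixing: np.ndarray  # [n_ic, n_pc]
    mixing: np.ndarray  # [n_channels, n_ic]
    n_ic: int
    seed: int
    converged: bool
    n_iter: int
    channel_names: tuple[str, ...]


def fit_ica(
    recording: Recording,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-4,
    var_threshold: float = 0.9999,
) -> IcaModel:
    """FastICA on a gradiometer-only recording, whitened internally.

    Symmetric (parallel) fixed-point iteration with the log-cosh contrast;
    deterministic given ``seed``.  A non-convergent fit is returned with
    ``converged=False`` and a warning rather than retried.
    """
    if any(c.kind is not ChannelKind.grad for c in recording.channels):
        raise ValidationError("fit_ica expects a gradiometer-only recording")
    whitener = fit_whitener(recording.data, var_threshold)
    z = whitener.transform(recording.data)  # [n_pc, n_samples]
    ica = FastICA(
        n_components=whitener.n_pc,
        algorithm="parallel",
        fun="logcosh",
        whiten=False,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(z.T)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        converged = False
        logger.warning("FastICA did not converge within %d iterations", max_iter)
    unmixing = np.asarray(ica.components_)
    # sign convention: largest-|.| entry of each mixing column positive
    mixing = np.linalg.pinv(unmixing @ whitener.projection)
    signs = np.sign(mixing[np.argmax(np.abs(mixing), axis=0), np.arange(mixing.shape[1])])
    signs[signs == 0] = 1.0
    unmixing *= signs[:, None]
    mixing *= signs[None, :]
    return IcaModel(
        whitener=whitener,
        unmixing=unmixing,
        mixing=mixing,
        n_ic=whitener.n_pc,
        seed=seed,
        converged=converged,
        n_iter=int(getattr(ica, "n_iter_", 0)),
        channel_names=tuple(recording.channel_names()),
    )


def get_sources(ica: IcaModel, recording: Recording) -> np.ndarray:
    """Component time courses ``[n_ic, n_samples]`` (unmixing of whitened data)."""
    if tuple(recording.channel_names()) != ica.channel_names:
        raise ValidationError("recording channels do not match the fitted ICA model")
    return ica.unmixing @ ica.whitener.transform(recording.data)


def remove_components(
    recording: Recording, ica: IcaModel, exclude: set[int] | frozenset[int]
) -> Recording:
    """Reconstruct the recording from the non-excluded components.

    The output is the PCA-truncated reconstruction with the excluded
    component contributions projected out, plus the channel means.
    """
    exclude = set(exclude)
    if not exclude <= set(range(ica.n_ic)):
        raise ValidationError(f"invalid component indices: {sorted(exclude)}")
    if len(exclude) == ica.n_ic:
        raise ValidationError("refusing to remove all components (would null the data)")
    sources = get_sources(ica, recording)
    keep = sorted(set(range(ica.n_ic)) - exclude)
    clean = ica.whitener.mean[:, None] + ica.mixing[:, keep] @ sources[keep]
    return Recording(
        sfreq=recording.sfreq,
        channels=list(recording.channels),
        data=clean,
        first_sample_time=recording.first_sample_time,
        seams=recording.seams,
    )


@dataclass
class EmgPcs:
    """Task-restricted EMG principal components (one PC per channel)."""

    task: str
    components: np.ndarray  # [n_emg_pc, n_samples], variance-ordered
    loadings: np.ndarray  # [n_emg_pc, n_channels]
    explained_variance: np.ndarray


def emg_pca(
    emg_recording: Recording, task: str, highpass_hz: float | None = None
) -> EmgPcs:
    """Full PCA of the (task-restricted) EMG channels.

    Rotation-only: components are variance-ordered projections without
    rescaling.  A constant channel yields a zero-variance PC which is kept
    with a warning.  ``highpass_hz`` optionally conditions the EMG with a
    zero-phase high-pass before the PCA; by default the recorded band is
    used as-is.
    """
    if emg_recording.n_channels < 2:
        raise ValidationError("EMG PCA needs at least 2 channels")
    data = emg_recording.data
    if highpass_hz is not None:
        from scipy import signal

        sos = signal.butter(
            4, highpass_hz, btype="highpass", fs=emg_recording.sfreq, output="sos"
        )
        data = signal.sosfiltfilt(sos, data, axis=1)
    centered = data - data.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / max(centered.shape[1] - 1, 1)
    if np.any(var <= var[0] * 1e-15):
        logger.warning("EMG contains (near-)constant channels; zero-variance PCs retained")
    components = u.T @ centered  # rotation only, no variance scaling
    return EmgPcs(task=task, components=components, loadings=u.T, explained_variance=var)


# ---------------------------------------------------------------------------
# Model serialization (fixture container /models group)
# ---------------------------------------------------------------------------


def save_ica(ica: IcaModel, path: str | Path) -> None:
    with h5py.File(path, "a") as f:
        if "models" in f:
            del f["models"]
        g = f.create_group("models/ica")
        g.create_dataset("mean", data=ica.whitener.mean)
        g.create_dataset("projection", data=ica.whitener.projection)
        g.create_dataset(
            "explained_variance_ratio", data=ica.whitener.explained_variance_ratio
        )
        g.create_dataset("unmixing", data=ica.unmixing)
        g.create_dataset("mixing", data=ica.mixing)
        g.create_dataset(
            "channel_names", data=np.array(ica.channel_names, dtype="S64")
        )
        g.attrs["n_pc"] = ica.whitener.n_pc
        g.attrs["n_ic"] = ica.n_ic
        g.attrs["seed"] = ica.seed
        g.attrs["converged"] = ica.converged
        g.attrs["n_iter"] = ica.n_iter


def load_ica(path: str | Path) -> IcaModel:
    with h5py.File(path, "r") as f:
        if "models/ica" not in f:
            raise IOError(f"{path}: no /models/ica group")
        g = f["models/ica"]
        whitener = Whitener(
            mean=g["mean"][()],
            projection=g["projection"][()],
            explained_variance_ratio=g["explained_variance_ratio"][()],
            n_pc=int(g.attrs["n_pc"]),
        )
        return IcaModel(
            whitener=whitener,
            unmixing=g["unmixing"][()],
            mixing=g["mixing"][()],
            n_ic=int(g.attrs["n_ic"]),
            seed=int(g.attrs["seed"]),
            converged=bool(g.attrs["converged"]),
            n_iter=int(g.attrs["n_iter"]),
            channel_names=tuple(n.decode() for n in g["channel_names"][()]),
        )
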
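"""Spike averaging, EEG/MEG fusion, sLORETA localization and ROI export.

The inverse stage turns epoched recordings into averaged evoked data,
whitens each channel by its baseline noise so EEG (microvolts) and MEG
(femtotesla) become commensurable, localizes activity with sLORETA at
chosen latencies relative to the spike peak, thresholds the F-value map at a
fraction of its maximum, groups supra-threshold nodes into clusters, and
exports each cluster peak as an axis-aligned cuboid ROI for targeted
high-resolution imaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .fem import LeadfieldSet
from .phantom import ChannelMeta, RawTrials

logger = logging.getLogger(__name__)

__all__ = [
    "EvokedData",
    "InverseConfig",
    "SourceEstimate",
    "Cluster",
    "RoiBox",
    "average_spikes",
    "whiten",
    "combine_emeg",
    "sloreta",
    "localize_at",
    "threshold_clusters",
    "roi_box",
    "dipole_scan_goal",
]


@dataclass
class EvokedData:
    """Averaged multichannel time series with per-channel noise statistics."""

    data: np.ndarray  # channels x time
    channel_meta: list[ChannelMeta]
    sampling_rate: float
    time_zero: int  # sample index of the spike/SEP peak (0 ms convention)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or len(self.channel_meta) != self.data.shape[0]:
            raise ValueError("data must be channels x time matching channel_meta")
        if any(m.noise_std <= 0 for m in self.channel_meta):
            raise ValueError("noise_std must be > 0 for every channel")

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.data.shape[1]) - self.time_zero) * 1000.0 / self.sampling_rate

    @property
    def modalities(self) -> np.ndarray:
        return np.array([m.modality for m in self.channel_meta])

    def sample_at(self, latency_ms: float) -> int:
        idx = self.time_zero + latency_ms * self.sampling_rate / 1000.0
        j = int(round(idx))
        if not 0 <= j < self.data.shape[1]:
            raise ValueError(f"latency {latency_ms} ms is outside the data window")
        return j

    def topography(self, latency_ms: float) -> np.ndarray:
        return self.data[:, self.sample_at(latency_ms)]

    def noise_std(self) -> np.ndarray:
        return np.array([m.noise_std for m in self.channel_meta])


@dataclass(frozen=True)
class InverseConfig:
    """sLORETA and clustering parameters.

    ``threshold_fraction`` keeps nodes with F >= fraction * max(F) (the
    85 %-of-maximum display convention).  ``analysis_latencies`` default to
    -7 ms ("near spike peak", the middle of the rising flank) and -23 ms
    (the earlier peak preceding the spike).
    """

    lambda_value: float | None = None  # fixed Tikhonov weight; None -> SNR rule
    lambda_relative: float | None = None  # lambda = rel * trace(L L^T) / n_sensors
    threshold_fraction: float = 0.85
    analysis_latencies: tuple[float, ...] = (-7.0, -23.0)
    min_cluster_size: int = 5
    adjacency_factor: float = 1.5

    def __post_init__(self):
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must be in (0, 1]")


@dataclass
class Cluster:
    nodes: np.ndarray  # source-node indices
    peak_node: int
    peak_f: float


@dataclass
class SourceEstimate:
    """Per-source-node sLORETA pseudo-F values with optional clusters."""

    f_values: np.ndarray
    positions: np.ndarray  # (n_src, 3) mm
    spacing: float
    latency_ms: float
    modality_set: str  # 'EEG' | 'MEG' | 'EMEG'
    clusters: list[Cluster] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.f_values < -1e-12):
            raise ValueError("F values must be nonnegative")
        self.f_values = np.clip(self.f_values, 0.0, None)

    @property
    def peak_position(self) -> np.ndarray:
        return self.positions[int(np.argmax(self.f_values))]


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned cuboid ROI for a zoomed acquisition (mm)."""

    center: np.ndarray
    extents: tuple[float, float, float] = (160.0, 82.0, 28.0)

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if any(e <= 0 for e in self.extents):
            raise ValueError("extents must be > 0")

    @property
    def lower(self) -> np.ndarray:
        return self.center - np.asarray(self.extents) / 2.0

    @property
    def upper(self) -> np.ndarray:
        return self.center + np.asarray(self.extents) / 2.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lower) & (p <= self.upper), axis=1)


# ---------------------------------------------------------------------------
# averaging and fusion
# ---------------------------------------------------------------------------


def average_spikes(
    trials: RawTrials,
    markers: np.ndarray | None = None,
    window_ms: tuple[float, float] = (-170.0, 120.0),
    baseline_ms: tuple[float, float] = (-165.0, -115.0),
) -> EvokedData:
    """Marker-aligned average of epoched trials.

    ``markers`` are per-trial sample indices of the spike peak (default: the
    simulation's nominal event latency for every trial).  The per-channel
    noise standard deviation of the *average* is estimated from the
    pre-onset baseline segment.
    """
    n_chan, n_time, n_trials = trials.data.shape
    if markers is None:
        markers = np.full(n_trials, trials.event_latency, dtype=int)
    markers = np.asarray(markers, dtype=int)
    if len(markers) != n_trials or len(markers) < 1:
        raise ValueError("need one marker per trial")
    dt = 1000.0 / trials.sampling_rate
    lo = int(round(window_ms[0] / dt))
    hi = int(round(window_ms[1] / dt))
    if np.any(markers + lo < 0) or np.any(markers + hi >= n_time):
        raise ValueError("marker-aligned window extends beyond the trial bounds")
    seg = np.stack([trials.data[:, m + lo : m + hi + 1, k] for k, m in enumerate(markers)], axis=2)
    avg = seg.mean(axis=2)
    time_zero = -lo
    times = (np.arange(avg.shape[1]) + lo) * dt
    bsel = (times >= baseline_ms[0]) & (times <= baseline_ms[1])
    if bsel.sum() < 10:
        raise ValueError("baseline window too short to estimate noise")
    noise = avg[:, bsel].std(axis=1, ddof=1)
    noise = np.where(noise > 0, noise, np.finfo(float).tiny)
    meta = [replace(m, noise_std=float(s)) for m, s in zip(trials.channel_meta, noise)]
    return EvokedData(avg, meta, trials.sampling_rate, time_zero)


def whiten(evoked: EvokedData, leadfield: LeadfieldSet) -> tuple[EvokedData, LeadfieldSet]:
    """Divide each channel of data and leadfield by the channel's noise std.

    After whitening both modalities are dimensionless with unit noise
    variance, so their rows can be stacked into one joint inverse problem.
    """
    std = evoked.noise_std()
    if leadfield.matrix.shape[0] != len(std):
        raise ValueError("evoked channels and leadfield rows do not match")
    data = evoked.data / std[:, None]
    meta = [replace(m, noise_std=1.0) for m in evoked.channel_meta]
    lf = LeadfieldSet(
        matrix=leadfield.matrix / std[:, None],
        row_modality=leadfield.row_modality.copy(),
        row_names=list(leadfield.row_names),
        source_positions=leadfield.source_positions,
        source_nearest_node=leadfield.source_nearest_node,
        spacing=leadfield.spacing,
        units={m: "noise-sd/nAm" for m in np.unique(leadfield.row_modality)},
    )
    return EvokedData(data, meta, evoked.sampling_rate, evoked.time_zero), lf


def combine_emeg(
    eeg: EvokedData,
    meg: EvokedData,
    eeg_lf: LeadfieldSet,
    meg_lf: LeadfieldSet,
) -> tuple[EvokedData, LeadfieldSet]:
    """Noise-whitened EEG+MEG fusion into one joint problem (EEG rows first)."""
    if eeg.sampling_rate != meg.sampling_rate or eeg.time_zero != meg.time_zero:
        raise ValueError("EEG and MEG evoked data are not time-aligned")
    if eeg.data.shape[1] != meg.data.shape[1]:
        raise ValueError("EEG and MEG evoked data have different lengths")
    if eeg_lf.source_space_hash() != meg_lf.source_space_hash():
        raise ValueError("leadfields were computed on different source spaces")
    we, wle = whiten(eeg, eeg_lf)
    wm, wlm = whiten(meg, meg_lf)
    data = np.vstack([we.data, wm.data])
    meta = we.channel_meta + wm.channel_meta
    lf = LeadfieldSet(
        matrix=np.vstack([wle.matrix, wlm.matrix]),
        row_modality=np.concatenate([wle.row_modality, wlm.row_modality]),
        row_names=wle.row_names + wlm.row_names,
        source_positions=eeg_lf.source_positions,
        source_nearest_node=eeg_lf.source_nearest_node,
        spacing=eeg_lf.spacing,
        units=wle.units | wlm.units,
    )
    return EvokedData(data, meta, eeg.sampling_rate, eeg.time_zero), lf


# ---------------------------------------------------------------------------
# sLORETA
# ---------------------------------------------------------------------------


def _blockwise_quadratic(blocks: np.ndarray, vecs: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """q_j = v_j^T pinv(S_j) v_j for stacks of symmetric 3x3 blocks.

    The pseudoinverse handles rank-deficient blocks (e.g. the radially
    silent direction of MEG in near-spherical geometry).
    """
    w, V = np.linalg.eigh(blocks)
    vmax = w[:, -1:]
    keep = w > rtol * np.clip(vmax, 1e-300, None)
    c = np.einsum("njk,nj->nk", V, vecs)
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    return np.einsum("nk,nk->n", c**2, winv)


def sloreta(
    leadfield: LeadfieldSet,
    topography: np.ndarray,
    config: InverseConfig = InverseConfig(),
    latency_ms: float = 0.0,
    modality_set: str | None = None,
) -> SourceEstimate:
    """Standardized low-resolution electromagnetic tomography.

    The minimum-norm estimate ``s = L^T (L L^T + lambda I)^-1 y`` is
    standardized per node by the corresponding 3x3 diagonal block of the
    resolution-derived variance ``S_j = L_j^T (L L^T + lambda I)^-1 L_j``,
    yielding the nonnegative pseudo-F value ``F_j = s_j^T S_j^+ s_j``.
    F is invariant under positive rescaling of the topography and, for a
    single noiseless source with lambda -> 0, attains its maximum exactly at
    the true node.

    With ``config.lambda_value is None`` the Tikhonov weight follows the
    whitened-data SNR rule ``lambda = trace(L L^T) / (n_sensors * snr^2)``
    with ``snr^2`` estimated as ``max(||y||^2 / n_sensors - 1, 1e-6)``
    (whitened noise has unit variance per channel).
    """
    y = np.asarray(topography, float).ravel()
    L = leadfield.matrix
    if L.shape[0] != len(y):
        raise ValueError("topography length does not match leadfield rows")
    if not np.any(y):
        raise ValueError("all-zero topography")
    n_sens = L.shape[0]
    gram = L @ L.T
    if config.lambda_value is not None:
        lam = float(config.lambda_value)
        if lam < 0:
            raise ValueError("lambda must be >= 0")
    elif config.lambda_relative is not None:
        lam = float(config.lambda_relative) * np.trace(gram) / n_sens
    else:
        snr2 = max(float(y @ y) / n_sens - 1.0, 1e-6)
        lam = np.trace(gram) / (n_sens * snr2)
    reg = gram + lam * np.eye(n_sens)
    try:
        from scipy.linalg import cho_factor, cho_solve

        cf = cho_factor(reg)
        g = cho_solve(cf, y)
        W = cho_solve(cf, L)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "gram matrix is rank-deficient; use a positive lambda_value"
        ) from exc
    n_src = leadfield.n_sources
    L3 = L.reshape(n_sens, n_src, 3)
    W3 = W.reshape(n_sens, n_src, 3)
    S = np.einsum("inj,ink->njk", L3, W3)  # resolution blocks
    shat = np.einsum("inj,i->nj", L3, g)  # minimum-norm estimate per node
    F = _blockwise_quadratic(S, shat)
    if modality_set is None:
        mods = sorted(set(np.unique(leadfield.row_modality)))
        modality_set = "EMEG" if len(mods) > 1 else mods[0].upper()
    return SourceEstimate(
        f_values=F,
        positions=leadfield.source_positions,
        spacing=leadfield.spacing,
        latency_ms=latency_ms,
        modality_set=modality_set,
    )


def localize_at(
    evoked: EvokedData,
    leadfield: LeadfieldSet,
    latency_ms: float,
    config: InverseConfig = InverseConfig(),
) -> SourceEstimate:
    """sLORETA at one latency, thresholded and clustered."""
    est = sloreta(leadfield, evoked.topography(latency_ms), config, latency_ms=latency_ms)
    return threshold_clusters(est, config)


def threshold_clusters(est: SourceEstimate, config: InverseConfig = InverseConfig()) -> SourceEstimate:
    """Group supra-threshold nodes into spatial clusters.

    Nodes with F >= threshold_fraction * max(F) are connected when closer
    than ``adjacency_factor * spacing``; connected components smaller than
    ``min_cluster_size`` are discarded; clusters are sorted by peak F
    descending.
    """
    if est.f_values.size == 0:
        raise ValueError("empty source estimate")
    fmax = est.f_values.max()
    sel = np.flatnonzero(est.f_values >= config.threshold_fraction * fmax)
    clusters: list[Cluster] = []
    if len(sel):
        pos = est.positions[sel]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(config.adjacency_factor * est.spacing, output_type="ndarray")
        n = len(sel)
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, comp = connected_components(adj, directed=False)
        for c in range(n_comp):
            nodes = sel[comp == c]
            if len(nodes) < config.min_cluster_size:
                continue
            peak = nodes[int(np.argmax(est.f_values[nodes]))]
            clusters.append(Cluster(nodes=nodes, peak_node=int(peak), peak_f=float(est.f_values[peak])))
        clusters.sort(key=lambda cl: -cl.peak_f)
    out = SourceEstimate(
        f_values=est.f_values,
        positions=est.positions,
        spacing=est.spacing,
        latency_ms=est.latency_ms,
        modality_set=est.modality_set,
        clusters=clusters,
    )
    return out


def roi_box(cluster_peak_mm, extents: tuple[float, float, float] = (160.0, 82.0, 28.0)) -> RoiBox:
    """Axis-aligned cuboid centered at a cluster peak (default the zoomed-
    acquisition extents 160 x 82 x 28 mm)."""
    return RoiBox(center=np.asarray(cluster_peak_mm, float), extents=tuple(float(e) for e in extents))


def dipole_scan_goal(leadfield: LeadfieldSet, topography: np.ndarray) -> np.ndarray:
    """Residual variance of a single-dipole fit at every source node.

    RV_j = 1 - ||P_j y||^2 / ||y||^2 with P_j the projector onto the
    3-column leadfield subspace of node j; RV is in [0, 1] and invariant to
    rescaling of the data.
    """
    y = np.asarray(topography, float).ravel()
    yy = float(y @ y)
    if yy == 0:
        raise ValueError("all-zero topography")
    L3 = leadfield.matrix.reshape(len(y), leadfield.n_sources, 3)
    G = np.einsum("inj,ink->njk", L3, L3)
    c = np.einsum("inj,i->nj", L3, y)
    explained = _blockwise_quadratic(G, c)
    rv = 1.0 - explained / yy
    return np.clip(rv, 0.0, 1.0)
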
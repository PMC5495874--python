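"""Synthetic inputs: layered-sphere head phantoms, sensor arrays, diffusion
tensors and simulated EEG/MEG recordings.

The phantom stands in for the segmented MRI, digitized sensor montage and
measured data of a real presurgical work-up.  Everything is generated from a
:class:`SphereSpec` (concentric tissue shells with literature conductivities)
so that the finite-element forward solution can be validated against analytic
sphere oracles, and the inverse/calibration stages can be exercised with known
ground truth.

Conventions
-----------
* All coordinates are RAS millimetres; voxel ``[i, j, k]`` occupies the
  half-open box ``origin + [i, i+1) x [j, j+1) x [k, k+1) * voxel_size``.
* Dipole moments are in nA*m, EEG in microvolts, MEG in femtotesla.
* Every stochastic operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Shell",
    "SphereSpec",
    "LabeledVoxelGrid",
    "SensorArray",
    "DipoleSource",
    "TensorField",
    "SpikeSimConfig",
    "ChannelMeta",
    "RawTrials",
    "four_shell_spec",
    "seven_compartment_spec",
    "voxelize_sphere_model",
    "make_sensor_array",
    "synthesize_dti_tensors",
    "fa_eigenvalue_ratio",
    "spike_waveform",
    "sep_waveform",
    "simulate_sep_recordings",
    "simulate_ied_recordings",
]

#: Literature tissue conductivities in S/m.  The skull values are the
#: individually calibrated pair reported for the modeled patient group;
#: the white-matter isotropic reference is the effective-medium literature
#: value (not individually calibrated).
TISSUE_CONDUCTIVITY = {
    "scalp": 0.43,
    "skull_compacta": 0.0033,
    "skull_spongiosa": 0.0116,
    "dura": 0.1,
    "csf": 1.79,
    "gm": 0.33,
    "wm": 0.14,
}


@dataclass(frozen=True)
class Shell:
    """One concentric tissue shell, delimited by its outer radius."""

    outer_radius: float  # mm
    tissue: str
    conductivity: float  # S/m


@dataclass(frozen=True)
class SphereSpec:
    """Concentric-shell head model, shells ordered outermost to innermost."""

    center: np.ndarray  # (3,) mm
    shells: tuple[Shell, ...]

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector in mm")
        if len(self.shells) < 2:
            raise ValueError("need at least 2 shells")
        radii = [s.outer_radius for s in self.shells]
        if not all(a > b for a, b in zip(radii, radii[1:])):
            raise ValueError(f"shell radii must be strictly decreasing, got {radii}")
        if any(s.conductivity <= 0 for s in self.shells):
            raise ValueError("conductivities must be > 0")

    @property
    def radii(self) -> np.ndarray:
        return np.array([s.outer_radius for s in self.shells])

    @property
    def conductivities(self) -> np.ndarray:
        return np.array([s.conductivity for s in self.shells])

    @property
    def outer_radius(self) -> float:
        return self.shells[0].outer_radius

    def label_table(self) -> dict[int, str]:
        """Integer label per shell; label ``i+1`` is the i-th shell (outer first)."""
        return {i + 1: s.tissue for i, s in enumerate(self.shells)}

    def conductivity_table(self) -> dict[int, float]:
        return {i + 1: s.conductivity for i, s in enumerate(self.shells)}

    def innermost_label(self) -> int:
        return len(self.shells)

    def label_of(self, tissue: str) -> int:
        for i, s in enumerate(self.shells):
            if s.tissue == tissue:
                return i + 1
        raise KeyError(tissue)


def four_shell_spec(
    center=(0.0, 0.0, 0.0),
    radii=(92.0, 86.0, 80.0, 78.0),
    conductivities=(0.43, 0.0033, 1.79, 0.33),
    tissues=("scalp", "skull_compacta", "csf", "gm"),
) -> SphereSpec:
    """Classic 4-shell sphere: scalp, (homogenized) skull, CSF, brain/GM."""
    shells = tuple(Shell(r, t, c) for r, t, c in zip(radii, tissues, conductivities))
    return SphereSpec(np.asarray(center, float), shells)


def seven_compartment_spec(center=(0.0, 0.0, 0.0), radii=(92.0, 88.0, 85.0, 81.5, 80.0, 78.0, 70.0)) -> SphereSpec:
    """Concentric stand-in for the seven-compartment head model.

    Shells outer to inner: scalp, skull compacta, skull spongiosa, dura,
    CSF, GM, WM.  Real skulls sandwich spongiosa between two compacta
    layers; the concentric simplification keeps one compacta layer.
    """
    tissues = ("scalp", "skull_compacta", "skull_spongiosa", "dura", "csf", "gm", "wm")
    shells = tuple(Shell(r, t, TISSUE_CONDUCTIVITY[t]) for r, t in zip(radii, tissues))
    return SphereSpec(np.asarray(center, float), shells)


@dataclass
class LabeledVoxelGrid:
    """3-D tissue-label volume in mm space (the geometry substrate)."""

    labels: np.ndarray  # (nx, ny, nz) int
    voxel_size: float  # mm, isotropic
    origin: np.ndarray  # (3,) mm corner of voxel (0,0,0)
    label_table: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels without a table entry: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self) -> np.ndarray:
        """(nx,ny,nz,3) array of voxel-center coordinates in mm."""
        idx = np.indices(self.shape).astype(float)
        return self.origin + (np.moveaxis(idx, 0, -1) + 0.5) * self.voxel_size


@dataclass
class SensorArray:
    """EEG electrode positions and MEG coil geometry (mm, RAS)."""

    eeg_positions: np.ndarray  # (n_eeg, 3)
    eeg_labels: list[str]
    meg_centers: np.ndarray  # (n_meg, 3)
    meg_orientations: np.ndarray  # (n_meg, 3) unit vectors
    meg_labels: list[str]
    meg_type: str = "magnetometer"  # or "axial_gradiometer"
    baseline: float | None = None  # mm, gradiometer only
    reference: str = "average"

    def __post_init__(self):
        self.eeg_positions = np.atleast_2d(np.asarray(self.eeg_positions, float))
        self.meg_centers = np.atleast_2d(np.asarray(self.meg_centers, float))
        self.meg_orientations = np.atleast_2d(np.asarray(self.meg_orientations, float))
        if len(self.meg_orientations):
            norms = np.linalg.norm(self.meg_orientations, axis=1)
            if np.any(np.abs(norms - 1) > 1e-8):
                raise ValueError("MEG orientations must be unit-norm")
        if self.meg_type not in ("magnetometer", "axial_gradiometer"):
            raise ValueError(f"unknown meg_type {self.meg_type!r}")
        if self.meg_type == "axial_gradiometer" and not self.baseline:
            raise ValueError("axial_gradiometer requires a baseline")

    @property
    def n_eeg(self) -> int:
        return len(self.eeg_positions)

    @property
    def n_meg(self) -> int:
        return len(self.meg_centers)


@dataclass(frozen=True)
class DipoleSource:
    """Point current dipole: position in mm, moment in nA*m."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "moment", np.asarray(self.moment, float))
        if self.position.shape != (3,) or self.moment.shape != (3,):
            raise ValueError("position and moment must be 3-vectors")


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 tensors on a labeled grid.

    ``kind='diffusion'`` stores mm^2/s, ``kind='conductivity'`` S/m.
    """

    grid: LabeledVoxelGrid
    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    kind: str

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, float)
        if self.tensors.shape != self.grid.shape + (3, 3):
            raise ValueError("tensor array must be grid.shape + (3, 3)")
        if self.kind not in ("diffusion", "conductivity"):
            raise ValueError(f"unknown tensor kind {self.kind!r}")


# ---------------------------------------------------------------------------
# geometry synthesis
# ---------------------------------------------------------------------------


def voxelize_sphere_model(spec: SphereSpec, voxel_size: float, shape) -> LabeledVoxelGrid:
    """Rasterize a concentric-shell spec onto a voxel grid.

    A voxel is labeled by the innermost shell whose outer radius exceeds the
    distance from the voxel center to the sphere center.  Centers exactly on
    a shell boundary belong to the *outer* side of that boundary (so a center
    exactly on the outermost radius is outside, label 0) -- a deterministic,
    documented tie-break.

    The grid is centered on the sphere; the sphere must fit with at least one
    voxel of margin on every side.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError("shape must be 3 positive integers")
    half_extent = np.array(shape) * voxel_size / 2.0
    R = spec.outer_radius
    if np.any(R + voxel_size > half_extent):
        raise ValueError(
            f"sphere of radius {R} mm does not fit in the grid "
            f"(half extents {half_extent} mm) with a 1-voxel margin"
        )
    origin = spec.center - half_extent
    idx = np.indices(shape).astype(float)
    centers = origin + (np.moveaxis(idx, 0, -1) + 0.5) * voxel_size
    dist = np.linalg.norm(centers - spec.center, axis=-1)
    radii = spec.radii  # descending
    # label = count of shells with outer_radius > dist (strict: ties go outward)
    labels = (radii[:, None, None, None] > dist[None]).sum(axis=0).astype(np.int16)
    return LabeledVoxelGrid(labels, voxel_size, origin, spec.label_table())


def _fibonacci_cap(n: int, z_min: float) -> np.ndarray:
    """n unit vectors spread on the spherical cap z in [z_min, 1] (golden spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - (1.0 - z_min) * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def make_sensor_array(
    spec: SphereSpec,
    n_eeg: int = 80,
    n_meg: int = 275,
    meg_standoff: float = 20.0,
    meg_type: str = "axial_gradiometer",
    baseline: float | None = 50.0,
) -> SensorArray:
    """Quasi-uniform sensor montage over the upper 3/4 of the phantom sphere.

    EEG electrodes sit on the outer surface, MEG coils at ``outer radius +
    standoff`` with radially outward orientations.  Defaults mirror a
    whole-head axial-gradiometer system with an 80-channel EEG cap.
    """
    if n_eeg < 1 or n_meg < 1:
        raise ValueError("need at least one sensor per modality")
    if meg_standoff <= 0:
        raise ValueError("meg_standoff must be > 0")
    R = spec.outer_radius
    # upper 3/4 of the sphere's solid angle: cos(theta) from 1 down to -0.5
    eeg_dirs = _fibonacci_cap(n_eeg, -0.5)
    meg_dirs = _fibonacci_cap(n_meg, -0.5)
    baseline = None if meg_type == "magnetometer" else baseline
    return SensorArray(
        eeg_positions=spec.center + R * eeg_dirs,
        eeg_labels=[f"E{i:03d}" for i in range(1, n_eeg + 1)],
        meg_centers=spec.center + (R + meg_standoff) * meg_dirs,
        meg_orientations=meg_dirs,
        meg_labels=[f"M{i:03d}" for i in range(1, n_meg + 1)],
        meg_type=meg_type,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# diffusion tensors
# ---------------------------------------------------------------------------


def fa_eigenvalue_ratio(fa: float) -> float:
    """Eigenvalue ratio t = lambda1/lambda23 of a prolate axially symmetric
    tensor with fractional anisotropy ``fa``.

    Closed form from FA(t) = (t - 1) / sqrt(t**2 + 2) solved for t >= 1.
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must be in [0, 1)")
    return (1.0 + fa * np.sqrt(3.0 - 2.0 * fa**2)) / (1.0 - fa**2)


def synthesize_dti_tensors(
    grid: LabeledVoxelGrid,
    wm_label: int,
    fa: float = 0.7,
    direction_field: str = "tangential",
    mean_diffusivity: float = 7e-4,
    center=None,
) -> TensorField:
    """Axially symmetric diffusion tensors in WM, isotropic elsewhere.

    ``direction_field`` sets the principal eigenvector per WM voxel:

    * ``"tangential"`` -- perpendicular to the radial direction (emulating
      fibers running along the cortical surface),
    * ``"radial"`` -- along the radial direction,
    * ``"uniform_z"`` -- constant +z.

    Mean diffusivity is constant everywhere (default 0.7e-3 mm^2/s, typical
    parenchyma), so only the anisotropy varies.
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must be in [0, 1)")
    if direction_field not in ("tangential", "radial", "uniform_z"):
        raise ValueError(f"unknown direction field {direction_field!r}")
    shape = grid.shape
    tensors = np.zeros(shape + (3, 3))
    iso = mean_diffusivity * np.eye(3)
    tensors[...] = iso
    wm = grid.labels == wm_label
    if fa == 0 or not wm.any():
        return TensorField(grid, tensors, "diffusion")

    t = fa_eigenvalue_ratio(fa)
    lam23 = 3.0 * mean_diffusivity / (t + 2.0)
    lam1 = t * lam23

    centers = grid.voxel_centers()[wm]
    if center is None:
        center = centers.mean(axis=0)
    rad = centers - np.asarray(center, float)
    rn = np.linalg.norm(rad, axis=1, keepdims=True)
    rhat = np.divide(rad, rn, out=np.tile([[0.0, 0.0, 1.0]], (len(rad), 1)), where=rn > 1e-9)
    if direction_field == "radial":
        e1 = rhat
    elif direction_field == "uniform_z":
        e1 = np.tile([[0.0, 0.0, 1.0]], (len(rad), 1))
    else:  # tangential: z-hat x rhat, with x-hat fallback near the poles
        e1 = np.cross(np.tile([[0.0, 0.0, 1.0]], (len(rad), 1)), rhat)
        n = np.linalg.norm(e1, axis=1, keepdims=True)
        polar = (n < 1e-6)[:, 0]
        if polar.any():
            e1[polar] = np.cross([1.0, 0.0, 0.0], rhat[polar])
            n = np.linalg.norm(e1, axis=1, keepdims=True)
        e1 /= n
    outer = np.einsum("ni,nj->nij", e1, e1)
    tensors[wm] = lam23 * np.eye(3) + (lam1 - lam23) * outer
    return TensorField(grid, tensors, "diffusion")


# ---------------------------------------------------------------------------
# simulated recordings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelMeta:
    name: str
    modality: str  # 'eeg' | 'meg'
    noise_std: float


@dataclass
class RawTrials:
    """Epoched simulated recordings: channels x time x trials."""

    data: np.ndarray
    channel_meta: list[ChannelMeta]
    sampling_rate: float
    event_latency: int  # sample index of the nominal spike/SEP peak

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x time x trials")
        if len(self.channel_meta) != self.data.shape[0]:
            raise ValueError("channel_meta length must match channel dimension")

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms with 0 at the event latency."""
        return (np.arange(self.n_times) - self.event_latency) * 1000.0 / self.sampling_rate


@dataclass(frozen=True)
class SpikeSimConfig:
    """Two-focus interictal-discharge simulation parameters.

    The onset focus fires first; the propagation (peak) focus follows after
    ``delay`` ms and dominates the signal peak, emulating fast interictal
    propagation between two epileptogenic lesions.
    """

    onset_source: DipoleSource
    peak_source: DipoleSource
    delay: float = 23.0  # ms
    n_trials: int = 10
    snr_eeg: float = 5.0
    snr_meg: float = 5.0
    sampling_rate: float = 1000.0
    seed: int = 0
    waveform_width: float = 9.0  # ms, main-lobe Gaussian sigma
    waveform_support: float = 70.0  # ms

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.snr_eeg <= 0 or self.snr_meg <= 0:
            raise ValueError("SNRs must be > 0")


def spike_waveform(times_ms: np.ndarray, peak_ms: float, width: float = 9.0, support: float = 70.0) -> np.ndarray:
    """Biphasic spike template: sharp positive lobe + shallow after-wave.

    Unit peak amplitude at ``peak_ms``; compact support of roughly
    ``support`` ms centered slightly after the peak (spikes trail a slow
    wave).  The template is smooth, so sub-sample peak alignment errors stay
    negligible at >= 1 kHz sampling.
    """
    t = np.asarray(times_ms, float) - peak_ms
    main = np.exp(-0.5 * (t / width) ** 2)
    after = -0.45 * np.exp(-0.5 * ((t - 0.3 * support) / (2.2 * width)) ** 2)
    w = main + after
    w[np.abs(t) > 1.2 * support] = 0.0
    return w / np.max(np.abs(main + after))


def sep_waveform(times_ms: np.ndarray, peak_ms: float = 20.0, width: float = 4.0) -> np.ndarray:
    """Unimodal early-cortical-response template (P20/N20-like), unit peak."""
    t = np.asarray(times_ms, float) - peak_ms
    return np.exp(-0.5 * (t / width) ** 2)


def _leadfield_topography(leadfields, source: DipoleSource) -> tuple[np.ndarray, int]:
    """Sensor topography of a dipole via its nearest source-space node."""
    pos = leadfields.source_positions
    j = int(np.argmin(np.linalg.norm(pos - source.position, axis=1)))
    snap = np.linalg.norm(pos[j] - source.position)
    if snap > 2.0 * leadfields.source_spacing_hint():
        raise ValueError(
            f"source at {source.position} is {snap:.1f} mm from the nearest "
            "source-space node; outside the source-space hull?"
        )
    topo = leadfields.matrix[:, 3 * j : 3 * j + 3] @ source.moment
    return topo, j


def _modality_noise_std(topo_peak: np.ndarray, modalities: np.ndarray, snr_eeg: float, snr_meg: float) -> np.ndarray:
    """Per-channel noise std giving the requested peak-amplitude SNR.

    SNR is defined per modality as RMS(peak topography) / noise std, with a
    common std within each modality.
    """
    std = np.zeros(len(modalities))
    for mod, snr in (("eeg", snr_eeg), ("meg", snr_meg)):
        sel = modalities == mod
        if sel.any():
            rms = np.sqrt(np.mean(topo_peak[sel] ** 2))
            if rms == 0:
                raise ValueError(f"zero {mod} signal; cannot set SNR")
            std[sel] = rms / snr
    return std


def simulate_sep_recordings(
    leadfields,
    source: DipoleSource,
    snr_eeg: float = 20.0,
    snr_meg: float = 20.0,
    n_trials: int = 100,
    seed: int = 0,
    sampling_rate: float = 1200.0,
    duration_ms: float = 60.0,
    peak_ms: float = 20.0,
) -> RawTrials:
    """Simulate single-trial somatosensory evoked recordings.

    Each trial is the dipole topography modulated by a unimodal waveform
    peaking ``peak_ms`` after stimulus, plus i.i.d. Gaussian channel noise
    scaled so the *single-trial* peak-amplitude SNR matches the request per
    modality.  Averaging n trials therefore raises SNR by sqrt(n).
    """
    topo, _ = _leadfield_topography(leadfields, source)
    n_times = int(round(duration_ms * sampling_rate / 1000.0)) + 1
    times = np.arange(n_times) * 1000.0 / sampling_rate
    wave = sep_waveform(times, peak_ms=peak_ms)
    peak_idx = int(np.argmax(wave))
    modalities = np.asarray(leadfields.row_modality)
    std = _modality_noise_std(topo * wave[peak_idx], modalities, snr_eeg, snr_meg)
    rng = np.random.default_rng(seed)
    signal = topo[:, None] * wave[None, :]
    data = signal[:, :, None] + std[:, None, None] * rng.standard_normal((len(topo), n_times, n_trials))
    meta = [
        ChannelMeta(name, mod, s if s > 0 else 1.0)
        for name, mod, s in zip(leadfields.row_names, modalities, std)
    ]
    return RawTrials(data, meta, sampling_rate, event_latency=peak_idx)


def simulate_ied_recordings(leadfields, config: SpikeSimConfig) -> RawTrials:
    """Simulate two-focus interictal discharges with a propagation delay.

    The onset source's waveform precedes the peak source's by
    ``config.delay`` ms; the event latency marks the peak source's waveform
    maximum.  The delay must be an integer number of samples.
    """
    dt_ms = 1000.0 / config.sampling_rate
    delay_samples = config.delay / dt_ms
    if abs(delay_samples - round(delay_samples)) > 1e-9:
        near = round(delay_samples) * dt_ms
        raise ValueError(
            f"delay {config.delay} ms is not a whole number of samples at "
            f"{config.sampling_rate} Hz; nearest representable is {near:g} ms"
        )
    topo_on, _ = _leadfield_topography(leadfields, config.onset_source)
    topo_pk, _ = _leadfield_topography(leadfields, config.peak_source)

    pre_ms, post_ms = 2.2 * config.waveform_support + config.delay, 2.2 * config.waveform_support
    n_times = int(round((pre_ms + post_ms) / dt_ms)) + 1
    times = np.arange(n_times) * dt_ms
    wave_pk = spike_waveform(times, pre_ms, config.waveform_width, config.waveform_support)
    wave_on = spike_waveform(times, pre_ms - config.delay, config.waveform_width, config.waveform_support)
    event_latency = int(np.argmax(wave_pk))

    signal = topo_pk[:, None] * wave_pk[None, :] + topo_on[:, None] * wave_on[None, :]
    modalities = np.asarray(leadfields.row_modality)
    # SNR is referenced to the strongest instant of the noiseless signal
    ref = signal[:, int(np.argmax(np.linalg.norm(signal, axis=0)))]
    std = _modality_noise_std(ref, modalities, config.snr_eeg, config.snr_meg)
    rng = np.random.default_rng(config.seed)
    data = signal[:, :, None] + std[:, None, None] * rng.standard_normal(
        (len(signal), n_times, config.n_trials)
    )
    meta = [
        ChannelMeta(name, mod, s if s > 0 else 1.0)
        for name, mod, s in zip(leadfields.row_names, modalities, std)
    ]
    return RawTrials(data, meta, config.sampling_rate, event_latency=event_latency)
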
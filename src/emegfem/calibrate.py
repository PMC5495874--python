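"""Combined EEG/MEG skull-conductivity calibration.

EEG is strongly sensitive to skull conductivity while MEG is nearly
insensitive to it; conversely MEG is nearly blind to quasi-radial sources
which EEG sees well.  The calibration exploits both asymmetries, per
candidate skull conductivity:

1. fix the source *position* by a single-dipole scan of the MEG topography
   of the somatosensory evoked response (robust to the skull-conductivity
   guess),
2. fix the *orientation* (and EEG amplitude) by a least-squares EEG fit at
   that position,
3. score the candidate by how well a single dipole with this jointly fixed
   position and orientation explains both modalities (sum of per-modality
   relative residual variances).

The minimizer of the goal curve is the calibrated skull conductivity.
Spongiosa is tied to compacta by a fixed ratio so the scan stays
one-dimensional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fem import LeadfieldSet
from .inverse import EvokedData, dipole_scan_goal

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationGrid",
    "CandidateRecord",
    "CalibrationResult",
    "meg_dipole_scan",
    "eeg_orientation_fit",
    "calibrate_skull",
]


@dataclass(frozen=True)
class CalibrationGrid:
    """Skull-compacta candidates (S/m, strictly increasing) and the fixed
    spongiosa/compacta conductivity ratio."""

    compacta_values: tuple[float, ...] = tuple(np.geomspace(0.0005, 0.02, 12).round(8))
    spongiosa_ratio: float = 3.5

    def __post_init__(self):
        v = np.asarray(self.compacta_values)
        if len(v) == 0 or np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise ValueError("compacta candidates must be positive and strictly increasing")
        if self.spongiosa_ratio <= 0:
            raise ValueError("spongiosa_ratio must be > 0")

    def spongiosa_values(self) -> np.ndarray:
        return np.asarray(self.compacta_values) * self.spongiosa_ratio


@dataclass
class CandidateRecord:
    compacta: float
    spongiosa: float
    position_index: int
    position_mm: np.ndarray
    orientation: np.ndarray  # unit vector
    eeg_amplitude: float  # nA*m
    meg_amplitude: float  # nA*m
    eeg_residual_variance: float
    meg_residual_variance: float
    goal_value: float


@dataclass
class CalibrationResult:
    best_compacta: float
    best_spongiosa: float
    records: list[CandidateRecord]
    unimodal: bool

    @property
    def goal_curve(self) -> np.ndarray:
        return np.array([r.goal_value for r in self.records])


def meg_dipole_scan(
    meg_evoked: EvokedData,
    meg_leadfield: LeadfieldSet,
    latency_ms: float,
) -> tuple[int, np.ndarray, float]:
    """Single-dipole scan: node minimizing the MEG residual variance.

    Returns (node index, least-squares 3-vector moment in nA*m, residual
    variance).  Ties are broken toward the lowest node index (argmin).
    """
    y = meg_evoked.topography(latency_ms)
    rv = dipole_scan_goal(meg_leadfield, y)
    j = int(np.argmin(rv))
    Lj = meg_leadfield.column_block(j)
    moment, *_ = np.linalg.lstsq(Lj, y, rcond=None)
    return j, moment, float(rv[j])


def eeg_orientation_fit(
    eeg_evoked: EvokedData,
    eeg_leadfield: LeadfieldSet,
    position_index: int,
    latency_ms: float,
) -> tuple[np.ndarray, float]:
    """Least-squares dipole fit at a fixed node, split into unit orientation
    and nonnegative amplitude (nA*m)."""
    y = eeg_evoked.topography(latency_ms)
    Lj = eeg_leadfield.column_block(position_index)
    if np.linalg.matrix_rank(Lj) < 3:
        raise np.linalg.LinAlgError(
            f"degenerate 3-column EEG leadfield at node {position_index}"
        )
    moment, *_ = np.linalg.lstsq(Lj, y, rcond=None)
    amp = float(np.linalg.norm(moment))
    if amp == 0:
        raise ValueError("zero fitted moment; all-zero EEG topography?")
    return moment / amp, amp


def _amplitude_and_rv(L_eta: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Best scalar amplitude for a fixed-orientation dipole and its relative
    residual variance."""
    gg = float(L_eta @ L_eta)
    yy = float(y @ y)
    if gg == 0 or yy == 0:
        return 0.0, 1.0
    a = float(L_eta @ y) / gg
    rv = max(0.0, 1.0 - a * a * gg / yy)
    return a, rv


def default_calibration_latency(meg_evoked: EvokedData) -> float:
    """Waveform maximum of the evoked response: latency (ms) of the MEG
    global-field-power peak (emulating the early cortical SEP component)."""
    gfp = np.linalg.norm(meg_evoked.data, axis=0)
    return float(meg_evoked.times_ms[int(np.argmax(gfp))])


def calibrate_skull(
    eeg_evoked: EvokedData,
    meg_evoked: EvokedData,
    leadfield_factory: Callable[[float, float], tuple[LeadfieldSet, LeadfieldSet]],
    grid: CalibrationGrid = CalibrationGrid(),
    latency_ms: float | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> CalibrationResult:
    """Scan the candidate grid and pick the skull conductivity that best
    reconciles EEG and MEG.

    ``leadfield_factory(compacta, spongiosa)`` must return the
    ``(eeg_leadfield, meg_leadfield)`` pair computed with that candidate
    skull conductivity on a shared source space.  ``weights`` are the
    (EEG, MEG) weights of the residual-variance goal.

    A non-unimodal goal curve is flagged (``result.unimodal``) and logged,
    not raised.
    """
    if latency_ms is None:
        latency_ms = default_calibration_latency(meg_evoked)
    y_eeg = eeg_evoked.topography(latency_ms)
    y_meg = meg_evoked.topography(latency_ms)
    w_e, w_m = weights
    records: list[CandidateRecord] = []
    for compacta, spongiosa in zip(grid.compacta_values, grid.spongiosa_values()):
        eeg_lf, meg_lf = leadfield_factory(compacta, spongiosa)
        j, _, _ = meg_dipole_scan(meg_evoked, meg_lf, latency_ms)
        eta, _ = eeg_orientation_fit(eeg_evoked, eeg_lf, j, latency_ms)
        a_e, rv_e = _amplitude_and_rv(eeg_lf.column_block(j) @ eta, y_eeg)
        a_m, rv_m = _amplitude_and_rv(meg_lf.column_block(j) @ eta, y_meg)
        records.append(
            CandidateRecord(
                compacta=float(compacta),
                spongiosa=float(spongiosa),
                position_index=j,
                position_mm=eeg_lf.source_positions[j].copy(),
                orientation=eta,
                eeg_amplitude=abs(a_e),
                meg_amplitude=abs(a_m),
                eeg_residual_variance=rv_e,
                meg_residual_variance=rv_m,
                goal_value=w_e * rv_e + w_m * rv_m,
            )
        )
    goal = np.array([r.goal_value for r in records])
    best = int(np.argmin(goal))
    # unimodal = goal decreases to the minimum then increases
    d = np.sign(np.diff(goal))
    unimodal = bool(np.all(d[:best] <= 0) and np.all(d[best:] >= 0))
    if not unimodal:
        logger.warning("calibration goal curve is not unimodal; inspect result.records")
    return CalibrationResult(
        best_compacta=records[best].compacta,
        best_spongiosa=records[best].spongiosa,
        records=records,
        unimodal=unimodal,
    )
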
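"""Shared fixtures: phantoms at two scales plus cached forward models.

The expensive objects are session-scoped so the validation-grade 2 mm
phantom and the candidate-grid calibration leadfields are built exactly
once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from emegfem import fem
from emegfem.calibrate import CalibrationGrid
from emegfem.inverse import EvokedData, average_spikes
from emegfem.mesh import ConductivityTable, assign_conductivities, build_source_space
from emegfem.phantom import (
    DipoleSource,
    four_shell_spec,
    make_sensor_array,
    simulate_sep_recordings,
    voxelize_sphere_model,
)
from emegfem.validate import ForwardModel

#: calibrated-pair ground truth used by the synthetic phantoms (S/m)
TRUE_COMPACTA = 0.0033
TRUE_SPONGIOSA_RATIO = 3.5


def twelve_candidate_grid() -> CalibrationGrid:
    """12 log-spaced skull-compacta candidates spanning the physiological
    range, anchored so the phantom's true value is a grid member."""
    base = np.geomspace(0.0005, 0.02, 12)
    vals = base * (TRUE_COMPACTA / base[6])
    return CalibrationGrid(compacta_values=tuple(vals), spongiosa_ratio=TRUE_SPONGIOSA_RATIO)


@pytest.fixture(scope="session")
def phantom2mm():
    """Validation-grade 4-shell sphere (92/86/80/78 mm) meshed at 2 mm.

    The conductivities are the study's literature/calibrated values:
    scalp 0.43, skull 0.0033, CSF 1.79, brain 0.33 S/m.
    """
    spec = four_shell_spec()
    sensors = make_sensor_array(spec, 32, 32, meg_type="magnetometer", baseline=None)
    return ForwardModel(spec, sensors, voxel_size=2.0, shape=(96, 96, 96))


@pytest.fixture(scope="session")
def inverse_phantom():
    """Coarser thick-shell phantom with a dense GM source space for the
    inverse-problem tests (sLORETA, fusion, clustering)."""
    spec = four_shell_spec(radii=(80.0, 72.0, 66.0, 60.0), conductivities=(0.43, 0.0033, 1.79, 0.33))
    sensors = make_sensor_array(spec, 32, 32, meg_type="magnetometer", baseline=None)
    model = ForwardModel(spec, sensors, voxel_size=4.0, shape=(44, 44, 44))
    source_space = build_source_space(model.mesh, spec.label_of("gm"), spacing=6.0)
    leadfields = fem.compute_leadfields(
        model.K, model.mesh, source_space, sensors, eeg=model.T_eeg, meg=model.T_meg
    )
    return {
        "spec": spec,
        "sensors": sensors,
        "model": model,
        "source_space": source_space,
        "leadfields": leadfields,
    }


@pytest.fixture(scope="session")
def calibration_setup():
    """Small phantom plus per-candidate leadfields over the 12-value grid.

    One stiffness assembly and transfer-matrix computation per candidate,
    cached for all calibration tests.
    """
    spec = four_shell_spec(radii=(60.0, 52.0, 46.0, 42.0), conductivities=(0.43, TRUE_COMPACTA, 1.79, 0.33))
    sensors = make_sensor_array(spec, 24, 24, meg_type="magnetometer", baseline=None)
    model = ForwardModel(spec, sensors, voxel_size=4.0, shape=(34, 34, 34))
    source_space = build_source_space(model.mesh, spec.label_of("gm"), spacing=6.0)
    grid = twelve_candidate_grid()
    skull_label = spec.label_of("skull_compacta")
    base_table = spec.conductivity_table()
    cache: dict[float, tuple] = {}

    def factory(compacta, spongiosa):
        if compacta not in cache:
            table = dict(base_table)
            table[skull_label] = compacta
            m2 = assign_conductivities(model.mesh, ConductivityTable(table))
            K2 = fem.assemble_stiffness(m2)
            Te = fem.eeg_transfer(K2, sensors, m2)
            Tm = fem.meg_transfer(K2, sensors, m2)
            lf = fem.compute_leadfields(K2, m2, source_space, sensors, eeg=Te, meg=Tm)
            cache[compacta] = (lf.block("eeg"), lf.block("meg"))
        return cache[compacta]

    for c, s in zip(grid.compacta_values, grid.spongiosa_values()):
        factory(c, s)
    eeg_true, meg_true = cache[grid.compacta_values[6]]
    lf_true = fem.LeadfieldSet(
        matrix=np.vstack([eeg_true.matrix, meg_true.matrix]),
        row_modality=np.concatenate([eeg_true.row_modality, meg_true.row_modality]),
        row_names=eeg_true.row_names + meg_true.row_names,
        source_positions=source_space.positions,
        source_nearest_node=source_space.nearest_node,
        spacing=source_space.spacing,
    )
    return {
        "spec": spec,
        "sensors": sensors,
        "model": model,
        "source_space": source_space,
        "grid": grid,
        "factory": factory,
        "cache": cache,
        "leadfields_true": lf_true,
        "sep_source": DipoleSource([0.0, 0.0, 25.0], [20.0, 0.0, 0.0]),
    }


def split_modalities(ev: EvokedData) -> tuple[EvokedData, EvokedData]:
    mods = ev.modalities
    eeg = EvokedData(
        ev.data[mods == "eeg"],
        [m for m in ev.channel_meta if m.modality == "eeg"],
        ev.sampling_rate,
        ev.time_zero,
    )
    meg = EvokedData(
        ev.data[mods == "meg"],
        [m for m in ev.channel_meta if m.modality == "meg"],
        ev.sampling_rate,
        ev.time_zero,
    )
    return eeg, meg


def simulate_sep_evoked(leadfields, source, snr, n_trials, seed):
    """SEP trials -> full-window average, split per modality."""
    trials = simulate_sep_recordings(
        leadfields, source, snr_eeg=snr, snr_meg=snr, n_trials=n_trials, seed=seed
    )
    dt = 1000.0 / trials.sampling_rate
    win = (-trials.event_latency * dt, (trials.n_times - 1 - trials.event_latency) * dt)
    ev = average_spikes(trials, window_ms=win, baseline_ms=(win[0], win[0] + 10.0))
    return split_modalities(ev)


@pytest.fixture
def tiny_leadfield():
    """Handcrafted 3-source leadfield for simulation-layer tests (no FEM)."""
    rng = np.random.default_rng(42)
    n_eeg, n_meg, n_src = 12, 10, 3
    pos = np.array([[0.0, 0.0, 30.0], [20.0, 0.0, 10.0], [-15.0, 10.0, 20.0]])
    return fem.LeadfieldSet(
        matrix=np.vstack(
            [rng.standard_normal((n_eeg, 3 * n_src)), 50.0 * rng.standard_normal((n_meg, 3 * n_src))]
        ),
        row_modality=np.array(["eeg"] * n_eeg + ["meg"] * n_meg),
        row_names=[f"E{i}" for i in range(n_eeg)] + [f"M{i}" for i in range(n_meg)],
        source_positions=pos,
        source_nearest_node=np.arange(n_src),
        spacing=15.0,
    )
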
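"""Configuration-driven orchestration of the full analysis chain.

``run_pipeline`` executes phantom -> mesh -> forward -> (calibrate) ->
(localize -> ROI) from a strictly validated YAML-style configuration,
persisting every intermediate artifact with a content hash into a run
manifest.  Reruns with the same configuration and seed are bit-identical
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, fem, io
from .calibrate import CalibrationGrid, calibrate_skull
from .inverse import (
    EvokedData,
    InverseConfig,
    average_spikes,
    combine_emeg,
    localize_at,
    roi_box,
    whiten,
)
from .mesh import (
    ConductivityTable,
    assign_conductivities,
    build_hex_mesh,
    build_source_space,
    map_dti_conductivity,
)
from .phantom import (
    DipoleSource,
    SensorArray,
    SpikeSimConfig,
    four_shell_spec,
    make_sensor_array,
    seven_compartment_spec,
    simulate_ied_recordings,
    simulate_sep_recordings,
    synthesize_dti_tensors,
    voxelize_sphere_model,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "generate_fixtures", "default_config"]


_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "phantom": {
        "model": str,  # four_shell | seven_compartment
        "radii": list,
        "conductivities": list,
        "voxel_size": float,
        "shape": list,
        "n_eeg": int,
        "n_meg": int,
        "meg_type": str,
        "baseline": float,
        "meg_standoff": float,
        "anisotropic_wm": bool,
        "wm_fa": float,
    },
    "mesh": {
        "node_shift_factor": float,
        "source_spacing": float,
    },
    "forward": {
        "solver_tol": float,
    },
    "calibration": {
        "compacta_values": list,
        "spongiosa_ratio": float,
        "snr_eeg": float,
        "snr_meg": float,
        "n_trials": int,
        "source_eccentricity": float,
    },
    "inverse": {
        "onset_position": list,
        "onset_moment": list,
        "peak_position": list,
        "peak_moment": list,
        "delay": float,
        "n_trials": int,
        "snr_eeg": float,
        "snr_meg": float,
        "latencies": list,
        "threshold_fraction": float,
        "min_cluster_size": int,
        "roi_extents": list,
    },
}


def _validate(cfg: dict, schema: dict, path: str = "") -> None:
    for key, val in cfg.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ValueError(f"unknown configuration key: {here}")
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(val, dict):
                raise ValueError(f"{here} must be a mapping")
            _validate(val, expect, here)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (nested dict + seed + output dir)."""

    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _validate(d, _SCHEMA)
        merged = default_config()
        for sect, val in d.items():
            if val is None:
                val = {}
            if isinstance(val, dict):
                merged.setdefault(sect, {}).update(val)
            else:
                merged[sect] = val
        # sections explicitly absent from the user config are optional stages
        for optional in ("calibration", "inverse"):
            if optional not in d:
                merged.pop(optional, None)
        return cls(raw=merged)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)


def default_config() -> dict:
    """Desk-scale demonstration defaults: a 4-shell phantom small enough to
    mesh and solve in seconds, two-focus discharges 40+ mm apart."""
    return {
        "seed": 0,
        "output_dir": "emeg_run",
        "phantom": {
            "model": "four_shell",
            "radii": [80.0, 72.0, 66.0, 60.0],
            "conductivities": [0.43, 0.0033, 1.79, 0.33],
            "voxel_size": 4.0,
            "shape": [44, 44, 44],
            "n_eeg": 32,
            "n_meg": 64,
            "meg_type": "magnetometer",
            "baseline": 50.0,
            "meg_standoff": 20.0,
            "anisotropic_wm": False,
            "wm_fa": 0.7,
        },
        "mesh": {"node_shift_factor": 0.33, "source_spacing": 6.0},
        "forward": {"solver_tol": 1e-9},
        "calibration": {
            "compacta_values": list(np.geomspace(0.0005, 0.02, 12).round(8)),
            "spongiosa_ratio": 3.5,
            "snr_eeg": 20.0,
            "snr_meg": 20.0,
            "n_trials": 1,
            "source_eccentricity": 0.6,
        },
        "inverse": {
            "onset_position": [-30.0, 10.0, 25.0],
            "onset_moment": [0.0, 20.0, 0.0],
            "peak_position": [25.0, 20.0, 20.0],
            "peak_moment": [20.0, 0.0, 0.0],
            "delay": 23.0,
            "n_trials": 10,
            "snr_eeg": 5.0,
            "snr_meg": 5.0,
            "latencies": [-7.0, -23.0],
            "threshold_fraction": 0.85,
            "min_cluster_size": 2,
            "roi_extents": [160.0, 82.0, 28.0],
        },
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: dict):
        self.outdir = outdir
        self.doc = {
            "package_version": __version__,
            "config": json.loads(json.dumps(config, default=float)),
            "stages": {},
        }

    def stage(self, name: str):
        return _Stage(self, name)

    def write(self):
        (self.outdir / "manifest.json").write_text(json.dumps(self.doc, indent=2, sort_keys=True))


class _Stage:
    def __init__(self, manifest: _Manifest, name: str):
        self.m, self.name = manifest, name
        self.outputs: list[Path] = []
        self.info: dict = {}

    def __enter__(self):
        self.t0 = time.time()
        logger.info("stage %s ...", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            logger.error("stage %s FAILED: %s", self.name, exc)
            self.m.doc["stages"][self.name] = {"status": "failed", "error": str(exc)}
            self.m.write()
            return False
        rec = {
            "status": "ok",
            "wall_time_s": round(time.time() - self.t0, 3),
            "outputs": {str(p.relative_to(self.m.outdir)): _sha256(p) for p in self.outputs},
        }
        rec.update(self.info)
        self.m.doc["stages"][self.name] = rec
        logger.info("stage %s done in %.1fs", self.name, rec["wall_time_s"])
        return False

    def emit(self, path: Path):
        self.outputs.append(path)
        return path


def _build_spec(pcfg: dict):
    if pcfg["model"] == "four_shell":
        return four_shell_spec(radii=tuple(pcfg["radii"]), conductivities=tuple(pcfg["conductivities"]))
    if pcfg["model"] == "seven_compartment":
        return seven_compartment_spec(radii=tuple(pcfg["radii"]))
    raise ValueError(f"unknown phantom model {pcfg['model']!r}")


def _sensors_from_config(spec, pcfg: dict) -> SensorArray:
    n_meg = int(pcfg["n_meg"])
    sens = make_sensor_array(
        spec,
        n_eeg=int(pcfg["n_eeg"]),
        n_meg=max(n_meg, 1),
        meg_standoff=pcfg.get("meg_standoff", 20.0),
        meg_type=pcfg["meg_type"],
        baseline=pcfg.get("baseline"),
    )
    if n_meg == 0:  # EEG-only run
        sens = SensorArray(
            eeg_positions=sens.eeg_positions,
            eeg_labels=sens.eeg_labels,
            meg_centers=np.empty((0, 3)),
            meg_orientations=np.empty((0, 3)),
            meg_labels=[],
            meg_type=sens.meg_type,
            baseline=sens.baseline,
        )
    return sens


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict.

    Artifacts are written under ``output_dir``; a failing stage aborts the
    run with the failing stage named in the manifest and prior artifacts
    retained.
    """
    cfg = config.raw
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = _Manifest(outdir, cfg)
    pcfg = cfg["phantom"]

    with manifest.stage("phantom") as st:
        spec = _build_spec(pcfg)
        grid = voxelize_sphere_model(spec, float(pcfg["voxel_size"]), pcfg["shape"])
        sensors = _sensors_from_config(spec, pcfg)
        io.save_label_volume(grid, st.emit(outdir / "labels.nii.gz"))
        st.outputs.append(outdir / "labels.labels.json")
        io.save_sensor_array(sensors, st.emit(outdir / "sensors.txt"))

    with manifest.stage("mesh") as st:
        mesh = build_hex_mesh(grid, float(cfg["mesh"]["node_shift_factor"]))
        mesh = assign_conductivities(mesh, ConductivityTable(spec.conductivity_table()))
        if pcfg.get("anisotropic_wm") and "wm" in [s.tissue for s in spec.shells]:
            wm_label = spec.label_of("wm")
            dti = synthesize_dti_tensors(grid, wm_label, fa=float(pcfg["wm_fa"]), center=spec.center)
            io.save_tensor_field(dti, st.emit(outdir / "dti.nii.gz"))
            mesh = map_dti_conductivity(mesh, dti, wm_label)
        gm_label = spec.label_of("gm")
        source_space = build_source_space(mesh, gm_label, float(cfg["mesh"]["source_spacing"]))
        io.save_mesh(mesh, st.emit(outdir / "mesh.h5"))
        st.info["n_elements"] = mesh.n_elements
        st.info["n_sources"] = len(source_space)

    tol = float(cfg["forward"]["solver_tol"])
    with manifest.stage("forward") as st:
        K = fem.assemble_stiffness(mesh)
        T_eeg = fem.eeg_transfer(K, sensors, mesh, tol=tol)
        T_meg = fem.meg_transfer(K, sensors, mesh, tol=tol) if sensors.n_meg else None
        leadfields = fem.compute_leadfields(K, mesh, source_space, sensors, eeg=T_eeg, meg=T_meg)
        io.save_leadfields(leadfields, st.emit(outdir / "leadfields.h5"))

    result: dict = {}
    if "calibration" in cfg:
        with manifest.stage("calibrate") as st:
            result["calibration"] = _run_calibration(
                cfg, spec, grid, mesh, sensors, source_space, leadfields, seed, tol, outdir, st
            )

    if "inverse" in cfg:
        with manifest.stage("localize") as st:
            result["localization"] = _run_localization(cfg, spec, sensors, leadfields, seed, outdir, st)
        with manifest.stage("roi") as st:
            result["rois"] = _run_roi(cfg, result["localization"], outdir, st)

    manifest.write()
    result["manifest"] = manifest.doc
    return result


def _run_calibration(cfg, spec, grid, mesh, sensors, source_space, leadfields, seed, tol, outdir, st):
    ccfg = cfg["calibration"]
    if sensors.n_meg == 0:
        raise ValueError("calibration needs both EEG and MEG")
    inner_r = spec.radii[-1]
    # focal tangential calibration source at the configured eccentricity
    pos = spec.center + np.array([0.0, 0.0, ccfg["source_eccentricity"] * inner_r])
    src = DipoleSource(pos, [20.0, 0.0, 0.0])
    trials = simulate_sep_recordings(
        leadfields,
        src,
        snr_eeg=ccfg["snr_eeg"],
        snr_meg=ccfg["snr_meg"],
        n_trials=int(ccfg["n_trials"]),
        seed=seed,
    )
    io.save_raw_trials(trials, st.emit(outdir / "sep_trials.h5"))
    n_t = trials.n_times
    win = ((0 - trials.event_latency) * 1000.0 / trials.sampling_rate, (n_t - 1 - trials.event_latency) * 1000.0 / trials.sampling_rate)
    ev = average_spikes(trials, window_ms=win, baseline_ms=(win[0], win[0] + 10.0))
    mods = ev.modalities
    eeg_ev = EvokedData(ev.data[mods == "eeg"], [m for m in ev.channel_meta if m.modality == "eeg"], ev.sampling_rate, ev.time_zero)
    meg_ev = EvokedData(ev.data[mods == "meg"], [m for m in ev.channel_meta if m.modality == "meg"], ev.sampling_rate, ev.time_zero)

    skull_label = spec.label_of("skull_compacta")
    spong_label = None
    if "skull_spongiosa" in [s.tissue for s in spec.shells]:
        spong_label = spec.label_of("skull_spongiosa")
    base_table = spec.conductivity_table()

    def factory(compacta, spongiosa):
        table = dict(base_table)
        table[skull_label] = compacta
        if spong_label is not None:
            table[spong_label] = spongiosa
        m2 = assign_conductivities(mesh, ConductivityTable(table))
        K2 = fem.assemble_stiffness(m2)
        Te = fem.eeg_transfer(K2, sensors, m2, tol=tol)
        Tm = fem.meg_transfer(K2, sensors, m2, tol=tol)
        lf = fem.compute_leadfields(K2, m2, source_space, sensors, eeg=Te, meg=Tm)
        return lf.block("eeg"), lf.block("meg")

    grid_cal = CalibrationGrid(
        compacta_values=tuple(ccfg["compacta_values"]), spongiosa_ratio=float(ccfg["spongiosa_ratio"])
    )
    res = calibrate_skull(eeg_ev, meg_ev, factory, grid_cal)
    report = outdir / "calibration.txt"
    lines = ["# compacta_S/m spongiosa_S/m goal eeg_rv meg_rv eeg_amp_nAm meg_amp_nAm"]
    for r in res.records:
        lines.append(
            f"{r.compacta:.6g} {r.spongiosa:.6g} {r.goal_value:.6g} "
            f"{r.eeg_residual_variance:.6g} {r.meg_residual_variance:.6g} "
            f"{r.eeg_amplitude:.6g} {r.meg_amplitude:.6g}"
        )
    lines.append(f"# best_compacta {res.best_compacta:.6g}")
    lines.append(f"# best_spongiosa {res.best_spongiosa:.6g}")
    report.write_text("\n".join(lines) + "\n")
    st.outputs.append(report)
    st.info["best_compacta"] = res.best_compacta
    st.info["best_spongiosa"] = res.best_spongiosa
    return res


def _run_localization(cfg, spec, sensors, leadfields, seed, outdir, st):
    icfg = cfg["inverse"]
    sim = SpikeSimConfig(
        onset_source=DipoleSource(np.asarray(icfg["onset_position"]) + spec.center, icfg["onset_moment"]),
        peak_source=DipoleSource(np.asarray(icfg["peak_position"]) + spec.center, icfg["peak_moment"]),
        delay=float(icfg["delay"]),
        n_trials=int(icfg["n_trials"]),
        snr_eeg=float(icfg["snr_eeg"]),
        snr_meg=float(icfg["snr_meg"]),
        seed=seed,
    )
    trials = simulate_ied_recordings(leadfields, sim)
    io.save_raw_trials(trials, st.emit(outdir / "ied_trials.h5"))
    ev = average_spikes(trials)
    io.save_evoked(ev, st.emit(outdir / "ied_evoked.h5"))
    mods = ev.modalities
    inv_cfg = InverseConfig(
        threshold_fraction=float(icfg["threshold_fraction"]),
        analysis_latencies=tuple(icfg["latencies"]),
        min_cluster_size=int(icfg["min_cluster_size"]),
    )
    if sensors.n_meg:
        eeg_ev = EvokedData(ev.data[mods == "eeg"], [m for m in ev.channel_meta if m.modality == "eeg"], ev.sampling_rate, ev.time_zero)
        meg_ev = EvokedData(ev.data[mods == "meg"], [m for m in ev.channel_meta if m.modality == "meg"], ev.sampling_rate, ev.time_zero)
        joint_ev, joint_lf = combine_emeg(eeg_ev, meg_ev, leadfields.block("eeg"), leadfields.block("meg"))
    else:
        joint_ev, joint_lf = whiten(ev, leadfields)
    estimates = [localize_at(joint_ev, joint_lf, lat, inv_cfg) for lat in inv_cfg.analysis_latencies]
    report = outdir / "clusters.tsv"
    rows = ["latency_ms\tmodality\tcluster\tn_nodes\tpeak_f\tpeak_x\tpeak_y\tpeak_z"]
    for est in estimates:
        for c, cl in enumerate(est.clusters):
            p = est.positions[cl.peak_node]
            rows.append(
                f"{est.latency_ms:g}\t{est.modality_set}\t{c}\t{len(cl.nodes)}\t"
                f"{cl.peak_f:.6g}\t{p[0]:.2f}\t{p[1]:.2f}\t{p[2]:.2f}"
            )
    report.write_text("\n".join(rows) + "\n")
    st.outputs.append(report)
    st.info["n_clusters"] = [len(e.clusters) for e in estimates]
    return estimates


def _run_roi(cfg, estimates, outdir, st):
    extents = tuple(cfg["inverse"]["roi_extents"])
    boxes = []
    rows = ["latency_ms\tcenter_x\tcenter_y\tcenter_z\textent_x\textent_y\textent_z"]
    for est in estimates:
        if not est.clusters:
            continue
        peak = est.positions[est.clusters[0].peak_node]
        box = roi_box(peak, extents)
        boxes.append((est.latency_ms, box))
        rows.append(
            f"{est.latency_ms:g}\t" + "\t".join(f"{v:.2f}" for v in box.center) + "\t" + "\t".join(f"{e:g}" for e in box.extents)
        )
    path = outdir / "roi_boxes.tsv"
    path.write_text("\n".join(rows) + "\n")
    st.outputs.append(path)
    return boxes


def generate_fixtures(size: str = "small", seed: int = 0, output_dir="fixtures") -> dict:
    """Write the canonical test phantom bundle (labels, sensors, leadfields,
    simulated recordings) and its manifest.

    ``small`` is a coarse sub-minute bundle; ``medium`` uses a finer mesh
    whose forward accuracy satisfies the oracle thresholds.
    """
    if size not in ("small", "medium"):
        raise ValueError("size must be 'small' or 'medium'")
    cfg = default_config()
    cfg["seed"] = int(seed)
    cfg["output_dir"] = str(output_dir)
    if size == "small":
        cfg["phantom"].update({"radii": [60.0, 52.0, 46.0, 42.0], "voxel_size": 4.0, "shape": [34, 34, 34], "n_eeg": 24, "n_meg": 24})
        cfg["mesh"]["source_spacing"] = 6.0
        cfg["calibration"]["compacta_values"] = list(np.geomspace(0.001, 0.01, 4).round(8))
    else:
        cfg["phantom"].update({"voxel_size": 2.0, "shape": [88, 88, 88]})
        cfg["mesh"]["source_spacing"] = 6.0
        cfg.pop("calibration")
    return run_pipeline(PipelineConfig.from_dict(cfg))
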
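"""Forward-solution validation against the analytic sphere oracles.

Builds the configured sphere phantom, computes FEM leadfield columns for
random tangential test dipoles, and scores them with RDM/lnMAG against the
multilayer-series EEG potential and the Sarvas MEG field.  Backs the
``emeg validate-forward`` subcommand and the validation test suite.
"""

from __future__ import annotations

import numpy as np

from . import fem
from .mesh import ConductivityTable, assign_conductivities, build_hex_mesh
from .oracle import eeg_sphere_potential, meg_sarvas, topography_error
from .phantom import DipoleSource, voxelize_sphere_model

__all__ = ["ForwardModel", "tangential_dipoles", "forward_validation_report"]


class ForwardModel:
    """Assembled phantom forward model: mesh, stiffness, transfer matrices.

    Bundles everything needed to evaluate FEM sensor topographies for
    arbitrary dipoles (via the transfer matrices) or via independent direct
    solves, plus the matching oracle predictions.
    """

    def __init__(self, spec, sensors, voxel_size, shape, node_shift_factor=0.33, tol=1e-9):
        self.spec = spec
        self.sensors = sensors
        grid = voxelize_sphere_model(spec, voxel_size, shape)
        mesh = build_hex_mesh(grid, node_shift_factor)
        self.mesh = assign_conductivities(mesh, ConductivityTable(spec.conductivity_table()))
        self.grid = grid
        self.K = fem.assemble_stiffness(self.mesh)
        self.tol = tol
        self.T_eeg = fem.eeg_transfer(self.K, sensors, self.mesh, tol=tol)
        self.S_meg = fem.meg_secondary_matrix(self.mesh, sensors) if sensors.n_meg else None
        self.T_meg = fem.meg_transfer(self.K, sensors, self.mesh, tol=tol) if sensors.n_meg else None

    def fem_topography(self, dipole: DipoleSource) -> dict[str, np.ndarray]:
        """EEG (uV) and MEG (fT) topographies via the transfer matrices."""
        nbrs, Q = fem.venant_loads(dipole.position, self.mesh)
        loads = Q @ (dipole.moment * 1e-9)
        out = {"eeg": 1e6 * (self.T_eeg.matrix[:, nbrs] @ loads)}
        if self.T_meg is not None:
            sec = self.T_meg.matrix[:, nbrs] @ loads
            prim = fem._primary_rows(self.sensors, dipole.position) @ (dipole.moment * 1e-9)
            out["meg"] = 1e15 * (sec + prim)
        return out

    def fem_topography_direct(self, dipole: DipoleSource) -> dict[str, np.ndarray]:
        """Same quantities via one full direct solve (independent route)."""
        return fem.direct_leadfield_column(
            self.K,
            self.mesh,
            self.sensors,
            dipole,
            eeg_snapped_nodes=self.T_eeg.snapped_nodes,
            meg_secondary=self.S_meg,
            tol=self.tol,
        )

    def oracle_topography(self, dipole: DipoleSource) -> dict[str, np.ndarray]:
        out = {
            "eeg": eeg_sphere_potential(
                self.spec, dipole, self.mesh.nodes[self.T_eeg.snapped_nodes]
            )
        }
        if self.sensors.n_meg:
            B = meg_sarvas(self.spec.center, dipole, self.sensors.meg_centers)
            bn = np.einsum("ij,ij->i", B, self.sensors.meg_orientations)
            if self.sensors.meg_type == "axial_gradiometer":
                far = self.sensors.meg_centers + self.sensors.baseline * self.sensors.meg_orientations
                Bf = meg_sarvas(self.spec.center, dipole, far)
                bn = bn - np.einsum("ij,ij->i", Bf, self.sensors.meg_orientations)
            out["meg"] = bn
        return out


def tangential_dipoles(spec, n: int, ecc_range=(0.3, 0.8), moment_nAm: float = 10.0, seed: int = 0):
    """Random tangentially oriented dipoles at eccentricities in ``ecc_range``
    (relative to the innermost shell radius)."""
    rng = np.random.default_rng(seed)
    inner = spec.radii[-1]
    dipoles = []
    for _ in range(n):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        ecc = rng.uniform(*ecc_range)
        t = np.cross(u, rng.standard_normal(3))
        t /= np.linalg.norm(t)
        dipoles.append(DipoleSource(spec.center + ecc * inner * u, moment_nAm * t))
    return dipoles


def forward_validation_report(config, n_dipoles: int = 8) -> list[dict]:
    """RDM/lnMAG rows for random tangential dipoles on the configured phantom."""
    from .pipeline import _build_spec, _sensors_from_config

    pcfg = config["phantom"]
    spec = _build_spec(pcfg)
    sensors = _sensors_from_config(spec, pcfg)
    model = ForwardModel(spec, sensors, float(pcfg["voxel_size"]), pcfg["shape"])
    rows = []
    for i, dip in enumerate(tangential_dipoles(spec, n_dipoles, seed=int(config.get("seed", 0)))):
        femt = model.fem_topography(dip)
        orat = model.oracle_topography(dip)
        me = topography_error(femt["eeg"], orat["eeg"])
        row = {
            "dipole": i,
            "eccentricity": float(np.linalg.norm(dip.position - spec.center) / spec.radii[-1]),
            "rdm_eeg": me.rdm,
            "lnmag_eeg": me.lnmag,
            "rdm_meg": float("nan"),
            "lnmag_meg": float("nan"),
        }
        if "meg" in femt:
            mm = topography_error(femt["meg"], orat["meg"])
            row["rdm_meg"] = mm.rdm
            row["lnmag_meg"] = mm.lnmag
        rows.append(row)
    return rows
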
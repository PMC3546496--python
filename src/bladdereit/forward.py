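"""Complete-electrode-model (CEM) finite-element forward solver.

A sinusoidal current (quasi-static, magnitude only) is injected from
each of the 64 array electrodes in turn and returns through the grounded
back electrode; voltages are read from the remaining 63 array
electrodes, giving a 64 x 63 = 4032-value measurement frame per
acquisition.

The CEM couples the interior potential u with the electrode potentials
U_l through a contact impedance z_l on each electrode patch E_l:

    div(sigma grad u) = 0            in the tank,
    u + z_l sigma du/dn = U_l        on E_l,
    integral_{E_l} sigma du/dn = I_l (prescribed net current),
    sigma du/dn = 0                  elsewhere on the boundary.

The discrete system is symmetric; the back electrode is grounded
(U_64 = 0) which both fixes the potential and absorbs the return
current.  The Jacobian d(measurements)/d(sigma_e) is computed with the
adjoint-field formula: because every drive and measurement pattern is a
current between one array electrode and ground, the 64 unit-current
fields provide both the direct and the adjoint fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh
from .phantom import ConductivityField, ElectrodeLayout, N_ARRAY_ELECTRODES

logger = logging.getLogger(__name__)

MM_TO_M = 1e-3
N_MEASUREMENTS = N_ARRAY_ELECTRODES * (N_ARRAY_ELECTRODES - 1)  # 4032
BACK_ELECTRODE = N_ARRAY_ELECTRODES  # index 64, signal ground

# canonical measurement ordering: injection i = 0..63 (outer),
# measurement electrode j != i in ascending order (inner)
_INJ = np.repeat(np.arange(N_ARRAY_ELECTRODES), N_ARRAY_ELECTRODES - 1)
_MEAS = np.concatenate(
    [np.delete(np.arange(N_ARRAY_ELECTRODES), i) for i in range(N_ARRAY_ELECTRODES)]
)


def measurement_pattern() -> tuple[np.ndarray, np.ndarray]:
    """(injection_index, electrode_index) arrays for the 4032 rows."""
    return _INJ.copy(), _MEAS.copy()


@dataclass
class MeasurementFrame:
    """Ordered vector of the 4032 electrode voltages of one acquisition."""

    values: np.ndarray
    current_ma: float = 10.0
    frame_kind: str = "simulated"  # "simulated" | "measured"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_MEASUREMENTS,):
            raise ValueError(f"frame must hold {N_MEASUREMENTS} voltages")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame contains non-finite voltages")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "injection_index": _INJ,
                "electrode_index": _MEAS,
                "voltage_v": [repr(float(v)) for v in self.values],
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# current_ma={self.current_ma!r} frame_kind={self.frame_kind}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementFrame":
        with open(path) as fh:
            header = fh.readline().strip()
            df = pd.read_csv(fh, dtype={"voltage_v": str})
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
        )
        if not (np.array_equal(df["injection_index"], _INJ)
                and np.array_equal(df["electrode_index"], _MEAS)):
            raise ValueError("CSV rows are not in the canonical frame order")
        return cls(
            values=np.array([float(v) for v in df["voltage_v"]]),
            current_ma=float(meta.get("current_ma", 10.0)),
            frame_kind=meta.get("frame_kind", "simulated"),
        )


@dataclass
class SensitivityMatrix:
    """Jacobian J: rows = 4032 measurements, cols = mesh elements, V/(S/m)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] != N_MEASUREMENTS:
            raise ValueError("Jacobian must have 4032 rows")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("Jacobian contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def to_matrix_market(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(path, sp.coo_matrix(self.entries))


class CEMSystem:
    """Assembled and factorized CEM system for one conductivity field.

    Works with an arbitrary list of electrode boundary-face patches; the
    last electrode is the ground.  Internally SI units (m, S/m, A, V).
    """

    def __init__(
        self,
        mesh: Mesh,
        sigma: np.ndarray,
        face_sets: list[np.ndarray],
        contact_impedance_ohm_m2: np.ndarray | float,
    ):
        sigma = np.asarray(sigma, dtype=float)
        if (sigma <= 0).any():
            raise ValueError("conductivity must be positive for the forward solve")
        self.mesh = mesh
        self.n_el = len(face_sets)
        if self.n_el < 2:
            raise ValueError("need at least a driven and a ground electrode")
        z = np.broadcast_to(
            np.asarray(contact_impedance_ohm_m2, dtype=float), (self.n_el,)
        )
        if (z <= 0).any():
            raise ValueError("contact impedance must be positive")
        self.z = z
        self.face_sets = face_sets

        n = mesh.n_nodes
        nu = self.n_el - 1  # electrode potential unknowns (ground removed)
        # stiffness in SI: grads 1/mm -> 1/m gives 1e6, volume mm^3 -> m^3
        # gives 1e-9; net factor 1e-3 on the mm-assembled matrix.
        k_nodes = _stiffness(mesh, sigma) * MM_TO_M

        areas = mesh.boundary_face_areas() * MM_TO_M**2
        faces = mesh.boundary_faces
        self._face_areas_m2 = areas
        rows, cols, vals = [], [], []
        w_rows, w_cols, w_vals = [], [], []
        self.el_area = np.zeros(self.n_el)
        for l, fs in enumerate(face_sets):
            if len(fs) == 0:
                raise ValueError(f"electrode {l} has no boundary faces")
            a = areas[fs]
            self.el_area[l] = a.sum()
            tri = faces[fs]
            # triangle mass matrix area/12 * (2 on diag, 1 off)
            for i in range(3):
                for j in range(3):
                    coef = 2.0 if i == j else 1.0
                    rows.append(tri[:, i])
                    cols.append(tri[:, j])
                    vals.append(coef * a / 12.0 / self.z[l])
            if l < nu:
                for i in range(3):
                    w_rows.append(tri[:, i])
                    w_cols.append(np.full(len(fs), l))
                    w_vals.append(-a / 3.0 / self.z[l])
        az = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        aw = sp.coo_matrix(
            (
                np.concatenate(w_vals),
                (np.concatenate(w_rows), np.concatenate(w_cols)),
            ),
            shape=(n, nu),
        )
        ad = sp.diags(self.el_area[:nu] / self.z[:nu])
        system = sp.bmat(
            [[k_nodes + az.tocsr(), aw.tocsr()], [aw.T.tocsr(), ad]], format="csc"
        )
        try:
            self._lu = spla.splu(system)
        except RuntimeError as exc:  # pragma: no cover - singular systems
            raise RuntimeError(
                "singular CEM system (disconnected mesh or zero conductivity)"
            ) from exc
        self._n = n
        self._nu = nu

    # ------------------------------------------------------------------
    def solve(self, currents_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Solve for net currents (A) at the non-ground electrodes.

        Returns node potentials (V) and all electrode potentials with the
        ground appended as 0.
        """
        b = np.zeros(self._n + self._nu)
        b[self._n:] = currents_a
        sol = self._lu.solve(b)
        u = sol[: self._n]
        volts = np.concatenate([sol[self._n:], [0.0]])
        return u, volts

    def solve_units(self) -> tuple[np.ndarray, np.ndarray]:
        """All unit-current fields (1 A drive vs ground) at once.

        Returns node potentials (n_nodes, L-1) and electrode potentials
        (L, L-1); column l is the field for unit current on electrode l.
        """
        b = np.zeros((self._n + self._nu, self._nu))
        b[self._n + np.arange(self._nu), np.arange(self._nu)] = 1.0
        sol = self._lu.solve(b)
        volts = np.vstack([sol[self._n:], np.zeros(self._nu)])
        return sol[: self._n], volts

    def electrode_currents(self, u: np.ndarray, volts: np.ndarray) -> np.ndarray:
        """Net current through each electrode from a solved field (A)."""
        faces = self.mesh.boundary_faces
        out = np.zeros(self.n_el)
        for l, fs in enumerate(self.face_sets):
            a = self._face_areas_m2[fs]
            u_mean = u[faces[fs]].mean(axis=1)
            out[l] = np.sum(a * (volts[l] - u_mean)) / self.z[l]
        return out


def _stiffness(mesh: Mesh, sigma: np.ndarray) -> sp.csr_matrix:
    from .mesh import assemble_stiffness

    return assemble_stiffness(mesh, sigma)


def _system(mesh: Mesh, fld: ConductivityField, layout: ElectrodeLayout) -> CEMSystem:
    return CEMSystem(
        mesh, fld.values, layout.face_sets(mesh), layout.contact_impedances()
    )


def solve_forward(
    mesh: Mesh,
    fld: ConductivityField,
    layout: ElectrodeLayout,
    injection_index: int,
    current_ma: float = 10.0,
    system: CEMSystem | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Node potentials and 65 electrode voltages for one injection.

    The current enters the indexed array electrode and exits the back
    electrode (ground, index 64).
    """
    if not 0 <= injection_index < N_ARRAY_ELECTRODES:
        raise ValueError("injection_index must be in [0, 63]")
    sys_ = system or _system(mesh, fld, layout)
    currents = np.zeros(sys_.n_el - 1)
    currents[injection_index] = current_ma * 1e-3
    return sys_.solve(currents)


def simulate_frame(
    mesh: Mesh,
    fld: ConductivityField,
    layout: ElectrodeLayout,
    current_ma: float = 10.0,
    system: CEMSystem | None = None,
) -> MeasurementFrame:
    """Simulate the full 64-injection, 4032-voltage measurement frame."""
    sys_ = system or _system(mesh, fld, layout)
    _, volts = sys_.solve_units()  # (65, 64) at 1 A
    amps = current_ma * 1e-3
    values = amps * volts[_MEAS, _INJ]
    return MeasurementFrame(values=values, current_ma=current_ma)


def compute_jacobian(
    mesh: Mesh,
    field_p: ConductivityField,
    layout: ElectrodeLayout,
    current_ma: float = 10.0,
    system: CEMSystem | None = None,
    chunk: int = 2048,
) -> SensitivityMatrix:
    """Sensitivity of each measurement to each element conductivity.

    Adjoint-field formula: with w_l the unit-current field of electrode
    l (against ground) and I the drive current,

        J[(i, j), e] = -I * V_e * grad(w_i)|_e . grad(w_j)|_e .

    The sign convention matches difference imaging with delta_x =
    x_p - x: J (x_p - x) ~= V_p - V.
    """
    field_p.validate_reference()
    sys_ = system or _system(mesh, field_p, layout)
    w, _ = sys_.solve_units()  # node potentials (n_nodes, 64)
    amps = current_ma * 1e-3
    grads = np.einsum(
        "eka,ekl->ela", mesh.grad_phi / MM_TO_M, w[mesh.tets]
    )  # (n_tets, 64, 3), V/m
    vol_m3 = mesh.tet_volumes * MM_TO_M**3
    j = np.empty((N_MEASUREMENTS, mesh.n_tets))
    for s in range(0, mesh.n_tets, chunk):
        e = slice(s, min(s + chunk, mesh.n_tets))
        # gg[c, a, b] = grad w_a . grad w_b on element c
        gg = np.einsum("eai,ebi->eab", grads[e], grads[e])
        j[:, e] = -amps * vol_m3[e][None, :] * gg[:, _INJ, _MEAS].T
    return SensitivityMatrix(entries=j)
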
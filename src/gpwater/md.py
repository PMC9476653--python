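"""Flexible-water molecular dynamics.

Forces are the sum of three terms, all exact gradients of the corresponding
energies so the dynamics is conservative:

* intramolecular: per-atom GPR energy surfaces, differentiated analytically
  through the feature Jacobians;
* electrostatic: multipolar Ewald over GPR-predicted, geometry-dependent
  (flexible) moments -- the fixed-moment force plus the chain-rule terms
  ``-(dE/dQ)(dQ/dr)`` that the position dependence of the moments introduces;
* van der Waals: 12-6 Lennard-Jones on intermolecular O-O and O-H pairs.

Integrators: velocity Verlet (NVE), Nose-Hoover chains (NVT, chain length 3)
and Martyna-Tobias-Klein isotropic cell dynamics (NPT).  The default
timestep is 1 fs; each ensemble tracks its conserved quantity.  Pressure
comes from a central-difference virial ``W = -3V dU/dV`` evaluated by
rescaling all atomic coordinates, which is exact for any potential term and
avoids hand-deriving a reciprocal-space multipole virial.

Internal units: A, A/ps, amu, kJ/mol (see :mod:`gpwater.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import electrostatics as es
from .gpr import WaterModels
from .units import KB, KJMOLA3_TO_ATM, MASS_H, MASS_O, MV2_TO_KJMOL, WATER_MASS

__all__ = [
    "SimulationState",
    "IntegratorConfig",
    "Simulation",
    "ForceResult",
    "build_water_box",
    "gas_monomer_state",
    "maxwell_velocities",
    "box_length_for_density",
]

HARD_FLOOR = 0.3  # A; pairs closer than this abort the run


class OverlapError(RuntimeError):
    pass


class IntegrationFailure(RuntimeError):
    pass


@dataclass
class SimulationState:
    """Positions are unwrapped (molecules stay whole); minimum image is
    applied inside the force evaluations."""

    positions: np.ndarray            # (n, 3) A
    velocities: np.ndarray           # (n, 3) A/ps
    masses: np.ndarray               # (n,) amu
    elements: list
    molecules: np.ndarray            # (n_mol, 3) site indices
    box_length: float | None = None  # A; None = open boundary
    xi: np.ndarray = field(default_factory=lambda: np.zeros(3))
    vxi: np.ndarray = field(default_factory=lambda: np.zeros(3))
    baro_eps: float = 0.0
    baro_p: float = 0.0
    step: int = 0

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dof(self) -> int:
        return 3 * self.n_atoms - 3          # COM momentum removed

    def kinetic_energy(self) -> float:
        return 0.5 * MV2_TO_KJMOL * float(
            np.einsum("i,ij,ij->", self.masses, self.velocities, self.velocities))

    def temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (self.n_dof * KB)

    def volume(self) -> float:
        if self.box_length is None:
            raise ValueError("open-boundary state has no volume")
        return self.box_length ** 3

    def to_dict(self) -> dict:
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationState":
        d = dict(d)
        for k in ("positions", "velocities", "masses", "molecules", "xi", "vxi"):
            d[k] = np.asarray(d[k])
        return cls(**d)


@dataclass
class IntegratorConfig:
    dt_fs: float = 1.0
    ensemble: str = "nve"            # nve | nvt | npt
    temperature: float = 298.0       # K
    pressure_atm: float = 1.0
    tau_t_ps: float = 0.1            # thermostat coupling time
    tau_p_ps: float = 1.0            # barostat coupling time
    chain: int = 3

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.ensemble not in ("nve", "nvt", "npt"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")


@dataclass
class ForceResult:
    forces: np.ndarray
    e_gpr: float
    e_elec: float
    e_lj: float
    total_dipole: np.ndarray         # e*A, sum of q*r + mu over sites
    virial: float | None = None      # sum f.r convention (W = -3V dU/dV)

    @property
    def e_pot(self) -> float:
        return self.e_gpr + self.e_elec + self.e_lj


def _sinhc(x: float) -> float:
    if abs(x) < 1e-4:
        return 1.0 + x * x / 6.0
    return math.sinh(x) / x


# --------------------------------------------------------------------------
# system builders

def box_length_for_density(n_mol: int, density_kg_m3: float) -> float:
    """Cubic box edge (A) holding n_mol waters at the given mass density."""
    mass_kg = n_mol * WATER_MASS * 1e-3 / 6.02214076e23
    vol_m3 = mass_kg / density_kg_m3
    return (vol_m3 * 1e30) ** (1.0 / 3.0)


def _monomer_template(r0: float = 0.96, ang: float = 104.5 * math.pi / 180.0):
    return np.array([[0.0, 0.0, 0.0],
                     [r0, 0.0, 0.0],
                     [r0 * math.cos(ang), r0 * math.sin(ang), 0.0]])


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def maxwell_velocities(masses, temperature, seed) -> np.ndarray:
    """Maxwell-Boltzmann velocities with the COM drift removed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * temperature / (masses * MV2_TO_KJMOL))
    v = rng.normal(size=(masses.size, 3)) * sigma[:, None]
    v -= (masses @ v) / masses.sum()
    return v


def build_water_box(n_mol: int, box_length: float, temperature: float = 298.0,
                    seed: int = 0, velocity_scale: float = 1.0) -> SimulationState:
    """Molecules on a simple cubic sublattice with random orientations.

    ``velocity_scale`` multiplies the initial Maxwell-Boltzmann draw; scaling
    initial velocities is a cheap way to decorrelate replica trajectories
    started from one configuration.
    """
    rng = np.random.default_rng(seed)
    per_side = math.ceil(n_mol ** (1.0 / 3.0))
    spacing = box_length / per_side
    template = _monomer_template()
    template = template - template.mean(axis=0)
    coords = []
    count = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if count >= n_mol:
                    break
                center = (np.array([i, j, k]) + 0.5) * spacing
                R = _random_rotation(rng)
                coords.append(template @ R.T + center)
                count += 1
    positions = np.concatenate(coords)
    masses = np.tile([MASS_O, MASS_H, MASS_H], n_mol).astype(float)
    elements = ["O", "H", "H"] * n_mol
    molecules = np.arange(3 * n_mol).reshape(n_mol, 3)
    vel = maxwell_velocities(masses, temperature, rng) * velocity_scale
    return SimulationState(positions=positions, velocities=vel, masses=masses,
                          elements=elements, molecules=molecules,
                          box_length=float(box_length))


def gas_monomer_state(temperature: float = 298.0, seed: int = 0) -> SimulationState:
    masses = np.array([MASS_O, MASS_H, MASS_H])
    return SimulationState(positions=_monomer_template().copy(),
                           velocities=maxwell_velocities(masses, temperature, seed),
                           masses=masses, elements=["O", "H", "H"],
                           molecules=np.array([[0, 1, 2]]), box_length=None)


# --------------------------------------------------------------------------
# simulation

class Simulation:
    """Force evaluation plus NVE / Nose-Hoover NVT / MTK NPT stepping."""

    def __init__(self, state: SimulationState, models: WaterModels | None,
                 integrator: IntegratorConfig | None = None,
                 es_config: es.ElectrostaticsConfig | None = None,
                 lj_params: es.LJParams | None = None,
                 lj_shift: bool = True,
                 electrostatics_enabled: bool = True,
                 lj_enabled: bool = True):
        self.state = state
        self.models = models
        self.integrator = integrator or IntegratorConfig()
        self.es_config = es_config or es.ElectrostaticsConfig()
        self.lj_params = lj_params or es.LJParams()
        self.lj_shift = lj_shift
        self.electrostatics_enabled = electrostatics_enabled
        self.lj_enabled = lj_enabled
        self._ewald: es.Ewald | None = None
        self._ewald_L: float | None = None
        self._cached: ForceResult | None = None

    # -- forces ----------------------------------------------------------
    def _get_ewald(self, L: float) -> es.Ewald:
        if self._ewald is None or self._ewald_L != L:
            self._ewald = es.Ewald(L, self.es_config)
            self._ewald_L = L
        return self._ewald

    def compute_forces(self, positions: np.ndarray | None = None,
                       box_length: float | None = None,
                       want_virial: bool = False,
                       check_overlap: bool = True) -> ForceResult:
        st = self.state
        pos = st.positions if positions is None else positions
        L = st.box_length if box_length is None else box_length
        res = self._forces_at(pos, L, check_overlap=check_overlap)
        if want_virial:
            # central-difference atomic-scaling virial W = -3V dU/dV
            if L is None:
                raise ValueError("virial needs a periodic box")
            d = 1e-4
            up = self._forces_at(pos * (1 + d), L * (1 + d), check_overlap=False).e_pot
            dn = self._forces_at(pos * (1 - d), L * (1 - d), check_overlap=False).e_pot
            dv = L ** 3 * ((1 + d) ** 3 - (1 - d) ** 3)
            res.virial = -3.0 * L ** 3 * (up - dn) / dv
        return res

    def _forces_at(self, pos: np.ndarray, L: float | None,
                   check_overlap: bool = True) -> ForceResult:
        st = self.state
        n = pos.shape[0]
        if not np.all(np.isfinite(pos)):
            raise IntegrationFailure(f"non-finite coordinates at step {st.step}")
        if check_overlap and n > 1:
            ii, jj = np.triu_indices(n, k=1)
            d = pos[ii] - pos[jj]
            if L is not None:
                d -= L * np.round(d / L)
            rmin = math.sqrt(float(np.min(np.einsum("mi,mi->m", d, d))))
            if rmin < HARD_FLOOR:
                raise OverlapError(
                    f"atom pair at {rmin:.3f} A (< {HARD_FLOOR} A) at step {st.step}")

        forces = np.zeros((n, 3))
        e_gpr = 0.0
        if self.models is not None:
            mol_coords = pos[st.molecules]                    # (n_mol, 3, 3)
            e_arr, f_mol = self.models.predict_energy_forces(mol_coords)
            np.add.at(forces, st.molecules, f_mol)
            e_gpr = float(e_arr.sum())

        e_elec = 0.0
        dip = np.zeros(3)
        if (self.electrostatics_enabled and self.models is not None
                and self.models.moments is not None):
            mol_coords = pos[st.molecules]
            mom = self.models.predict_moments(mol_coords, gradients=True)
            nsites = n
            q = np.zeros(nsites)
            mu = np.zeros((nsites, 3))
            th = np.zeros((nsites, 3, 3))
            q[st.molecules] = mom["q"]
            mu[st.molecules] = mom["mu"]
            th[st.molecules] = mom["theta"]
            mol_id = np.empty(n, dtype=int)
            for m, idx in enumerate(st.molecules):
                mol_id[idx] = m
            if L is None:
                e_elec, f_fixed, phi = es.direct_sum(
                    pos, q, mu, th, lprime=self.es_config.lprime, exclusions=mol_id)
            else:
                r = self._get_ewald(L).compute(pos, q, mu, th, molecule=mol_id)
                e_elec, f_fixed, phi = r.energy, r.forces, r.phi
            forces += f_fixed
            forces += es.assemble_flexible_forces(
                phi, st.molecules, mom["dq"], mom["dmu"], mom["dtheta"])
            dip = q @ pos + mu.sum(axis=0)

        e_lj = 0.0
        if self.lj_enabled:
            mol_id = np.empty(n, dtype=int)
            for m, idx in enumerate(st.molecules):
                mol_id[idx] = m
            e_lj, f_lj, _ = es.lj_energy_forces(
                pos, np.asarray(st.elements), mol_id, self.lj_params,
                rcut=self.es_config.rcut, box_length=L, shift=self.lj_shift)
            forces += f_lj

        return ForceResult(forces=forces, e_gpr=e_gpr, e_elec=e_elec,
                           e_lj=float(e_lj), total_dipole=dip)

    # -- thermostat ------------------------------------------------------
    def _nhc_masses(self) -> np.ndarray:
        cfg = self.integrator
        kt = KB * cfg.temperature
        Q = np.full(cfg.chain, kt * cfg.tau_t_ps ** 2)
        Q[0] *= self.state.n_dof
        return Q

    def _nhc_half(self, dt: float) -> None:
        """Half-step Nose-Hoover chain update; scales the velocities."""
        st = self.state
        cfg = self.integrator
        kt = KB * cfg.temperature
        Q = self._nhc_masses()
        M = cfg.chain
        k2 = 2.0 * st.kinetic_energy()
        dt2, dt4, dt8 = dt / 2, dt / 4, dt / 8
        G = np.empty(M)
        G[0] = (k2 - st.n_dof * kt) / Q[0]
        for j in range(1, M):
            G[j] = (Q[j - 1] * st.vxi[j - 1] ** 2 - kt) / Q[j]
        st.vxi[M - 1] += G[M - 1] * dt4
        for j in range(M - 2, -1, -1):
            e = math.exp(-dt8 * st.vxi[j + 1])
            st.vxi[j] = (st.vxi[j] * e + G[j] * dt4) * e
        scale = math.exp(-dt2 * st.vxi[0])
        st.velocities *= scale
        k2 *= scale * scale
        st.xi += dt2 * st.vxi
        G[0] = (k2 - st.n_dof * kt) / Q[0]
        for j in range(M - 1):
            e = math.exp(-dt8 * st.vxi[j + 1])
            st.vxi[j] = (st.vxi[j] * e + G[j] * dt4) * e
            G[j + 1] = (Q[j] * st.vxi[j] ** 2 - kt) / Q[j + 1]
        st.vxi[M - 1] += G[M - 1] * dt4

    def thermostat_energy(self) -> float:
        cfg = self.integrator
        kt = KB * cfg.temperature
        Q = self._nhc_masses()
        e = 0.5 * float(np.sum(Q * self.state.vxi ** 2))
        e += self.state.n_dof * kt * self.state.xi[0] + kt * float(self.state.xi[1:].sum())
        return e

    # -- steps -----------------------------------------------------------
    def _ensure_cached(self, want_virial=False) -> ForceResult:
        if self._cached is None or (want_virial and self._cached.virial is None):
            self._cached = self.compute_forces(want_virial=want_virial)
        return self._cached

    def nve_step(self) -> None:
        st = self.state
        dt = self.integrator.dt_fs * 1e-3
        f = self._ensure_cached()
        acc = f.forces / (st.masses[:, None] * MV2_TO_KJMOL)
        st.velocities += 0.5 * dt * acc
        st.positions += dt * st.velocities
        f2 = self.compute_forces()
        acc2 = f2.forces / (st.masses[:, None] * MV2_TO_KJMOL)
        st.velocities += 0.5 * dt * acc2
        self._cached = f2
        st.step += 1

    def nvt_step(self) -> None:
        dt = self.integrator.dt_fs * 1e-3
        self._nhc_half(dt)
        self.nve_step()
        self._nhc_half(dt)

    def npt_step(self) -> None:
        """Isotropic MTK cell dynamics with a Nose-Hoover chain."""
        st = self.state
        cfg = self.integrator
        if st.box_length is None:
            raise ValueError("NPT needs a periodic box")
        dt = cfg.dt_fs * 1e-3
        kt = KB * cfg.temperature
        p_ext = cfg.pressure_atm / KJMOLA3_TO_ATM     # kJ/mol/A^3
        W = (st.n_dof + 3) * kt * cfg.tau_p_ps ** 2
        a = 1.0 + 3.0 / st.n_dof

        self._nhc_half(dt)
        # couple the cell momentum to the first thermostat
        st.baro_p *= math.exp(-0.5 * dt * st.vxi[0])

        f = self._ensure_cached(want_virial=True)
        V = st.volume()
        G = a * 2.0 * st.kinetic_energy() + f.virial - 3.0 * V * p_ext
        st.baro_p += 0.5 * dt * G

        veps = st.baro_p / W
        x = 0.5 * dt * a * veps
        acc = f.forces / (st.masses[:, None] * MV2_TO_KJMOL)
        st.velocities = (st.velocities * math.exp(-x)
                         + 0.5 * dt * acc * math.exp(-x / 2) * _sinhc(x / 2))

        xr = dt * veps
        st.positions = (st.positions * math.exp(xr)
                        + dt * st.velocities * math.exp(xr / 2) * _sinhc(xr / 2))
        st.baro_eps += veps * dt
        st.box_length *= math.exp(xr)   # V scales as exp(3 veps dt)
        self._cached = None

        f2 = self.compute_forces(want_virial=True)
        acc2 = f2.forces / (st.masses[:, None] * MV2_TO_KJMOL)
        st.velocities = (st.velocities * math.exp(-x)
                         + 0.5 * dt * acc2 * math.exp(-x / 2) * _sinhc(x / 2))
        V = st.volume()
        G = a * 2.0 * st.kinetic_energy() + f2.virial - 3.0 * V * p_ext
        st.baro_p += 0.5 * dt * G
        st.baro_p *= math.exp(-0.5 * dt * st.vxi[0])
        self._cached = f2
        self._nhc_half(dt)
        st.step += 1

    def step(self) -> None:
        getattr(self, f"{self.integrator.ensemble}_step")()

    def conserved_quantity(self) -> float:
        f = self._ensure_cached()
        e = f.e_pot + self.state.kinetic_energy()
        cfg = self.integrator
        if cfg.ensemble in ("nvt", "npt"):
            e += self.thermostat_energy()
        if cfg.ensemble == "npt":
            kt = KB * cfg.temperature
            W = (self.state.n_dof + 3) * kt * cfg.tau_p_ps ** 2
            p_ext = cfg.pressure_atm / KJMOLA3_TO_ATM
            e += self.state.baro_p ** 2 / (2.0 * W) + p_ext * self.state.volume()
        return e

    def pressure(self) -> float:
        """Instantaneous pressure in atm (virial route)."""
        f = self._ensure_cached(want_virial=True)
        V = self.state.volume()
        p = (2.0 * self.state.kinetic_energy() + f.virial) / (3.0 * V)
        return p * KJMOLA3_TO_ATM

    def invalidate_forces(self) -> None:
        self._cached = None
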
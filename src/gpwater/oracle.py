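"""Synthetic per-atom property oracle for distorted water monomers.

Stand-in for the quantum-chemistry pipeline that, in production use of this
kind of force field, turns a monomer geometry into per-atom energies and
multipole moments (a DFT wavefunction partitioned into atomic basins).  Here
both are closed-form functions of the internal coordinates so that every
downstream stage (feature building, GPR training, electrostatics, dynamics)
can be tested against known ground truth.  The constants are documented
non-physical stand-ins chosen to be water-like in scale, not fitted to any
ab initio data.

**Molecular potential energy surface** (kJ/mol), in the internal coordinates
``r1 = d(O,H1)``, ``r2 = d(O,H2)``, ``a = angle(H1-O-H2)``::

    E(r1, r2, a) = De [ (1 - exp(-aM (r1-r0)))^2 + (1 - exp(-aM (r2-r0)))^2 ]
                   + 1/2 kA (a - a0)^2
                   + krr (r1-r0)(r2-r0)
                   + kra [(r1-r0) + (r2-r0)] (a - a0)
                   + E0

two Morse bonds, a harmonic bend, bond-bond and bond-angle couplings; the
minimum sits exactly at the equilibrium geometry (r0, r0, a0).  The molecular
energy is partitioned into per-atom shares by fixed fractions plus a smooth
geometry-dependent transfer term that moves energy between O and the
hydrogens while summing to zero, so the partition reproduces the molecular
total identically.

**Multipole moments** come from an explicit auxiliary point-charge
construction: geometry-dependent site charges (hydrogens carry
``qh0 + c_self dr_i + c_other dr_j + c_ang da``, oxygen the exact negative
sum) plus, per atom, a small satellite charge pair at fixed positions in the
atom's local frame with geometry-dependent strength.  The atomic dipole and
traceless quadrupole of an atom are the exact moments of its satellites about
the atom, so electroneutrality and tracelessness hold by construction and the
molecular dipole equals that of the explicit array.  All charges carry a
single overall scale factor calibrated so the equilibrium molecular dipole is
exactly ``dipole_target`` (2.15 D by default, emulating an implicit-solvent
polarized monomer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from . import features as ft
from .electrostatics import MultipoleSet
from .units import DEG, EA_TO_DEBYE

__all__ = [
    "OracleConfig",
    "MonomerGeometry",
    "OracleProperties",
    "equilibrium_geometry",
    "geometry_from_internals",
    "oracle_energies",
    "oracle_energy_gradient",
    "oracle_multipoles",
    "oracle_properties",
    "sample_geometries",
    "write_training_set",
]

ELEMENTS = ("O", "H", "H")


class GeometryDomainError(ValueError):
    """Geometry outside the oracle's domain of validity."""


@dataclass(frozen=True)
class OracleConfig:
    """Constants of the analytic surrogate (documented stand-ins)."""

    # PES
    de: float = 450.0          # Morse well depth, kJ/mol
    a_morse: float = 2.2       # Morse range parameter, 1/A
    r0: float = 0.96           # equilibrium O-H, A
    ang0: float = 104.5 * DEG  # equilibrium H-O-H, rad
    k_ang: float = 300.0       # bend force constant, kJ/mol/rad^2
    k_rr: float = 30.0         # bond-bond coupling, kJ/mol/A^2
    k_ra: float = -20.0        # bond-angle coupling, kJ/mol/(A rad)
    e0: float = -250.0         # molecular offset, kJ/mol
    # partition
    w_oxygen: float = 0.8      # share of e0 on O (hydrogens split the rest)
    c_transfer: float = 5.0    # smooth O<->H energy transfer amplitude, kJ/mol
    # site charges (unscaled)
    qh0: float = 0.45
    c_self: float = 0.20       # e/A, response of q_H to its own bond
    c_other: float = -0.06     # e/A, response to the other bond
    c_ang: float = 0.05        # e/rad
    # satellite pairs: local-frame positions and unscaled strengths
    sat_o_pos: tuple = ((0.25, 0.15, 0.0), (0.25, -0.15, 0.0))
    sat_h_pos: tuple = ((-0.10, 0.12, 0.0), (-0.10, -0.12, 0.0))
    sat_o0: float = 0.30       # e
    sat_h0: float = 0.12       # e
    g_o_r: float = 0.30        # 1/A, satellite strength response
    g_o_ang: float = 0.20      # 1/rad
    g_h_r: float = 0.40
    g_h_ang: float = -0.10
    # calibration
    dipole_target: float = 2.15  # debye at equilibrium
    charge_scale: float | None = None  # filled in by calibration

    def calibrated(self) -> "OracleConfig":
        """Return a copy whose charge scale hits `dipole_target` exactly."""
        if self.charge_scale is not None:
            return self
        base = replace(self, charge_scale=1.0)
        geom = equilibrium_geometry(base)
        props = oracle_multipoles(geom, base)
        d = _molecular_dipole(geom.coords, props)
        scale = self.dipole_target / (np.linalg.norm(d) * EA_TO_DEBYE)
        return replace(self, charge_scale=scale)


DEFAULT_CONFIG: OracleConfig | None = None  # calibrated lazily by get_config()


@dataclass
class MonomerGeometry:
    """One water monomer, atoms ordered O, H1, H2, coordinates in A."""

    coords: np.ndarray
    elements: tuple = ELEMENTS

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3, 3):
            raise GeometryDomainError(
                f"monomer must have exactly 3 atoms, got shape {self.coords.shape}")
        r1, r2, ang = self.internals()
        for name, r in (("O-H1", r1), ("O-H2", r2)):
            if not 0.5 < r < 1.6:
                raise GeometryDomainError(
                    f"{name} distance {r:.3f} A outside (0.5, 1.6) A")
        if not 60.0 * DEG < ang < 180.0 * DEG:
            raise GeometryDomainError(
                f"H-O-H angle {ang / DEG:.1f} deg outside (60, 180) deg")

    def internals(self) -> tuple[float, float, float]:
        v1 = self.coords[1] - self.coords[0]
        v2 = self.coords[2] - self.coords[0]
        r1 = float(np.linalg.norm(v1))
        r2 = float(np.linalg.norm(v2))
        ang = float(np.arccos(np.clip(np.dot(v1, v2) / (r1 * r2), -1.0, 1.0)))
        return r1, r2, ang


@dataclass
class OracleProperties:
    """Per-atom IQA-style energies plus multipoles for one monomer."""

    atom_energies: np.ndarray            # (3,) kJ/mol, sums to molecular_energy
    e_intra: np.ndarray                  # (3,) emulated intra-atomic share
    e_inter: np.ndarray                  # (3,) emulated interaction share
    molecular_energy: float
    multipoles: list[MultipoleSet]       # per atom, global frame
    molecular_dipole_debye: float


def get_config() -> OracleConfig:
    global DEFAULT_CONFIG
    if DEFAULT_CONFIG is None:
        DEFAULT_CONFIG = OracleConfig().calibrated()
    return DEFAULT_CONFIG


def geometry_from_internals(r1: float, r2: float, ang: float) -> MonomerGeometry:
    """Canonical placement: O at origin, H1 on +x, H2 in the x-y plane."""
    coords = np.array([
        [0.0, 0.0, 0.0],
        [r1, 0.0, 0.0],
        [r2 * math.cos(ang), r2 * math.sin(ang), 0.0],
    ])
    return MonomerGeometry(coords)


def equilibrium_geometry(config: OracleConfig | None = None) -> MonomerGeometry:
    cfg = config or get_config()
    return geometry_from_internals(cfg.r0, cfg.r0, cfg.ang0)


# --------------------------------------------------------------------------
# energies

def _pes_terms(r1, r2, ang, cfg: OracleConfig):
    d1, d2, da = r1 - cfg.r0, r2 - cfg.r0, ang - cfg.ang0
    m1 = cfg.de * (1.0 - math.exp(-cfg.a_morse * d1)) ** 2
    m2 = cfg.de * (1.0 - math.exp(-cfg.a_morse * d2)) ** 2
    bend = 0.5 * cfg.k_ang * da ** 2
    coup = cfg.k_rr * d1 * d2 + cfg.k_ra * (d1 + d2) * da
    return m1, m2, bend, coup


def molecular_energy(geom: MonomerGeometry, config: OracleConfig | None = None) -> float:
    cfg = config or get_config()
    m1, m2, bend, coup = _pes_terms(*geom.internals(), cfg)
    return m1 + m2 + bend + coup + cfg.e0


def oracle_energies(geom: MonomerGeometry,
                    config: OracleConfig | None = None) -> OracleProperties:
    """Per-atom energies whose sum is exactly the molecular PES value."""
    cfg = config or get_config()
    r1, r2, ang = geom.internals()
    m1, m2, bend, coup = _pes_terms(r1, r2, ang, cfg)
    e_mol = m1 + m2 + bend + coup + cfg.e0
    w_h = 0.5 * (1.0 - cfg.w_oxygen)
    transfer = cfg.c_transfer * math.sin(ang) * 0.5 * (r1 + r2)
    shared = 0.5 * (bend + coup)
    e_o = 0.5 * (m1 + m2) + shared + cfg.w_oxygen * cfg.e0 + transfer
    e_h1 = 0.5 * m1 + 0.5 * shared + w_h * cfg.e0 - 0.5 * transfer
    e_h2 = 0.5 * m2 + 0.5 * shared + w_h * cfg.e0 - 0.5 * transfer
    atom_e = np.array([e_o, e_h1, e_h2])
    # emulated intra/inter split: offsets+transfer are "intra", bonded terms "inter"
    e_intra = np.array([cfg.w_oxygen * cfg.e0 + transfer,
                        w_h * cfg.e0 - 0.5 * transfer,
                        w_h * cfg.e0 - 0.5 * transfer])
    e_inter = atom_e - e_intra
    props = oracle_multipoles(geom, cfg)
    d = _molecular_dipole(geom.coords, props)
    return OracleProperties(
        atom_energies=atom_e, e_intra=e_intra, e_inter=e_inter,
        molecular_energy=e_mol, multipoles=props,
        molecular_dipole_debye=float(np.linalg.norm(d) * EA_TO_DEBYE),
    )


def oracle_energy_gradient(geom: MonomerGeometry,
                           config: OracleConfig | None = None) -> np.ndarray:
    """Analytic Cartesian gradient (3, 3) of the molecular PES."""
    cfg = config or get_config()
    r1, r2, ang = geom.internals()
    d1, d2, da = r1 - cfg.r0, r2 - cfg.r0, ang - cfg.ang0
    x1 = math.exp(-cfg.a_morse * d1)
    x2 = math.exp(-cfg.a_morse * d2)
    de_dr1 = 2.0 * cfg.de * (1.0 - x1) * cfg.a_morse * x1 + cfg.k_rr * d2 + cfg.k_ra * da
    de_dr2 = 2.0 * cfg.de * (1.0 - x2) * cfg.a_morse * x2 + cfg.k_rr * d1 + cfg.k_ra * da
    de_da = cfg.k_ang * da + cfg.k_ra * (d1 + d2)
    _, jac = ft.batch_features(geom.coords, 0)   # features are (r1, r2, ang)
    return np.einsum("f,fax->ax", np.array([de_dr1, de_dr2, de_da]), jac)


# --------------------------------------------------------------------------
# multipoles

def _site_charges(r1, r2, ang, cfg: OracleConfig) -> np.ndarray:
    d1, d2, da = r1 - cfg.r0, r2 - cfg.r0, ang - cfg.ang0
    qh1 = cfg.qh0 + cfg.c_self * d1 + cfg.c_other * d2 + cfg.c_ang * da
    qh2 = cfg.qh0 + cfg.c_self * d2 + cfg.c_other * d1 + cfg.c_ang * da
    return np.array([-(qh1 + qh2), qh1, qh2])


def _satellites(geom: MonomerGeometry, cfg: OracleConfig):
    """Global-frame satellite positions/charges for each atom (unscaled)."""
    r1, r2, ang = geom.internals()
    d1, d2, da = r1 - cfg.r0, r2 - cfg.r0, ang - cfg.ang0
    strengths = [
        cfg.sat_o0 * (1.0 + cfg.g_o_r * (d1 + d2) + cfg.g_o_ang * da),
        cfg.sat_h0 * (1.0 + cfg.g_h_r * d1 + cfg.g_h_ang * da),
        cfg.sat_h0 * (1.0 + cfg.g_h_r * d2 + cfg.g_h_ang * da),
    ]
    local_pos = [np.asarray(cfg.sat_o_pos), np.asarray(cfg.sat_h_pos),
                 np.asarray(cfg.sat_h_pos)]
    out = []
    for atom in range(3):
        R = ft.batch_local_frames(geom.coords, atom)   # global -> local
        pg = geom.coords[atom] + local_pos[atom] @ R   # rows are axes: p_glob = R^T p_loc
        out.append((pg, np.array([strengths[atom], -strengths[atom]])))
    return out


def oracle_multipoles(geom: MonomerGeometry,
                      config: OracleConfig | None = None) -> list[MultipoleSet]:
    """Geometry-dependent per-atom charge, dipole and traceless quadrupole."""
    cfg = config or get_config()
    scale = cfg.charge_scale if cfg.charge_scale is not None else 1.0
    r1, r2, ang = geom.internals()
    qs = _site_charges(r1, r2, ang, cfg) * scale
    sats = _satellites(geom, cfg)
    out = []
    for atom in range(3):
        pg, sq = sats[atom]
        sq = sq * scale
        rel = pg - geom.coords[atom]
        mu = sq @ rel
        rr = np.einsum("s,si,sj->ij", sq, rel, rel)
        theta = 1.5 * rr - 0.5 * np.trace(rr) * np.eye(3)
        theta = 0.5 * (theta + theta.T)
        out.append(MultipoleSet(q=float(qs[atom]), mu=mu, theta=theta))
    return out


def _molecular_dipole(coords: np.ndarray, multipoles: list[MultipoleSet]) -> np.ndarray:
    """Molecular dipole (e*A) from site charges + atomic dipoles, about the
    centre of charge; exact for a neutral molecule."""
    d = np.zeros(3)
    for xyz, m in zip(coords, multipoles):
        d += m.q * xyz + m.mu
    return d


def molecular_dipole(geom: MonomerGeometry,
                     config: OracleConfig | None = None) -> np.ndarray:
    return _molecular_dipole(geom.coords, oracle_multipoles(geom, config))


def explicit_charge_array(geom: MonomerGeometry,
                          config: OracleConfig | None = None):
    """The underlying point-charge array (positions, charges), global frame.

    Site charges at the nuclei plus the satellite pairs; the oracle's
    multipoles are exactly the per-atom moments of this array, so its total
    dipole is a brute-force cross-check of the q + mu moments.
    """
    cfg = config or get_config()
    scale = cfg.charge_scale if cfg.charge_scale is not None else 1.0
    qs = _site_charges(*geom.internals(), cfg) * scale
    pos = [geom.coords]
    chg = [qs]
    for pg, sq in _satellites(geom, cfg):
        pos.append(pg)
        chg.append(sq * scale)
    return np.vstack(pos), np.concatenate(chg)


def oracle_properties(geom: MonomerGeometry,
                      config: OracleConfig | None = None) -> OracleProperties:
    """Energies and multipoles in one record."""
    return oracle_energies(geom, config)


# --------------------------------------------------------------------------
# geometry sampling

def sample_geometries(n: int, spread: float = 1.0,
                      seed: int | np.random.Generator = 0,
                      config: OracleConfig | None = None) -> list[MonomerGeometry]:
    """Distorted monomers with liquid-like internal-coordinate coverage.

    Bond lengths and angle are drawn independently from truncated normals
    centred slightly above the equilibrium values (bonds in a liquid are
    stretched relative to the isolated-molecule minimum): at ``spread = 1``
    bonds cover ~0.90-1.10 A and the angle ~95-115 deg; ``spread = 0``
    collapses to the equilibrium geometry.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 geometries, got {n}")
    if spread < 0:
        raise ValueError("spread must be non-negative")
    cfg = config or get_config()
    if spread == 0.0:
        return [equilibrium_geometry(cfg) for _ in range(n)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def trunc(lo, hi, mean, sd, size):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)

    r_mean = cfg.r0 + 0.04 * spread
    r = trunc(cfg.r0 - 0.06 * spread, cfg.r0 + 0.14 * spread,
              r_mean, 0.035 * spread, (n, 2))
    a_mean = cfg.ang0 + 0.5 * DEG * spread
    ang = trunc(cfg.ang0 - 9.5 * DEG * spread, cfg.ang0 + 10.5 * DEG * spread,
                a_mean, 3.5 * DEG * spread, n)
    return [geometry_from_internals(r[i, 0], r[i, 1], ang[i]) for i in range(n)]


def write_training_set(geoms: list[MonomerGeometry], xyz_path, csv_path,
                       config: OracleConfig | None = None) -> None:
    """Write geometries (extended XYZ) and per-atom properties (CSV)."""
    from . import io as gio
    cfg = config or get_config()
    rows = []
    frames = []
    for ig, geom in enumerate(geoms):
        props = oracle_energies(geom, cfg)
        frames.append((geom.coords, list(geom.elements), {"geometry": ig}))
        for ia in range(3):
            m = props.multipoles[ia]
            rows.append({
                "geometry": ig, "atom": ia, "element": geom.elements[ia],
                "energy": props.atom_energies[ia], "q": m.q,
                "mux": m.mu[0], "muy": m.mu[1], "muz": m.mu[2],
                "thxx": m.theta[0, 0], "thxy": m.theta[0, 1],
                "thxz": m.theta[0, 2], "thyy": m.theta[1, 1],
                "thyz": m.theta[1, 2],
            })
    gio.write_extxyz(xyz_path, frames)
    import pandas as pd
    pd.DataFrame(rows).to_csv(csv_path, index=False)
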
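"""In-situ electrostatics validation on harvested water dimers.

Close dimers (O-O distance up to a harvest cutoff, 3.5 A by default) are
collected from trajectory frames and parameterised by 12 internal
coordinates: 2 bonds + 1 angle per molecule, spherical polar coordinates of
the second oxygen in the first molecule's O-centred local frame, and three
ZYZ Euler angles for the second molecule's orientation in that frame.  The
12 marginal distributions are sampled independently to produce a
representative dimer set (100 by default), and the per-dimer electrostatic
prediction error is the sum over the nine intermolecular atom pairs of the
absolute difference between pair energies computed with reference and with
predicted multipole moments, at each truncation level L' = 0, 1, 2.

Reference moments are monomer-wise (each molecule's moments evaluated in
isolation), matching how monomeric models are trained; at desk scale they
come from the synthetic oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import features as ft
from .electrostatics import MultipoleSet, pair_multipole_energy
from .gpr import SCurve, WaterModels, s_curve

__all__ = [
    "DimerRecord",
    "dimer_record_from_coords",
    "harvest_dimers",
    "sample_representative",
    "electrostatic_error",
    "error_s_curves",
    "oracle_dimer_moments",
    "predicted_dimer_moments",
]

FIELD_NAMES = ("r1a", "r1b", "ang1", "r2a", "r2b", "ang2",
               "R", "polar", "azimuth", "euler_a", "euler_b", "euler_g")


@dataclass
class DimerRecord:
    """12 internal coordinates of a water dimer (+ provenance tags).

    The first molecule owns the frame (lower molecule index when harvested).
    """

    values: np.ndarray               # (12,) in the FIELD_NAMES order
    frame: int = -1                  # source trajectory frame
    pair: tuple = (-1, -1)           # source molecule indices

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError("a dimer record has exactly 12 coordinates")

    def reconstruct(self) -> tuple[np.ndarray, np.ndarray]:
        """Cartesian coordinates (two (3,3) arrays) in the first molecule's
        frame; identical to the source dimer up to rigid motion."""
        v = self.values
        mol1 = _canonical_monomer(v[0], v[1], v[2])
        mol2 = _canonical_monomer(v[3], v[4], v[5])
        R, th, ph = v[6], v[7], v[8]
        o2 = R * np.array([math.sin(th) * math.cos(ph),
                           math.sin(th) * math.sin(ph),
                           math.cos(th)])
        A = _euler_zyz(v[9], v[10], v[11])
        return mol1, mol2 @ A.T + o2


def _canonical_monomer(r1, r2, ang) -> np.ndarray:
    return np.array([[0.0, 0.0, 0.0],
                     [r1, 0.0, 0.0],
                     [r2 * math.cos(ang), r2 * math.sin(ang), 0.0]])


def _euler_zyz(a, b, g) -> np.ndarray:
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cg, sg = math.cos(g), math.sin(g)
    return np.array([
        [ca * cb * cg - sa * sg, -ca * cb * sg - sa * cg, ca * sb],
        [sa * cb * cg + ca * sg, -sa * cb * sg + ca * cg, sa * sb],
        [-sb * cg, sb * sg, cb],
    ])


def _euler_from_matrix(A: np.ndarray) -> tuple[float, float, float]:
    """ZYZ angles of a proper rotation; gamma = 0 at the gimbal limit."""
    cb = float(np.clip(A[2, 2], -1.0, 1.0))
    b = math.acos(cb)
    if abs(abs(cb) - 1.0) < 1e-12:
        return math.atan2(A[1, 0], A[0, 0]), b, 0.0
    a = math.atan2(A[1, 2], A[0, 2])
    g = math.atan2(A[2, 1], -A[2, 0])
    return a, b, g


def _monomer_internals(coords: np.ndarray) -> tuple[float, float, float]:
    v1 = coords[1] - coords[0]
    v2 = coords[2] - coords[0]
    r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
    ang = math.acos(float(np.clip(v1 @ v2 / (r1 * r2), -1.0, 1.0)))
    return float(r1), float(r2), ang


def dimer_record_from_coords(mol1: np.ndarray, mol2: np.ndarray,
                             frame: int = -1, pair: tuple = (-1, -1)) -> DimerRecord:
    """Parameterise a Cartesian dimer; molecule 1 owns the local frame."""
    mol1 = np.asarray(mol1, dtype=float)
    mol2 = np.asarray(mol2, dtype=float)
    r1a, r1b, ang1 = _monomer_internals(mol1)
    r2a, r2b, ang2 = _monomer_internals(mol2)
    R1 = ft.batch_local_frames(mol1, 0)              # global -> frame1
    rel = R1 @ (mol2[0] - mol1[0])
    R = float(np.linalg.norm(rel))
    polar = math.acos(float(np.clip(rel[2] / R, -1.0, 1.0)))
    azimuth = math.atan2(rel[1], rel[0])
    R2 = ft.batch_local_frames(mol2, 0)
    A = R1 @ R2.T                                    # canonical mol2 -> frame1
    ea, eb, eg = _euler_from_matrix(A)
    return DimerRecord(values=np.array([r1a, r1b, ang1, r2a, r2b, ang2,
                                        R, polar, azimuth, ea, eb, eg]),
                       frame=frame, pair=tuple(pair))


# --------------------------------------------------------------------------
# harvesting and sampling

def harvest_dimers(frames, molecules, box_length: float | None,
                   cutoff: float = 3.5) -> list[DimerRecord]:
    """All O-O pairs at or below ``cutoff`` (inclusive), minimum image."""
    molecules = np.asarray(molecules)
    out = []
    for f, pos in enumerate(np.asarray(frames, dtype=float)):
        opos = pos[molecules[:, 0]]
        n = opos.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        d = opos[ii] - opos[jj]
        shift = np.zeros_like(d)
        if box_length is not None:
            shift = -box_length * np.round(d / box_length)
            d = d + shift
        r = np.sqrt(np.einsum("mi,mi->m", d, d))
        for k in np.flatnonzero(r <= cutoff):
            i, j = int(ii[k]), int(jj[k])
            mol1 = pos[molecules[i]]
            mol2 = pos[molecules[j]] - shift[k]      # image closest to mol1
            out.append(dimer_record_from_coords(mol1, mol2, frame=f, pair=(i, j)))
    return out


def sample_representative(records: list[DimerRecord], n: int = 100,
                          seed: int = 0, clash_distance: float = 1.2,
                          max_tries: int = 1000):
    """Independent bootstrap of the 12 marginals, with clash rejection.

    Each coordinate of each sample is drawn independently from that
    coordinate's harvested marginal distribution, so the samples span the
    observed range in every dimension; joint geometries with any
    intermolecular atom pair closer than ``clash_distance`` are rejected and
    redrawn.  Returns ``(samples, n_rejected)``.
    """
    if not records:
        raise ValueError("no harvested dimers to sample from")
    rng = np.random.default_rng(seed)
    table = np.array([r.values for r in records])    # (m, 12)
    out = []
    rejected = 0
    for _ in range(n):
        for _try in range(max_tries):
            v = table[rng.integers(0, table.shape[0], size=12), np.arange(12)]
            rec = DimerRecord(values=v)
            m1, m2 = rec.reconstruct()
            dmin = np.min(np.linalg.norm(m1[:, None, :] - m2[None, :, :], axis=2))
            if dmin >= clash_distance:
                out.append(rec)
                break
            rejected += 1
        else:
            raise RuntimeError("clash rejection failed to find a valid dimer")
    return out, rejected


# --------------------------------------------------------------------------
# electrostatic error

def _moments_for(coords: np.ndarray, source) -> list[MultipoleSet]:
    """Monomer-wise moments of one molecule from a model set or the oracle."""
    if isinstance(source, WaterModels):
        mom = source.predict_moments(coords[None], gradients=False)
        return [MultipoleSet(q=float(mom["q"][0, s]), mu=mom["mu"][0, s],
                             theta=mom["theta"][0, s]) for s in range(3)]
    # oracle path
    from . import oracle as orc
    geom = orc.MonomerGeometry(coords)
    return orc.oracle_multipoles(geom, source if isinstance(source, orc.OracleConfig) else None)


def oracle_dimer_moments(mol1, mol2) -> list[MultipoleSet]:
    """Reference moments: each molecule evaluated in isolation by the oracle."""
    return _moments_for(np.asarray(mol1, float), None) + \
        _moments_for(np.asarray(mol2, float), None)


def predicted_dimer_moments(models: WaterModels, mol1, mol2) -> list[MultipoleSet]:
    return _moments_for(np.asarray(mol1, float), models) + \
        _moments_for(np.asarray(mol2, float), models)


def electrostatic_error(mol1, mol2, reference: list[MultipoleSet],
                        predicted: list[MultipoleSet], lprime: int) -> float:
    """Summed absolute pair-energy error over the 9 intermolecular pairs."""
    if len(reference) != 6 or len(predicted) != 6:
        raise ValueError("need moments for all 6 atoms of the dimer")
    coords = np.vstack([np.asarray(mol1, float), np.asarray(mol2, float)])
    err = 0.0
    for a in range(3):
        for b in range(3, 6):
            rab = coords[b] - coords[a]
            e_ref, _ = pair_multipole_energy(reference[a], reference[b], rab, lprime)
            e_prd, _ = pair_multipole_energy(predicted[a], predicted[b], rab, lprime)
            err += abs(e_ref - e_prd)
    return err


def error_s_curves(errors_by_level: dict[int, np.ndarray]) -> dict[int, SCurve]:
    """One cumulative error curve per truncation level."""
    return {lp: s_curve(np.asarray(e)) for lp, e in errors_by_level.items()}


def dimer_error_experiment(models: WaterModels, dimers: list[DimerRecord],
                           levels=(0, 1, 2)) -> dict[int, np.ndarray]:
    """Reference-vs-predicted electrostatic errors for a set of dimers."""
    errors = {lp: np.empty(len(dimers)) for lp in levels}
    for i, rec in enumerate(dimers):
        m1, m2 = rec.reconstruct()
        ref = oracle_dimer_moments(m1, m2)
        prd = predicted_dimer_moments(models, m1, m2)
        for lp in levels:
            errors[lp][i] = electrostatic_error(m1, m2, ref, prd, lp)
    return errors
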
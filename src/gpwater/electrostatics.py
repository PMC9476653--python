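"""Point traceless Cartesian multipole electrostatics, Ewald summation and LJ.

Sites carry a charge ``q`` (e), a dipole ``mu`` (e*A) and a traceless
symmetric quadrupole ``theta`` (e*A^2).  With the traceless convention
``theta = 1/2 * sum_s q_s (3 r_s r_s - r_s^2 I)`` the potential generated at a
field point ``r`` by a site at ``r_s`` is::

    phi(r) = [ q - mu . grad + (1/3) theta : grad grad ] g(|r - r_s|)

with ``g = 1/r`` in open boundary (the 1/3 is the quadrupole contraction
prefactor that goes with traceless moments).  Every quantity this module
returns is derived from the per-site potential derivative arrays
``P0 = phi``, ``P1 = grad phi``, ``P2 = grad grad phi``, ``P3 = grad^3 phi``:

* energy        ``E = 1/2 sum_i [ q_i P0_i + mu_i . P1_i + (1/3) theta_i : P2_i ]``
* fixed-moment force ``F_i = -[ q_i P1_i + mu_i . P2_i + (1/3) theta_i : P3_i ]``
* moment derivatives ``dE/dq_i = P0_i``, ``dE/dmu_i = P1_i``,
  ``dE/dtheta_i = (1/3) P2_i`` (used for the extra force terms that arise when
  the moments themselves depend on atomic positions).

The same contraction engine runs open-boundary direct sums (Coulomb kernel),
the Ewald real-space part (erfc kernel), intramolecular exclusions and self
terms (erf kernel / its ``r -> 0`` series), so the periodic and open-boundary
paths agree by construction up to the Ewald precision target.  The Ewald
surface term uses the tin-foil (conducting) convention: no dipole surface
correction, which is what the dipole-fluctuation permittivity formula assumes.

Interaction tensors ``T(n) = grad^n g(r)`` up to rank 5 are assembled from the
scalar derivatives ``D_n = (1/r d/dr)^n g`` via the pairing expansion
``T(n) = sum_m D_{n-m} Sym[ delta^m u^(n-2m) ]``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .units import COULOMB

__all__ = [
    "MultipoleSet",
    "ElectrostaticsConfig",
    "LJParams",
    "PhiDerivs",
    "pair_multipole_energy",
    "direct_sum",
    "Ewald",
    "ewald_sum",
    "lj_energy_forces",
    "assemble_flexible_forces",
    "self_interaction_constant",
]

_NMAX = 5


# --------------------------------------------------------------------------
# types

@dataclass
class MultipoleSet:
    """Charge, dipole and traceless quadrupole of one site."""

    q: float = 0.0
    mu: np.ndarray = field(default_factory=lambda: np.zeros(3))
    theta: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    frame: str = "global"

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.mu.shape != (3,) or self.theta.shape != (3, 3):
            raise ValueError("dipole must be (3,), quadrupole (3,3)")
        if not np.allclose(self.theta, self.theta.T, atol=1e-10):
            raise ValueError("quadrupole must be symmetric")
        if abs(np.trace(self.theta)) > 1e-10 * max(1.0, np.abs(self.theta).max()):
            raise ValueError(f"quadrupole must be traceless, trace={np.trace(self.theta):g}")


@dataclass
class ElectrostaticsConfig:
    """Multipole truncation and Ewald controls.

    ``lprime`` is the highest multipole rank enabled; all pair interactions
    between enabled ranks are computed (lprime=2 includes
    quadrupole-quadrupole).  ``precision`` drives the automatic choice of the
    splitting parameter and reciprocal cutoff, mirroring the precision-target
    interface of mesh Ewald codes.
    """

    lprime: int = 2
    precision: float = 1e-7
    rcut: float = 8.0
    alpha: float | None = None
    kmax: float | None = None
    boundary: str = "tinfoil"

    def __post_init__(self):
        if self.lprime not in (0, 1, 2):
            raise ValueError(f"lprime must be 0, 1 or 2, got {self.lprime}")
        if self.boundary not in ("tinfoil", "vacuum"):
            raise ValueError("boundary must be 'tinfoil' or 'vacuum'")
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        if self.rcut <= 0:
            raise ValueError("rcut must be positive")


@dataclass
class LJParams:
    """12-6 parameters (kJ/mol, A); O-O and O-H pairs only, intermolecular."""

    eps_oo: float = 0.763
    sigma_oo: float = 3.17
    eps_oh: float = 0.106
    sigma_oh: float = 1.902

    def __post_init__(self):
        if min(self.eps_oo, self.sigma_oo, self.eps_oh, self.sigma_oh) <= 0:
            raise ValueError("all LJ parameters must be positive")


@dataclass
class PhiDerivs:
    """Per-site potential derivative arrays generated by all other sites."""

    p0: np.ndarray  # (n,)
    p1: np.ndarray  # (n, 3)
    p2: np.ndarray  # (n, 3, 3)
    p3: np.ndarray  # (n, 3, 3, 3)

    @classmethod
    def zeros(cls, n: int) -> "PhiDerivs":
        return cls(np.zeros(n), np.zeros((n, 3)), np.zeros((n, 3, 3)),
                   np.zeros((n, 3, 3, 3)))

    def __iadd__(self, other: "PhiDerivs") -> "PhiDerivs":
        self.p0 += other.p0
        self.p1 += other.p1
        self.p2 += other.p2
        self.p3 += other.p3
        return self


# --------------------------------------------------------------------------
# pairing expansion: constant symmetrisation matrices S[(n, m)] mapping the
# flattened (n-2m)-fold outer power of u onto the flattened rank-n tensor

def _pairing_matrices() -> dict[tuple[int, int], np.ndarray]:
    mats: dict[tuple[int, int], np.ndarray] = {}
    for n in range(_NMAX + 1):
        for m in range(n // 2 + 1):
            k = n - 2 * m
            S = np.zeros((3 ** n, 3 ** k))
            # enumerate distinct ways of choosing m disjoint index pairs
            for combo in _pairings(list(range(n)), m):
                pairs, singles = combo
                for idx in itertools.product(range(3), repeat=n):
                    ok = all(idx[a] == idx[b] for a, b in pairs)
                    if not ok:
                        continue
                    row = 0
                    for i in idx:
                        row = row * 3 + i
                    col = 0
                    for s in singles:
                        col = col * 3 + idx[s]
                    S[row, col] += 1.0
            mats[(n, m)] = S
    return mats


def _pairings(indices: list[int], m: int):
    """Distinct sets of m disjoint pairs from `indices` (plus leftovers)."""
    if m == 0:
        yield [], list(indices)
        return
    if len(indices) < 2 * m:
        return
    first, rest = indices[0], indices[1:]
    for j in range(len(rest)):
        for pairs, singles in _pairings(rest[:j] + rest[j + 1:], m - 1):
            yield [(first, rest[j])] + pairs, singles
    for pairs, singles in _pairings(rest, m):
        yield pairs, [first] + singles


_S = _pairing_matrices()


def _u_powers(u: np.ndarray, nmax: int) -> list[np.ndarray]:
    """Flattened outer powers of u: [(m,1), (m,3), (m,9), ...]."""
    out = [np.ones((u.shape[0], 1))]
    for _ in range(nmax):
        out.append(np.einsum("mp,mi->mpi", out[-1], u).reshape(u.shape[0], -1))
    return out


def t_tensors(u: np.ndarray, D: np.ndarray, nmax: int = _NMAX) -> list[np.ndarray]:
    """Interaction tensors T(n) = grad^n g for each pair vector.

    Parameters
    ----------
    u : (m, 3) pair vectors (field minus source)
    D : (m, nmax+1) scalar kernel derivatives D_n = (1/r d/dr)^n g
    """
    up = _u_powers(u, nmax)
    out = []
    for n in range(nmax + 1):
        acc = np.zeros((u.shape[0], 3 ** n))
        for m in range(n // 2 + 1):
            acc += D[:, n - m, None] * (up[n - 2 * m] @ _S[(n, m)].T)
        out.append(acc.reshape((u.shape[0],) + (3,) * n))
    return out


# --------------------------------------------------------------------------
# scalar kernels

def d_coulomb(r: np.ndarray, nmax: int = _NMAX) -> np.ndarray:
    """D_n for g = 1/r:  D_n = (-1)^n (2n-1)!! / r^(2n+1)."""
    r = np.asarray(r, dtype=float)
    out = np.empty(r.shape + (nmax + 1,))
    dfact = 1.0
    for n in range(nmax + 1):
        if n > 0:
            dfact *= 2 * n - 1
        out[..., n] = (-1) ** n * dfact / r ** (2 * n + 1)
    return out


def d_erfc(r: np.ndarray, alpha: float, nmax: int = _NMAX) -> np.ndarray:
    """D_n for the screened kernel g = erfc(alpha r)/r (Ewald real space)."""
    r = np.asarray(r, dtype=float)
    out = np.empty(r.shape + (nmax + 1,))
    expf = (2.0 * alpha / math.sqrt(math.pi)) * np.exp(-(alpha * r) ** 2)
    b = erfc(alpha * r) / r
    out[..., 0] = b
    r2 = r * r
    for n in range(1, nmax + 1):
        # B_n = [(2n-1) B_{n-1} + (2 alpha^2)^(n-1) * expf] / r^2 ; D_n = (-1)^n B_n
        b = ((2 * n - 1) * b + (2.0 * alpha ** 2) ** (n - 1) * expf) / r2
        out[..., n] = (-1) ** n * b
    return out


def d_erf(r: np.ndarray, alpha: float, nmax: int = _NMAX) -> np.ndarray:
    """D_n for g = erf(alpha r)/r = 1/r - erfc(alpha r)/r (finite at r=0)."""
    return d_coulomb(r, nmax) - d_erfc(r, alpha, nmax)


def _d_erf_origin(alpha: float, nmax: int = _NMAX) -> np.ndarray:
    """Series limit of D_n[erf(alpha r)/r] at r -> 0."""
    pref = 2.0 * alpha / math.sqrt(math.pi)
    return np.array([pref * (-1) ** n * (2.0 * alpha ** 2) ** n / (2 * n + 1)
                     for n in range(nmax + 1)])


# --------------------------------------------------------------------------
# pairwise accumulation

def _mask_moments(q, mu, theta, lprime):
    q = np.asarray(q, dtype=float)
    mu = np.zeros((q.shape[0], 3)) if lprime < 1 else np.asarray(mu, dtype=float)
    theta = np.zeros((q.shape[0], 3, 3)) if lprime < 2 else np.asarray(theta, dtype=float)
    return q, mu, theta


def _accumulate_pairs(phi: PhiDerivs, i_idx, j_idx, u, D, q, mu, theta,
                      scale: float = 1.0) -> None:
    """Add the pair interactions (i as field, j as source and vice versa).

    ``u = r_i - r_j``.  Tensors for the reversed direction follow from parity
    T(n)(-u) = (-1)^n T(n)(u).
    """
    T = t_tensors(u, D)
    qj, muj, thj = q[j_idx], mu[j_idx], theta[j_idx]
    qi, mui, thi = q[i_idx], mu[i_idx], theta[i_idx]

    def contract(src_q, src_mu, src_th, order, sign):
        """sum over sources: q T(o) - mu.T(o+1) + 1/3 th:T(o+2), x sign^order parity."""
        a = np.einsum("m,m...->m...", src_q, T[order])
        a -= np.einsum("mz,m...z->m...", src_mu, T[order + 1])
        a += np.einsum("myz,m...yz->m...", src_th, T[order + 2]) / 3.0
        return sign * a

    for order, tgt in enumerate((phi.p0, phi.p1, phi.p2, phi.p3)):
        np.add.at(tgt, i_idx, scale * contract(qj, muj, thj, order, 1.0))
        # field at j from source i: u -> -u flips parity of every tensor
        np.add.at(tgt, j_idx,
                  scale * (-1.0) ** order * contract(qi, -mui, thi, order, 1.0))


def energy_from_phi(phi: PhiDerivs, q, mu, theta) -> float:
    return 0.5 * float(
        np.dot(q, phi.p0)
        + np.einsum("mi,mi->", mu, phi.p1)
        + np.einsum("mij,mij->", theta, phi.p2) / 3.0
    )


def forces_from_phi(phi: PhiDerivs, q, mu, theta) -> np.ndarray:
    f = np.einsum("m,mi->mi", q, phi.p1)
    f += np.einsum("mj,mji->mi", mu, phi.p2)
    f += np.einsum("mjk,mjki->mi", theta, phi.p3) / 3.0
    return -f


# --------------------------------------------------------------------------
# open boundary

def direct_sum(positions, q, mu, theta, lprime: int = 2,
               exclusions: np.ndarray | None = None):
    """Open-boundary multipole sum.

    Parameters
    ----------
    positions : (n, 3) A
    q, mu, theta : per-site moments (global frame)
    exclusions : optional (n,) integer molecule labels; pairs within the same
        molecule are skipped.

    Returns
    -------
    energy (kJ/mol), forces (n,3), :class:`PhiDerivs`
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    q, mu, theta = _mask_moments(q, mu, theta, lprime)
    phi = PhiDerivs.zeros(n)
    ii, jj = np.triu_indices(n, k=1)
    if exclusions is not None:
        excl = np.asarray(exclusions)
        keep = excl[ii] != excl[jj]
        ii, jj = ii[keep], jj[keep]
    if len(ii):
        u = positions[ii] - positions[jj]
        r = np.linalg.norm(u, axis=1)
        if np.any(r < 1e-10):
            raise ZeroDivisionError("zero separation between multipole sites")
        _accumulate_pairs(phi, ii, jj, u, d_coulomb(r), q, mu, theta)
    phi.p0 *= COULOMB
    phi.p1 *= COULOMB
    phi.p2 *= COULOMB
    phi.p3 *= COULOMB
    energy = energy_from_phi(phi, q, mu, theta)
    forces = forces_from_phi(phi, q, mu, theta)
    return energy, forces, phi


def pair_multipole_energy(mA: MultipoleSet, mB: MultipoleSet, rAB,
                          lprime: int = 2):
    """Interaction energy of two multipole sites and its gradient.

    ``rAB`` is the position of B relative to A (A sits at the origin).
    Returns ``(energy kJ/mol, dE/drAB kJ/mol/A)``.
    """
    rAB = np.asarray(rAB, dtype=float)
    if np.linalg.norm(rAB) < 1e-10:
        raise ZeroDivisionError("zero separation between multipole sites")
    pos = np.array([[0.0, 0.0, 0.0], rAB])
    q = np.array([mA.q, mB.q])
    mu = np.array([mA.mu, mB.mu])
    th = np.array([mA.theta, mB.theta])
    energy, forces, _ = direct_sum(pos, q, mu, th, lprime=lprime)
    return energy, -forces[1]


# --------------------------------------------------------------------------
# Ewald

class NonNeutralError(ValueError):
    pass


@dataclass
class EwaldResult:
    energy: float
    forces: np.ndarray
    phi: PhiDerivs
    components: dict


class Ewald:
    """Plain (non-mesh) Ewald summation for multipoles in a cubic box.

    The splitting parameter and reciprocal cutoff are chosen from the
    precision target: ``alpha = sqrt(-ln eps)/rcut`` and
    ``kmax = 2 alpha sqrt(-ln eps)``; both can be overridden in the config.
    Tin-foil boundary (no surface dipole term).
    """

    def __init__(self, box_length: float, config: ElectrostaticsConfig | None = None):
        self.config = config or ElectrostaticsConfig()
        self.L = float(box_length)
        if self.config.rcut > self.L / 2 + 1e-9:
            raise ValueError(
                f"real-space cutoff {self.config.rcut} exceeds half box {self.L / 2}")
        eps = self.config.precision
        s = math.sqrt(-math.log(eps))
        self.alpha = self.config.alpha if self.config.alpha is not None else s / self.config.rcut
        if self.config.kmax is not None:
            kmax = self.config.kmax
        else:
            # charge-only heuristic plus a margin for the k^2, k^4 factors that
            # dipole/quadrupole structure factors put in front of the Gaussian tail
            kmax = 2.0 * self.alpha * s * (1.0 + 0.15 * self.config.lprime)
        nmax = max(1, int(math.ceil(kmax * self.L / (2.0 * math.pi))))
        grid = np.arange(-nmax, nmax + 1)
        nx, ny, nz = np.meshgrid(grid, grid, grid, indexing="ij")
        nvec = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1)
        # half space (k and -k carry the same information); weights doubled
        half = ((nvec[:, 0] > 0)
                | ((nvec[:, 0] == 0) & (nvec[:, 1] > 0))
                | ((nvec[:, 0] == 0) & (nvec[:, 1] == 0) & (nvec[:, 2] > 0)))
        nvec = nvec[half]
        k = 2.0 * math.pi / self.L * nvec.astype(float)
        k2 = np.einsum("ki,ki->k", k, k)
        keep = k2 <= kmax ** 2
        self.kvecs = k[keep]
        self._nvec = nvec[keep]
        self._nmax = nmax
        k2 = k2[keep]
        self.kweights = 2.0 * 4.0 * math.pi / self.L ** 3 \
            * np.exp(-k2 / (4.0 * self.alpha ** 2)) / k2
        # flattened k outer powers for the potential-derivative matmuls
        self.K1 = self.kvecs
        self.K2 = np.einsum("ki,kj->kij", self.kvecs, self.kvecs).reshape(-1, 9)
        self.K3 = np.einsum("ki,kj,kl->kijl", self.kvecs, self.kvecs,
                            self.kvecs).reshape(-1, 27)
        self._d_self = _d_erf_origin(self.alpha)

    # -- pieces ----------------------------------------------------------
    def _real_space(self, phi, pos, q, mu, theta, molecule):
        n = pos.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        u = pos[ii] - pos[jj]
        u -= self.L * np.round(u / self.L)
        r2 = np.einsum("mi,mi->m", u, u)
        mask = r2 <= self.config.rcut ** 2
        if molecule is not None:
            mask &= molecule[ii] != molecule[jj]
        ii, jj, u = ii[mask], jj[mask], u[mask]
        if len(ii):
            r = np.sqrt(r2[mask])
            if np.any(r < 1e-10):
                raise ZeroDivisionError("zero separation between multipole sites")
            _accumulate_pairs(phi, ii, jj, u, d_erfc(r, self.alpha), q, mu, theta)

    def _exclusion_correction(self, phi, pos, q, mu, theta, molecule):
        """Remove the erf (reciprocal-space) part of intramolecular pairs."""
        n = pos.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        mask = molecule[ii] == molecule[jj]
        ii, jj = ii[mask], jj[mask]
        if len(ii) == 0:
            return
        u = pos[ii] - pos[jj]
        u -= self.L * np.round(u / self.L)
        r = np.linalg.norm(u, axis=1)
        _accumulate_pairs(phi, ii, jj, u, d_erf(r, self.alpha), q, mu, theta,
                          scale=-1.0)

    def _self_correction(self, phi, q, mu, theta):
        """Remove each site's interaction with its own Gaussian screening charge.

        At u = 0 only the all-delta pairing terms of the erf-kernel tensors
        survive: T2(0) = I*D1(0), T4(0) = D2(0) * Sym[delta delta].
        """
        d = self._d_self
        eye = np.eye(3)
        phi.p0 -= q * d[0]
        phi.p1 -= -mu * d[1]
        phi.p2 -= (d[1] * q[:, None, None] * eye[None]
                   + (2.0 / 3.0) * d[2] * theta)
        sym = (np.einsum("ij,mk->mijk", eye, mu)
               + np.einsum("ik,mj->mijk", eye, mu)
               + np.einsum("jk,mi->mijk", eye, mu))
        phi.p3 -= -d[2] * sym

    def _phases(self, pos):
        """e^{i k.r_j} for every site/k, via per-axis phase tables."""
        grid = np.arange(-self._nmax, self._nmax + 1)
        ax = np.exp(1j * (2.0 * math.pi / self.L) * pos[:, :, None] * grid)  # (n,3,g)
        idx = self._nvec + self._nmax
        return ax[:, 0, idx[:, 0]] * ax[:, 1, idx[:, 1]] * ax[:, 2, idx[:, 2]]

    def _reciprocal(self, phi, pos, q, mu, theta):
        k = self.kvecs
        w = self.kweights
        phase = self._phases(pos)                            # (n, nk)
        lam = (q[:, None]
               + 1j * (mu @ k.T)
               - np.einsum("mij,kij->mk", theta,
                           np.einsum("ki,kj->kij", k, k)) / 3.0)
        S = np.einsum("mk,mk->k", lam, phase)
        G = phase * S.conj()[None, :]                        # e^{ik r_j} S*
        a = G.real * w[None, :]
        b = G.imag * w[None, :]
        phi.p0 += a.sum(axis=1)
        phi.p1 += -(b @ self.K1)
        phi.p2 += -(a @ self.K2).reshape(-1, 3, 3)
        phi.p3 += (b @ self.K3).reshape(-1, 3, 3, 3)
        return 0.5 * float(w @ np.abs(S) ** 2)

    # -- driver ----------------------------------------------------------
    def compute(self, positions, q, mu, theta, molecule=None) -> EwaldResult:
        pos = np.asarray(positions, dtype=float)
        n = pos.shape[0]
        q, mu, theta = _mask_moments(q, mu, theta, self.config.lprime)
        net = float(q.sum())
        if abs(net) > 1e-8:
            raise NonNeutralError(f"system has net charge {net:g} e")
        molecule = None if molecule is None else np.asarray(molecule)

        phi = PhiDerivs.zeros(n)
        self._real_space(phi, pos, q, mu, theta, molecule)
        self._reciprocal(phi, pos, q, mu, theta)
        if molecule is not None:
            self._exclusion_correction(phi, pos, q, mu, theta, molecule)
        self._self_correction(phi, q, mu, theta)
        if self.config.boundary == "vacuum":
            # surface (k=0) dipole term of the eps_surround = 1 convention;
            # E = (2 pi / 3V) |M|^2 with M the total cell dipole, folded into
            # the potential arrays so energies/forces/dE/dQ stay consistent
            M = (q @ pos) + mu.sum(axis=0)
            c = 2.0 * math.pi / (3.0 * self.L ** 3)
            phi.p0 += 2.0 * c * (pos @ M)
            phi.p1 += 2.0 * c * M
        phi.p0 *= COULOMB
        phi.p1 *= COULOMB
        phi.p2 *= COULOMB
        phi.p3 *= COULOMB
        energy = energy_from_phi(phi, q, mu, theta)
        forces = forces_from_phi(phi, q, mu, theta)
        return EwaldResult(energy=energy, forces=forces, phi=phi,
                           components={"alpha": self.alpha,
                                       "n_kvec": len(self.kvecs)})


def ewald_sum(positions, q, mu, theta, box_length: float,
              config: ElectrostaticsConfig | None = None,
              molecule=None) -> EwaldResult:
    """One-shot Ewald evaluation (see :class:`Ewald` for the cached form)."""
    return Ewald(box_length, config).compute(positions, q, mu, theta, molecule)


def net_moments(positions, q, mu, theta, origin=None):
    """Total charge, dipole and traceless quadrupole of a set of sites.

    Moments are accumulated about ``origin`` (default: coordinate origin)
    with the same traceless convention the interaction tensors use; useful
    for judging how strongly a cluster couples to its own periodic images.
    """
    pos = np.asarray(positions, dtype=float)
    if origin is not None:
        pos = pos - np.asarray(origin, dtype=float)
    q = np.asarray(q, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    Q = float(q.sum())
    M = q @ pos + mu.sum(axis=0)
    rr = np.einsum("mi,mj->mij", pos, pos)
    r2 = np.einsum("mi,mi->m", pos, pos)
    eye = np.eye(3)
    T = np.einsum("m,mij->ij", q, 1.5 * rr) - 0.5 * (q @ r2) * eye
    rmu = np.einsum("mi,mj->mij", pos, mu)
    T += 1.5 * (rmu.sum(axis=0) + rmu.sum(axis=0).T) \
        - np.einsum("mi,mi->", pos, mu) * eye
    T += theta.sum(axis=0)
    return Q, M, T


def self_interaction_constant(n_real: int = 6, n_recip: int = 12) -> float:
    """Periodic self-interaction constant xi of a unit charge in a cube.

    Converged Ewald lattice summation of the interaction of a point charge
    with its own periodic images plus neutralising background, for a cube of
    side 1; enters the hydrodynamic finite-size correction of the diffusion
    coefficient as ``D_inf = D(L) + kB T xi / (6 pi eta L)``.
    """
    L = 1.0
    alpha = 3.5
    # real-space image sum
    grid = np.arange(-n_real, n_real + 1)
    nx, ny, nz = np.meshgrid(grid, grid, grid, indexing="ij")
    nvec = np.stack([nx.ravel(), ny.ravel(), nz.ravel()], axis=1).astype(float)
    nvec = nvec[np.any(nvec != 0, axis=1)]
    rn = np.linalg.norm(nvec * L, axis=1)
    v = float(np.sum(erfc(alpha * rn) / rn))
    # reciprocal sum
    grid = np.arange(-n_recip, n_recip + 1)
    kx, ky, kz = np.meshgrid(grid, grid, grid, indexing="ij")
    kvec = np.stack([kx.ravel(), ky.ravel(), kz.ravel()], axis=1).astype(float)
    kvec = kvec[np.any(kvec != 0, axis=1)] * 2.0 * math.pi / L
    k2 = np.einsum("ki,ki->k", kvec, kvec)
    v += float(np.sum(4.0 * math.pi / L ** 3 * np.exp(-k2 / (4 * alpha ** 2)) / k2))
    # self and background
    v -= 2.0 * alpha / math.sqrt(math.pi)
    v -= math.pi / (alpha ** 2 * L ** 3)
    return -v * L


# --------------------------------------------------------------------------
# Lennard-Jones

def lj_energy_forces(positions, species, molecule, params: LJParams,
                     rcut: float, box_length: float | None = None,
                     shift: bool = True):
    """12-6 energy/forces on intermolecular O-O and O-H pairs.

    ``species`` is an array of "O"/"H" labels; H-H pairs carry no LJ term.
    ``shift=True`` subtracts the cutoff energy (cut-and-shift) so the
    potential is continuous at ``rcut``; ``shift=False`` is plain truncation.
    Returns ``(energy, forces, virial)`` with the scalar virial
    ``sum f_pair . u_pair`` for the pressure.
    """
    if rcut <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(positions, dtype=float)
    species = np.asarray(species)
    molecule = np.asarray(molecule)
    n = pos.shape[0]
    bad = set(np.unique(species)) - {"O", "H"}
    if bad:
        raise ValueError(f"no LJ parameters for species {sorted(bad)}")
    is_o = species == "O"
    ii, jj = np.triu_indices(n, k=1)
    keep = molecule[ii] != molecule[jj]
    ii, jj = ii[keep], jj[keep]
    u = pos[ii] - pos[jj]
    if box_length is not None:
        u -= box_length * np.round(u / box_length)
    r2 = np.einsum("mi,mi->m", u, u)
    mask = r2 <= rcut * rcut
    ii, jj, u, r2 = ii[mask], jj[mask], u[mask], r2[mask]

    n_o = is_o[ii].astype(int) + is_o[jj].astype(int)
    eps = np.where(n_o == 2, params.eps_oo, np.where(n_o == 1, params.eps_oh, 0.0))
    sig = np.where(n_o == 2, params.sigma_oo, np.where(n_o == 1, params.sigma_oh, 1.0))

    s6 = (sig * sig / r2) ** 3
    e_pair = 4.0 * eps * (s6 * s6 - s6)
    if shift:
        sc6 = (sig / rcut) ** 6
        e_pair -= 4.0 * eps * (sc6 * sc6 - sc6)
    # dU/dr * (1/r) u ; dU/dr = -24 eps (2 s12 - s6)/r
    fmag_over_r = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
    fpair = fmag_over_r[:, None] * u
    forces = np.zeros((n, 3))
    np.add.at(forces, ii, fpair)
    np.add.at(forces, jj, -fpair)
    virial = float(np.einsum("mi,mi->", fpair, u))
    return float(e_pair.sum()), forces, virial


# --------------------------------------------------------------------------
# flexible-moment force assembly

def assemble_flexible_forces(phi: PhiDerivs, mol_index, dq_dr, dmu_dr, dth_dr):
    """Chain-rule force terms from geometry-dependent moments.

    For every site ``s`` of molecule ``m`` the moments depend on the three
    atoms of that molecule; the contribution to the force on atom ``a`` is
    ``-(dE/dq_s dq_s/dr_a + dE/dmu_s . dmu_s/dr_a + dE/dtheta_s : dtheta_s/dr_a)``.

    Parameters
    ----------
    phi : potential derivatives at every site (dE/dq = p0, dE/dmu = p1,
        dE/dtheta = p2/3)
    mol_index : (n_mol, sites_per_mol) site indices of each molecule
    dq_dr : (n_mol, s, a, 3) with s sites and a atoms per molecule
    dmu_dr : (n_mol, s, 3, a, 3)
    dth_dr : (n_mol, s, 3, 3, a, 3)

    Returns
    -------
    (n_sites, 3) force array (sites double as atoms for water).
    """
    mol_index = np.asarray(mol_index)
    n_sites = phi.p0.shape[0]
    p0 = phi.p0[mol_index]              # (n_mol, s)
    p1 = phi.p1[mol_index]              # (n_mol, s, 3)
    p2 = phi.p2[mol_index] / 3.0        # (n_mol, s, 3, 3)
    fmol = -(np.einsum("ms,msax->max", p0, dq_dr)
             + np.einsum("msi,msiax->max", p1, dmu_dr)
             + np.einsum("msij,msijax->max", p2, dth_dr))
    forces = np.zeros((n_sites, 3))
    np.add.at(forces, mol_index, fmol)
    return forces
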
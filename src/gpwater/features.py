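"""Internal-coordinate features and local atomic frames.

A GPR model for an atom in a water monomer sees the molecule through a
rotation/translation-invariant feature vector of length ``3*N_atom - 6 = 3``:

* centred on O (atom 0): ``(d(O,H1), d(O,H2), angle H1-O-H2)``
* centred on H1 (atom 1): ``(d(H1,O), d(H1,H2), angle O-H1-H2)``
* centred on H2 (atom 2): ``(d(H2,O), d(H2,H1), angle O-H2-H1)``

i.e. always ``(distance to partner a, distance to partner b, angle a-centre-b)``
with partners ordered O-first, then by atom index.  Distances are in angstrom,
angles in radians.  The Jacobian ``df/dr`` (shape ``(3, N_atom, 3)``) is
analytic, which is what makes GPR forces exact gradients of the predicted
potential.

Atomic multipole moments are learnt in a local right-handed frame attached to
each atom (x towards the first partner, the second partner in the x-y plane)
and rotated to the global frame at prediction time; dipoles rotate as vectors
and quadrupoles as rank-2 tensors.  The analytic derivative of the rotation
matrix with respect to the atomic coordinates is provided for the
flexible-moment force terms.

All functions accept a single geometry ``(n, 3)`` or a batch ``(m, n, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureVector",
    "LocalFrame",
    "monomer_partners",
    "build_features",
    "batch_features",
    "local_frame",
    "batch_local_frames",
    "local_frame_gradient",
    "rotate_multipoles",
]


class DegenerateFrameError(ValueError):
    """Raised when the frame-defining atoms are (nearly) collinear."""


@dataclass
class FeatureVector:
    """Feature values plus their Jacobian with respect to Cartesians."""

    values: np.ndarray        # (3,)
    jacobian: np.ndarray      # (3, n_atom, 3)
    center: int
    partners: tuple[int, int]

    @property
    def n_feat(self) -> int:
        return self.values.shape[0]


@dataclass
class LocalFrame:
    """Proper rotation taking global-frame vectors into an atom's local frame.

    ``rotation`` has the local axes as rows: ``v_local = rotation @ v_global``.
    """

    center: int
    partners: tuple[int, int]
    rotation: np.ndarray = field(repr=False)   # (3, 3)


def monomer_partners(center: int, n_atom: int = 3) -> tuple[int, int]:
    """Partner ordering for a water monomer: O first, then by index."""
    others = [i for i in range(n_atom) if i != center]
    others.sort(key=lambda i: (i != 0, i))
    return others[0], others[1]


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2] < 3 or coords.shape[-1] != 3:
        raise ValueError(f"need at least 3 atoms with xyz coordinates, got shape {coords.shape}")
    return coords


def _unit(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("coincident atoms: zero-length bond vector")
    return v / n, n[..., 0]


def batch_features(coords: np.ndarray, center: int) -> tuple[np.ndarray, np.ndarray]:
    """Features and Jacobians for a batch of geometries.

    Parameters
    ----------
    coords : (m, n_atom, 3) array
    center : index of the atom the model sits on

    Returns
    -------
    values : (m, 3) array
    jacobian : (m, 3, n_atom, 3) array
    """
    coords = _check_coords(coords)
    squeeze = coords.ndim == 2
    if squeeze:
        coords = coords[None]
    m, n_atom, _ = coords.shape
    a, b = monomer_partners(center, n_atom)

    c = coords[:, center]
    u = coords[:, a] - c
    v = coords[:, b] - c
    uh, ru = _unit(u)
    vh, rv = _unit(v)

    cosang = np.clip(np.einsum("mi,mi->m", uh, vh), -1.0, 1.0)
    sinang = np.sqrt(np.maximum(1.0 - cosang ** 2, 0.0))
    if np.any(sinang < 1e-10):
        raise DegenerateFrameError("collinear defining atoms: angle feature is degenerate")
    theta = np.arccos(cosang)

    values = np.stack([ru, rv, theta], axis=1)

    jac = np.zeros((m, 3, n_atom, 3))
    # distances
    jac[:, 0, a] = uh
    jac[:, 0, center] = -uh
    jac[:, 1, b] = vh
    jac[:, 1, center] = -vh
    # angle
    dth_da = -(vh - cosang[:, None] * uh) / (ru * sinang)[:, None]
    dth_db = -(uh - cosang[:, None] * vh) / (rv * sinang)[:, None]
    jac[:, 2, a] = dth_da
    jac[:, 2, b] = dth_db
    jac[:, 2, center] = -(dth_da + dth_db)

    if squeeze:
        return values[0], jac[0]
    return values, jac


def build_features(coords: np.ndarray, center: int) -> FeatureVector:
    """Feature vector of a single atomic environment (see module docstring)."""
    values, jac = batch_features(np.asarray(coords, dtype=float), center)
    n_atom = np.asarray(coords).shape[0]
    return FeatureVector(values=values, jacobian=jac, center=center,
                         partners=monomer_partners(center, n_atom))


def batch_local_frames(coords: np.ndarray, center: int) -> np.ndarray:
    """Rotation matrices (rows = local axes) for a batch of geometries.

    x towards the first partner, second partner in the x-y half-plane with
    positive y, z = x cross (towards second partner), right handed.
    """
    coords = _check_coords(coords)
    squeeze = coords.ndim == 2
    if squeeze:
        coords = coords[None]
    n_atom = coords.shape[1]
    a, b = monomer_partners(center, n_atom)
    c = coords[:, center]
    u = coords[:, a] - c
    v = coords[:, b] - c
    x, _ = _unit(u)
    w = np.cross(u, v)
    wn = np.linalg.norm(w, axis=-1)
    if np.any(wn < 1e-10):
        raise DegenerateFrameError("collinear defining atoms: local frame undefined")
    z = w / wn[:, None]
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=1)
    return R[0] if squeeze else R


def local_frame(coords: np.ndarray, center: int) -> LocalFrame:
    R = batch_local_frames(coords, center)
    n_atom = np.asarray(coords).shape[0]
    return LocalFrame(center=center, partners=monomer_partners(center, n_atom), rotation=R)


def _cross_mat(v: np.ndarray) -> np.ndarray:
    """Skew matrices: (m,3) -> (m,3,3) with X @ w = v cross w."""
    m = v.shape[0]
    X = np.zeros((m, 3, 3))
    X[:, 0, 1] = -v[:, 2]
    X[:, 0, 2] = v[:, 1]
    X[:, 1, 0] = v[:, 2]
    X[:, 1, 2] = -v[:, 0]
    X[:, 2, 0] = -v[:, 1]
    X[:, 2, 1] = v[:, 0]
    return X


def local_frame_gradient(coords: np.ndarray, center: int) -> tuple[np.ndarray, np.ndarray]:
    """Local frame rotations and their Cartesian derivatives, batched.

    Returns
    -------
    R : (m, 3, 3)
    dR : (m, 3, 3, n_atom, 3) with ``dR[..., k, :]`` the derivative of R with
        respect to the coordinates of atom k.
    """
    coords = _check_coords(coords)
    squeeze = coords.ndim == 2
    if squeeze:
        coords = coords[None]
    m, n_atom, _ = coords.shape
    a, b = monomer_partners(center, n_atom)
    c = coords[:, center]
    u = coords[:, a] - c
    v = coords[:, b] - c
    x, ru = _unit(u)
    w = np.cross(u, v)
    wn = np.linalg.norm(w, axis=-1)
    if np.any(wn < 1e-10):
        raise DegenerateFrameError("collinear defining atoms: local frame undefined")
    z = w / wn[:, None]
    y = np.cross(z, x)

    eye = np.broadcast_to(np.eye(3), (m, 3, 3))
    Px = (eye - np.einsum("mi,mj->mij", x, x)) / ru[:, None, None]
    Pz = (eye - np.einsum("mi,mj->mij", z, z)) / wn[:, None, None]
    Xu = _cross_mat(u)
    Xv = _cross_mat(v)
    Xx = _cross_mat(x)
    Xz = _cross_mat(z)

    # du/d(atom) and dv/d(atom) are +-identity for the involved atoms.
    dR = np.zeros((m, 3, 3, n_atom, 3))
    for atom, su, sv in ((a, 1.0, 0.0), (b, 0.0, 1.0), (center, -1.0, -1.0)):
        # derivative matrices D[...]: (m, 3, 3); column j = d(axis)/d r_atom,j
        dx = su * Px
        dw = sv * Xu - su * Xv  # d(u x v) = du x v + u x dv = -[v]x du + [u]x dv
        dz = Pz @ dw
        dy = -Xx @ dz + Xz @ dx
        dR[:, 0, :, atom, :] = dx
        dR[:, 1, :, atom, :] = dy
        dR[:, 2, :, atom, :] = dz

    R = np.stack([x, y, z], axis=1)
    if squeeze:
        return R, dR[0]
    return R, dR


def rotate_multipoles(q, mu, theta, R):
    """Rotate a (q, dipole, quadrupole) triple by rotation matrix R.

    The charge is invariant, the dipole rotates as a vector (``R @ mu``) and
    the quadrupole as a rank-2 tensor (``R @ theta @ R.T``).  Pass ``R`` to go
    global -> local with a `LocalFrame` rotation, or ``R.T`` for local ->
    global.  Works on batches when ``R`` is ``(m, 3, 3)`` and the moments
    carry a matching leading axis.
    """
    R = np.asarray(R, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    mu_r = np.einsum("...ij,...j->...i", R, mu)
    th_r = np.einsum("...ij,...jk,...lk->...il", R, theta, R)
    return q, mu_r, th_r
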
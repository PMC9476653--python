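"""Gaussian process regression for per-atom properties.

One GPR model per atom and per property (energy, charge, dipole and
quadrupole components) maps the monomer feature vector to the property; the
posterior mean is differentiated analytically and chained through the feature
Jacobian to give exact Cartesian gradients, which is what makes the dynamics
conservative.

Kernels: squared-exponential with per-feature lengthscales (automatic
relevance determination; default) and Matern-5/2.  Hyperparameters maximise
the log marginal likelihood by multi-restart L-BFGS in log space with
analytic gradients.  With zero noise the posterior interpolates the training
targets; a small jitter is escalated only as far as needed to keep the
Cholesky factorisation positive definite.

Training sets are built the way compact interatomic-potential models are
usually made: a random subset followed by active learning, greedily adding
the pool point with the largest posterior variance and refitting after every
addition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

__all__ = ["GPConfig", "GPRModel", "SCurve", "train", "active_learn", "s_curve"]


class ConditioningError(RuntimeError):
    """Kernel matrix not positive definite even at maximum jitter."""


@dataclass
class GPConfig:
    kernel: str = "rbf"            # "rbf" or "matern52"
    noise: float = 0.0             # target noise variance; 0 = interpolate
    n_restarts: int = 5
    optimizer_tol: float = 1e-8
    max_jitter: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("rbf", "matern52"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


# --------------------------------------------------------------------------
# kernels

def _scaled_sq_dists(X1, X2, ls):
    """Per-dimension scaled squared distances, shape (n1, n2, d)."""
    diff = X1[:, None, :] - X2[None, :, :]
    return (diff / ls) ** 2, diff


def _kernel(X1, X2, ls, sf2, kind):
    Q, _ = _scaled_sq_dists(X1, X2, ls)
    q = Q.sum(axis=2)
    if kind == "rbf":
        return sf2 * np.exp(-0.5 * q)
    r = np.sqrt(np.maximum(q, 0.0))
    s5 = math.sqrt(5.0)
    return sf2 * (1.0 + s5 * r + (5.0 / 3.0) * r * r) * np.exp(-s5 * r)


def _kernel_and_grads(X, ls, sf2, kind):
    """K plus dK/d(log ls_j) for each j and dK/d(log sf2)."""
    Q, _ = _scaled_sq_dists(X, X, ls)
    q = Q.sum(axis=2)
    if kind == "rbf":
        K = sf2 * np.exp(-0.5 * q)
        dls = [K * Q[:, :, j] for j in range(X.shape[1])]
    else:
        r = np.sqrt(np.maximum(q, 0.0))
        s5 = math.sqrt(5.0)
        e = np.exp(-s5 * r)
        K = sf2 * (1.0 + s5 * r + (5.0 / 3.0) * r * r) * e
        # dK/dr = -(5/3) sf2 r (1 + sqrt5 r) e; dr/dlog ls_j = -Q_j / r
        fac = (5.0 / 3.0) * sf2 * (1.0 + s5 * r) * e  # = -(dK/dr)/r
        dls = [fac * Q[:, :, j] for j in range(X.shape[1])]
    return K, dls, K.copy()  # dK/dlog sf2 = K


# --------------------------------------------------------------------------
# model

@dataclass
class GPRModel:
    """Trained per-atom, per-property regressor."""

    kernel: str
    lengthscales: np.ndarray       # (d,)
    signal_variance: float
    noise: float
    X_train: np.ndarray            # (n, d)
    alpha: np.ndarray              # dual weights (n,)
    y_mean: float
    label: str = ""
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_train(self) -> int:
        return self.X_train.shape[0]

    # -- prediction ------------------------------------------------------
    def predict(self, X, return_var: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_train.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {self.X_train.shape[1]}")
        Ks = _kernel(X, self.X_train, self.lengthscales, self.signal_variance,
                     self.kernel)
        mean = Ks @ self.alpha + self.y_mean
        if not return_var:
            return mean
        if self._chol is None:
            self._chol = self._factor()
        v = solve_triangular(self._chol, Ks.T, lower=True)
        var = np.maximum(self.signal_variance - np.einsum("ij,ij->j", v, v), 0.0)
        return mean, var

    def predict_feature_gradient(self, X) -> np.ndarray:
        """d(mean)/d(features), shape (m, d)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = self.X_train[None, :, :] - X[:, None, :]   # (m, n, d)
        ls2 = self.lengthscales ** 2
        if self.kernel == "rbf":
            K = _kernel(X, self.X_train, self.lengthscales, self.signal_variance,
                        self.kernel)
            return np.einsum("mn,mnd,n->md", K, diff / ls2, self.alpha)
        q = ((diff / self.lengthscales) ** 2).sum(axis=2)
        r = np.sqrt(np.maximum(q, 1e-300))
        s5 = math.sqrt(5.0)
        fac = (5.0 / 3.0) * self.signal_variance * (1.0 + s5 * r) * np.exp(-s5 * r)
        return np.einsum("mn,mnd,n->md", fac, diff / ls2, self.alpha)

    def predict_gradient(self, X, jacobian) -> np.ndarray:
        """Cartesian gradient of the posterior mean.

        ``jacobian`` is the feature Jacobian ``df/dr`` with shape
        ``(m, d, n_atom, 3)`` (or ``(d, n_atom, 3)`` for a single input).
        """
        single = np.asarray(X).ndim == 1
        g = self.predict_feature_gradient(X)
        jac = np.asarray(jacobian, dtype=float)
        if jac.ndim == 3:
            jac = jac[None]
        out = np.einsum("md,mdax->max", g, jac)
        return out[0] if single else out

    # -- internals -------------------------------------------------------
    def _factor(self):
        K = _kernel(self.X_train, self.X_train, self.lengthscales,
                    self.signal_variance, self.kernel)
        return _robust_cholesky(K, self.noise)[0]

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "gpwater-gpr-1",
            "kernel": self.kernel,
            "lengthscales": self.lengthscales.tolist(),
            "signal_variance": self.signal_variance,
            "noise": self.noise,
            "X_train": self.X_train.tolist(),
            "alpha": self.alpha.tolist(),
            "y_mean": self.y_mean,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPRModel":
        if d.get("format") != "gpwater-gpr-1":
            raise ValueError(f"unknown model bundle format {d.get('format')!r}")
        return cls(kernel=d["kernel"],
                   lengthscales=np.asarray(d["lengthscales"], dtype=float),
                   signal_variance=float(d["signal_variance"]),
                   noise=float(d["noise"]),
                   X_train=np.asarray(d["X_train"], dtype=float),
                   alpha=np.asarray(d["alpha"], dtype=float),
                   y_mean=float(d["y_mean"]), label=d.get("label", ""))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "GPRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _robust_cholesky(K, noise, max_jitter=1e-6):
    n = K.shape[0]
    jitter = max(noise, 1e-12)
    while jitter <= max_jitter * 1.0001:
        try:
            L = cholesky(K + jitter * np.eye(n), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise ConditioningError(
        f"kernel matrix not positive definite at maximum jitter {max_jitter:g}")


# --------------------------------------------------------------------------
# training

def _neg_lml_and_grad(log_params, X, yc, kind, noise):
    d = X.shape[1]
    ls = np.exp(log_params[:d])
    sf2 = np.exp(log_params[d])
    K, dls, dsf = _kernel_and_grads(X, ls, sf2, kind)
    n = X.shape[0]
    try:
        L = cholesky(K + max(noise, 1e-12) * np.eye(n), lower=True)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(log_params)
    alpha = cho_solve((L, True), yc)
    lml = -0.5 * yc @ alpha - np.log(np.diag(L)).sum() - 0.5 * n * math.log(2 * math.pi)
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(log_params)
    for j in range(d):
        grad[j] = 0.5 * np.einsum("ij,ij->", W, dls[j])
    grad[d] = 0.5 * np.einsum("ij,ij->", W, dsf)
    return -lml, -grad


def train(X, y, config: GPConfig | None = None, label: str = "") -> GPRModel:
    """Fit hyperparameters by multi-restart LML maximisation and solve duals."""
    cfg = config or GPConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) with matching targets")
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 training points")
    if cfg.noise == 0.0:
        # duplicated inputs make a singular kernel under exact interpolation
        order = np.lexsort(X.T)
        if n > 1 and np.any(np.all(np.abs(np.diff(X[order], axis=0)) < 1e-12, axis=1)):
            raise ValueError("duplicate training inputs need noise > 0")

    y_mean = float(y.mean())
    yc = y - y_mean
    yvar = max(float(yc.var()), 1e-12)
    ls0 = np.maximum(X.std(axis=0), 1e-3)

    rng = np.random.default_rng(cfg.seed)
    best = None
    x0_base = np.concatenate([np.log(ls0), [math.log(yvar)]])
    # lengthscales within a few decades of the data spread and a cap on the
    # signal variance keep the zero-noise interpolation well conditioned
    # (unbounded LML maximisation on very smooth targets drifts to huge
    # sf^2 / lengthscales and dual weights that drown the predictions in
    # round-off)
    bounds = [(math.log(0.05 * s), math.log(20.0 * s)) for s in ls0]
    bounds.append((math.log(1e-4 * yvar), math.log(50.0 * yvar)))
    for restart in range(max(1, cfg.n_restarts)):
        x0 = x0_base if restart == 0 else x0_base + rng.normal(0, 1.0, d + 1)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(_neg_lml_and_grad, x0, args=(X, yc, cfg.kernel, cfg.noise),
                       jac=True, method="L-BFGS-B", tol=cfg.optimizer_tol,
                       bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ls = np.exp(best.x[:d])
    sf2 = float(np.exp(best.x[d]))

    K = _kernel(X, X, ls, sf2, cfg.kernel)
    L, jitter = _robust_cholesky(K, cfg.noise, cfg.max_jitter)
    alpha = cho_solve((L, True), yc)
    return GPRModel(kernel=cfg.kernel, lengthscales=ls, signal_variance=sf2,
                    noise=jitter, X_train=X.copy(), alpha=alpha, y_mean=y_mean,
                    label=label, _chol=L)


def _refit_duals(model: GPRModel, X, y) -> GPRModel:
    """New training set, same hyperparameters."""
    K = _kernel(X, X, model.lengthscales, model.signal_variance, model.kernel)
    L, jitter = _robust_cholesky(K, model.noise)
    y_mean = float(np.mean(y))
    alpha = cho_solve((L, True), y - y_mean)
    return GPRModel(kernel=model.kernel, lengthscales=model.lengthscales,
                    signal_variance=model.signal_variance, noise=jitter,
                    X_train=np.asarray(X, float).copy(), alpha=alpha,
                    y_mean=y_mean, label=model.label, _chol=L)


def active_learn(X_pool, y_pool, n_init: int = 50, n_final: int = 100,
                 seed: int = 0, config: GPConfig | None = None,
                 refit_interval: int = 10, label: str = ""):
    """Build a compact training set: random start + variance-greedy growth.

    ``n_init`` points are drawn at random (seeded); the remaining
    ``n_final - n_init`` are added one at a time, each the pool point with
    the largest posterior variance under the current model (ties broken by
    lowest pool index).  Dual weights are refit after every addition;
    hyperparameters are re-optimised every ``refit_interval`` additions and
    at the end.

    Returns ``(model, selected_indices)``.
    """
    X_pool = np.asarray(X_pool, dtype=float)
    y_pool = np.asarray(y_pool, dtype=float)
    n_pool = X_pool.shape[0]
    if n_final > n_pool:
        raise ValueError(f"pool of {n_pool} points cannot supply {n_final}")
    if n_init > n_final:
        raise ValueError("n_init cannot exceed n_final")
    cfg = config or GPConfig()
    rng = np.random.default_rng(seed)
    selected = list(rng.choice(n_pool, size=n_init, replace=False))
    model = train(X_pool[selected], y_pool[selected], cfg, label=label)
    remaining = [i for i in range(n_pool) if i not in set(selected)]
    since_opt = 0
    while len(selected) < n_final:
        _, var = model.predict(X_pool[remaining], return_var=True)
        pick = remaining[int(np.argmax(var))]   # argmax takes the first maximum
        selected.append(pick)
        remaining.remove(pick)
        since_opt += 1
        if since_opt >= refit_interval or len(selected) == n_final:
            model = train(X_pool[selected], y_pool[selected], cfg, label=label)
            since_opt = 0
        else:
            model = _refit_duals(model, X_pool[selected], y_pool[selected])
    return model, np.asarray(selected)


# --------------------------------------------------------------------------
# water model sets: one model per atom per property

_THETA_COMPS = ("xx", "xy", "xz", "yy", "yz")   # zz follows from tracelessness


def _theta_from_components(c):
    """(..., 5) components -> (..., 3, 3) traceless symmetric tensors."""
    c = np.asarray(c, dtype=float)
    out = np.empty(c.shape[:-1] + (3, 3))
    xx, xy, xz, yy, yz = (c[..., i] for i in range(5))
    out[..., 0, 0] = xx
    out[..., 0, 1] = out[..., 1, 0] = xy
    out[..., 0, 2] = out[..., 2, 0] = xz
    out[..., 1, 1] = yy
    out[..., 1, 2] = out[..., 2, 1] = yz
    out[..., 2, 2] = -xx - yy
    return out


class WaterModels:
    """Per-atom GPR models for a water monomer: energy + local-frame moments.

    ``energy[i]`` predicts atom i's share of the molecular PES from atom i's
    feature vector; ``moments[i]`` is a dict with keys ``q``, ``mu`` (3
    models, local frame) and ``theta`` (5 independent traceless components,
    local frame).  Predicted charges are shifted by the per-molecule mean so
    each molecule is exactly neutral (the shift and its gradient are smooth).
    """

    def __init__(self, energy: list, moments: list | None = None):
        self.energy = energy
        self.moments = moments

    # -- training --------------------------------------------------------
    @classmethod
    def train(cls, geoms, config: GPConfig | None = None, with_moments: bool = True,
              n_train: int | None = None, active: bool = False, n_init: int = 50,
              seed: int = 0):
        """Fit models on oracle-labelled geometries.

        ``active=True`` uses the random + variance-greedy protocol with
        ``n_init`` random points growing to ``n_train``; otherwise the first
        ``n_train`` geometries (or all) are used directly.
        """
        from . import features as ft
        from . import oracle as orc

        cfg = config or GPConfig()
        coords = np.array([g.coords for g in geoms])
        props = [orc.oracle_energies(g) for g in geoms]
        energies = np.array([p.atom_energies for p in props])     # (m, 3)
        energy_models = []
        moment_models: list | None = [] if with_moments else None
        for atom in range(3):
            X, _ = ft.batch_features(coords, atom)
            y = energies[:, atom]
            if active and n_train is not None:
                model, _ = active_learn(X, y, n_init=min(n_init, n_train),
                                        n_final=n_train, seed=seed + atom,
                                        config=cfg, label=f"E[{atom}]")
            else:
                sel = slice(None) if n_train is None else slice(n_train)
                model = train(X[sel], y[sel], cfg, label=f"E[{atom}]")
            energy_models.append(model)

            if not with_moments:
                continue
            # rotate the oracle's global moments into each atom's local frame
            R = ft.batch_local_frames(coords, atom)               # (m, 3, 3)
            q = np.array([p.multipoles[atom].q for p in props])
            mu_g = np.array([p.multipoles[atom].mu for p in props])
            th_g = np.array([p.multipoles[atom].theta for p in props])
            _, mu_l, th_l = ft.rotate_multipoles(q, mu_g, th_g, R)
            sel = slice(None) if n_train is None else slice(n_train)
            entry = {"q": train(X[sel], q[sel], cfg, label=f"q[{atom}]"),
                     "mu": [train(X[sel], mu_l[sel, k], cfg, label=f"mu{k}[{atom}]")
                            for k in range(3)],
                     "theta": [train(X[sel], _theta_component(th_l, k)[sel], cfg,
                                     label=f"th{_THETA_COMPS[k]}[{atom}]")
                               for k in range(5)]}
            moment_models.append(entry)
        return cls(energy_models, moment_models)

    # -- prediction ------------------------------------------------------
    def predict_energy_forces(self, mol_coords: np.ndarray):
        """Summed per-atom energies and Cartesian forces for (m, 3, 3) monomers."""
        from . import features as ft
        m = mol_coords.shape[0]
        e = np.zeros(m)
        f = np.zeros((m, 3, 3))
        for atom in range(3):
            X, J = ft.batch_features(mol_coords, atom)
            e += self.energy[atom].predict(X)
            f -= self.energy[atom].predict_gradient(X, J)
        return e, f

    def predict_moments(self, mol_coords: np.ndarray, gradients: bool = True):
        """Global-frame per-site moments (and gradients) for (m,3,3) monomers.

        Returns a dict with ``q`` (m,3), ``mu`` (m,3,3), ``theta`` (m,3,3,3)
        and, when requested, ``dq`` (m,3,3,3), ``dmu`` (m,3,3,3,3),
        ``dtheta`` (m,3,3,3,3,3); gradient axes are (site, [component...],
        atom, xyz).
        """
        from . import features as ft
        m = mol_coords.shape[0]
        q = np.empty((m, 3))
        mu = np.empty((m, 3, 3))
        th = np.empty((m, 3, 3, 3))
        if gradients:
            dq = np.empty((m, 3, 3, 3))
            dmu = np.empty((m, 3, 3, 3, 3))
            dth = np.empty((m, 3, 3, 3, 3, 3))
        for s in range(3):
            mm = self.moments[s]
            X, J = ft.batch_features(mol_coords, s)
            if gradients:
                R, dR = ft.local_frame_gradient(mol_coords, s)
            else:
                R = ft.batch_local_frames(mol_coords, s)
            q[:, s] = mm["q"].predict(X)
            mu_l = np.stack([mm["mu"][k].predict(X) for k in range(3)], axis=1)
            th_c = np.stack([mm["theta"][k].predict(X) for k in range(5)], axis=1)
            th_l = _theta_from_components(th_c)
            # local -> global: R rows are the local axes
            mu[:, s] = np.einsum("mji,mj->mi", R, mu_l)
            th[:, s] = np.einsum("mia,mab,mjb->mij", np.transpose(R, (0, 2, 1)),
                                 th_l, np.transpose(R, (0, 2, 1)))
            if not gradients:
                continue
            dq[:, s] = np.einsum("mf,mfax->max", mm["q"].predict_feature_gradient(X), J)
            dmu_l = np.stack([np.einsum("mf,mfax->max",
                                        mm["mu"][k].predict_feature_gradient(X), J)
                              for k in range(3)], axis=1)          # (m,3,atom,3)
            dth_c = np.stack([np.einsum("mf,mfax->max",
                                        mm["theta"][k].predict_feature_gradient(X), J)
                              for k in range(5)], axis=1)          # (m,5,atom,3)
            dth_l = _theta_from_components(np.moveaxis(dth_c, 1, -1))  # (m,atom,3,3,3)
            dth_l = np.moveaxis(dth_l, (3, 4), (1, 2))                 # (m,3,3,atom,3)
            # product rule through the frame rotation (R^T carries loc->glob)
            dRT = np.transpose(dR, (0, 2, 1, 3, 4))                    # d(R^T)
            dmu[:, s] = (np.einsum("mijax,mj->miax", dRT, mu_l)
                         + np.einsum("mji,mjax->miax", R, dmu_l))
            RT = np.transpose(R, (0, 2, 1))
            dth[:, s] = (np.einsum("miaqx,mab,mjb->mijqx", dRT, th_l, RT)
                         + np.einsum("mia,mab,mjbqx->mijqx", RT, th_l, dRT)
                         + np.einsum("mia,mabqx,mjb->mijqx", RT, dth_l, RT))
        # per-molecule neutrality shift (smooth, symmetric)
        qbar = q.mean(axis=1, keepdims=True)
        q = q - qbar
        out = {"q": q, "mu": mu, "theta": th}
        if gradients:
            dq = dq - dq.mean(axis=1, keepdims=True)
            out.update({"dq": dq, "dmu": dmu, "dtheta": dth})
        return out

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {"format": "gpwater-watermodels-1",
             "energy": [m.to_dict() for m in self.energy]}
        if self.moments is not None:
            d["moments"] = [{"q": e["q"].to_dict(),
                             "mu": [m.to_dict() for m in e["mu"]],
                             "theta": [m.to_dict() for m in e["theta"]]}
                            for e in self.moments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WaterModels":
        if d.get("format") != "gpwater-watermodels-1":
            raise ValueError("unknown model bundle format")
        energy = [GPRModel.from_dict(m) for m in d["energy"]]
        moments = None
        if "moments" in d:
            moments = [{"q": GPRModel.from_dict(e["q"]),
                        "mu": [GPRModel.from_dict(m) for m in e["mu"]],
                        "theta": [GPRModel.from_dict(m) for m in e["theta"]]}
                       for e in d["moments"]]
        return cls(energy, moments)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "WaterModels":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _theta_component(th: np.ndarray, k: int) -> np.ndarray:
    i, j = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2))[k]
    return th[:, i, j]


# --------------------------------------------------------------------------
# study protocol: held-out accuracy of compact active-learned energy models

def energy_model_benchmark(n_total: int = 600, n_train: int = 100,
                           n_init: int = 50, seed: int = 0,
                           config: GPConfig | None = None) -> dict:
    """Held-out accuracy of per-atom energy models under the compact-training
    protocol.

    ``n_total`` monomer geometries are sampled from the oracle; each atom's
    model selects ``n_train`` training points from that pool (``n_init``
    random + the rest by active learning) and is evaluated on the unselected
    remainder.  Returns per-atom maximum absolute errors and S-curves, plus
    the overall maximum (kJ/mol).
    """
    from . import features as ft
    from . import oracle as orc

    cfg = config or GPConfig(seed=seed)
    geoms = orc.sample_geometries(n_total, seed=seed)
    coords = np.array([g.coords for g in geoms])
    energies = np.array([orc.oracle_energies(g).atom_energies for g in geoms])
    out = {"per_atom_max": [], "curves": [], "n_test": n_total - n_train}
    overall = 0.0
    for atom in range(3):
        X, _ = ft.batch_features(coords, atom)
        y = energies[:, atom]
        model, sel = active_learn(X, y, n_init=n_init, n_final=n_train,
                                  seed=seed + atom, config=cfg,
                                  label=f"E[{atom}]")
        mask = np.ones(n_total, dtype=bool)
        mask[sel] = False
        err = np.abs(model.predict(X[mask]) - y[mask])
        out["per_atom_max"].append(float(err.max()))
        out["curves"].append(s_curve(err))
        overall = max(overall, float(err.max()))
    out["max_abs_error"] = overall
    return out


# --------------------------------------------------------------------------
# S-curves

@dataclass
class SCurve:
    """Cumulative distribution of absolute prediction errors."""

    errors: np.ndarray       # sorted ascending
    percent: np.ndarray      # cumulative %, reaching 100

    def percent_at_or_below(self, threshold: float) -> float:
        return 100.0 * float(np.mean(self.errors <= threshold))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"abs_error": self.errors, "cumulative_percent": self.percent})


def s_curve(errors) -> SCurve:
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("cannot build an S-curve from zero errors")
    if np.any(errors < 0):
        raise ValueError("errors must be non-negative")
    srt = np.sort(errors)
    pct = 100.0 * np.arange(1, srt.size + 1) / srt.size
    return SCurve(errors=srt, percent=pct)
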
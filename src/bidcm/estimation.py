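"""Variational-Laplace inversion of the two-region DCM.

:class:`BilinearDCM` is the subject-level model object: it binds one
subject's two-region BOLD record to a candidate network structure, the
driving inputs and shrinkage priors, and its :meth:`~BilinearDCM.fit`
performs Gauss-Newton ascent on the variational free energy

    F = accuracy - KL(posterior || prior)

returning a :class:`DCMResults` with the Gaussian parameter posterior and
F as the model-evidence approximation used downstream by group BMS.

Parameterisation.  Self-connections are A_ii = -0.5 exp(theta) so the
prior mass lies on stable systems; off-diagonal A, B and C entries are
identity-mapped; the haemodynamic parameters are log-scaled around their
conventional values (kappa = 0.64 exp(theta) Hz, tau = 2 exp(theta) s,
epsilon = 0.25 exp(theta)); observation-noise log-precisions (one per region)
carry a tight hyperprior (mean 6, variance 1/128).  To keep that
hyperprior calibrated, the data are rescaled per region to SD
sqrt(2) * 0.05 with the (known) gain applied to the model prediction, so
that at a signal-to-noise ratio of 1 the true log-precision is exactly 6;
parameters keep their physical units.

Also here: the volume-of-interest utilities (first-eigenvariate extraction
and effects-of-interest adjustment) that produce region time series from
multi-voxel data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernel
from ._linalg import propagators
from .core import (MODULATORY_INPUTS, BoldRecord, DCMParameters,
                   ModelStructure)
from .paradigm import INPUT_NAMES, InputSet, RegressorMatrix

__all__ = [
    "PriorSpec", "Posterior", "DCMResults", "BilinearDCM",
    "default_priors", "fit_dcm", "extract_eigenvariate",
    "extract_voi_sphere", "adjust_timeseries",
]

_REGIONS = ("DLPFC", "Striatum")
_OFFDIAG = ((1, 0), (0, 1))  # DLPFC->Striatum, Striatum->DLPFC
_SELF_SCALE = 0.5
_KAPPA0, _TAU0, _EPS0 = 0.64, 2.0, 0.25
_LAM_MEAN, _LAM_VAR = 6.0, 1.0 / 128.0
#: target per-region SD of the rescaled data (makes lambda_true = 6 at SNR 1)
_SCALE_TARGET = 0.05 * np.sqrt(2.0)


# ---------------------------------------------------------------------------
# Priors and the theta <-> DCMParameters map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Diagonal Gaussian prior over the free parameters of one structure.

    The vector covers the neural/haemodynamic parameters followed by the
    two noise log-precisions (names ``lambda_<region>``).
    """

    names: tuple[str, ...]
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != self.mean.size or self.mean.size != self.var.size:
            raise ValueError("names, mean and var must have equal length")
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be positive")

    @property
    def n_params(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _param_entries(structure: ModelStructure) -> list[tuple[str, str, tuple]]:
    """Ordered (name, kind, location) for the free parameters of a structure."""
    entries: list[tuple[str, str, tuple]] = []
    for i, reg in enumerate(_REGIONS):
        entries.append((f"A_self_{reg}", "a_self", (i,)))
    for (i, j) in _OFFDIAG:
        entries.append((f"A_{_REGIONS[j]}->{_REGIONS[i]}", "a_off", (i, j)))
    bmasks = structure.b_matrix_masks()
    for name in MODULATORY_INPUTS:
        for (i, j) in _OFFDIAG:
            if bmasks[name][i, j]:
                entries.append(
                    (f"B_{name}_{_REGIONS[j]}->{_REGIONS[i]}", "b",
                     (name, i, j)))
    cmask = structure.c_matrix_mask()
    for i, reg in enumerate(_REGIONS):
        for j, inp in enumerate(INPUT_NAMES):
            if cmask[i, j]:
                entries.append((f"C_{inp}->{reg}", "c", (i, j)))
    for i, reg in enumerate(_REGIONS):
        entries.append((f"kappa_{reg}", "kappa", (i,)))
    for i, reg in enumerate(_REGIONS):
        entries.append((f"tau_{reg}", "tau", (i,)))
    for i, reg in enumerate(_REGIONS):
        entries.append((f"epsilon_{reg}", "epsilon", (i,)))
    return entries


_PRIOR_VAR = {"a_self": 1.0 / 256.0, "a_off": 1.0 / 16.0, "b": 1.0,
              "c": 1.0, "kappa": 1.0 / 256.0, "tau": 1.0 / 256.0,
              "epsilon": 1.0 / 256.0}


def default_priors(structure: ModelStructure) -> PriorSpec:
    """Zero-mean shrinkage priors over the structure's free parameters."""
    entries = _param_entries(structure)
    names = [e[0] for e in entries]
    var = [_PRIOR_VAR[e[1]] for e in entries]
    mean = [0.0] * len(entries)
    for reg in _REGIONS:
        names.append(f"lambda_{reg}")
        mean.append(_LAM_MEAN)
        var.append(_LAM_VAR)
    return PriorSpec(names=tuple(names), mean=np.array(mean),
                     var=np.array(var))


def theta_to_params(structure: ModelStructure, theta: np.ndarray,
                    lam: np.ndarray | None = None) -> DCMParameters:
    """Map a parameter vector (without the lambdas) to physical parameters."""
    entries = _param_entries(structure)
    if theta.size != len(entries):
        raise ValueError(f"expected {len(entries)} parameters, got {theta.size}")
    p = DCMParameters.baseline()
    p.A[:] = 0.0
    for th, (_, kind, loc) in zip(theta, entries):
        if kind == "a_self":
            p.A[loc[0], loc[0]] = -_SELF_SCALE * np.exp(th)
        elif kind == "a_off":
            p.A[loc[0], loc[1]] = th
        elif kind == "b":
            p.B[loc[0]][loc[1], loc[2]] = th
        elif kind == "c":
            p.C[loc[0], loc[1]] = th
        elif kind == "kappa":
            p.kappa[loc[0]] = _KAPPA0 * np.exp(th)
        elif kind == "tau":
            p.tau[loc[0]] = _TAU0 * np.exp(th)
        elif kind == "epsilon":
            p.epsilon[loc[0]] = _EPS0 * np.exp(th)
    if lam is not None:
        p.lam = np.asarray(lam, float).copy()
    return p


def params_to_theta(structure: ModelStructure,
                    params: DCMParameters) -> np.ndarray:
    """Inverse of :func:`theta_to_params` (without the lambdas)."""
    entries = _param_entries(structure)
    theta = np.empty(len(entries))
    for idx, (_, kind, loc) in enumerate(entries):
        if kind == "a_self":
            theta[idx] = np.log(-params.A[loc[0], loc[0]] / _SELF_SCALE)
        elif kind == "a_off":
            theta[idx] = params.A[loc[0], loc[1]]
        elif kind == "b":
            theta[idx] = params.B[loc[0]][loc[1], loc[2]]
        elif kind == "c":
            theta[idx] = params.C[loc[0], loc[1]]
        elif kind == "kappa":
            theta[idx] = np.log(params.kappa[loc[0]] / _KAPPA0)
        elif kind == "tau":
            theta[idx] = np.log(params.tau[loc[0]] / _TAU0)
        elif kind == "epsilon":
            theta[idx] = np.log(params.epsilon[loc[0]] / _EPS0)
    return theta


# ---------------------------------------------------------------------------
# VOI utilities
# ---------------------------------------------------------------------------

def extract_eigenvariate(voxel_timeseries: np.ndarray) -> np.ndarray:
    """First eigenvariate of a multi-voxel time-series matrix.

    The first left singular vector of the column-demeaned matrix,
    sign-flipped so it correlates non-negatively with the voxel mean and
    scaled to the root-mean-square amplitude of the contributing voxels.
    For a single voxel this returns the demeaned series itself.
    """
    Y = np.asarray(voxel_timeseries, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] < 2 or Y.shape[1] < 1:
        raise ValueError("need >= 2 scans and >= 1 voxel")
    if not np.all(np.isfinite(Y)):
        raise ValueError("voxel time series contain non-finite values")
    Yd = Y - Y.mean(axis=0)
    if not np.any(Yd):
        raise ValueError("voxel time series are constant (all-zero after "
                         "demeaning)")
    U, s, _ = np.linalg.svd(Yd, full_matrices=False)
    u = U[:, 0]
    if u @ Yd.mean(axis=1) < 0:
        u = -u
    rms = np.sqrt(np.mean(Yd ** 2))
    return u * rms * np.sqrt(Y.shape[0])


def extract_voi_sphere(img, center, radius: float = 6.0) -> np.ndarray:
    """First eigenvariate of the voxels inside a sphere of a 4-D image.

    Parameters
    ----------
    img
        A nibabel spatial image (or a path to one) with time on the 4th
        axis.
    center
        Sphere centre in world (mm) coordinates, e.g. the peak voxel of a
        subject-level contrast.
    radius
        Sphere radius in mm (default 6, the conventional VOI size).
    """
    import nibabel as nib
    if not hasattr(img, "get_fdata"):
        img = nib.load(str(img))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) image")
    shape = data.shape[:3]
    ijk = np.indices(shape).reshape(3, -1)
    xyz = img.affine[:3, :3] @ ijk + img.affine[:3, [3]]
    d2 = ((xyz - np.asarray(center, float)[:, None]) ** 2).sum(axis=0)
    sel = d2 <= radius ** 2
    if not sel.any():
        raise ValueError(f"no voxels within {radius} mm of {center}")
    voxels = data.reshape(-1, data.shape[3])[sel].T  # scans x voxels
    return extract_eigenvariate(voxels)


def adjust_timeseries(y: np.ndarray, regressors: RegressorMatrix,
                      keep: list[str] | list[int] | None = None) -> np.ndarray:
    """Remove confound (non-effect-of-interest) variance from a series.

    Residualises ``y`` against every regressor column *not* in ``keep``
    (default: keep the task columns, remove confounds), then demeans.
    Idempotent: the removal is an orthogonal projection.
    """
    y = np.asarray(y, float)
    if keep is None:
        keep_idx = set(range(regressors.n_task))
    else:
        keep_idx = {k if isinstance(k, (int, np.integer))
                    else regressors.names.index(k) for k in keep}
    drop = [j for j in range(regressors.X.shape[1]) if j not in keep_idx]
    X0 = regressors.X[:, drop]
    if X0.shape[1] == 0:
        return y - y.mean()
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        names = [regressors.names[j] for j in drop]
        raise ValueError(
            f"confound block is rank-deficient (rank {rank} < {X0.shape[1]} "
            f"columns: {names})")
    beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
    out = y - X0 @ beta
    return out - out.mean()


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class Posterior:
    """Gaussian parameter posterior plus free-energy evidence (one
    subject x one model)."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    free_energy: float
    n_iterations: int
    converged: bool
    subject_id: str = ""
    model_id: int = -1

    def marginal(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.mean[i]), float(np.sqrt(self.cov[i, i]))

    def to_dict(self) -> dict:
        return {"names": list(self.names), "mean": self.mean.tolist(),
                "cov": self.cov.tolist(),
                "free_energy": float(self.free_energy),
                "n_iterations": int(self.n_iterations),
                "converged": bool(self.converged),
                "subject_id": self.subject_id,
                "model_id": int(self.model_id)}

    @classmethod
    def from_dict(cls, d: dict) -> "Posterior":
        return cls(names=tuple(d["names"]),
                   mean=np.asarray(d["mean"], float),
                   cov=np.asarray(d["cov"], float),
                   free_energy=float(d["free_energy"]),
                   n_iterations=int(d["n_iterations"]),
                   converged=bool(d["converged"]),
                   subject_id=str(d.get("subject_id", "")),
                   model_id=int(d.get("model_id", -1)))


class DCMResults:
    """Fit results of one :class:`BilinearDCM`.

    Attributes
    ----------
    posterior : Posterior
        Gaussian posterior over the named parameters (model parameters,
        confound betas, noise log-precisions).
    free_energy : float
        Variational free energy (nats), the evidence approximation.
    params : DCMParameters
        Physical parameters at the posterior mean.
    f_trace : ndarray
        Free energy across accepted iterations (non-decreasing up to the
        convergence tolerance).
    """

    def __init__(self, model: "BilinearDCM", posterior: Posterior,
                 f_trace: np.ndarray):
        self.model = model
        self.posterior = posterior
        self.f_trace = np.asarray(f_trace, float)

    @property
    def free_energy(self) -> float:
        return self.posterior.free_energy

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    @property
    def n_iterations(self) -> int:
        return self.posterior.n_iterations

    @property
    def params(self) -> DCMParameters:
        n_model = len(self.model.entries)
        theta = self.posterior.mean[:n_model]
        lam = np.array([self.posterior.mean[self.posterior.names.index(f"lambda_{r}")]
                        for r in _REGIONS])
        return theta_to_params(self.model.structure, theta, lam=lam)

    def fitted(self) -> np.ndarray:
        """Model prediction at the posterior mean, on the data scale."""
        n_model = len(self.model.entries)
        g = self.model._forward_batch(self.posterior.mean[:n_model][None])[0]
        return g / self.model.scale  # back to raw units

    def summary(self) -> str:
        p = self.posterior
        lines = [
            "Bilinear two-region DCM (variational Laplace)",
            f"subject: {p.subject_id or '-'}   model: {p.model_id}",
            f"free energy: {p.free_energy:.2f} nats   "
            f"iterations: {p.n_iterations}   converged: {p.converged}",
            "",
            f"{'parameter':<28}{'post. mean':>12}{'post. sd':>10}",
        ]
        for i, name in enumerate(p.names):
            lines.append(f"{name:<28}{p.mean[i]:>12.4f}"
                         f"{np.sqrt(p.cov[i, i]):>10.4f}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed vs fitted BOLD per region (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = np.arange(self.model.record.n_scans) * self.model.record.tr
        fit = self.fitted()
        for r, name in enumerate(_REGIONS):
            ax.plot(t, self.model.y_raw[:, r], lw=0.6, alpha=0.6,
                    label=f"{name} data")
            ax.plot(t, fit[:, r], lw=1.2, label=f"{name} fit")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("BOLD (a.u., demeaned)")
        ax.legend(fontsize=8)
        return ax


# ---------------------------------------------------------------------------
# The model object
# ---------------------------------------------------------------------------

class BilinearDCM:
    """Subject-level DCM: data + structure + inputs + priors.

    Parameters
    ----------
    record
        Two-region BOLD record (raw units; demeaned and rescaled
        internally).
    structure
        Candidate network structure (which modulations/inputs exist).
    inputs
        Driving-input functions on the microtime grid.
    priors
        Parameter priors; defaults to :func:`default_priors`.
    confounds
        Optional nuisance columns (n_scans x k), fitted jointly with the
        model as fixed-effect regressors (a constant is always included).
    ar1_rho
        Optional AR(1) coefficient for residual pre-whitening (``None``
        disables; ``"estimate"`` uses the lag-1 autocorrelation of the
        confound-adjusted data).
    """

    def __init__(self, record: BoldRecord, structure: ModelStructure,
                 inputs: InputSet, priors: PriorSpec | None = None,
                 confounds: np.ndarray | None = None,
                 ar1_rho: float | str | None = None):
        if record.n_scans != inputs.n_scans:
            raise ValueError("record and inputs disagree on n_scans")
        self.record = record
        self.structure = structure
        self.inputs = inputs
        self.priors = priors if priors is not None else default_priors(structure)
        self.entries = _param_entries(structure)
        if self.priors.n_params != len(self.entries) + 2:
            raise ValueError("priors do not match the structure's parameters")

        y = np.asarray(record.y, float)
        self.y_raw = y - y.mean(axis=0)
        sd = self.y_raw.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant region time series")
        self.scale = _SCALE_TARGET / sd  # per-region gain applied to data & model
        self.ys = self.y_raw * self.scale

        n = record.n_scans
        X0 = [np.ones(n)]
        names0 = ["constant"]
        if confounds is not None:
            confounds = np.atleast_2d(np.asarray(confounds, float))
            if confounds.shape[0] != n:
                raise ValueError("confounds must have n_scans rows")
            for k in range(confounds.shape[1]):
                col = confounds[:, k]
                s = col.std()
                X0.append((col - col.mean()) / (s if s > 0 else 1.0))
                names0.append(f"confound_{k + 1}")
        self.X0 = np.column_stack(X0)
        self.beta_names = tuple(f"beta_{nm}_{reg}" for reg in _REGIONS
                                for nm in names0)

        if ar1_rho == "estimate":
            resid = self.ys - self.X0 @ np.linalg.lstsq(
                self.X0, self.ys, rcond=None)[0]
            num = np.sum(resid[1:] * resid[:-1])
            den = np.sum(resid ** 2)
            ar1_rho = float(num / den) if den > 0 else 0.0
        self.ar1_rho = None if ar1_rho in (None, 0.0) else float(ar1_rho)

        # distinct input patterns (fixed across the fit)
        self._patterns, pat = np.unique(inputs.u, axis=0, return_inverse=True)
        self._pat = pat.astype(np.int64)

    # -- forward model ----------------------------------------------------
    def _propagators(self, thetas: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Neural propagators and haemo parameter arrays per theta row."""
        P = thetas.shape[0]
        K = self._patterns.shape[0]
        J = np.empty((P, K, 2, 2))
        c = np.empty((P, K, 2))
        hemo = np.empty((P, 3, 2))  # kappa, tau, eps
        for p in range(P):
            pars = theta_to_params(self.structure, thetas[p])
            hemo[p, 0] = pars.kappa
            hemo[p, 1] = pars.tau
            hemo[p, 2] = pars.epsilon
            for k, u in enumerate(self._patterns):
                Jk = pars.A.copy()
                for name in MODULATORY_INPUTS:
                    Jk = Jk + u[INPUT_NAMES.index(name)] * pars.B[name]
                J[p, k] = Jk
                c[p, k] = pars.C @ u
        E, f = propagators(J, c, self.inputs.dt)
        return (np.ascontiguousarray(E), np.ascontiguousarray(f), hemo)

    def _forward_batch(self, thetas: np.ndarray) -> np.ndarray:
        """Scaled model predictions for a batch of theta vectors.

        Returns (P, n_scans, 2); rows whose trajectory diverged are NaN.
        """
        E, Fc, hemo = self._propagators(thetas)
        pars0 = DCMParameters.baseline()
        out = np.empty((thetas.shape[0], self.inputs.n_scans, 2))
        status = _kernel.forward_batch(
            E, Fc, self._pat,
            np.ascontiguousarray(hemo[:, 0]), np.ascontiguousarray(hemo[:, 1]),
            np.ascontiguousarray(hemo[:, 2]),
            pars0.gamma, pars0.alpha, pars0.E0, pars0.V0,
            pars0.k1, pars0.k2, pars0.k3,
            self.inputs.dt, self.inputs.bins_per_scan, out)
        out -= out.mean(axis=1, keepdims=True)
        out *= self.scale
        out[status != _kernel.OK] = np.nan
        return out

    def predict(self, params: DCMParameters) -> np.ndarray:
        """Noise-free prediction (raw units, demeaned) for given parameters."""
        theta = params_to_theta(self.structure, params)
        return self._forward_batch(theta[None])[0] / self.scale

    # -- whitening --------------------------------------------------------
    def _whiten(self, a: np.ndarray) -> np.ndarray:
        """Apply the AR(1) whitening filter along axis 0 (no-op if unset)."""
        if self.ar1_rho is None:
            return a
        rho = self.ar1_rho
        out = np.empty_like(a)
        out[0] = a[0] * np.sqrt(1.0 - rho ** 2)
        out[1:] = a[1:] - rho * a[:-1]
        return out

    # -- free energy ------------------------------------------------------
    def _free_energy(self, e_blocks, lam, mu, dmu, P0, Sigma, JtJ_r,
                     lam_prior):
        """Laplace free energy given residual blocks and posterior Sigma."""
        lam_mean, lam_prec = lam_prior
        n = e_blocks[0].size
        F = 0.0
        for r in range(2):
            ssr = float(e_blocks[r] @ e_blocks[r])
            trc = float(np.sum(JtJ_r[r] * Sigma))
            F += -0.5 * np.exp(lam[r]) * (ssr + trc) + 0.5 * n * lam[r]
            F += -0.5 * n * np.log(2.0 * np.pi)
        # parameter complexity
        sign, logdet_S = np.linalg.slogdet(Sigma)
        F += -0.5 * float(dmu @ (P0 * dmu))
        F += 0.5 * logdet_S + 0.5 * float(np.sum(np.log(P0)))
        # hyperparameter complexity
        for r in range(2):
            ssr = float(e_blocks[r] @ e_blocks[r])
            trc = float(np.sum(JtJ_r[r] * Sigma))
            h_post = 0.5 * np.exp(lam[r]) * (ssr + trc) + lam_prec[r]
            F += -0.5 * lam_prec[r] * (lam[r] - lam_mean[r]) ** 2
            F += 0.5 * (np.log(lam_prec[r]) - np.log(h_post))
        return F

    @staticmethod
    def _update_lambda(lam, e_blocks, Sigma, JtJ_r, lam_prior):
        """Newton update of the noise log-precisions under their hyperprior."""
        lam_mean, lam_prec = lam_prior
        n = e_blocks[0].size
        lam = lam.copy()
        for r in range(2):
            ssr = float(e_blocks[r] @ e_blocks[r])
            trc = float(np.sum(JtJ_r[r] * Sigma))
            for _ in range(8):
                g = -0.5 * np.exp(lam[r]) * (ssr + trc) + 0.5 * n \
                    - lam_prec[r] * (lam[r] - lam_mean[r])
                h = -0.5 * np.exp(lam[r]) * (ssr + trc) - lam_prec[r]
                step = np.clip(-g / h, -2.0, 2.0)
                lam[r] += step
                if abs(step) < 1e-6:
                    break
        return lam

    # -- fitting ----------------------------------------------------------
    def fit(self, max_iter: int = 64, tol: float = 1e-2,
            fd_step: float = 1e-4, warm_start: bool = True,
            n_starts: int = 1, start_seed: int = 0,
            verbose: bool = False) -> DCMResults:
        """Gauss-Newton / Levenberg-Marquardt ascent on the free energy.

        Gradients use forward finite differences on the forward model
        (relative step ``fd_step``); non-improving steps are re-tried with
        increased damping.  Convergence requires |dF| < ``tol`` on four
        successive accepted iterations.

        With ``warm_start`` (default), models with modulatory parameters
        are fitted by continuation: a first ascent with the B entries
        pinned at their prior mean (the nested no-modulation landscape,
        which is easier to search), then a second ascent over all
        parameters from that solution.  This keeps the evidence of nested
        models ordered by their actual fit rather than by basin luck.
        ``n_starts > 1`` additionally re-runs the ascent from seeded
        jittered starting points and keeps the solution with the highest
        free energy (guards against residual local optima).
        """
        n_model = len(self.entries)
        n_beta = self.X0.shape[1] * 2
        prior_mean = np.concatenate(
            [self.priors.mean[:n_model], np.zeros(n_beta)])
        prior_var = np.concatenate(
            [self.priors.var[:n_model], np.ones(n_beta)])
        P0 = 1.0 / prior_var
        lam0_idx = self.priors.index(f"lambda_{_REGIONS[0]}")
        lam_prior = (np.array([self.priors.mean[lam0_idx],
                               self.priors.mean[lam0_idx + 1]]),
                     1.0 / np.array([self.priors.var[lam0_idx],
                                     self.priors.var[lam0_idx + 1]]))

        n = self.record.n_scans
        ys_w = self._whiten(self.ys)
        X0w = self._whiten(self.X0)

        def residual_blocks(g, beta):
            res = ys_w - self._whiten(g)
            res -= X0w @ beta.reshape(2, -1).T
            return [res[:, 0], res[:, 1]]

        def jacobian(theta, g0, fd_idx):
            """FD Jacobian for the fd_idx model parameters plus analytic
            confound columns; other columns are zero (pinned parameters).

            Returns per-region J blocks, shape (2, n, p)."""
            h = fd_step * np.maximum(1.0, np.abs(theta))
            thetas = np.repeat(theta[None], len(fd_idx), axis=0)
            for row, i in enumerate(fd_idx):
                thetas[row, i] += h[i]
            gp = self._forward_batch(thetas)
            J = np.zeros((2, n, n_model + n_beta))
            for row, i in enumerate(fd_idx):
                col = (gp[row] - g0) / h[i]
                if not np.all(np.isfinite(col)):
                    col = np.zeros_like(col)  # divergent perturbation
                colw = self._whiten(col)
                J[0, :, i] = colw[:, 0]
                J[1, :, i] = colw[:, 1]
            k0 = self.X0.shape[1]
            J[0, :, n_model:n_model + k0] = X0w
            J[1, :, n_model + k0:] = X0w
            return J

        def evaluate(mu_, lam_ref, Sigma_ref, fd_idx):
            """Forward + curvature + free energy at mu_ (None if divergent)."""
            g = self._forward_batch(mu_[:n_model][None])[0]
            if not np.all(np.isfinite(g)):
                return None
            e = residual_blocks(g, mu_[n_model:])
            Jm = jacobian(mu_[:n_model], g, fd_idx)
            JtJ = [Jm[r].T @ Jm[r] for r in range(2)]
            lam_ = self._update_lambda(lam_ref, e, Sigma_ref, JtJ, lam_prior)
            H = sum(np.exp(lam_[r]) * JtJ[r] for r in range(2)) + np.diag(P0)
            Sigma = np.linalg.inv(H)
            Sigma = 0.5 * (Sigma + Sigma.T)
            F = self._free_energy(e, lam_, mu_, mu_ - prior_mean, P0, Sigma,
                                  JtJ, lam_prior)
            return {"mu": mu_, "lam": lam_, "g": g, "e": e, "J": Jm,
                    "JtJ": JtJ, "Sigma": Sigma, "F": F}

        def ascend(state, fd_idx, iters, label):
            """LM ascent over the fd_idx parameters from a starting state."""
            damping = 0.25
            trace = [state["F"]]
            n_small, it, dF = 0, 0, np.inf
            converged = False
            for it in range(1, iters + 1):
                Lam_w = [np.exp(state["lam"][r]) for r in range(2)]
                H = sum(Lam_w[r] * state["JtJ"][r] for r in range(2)) \
                    + np.diag(P0)
                grad = sum(Lam_w[r] * (state["J"][r].T @ state["e"][r])
                           for r in range(2)) \
                    - P0 * (state["mu"] - prior_mean)
                Hd = H + damping * np.diag(np.diag(H))
                try:
                    step = np.linalg.solve(Hd, grad)
                except np.linalg.LinAlgError:
                    damping *= 8.0
                    continue
                cand = evaluate(state["mu"] + step, state["lam"],
                                state["Sigma"], fd_idx)
                if cand is not None and np.isfinite(cand["F"]) \
                        and cand["F"] > state["F"]:
                    dF = cand["F"] - state["F"]
                    state = cand
                    trace.append(state["F"])
                    damping = max(damping / 2.0, 1e-6)
                    if verbose:
                        print(f"  {label} it {it:3d}  F = {state['F']:12.4f}"
                              f"  dF = {dF:9.5f}")
                    n_small = n_small + 1 if dF < tol else 0
                    if n_small >= 4:
                        converged = True
                        break
                else:
                    damping *= 8.0
                    if verbose and cand is not None:
                        print(f"  {label} it {it:3d}  rejected "
                              f"(F = {cand['F']:12.4f})")
                    if damping > 1e8:
                        # no damped direction improves F: a plateau
                        converged = dF < tol
                        break
            return state, trace, it, converged

        lam0 = lam_prior[0].copy()
        Sigma0 = np.diag(prior_var)
        all_idx = list(range(n_model))
        b_idx = [i for i, e in enumerate(self.entries) if e[1] == "b"]
        jitter_rng = np.random.default_rng(start_seed)

        def one_start(mu0):
            total = 0
            if warm_start and b_idx:
                # continuation: search the nested no-mod landscape first
                sub_idx = [i for i in all_idx if i not in b_idx]
                state = evaluate(mu0, lam0, Sigma0, sub_idx)
                if state is None:
                    return None
                state, _, it1, _ = ascend(state, sub_idx, max_iter, "warm")
                total += it1
                state = evaluate(state["mu"], state["lam"], state["Sigma"],
                                 all_idx)
            else:
                state = evaluate(mu0, lam0, Sigma0, all_idx)
                if state is None:
                    return None
            state, trace, it2, conv = ascend(state, all_idx, max_iter,
                                             "main")
            return state, trace, total + it2, conv

        best = None
        for s in range(max(1, n_starts)):
            mu0 = prior_mean.copy()
            if s > 0:
                mu0[:n_model] += 0.5 * np.sqrt(prior_var[:n_model]) \
                    * jitter_rng.standard_normal(n_model)
            outcome = one_start(mu0)
            if outcome is None:
                if s == 0:
                    raise FloatingPointError(
                        "forward model diverged at the prior mean")
                continue
            if best is None or outcome[0]["F"] > best[0]["F"]:
                best = outcome
        if best is None:
            raise FloatingPointError("all starting points diverged")
        state, f_trace, it, converged = best
        mu, lam, F, Sigma = state["mu"], state["lam"], state["F"], \
            state["Sigma"]
        e_blocks, JtJ_r = state["e"], state["JtJ"]

        if not np.isfinite(F):
            raise FloatingPointError(
                f"non-finite free energy after {it} iterations; "
                f"trace: {np.array2string(np.array(f_trace), precision=3)}")

        # jitter to guarantee a usable PD covariance
        w, V = np.linalg.eigh(Sigma)
        w = np.maximum(w, 1e-9)
        Sigma = (V * w) @ V.T

        lam_var = np.empty(2)
        for r in range(2):
            ssr = float(e_blocks[r] @ e_blocks[r])
            trc = float(np.sum(JtJ_r[r] * Sigma))
            lam_var[r] = 1.0 / (0.5 * np.exp(lam[r]) * (ssr + trc)
                                + lam_prior[1][r])

        names = tuple(self.priors.names[:n_model]) + self.beta_names \
            + (f"lambda_{_REGIONS[0]}", f"lambda_{_REGIONS[1]}")
        mean = np.concatenate([mu, lam])
        cov = np.zeros((mean.size, mean.size))
        cov[:mu.size, :mu.size] = Sigma
        cov[mu.size, mu.size] = lam_var[0]
        cov[mu.size + 1, mu.size + 1] = lam_var[1]

        if not converged:
            warnings.warn(
                f"DCM fit did not meet the convergence criterion in {it} "
                "iterations", RuntimeWarning, stacklevel=2)
        post = Posterior(names=names, mean=mean, cov=cov, free_energy=float(F),
                         n_iterations=int(it), converged=bool(converged),
                         subject_id=self.record.subject_id,
                         model_id=self.structure.model_id)
        return DCMResults(self, post, np.array(f_trace))


def fit_dcm(record: BoldRecord, structure: ModelStructure, inputs: InputSet,
            priors: PriorSpec | None = None, confounds: np.ndarray | None = None,
            max_iter: int = 64, tol: float = 1e-2,
            ar1_rho: float | str | None = None) -> DCMResults:
    """Convenience wrapper: build a :class:`BilinearDCM` and fit it."""
    model = BilinearDCM(record, structure, inputs, priors=priors,
                        confounds=confounds, ar1_rho=ar1_rho)
    return model.fit(max_iter=max_iter, tol=tol)
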
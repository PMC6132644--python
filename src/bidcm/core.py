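"""Two-region bilinear neural model with balloon haemodynamics.

The neural state x (one scalar per region, here DLPFC and striatum) follows
the deterministic bilinear equation

    dx/dt = (A + sum_j u_j(t) B_j) x + C u(t)

where A is the intrinsic (condition-independent) coupling, the B_j are
condition-specific modulations of the connections, and C routes the
experimental inputs u(t) (EN, EP, RN, RP) into the regions.  Each region's
neural activity drives a balloon/Windkessel haemodynamic cascade
(vasodilatory signal s, blood flow f, venous volume v, deoxyhemoglobin q)
whose output is the BOLD signal

    y = V0 (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)).

Only the signal decay kappa, the transit time tau and the neuronal efficacy
epsilon are free haemodynamic parameters; the remaining constants are fixed
at conventional 1.5T values (V0 = 4, gamma = 0.32, alpha = 0.32, E0 = 0.4,
k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from ._linalg import propagators
from .paradigm import INPUT_NAMES, InputSet

__all__ = [
    "REGIONS",
    "MODULATORY_INPUTS",
    "ModelStructure",
    "DCMParameters",
    "BoldRecord",
    "simulate_neural",
    "simulate_bold",
    "add_noise",
]

#: The two modelled regions, in index order.
REGIONS = ("DLPFC", "Striatum")

#: Inputs allowed to modulate connections (the encoding conditions).
MODULATORY_INPUTS = ("EN", "EP")

#: Driving-input routing flags: (bundle, target-region-index).
C_FLAGS = (("enc", 0), ("enc", 1), ("ret", 0), ("ret", 1))

_BUNDLES = {"enc": ("EN", "EP"), "ret": ("RN", "RP")}


@dataclass(frozen=True)
class ModelStructure:
    """Which connections, modulations and inputs exist in one model.

    ``b_masks[j][i, k]`` enables modulation of the k->i connection by input
    j (off-diagonal only).  ``c_mask`` holds four routing flags over
    (encoding bundle -> DLPFC, encoding bundle -> striatum, retrieval
    bundle -> DLPFC, retrieval bundle -> striatum); a set flag enables the
    two per-condition C entries of that bundle into that region.  Intrinsic
    connections are bidirectional in every model.
    """

    b_masks: tuple[tuple[bool, bool], tuple[bool, bool]]  # (EN, EP) x (d->s, s->d)
    c_mask: tuple[bool, bool, bool, bool]
    model_id: int = -1
    family_id: int = -1
    region_names: tuple[str, str] = REGIONS

    def __post_init__(self) -> None:
        if len(self.b_masks) != 2 or any(len(m) != 2 for m in self.b_masks):
            raise ValueError("b_masks must be 2 inputs x 2 directed connections")
        if len(self.c_mask) != 4:
            raise ValueError("c_mask must hold 4 routing flags")

    @property
    def a_mask(self) -> np.ndarray:
        """Intrinsic coupling mask: full (self + bidirectional)."""
        return np.ones((2, 2), dtype=bool)

    def b_matrix_masks(self) -> dict[str, np.ndarray]:
        """Modulation masks as 2x2 boolean matrices keyed by input name."""
        out = {}
        for j, name in enumerate(MODULATORY_INPUTS):
            m = np.zeros((2, 2), dtype=bool)
            m[1, 0] = self.b_masks[j][0]  # DLPFC -> striatum
            m[0, 1] = self.b_masks[j][1]  # striatum -> DLPFC
            out[name] = m
        return out

    def c_matrix_mask(self) -> np.ndarray:
        """Driving-input mask as a 2x4 boolean matrix (region x EN,EP,RN,RP)."""
        m = np.zeros((2, 4), dtype=bool)
        for flag, (bundle, region) in zip(self.c_mask, C_FLAGS):
            if flag:
                for cond in _BUNDLES[bundle]:
                    m[region, INPUT_NAMES.index(cond)] = True
        return m

    @classmethod
    def full(cls, model_id: int = -1, family_id: int = -1) -> "ModelStructure":
        """Full modulation, all inputs to both regions."""
        return cls(b_masks=((True, True), (True, True)),
                   c_mask=(True, True, True, True),
                   model_id=model_id, family_id=family_id)


@dataclass
class DCMParameters:
    """Numerical parameters of one model (rates in Hz, times in s).

    ``A[i, k]`` is the coupling from region k to region i; the diagonal
    holds the (negative) self-decay.  ``B`` maps modulatory input name to
    its 2x2 modulation matrix; ``C`` is 2x4 over (region x EN,EP,RN,RP).
    ``lam`` is the log-precision of the observation noise per region and
    ``rho`` its AR(1) coefficient (used when synthesising noise).
    """

    A: np.ndarray
    B: dict[str, np.ndarray]
    C: np.ndarray
    kappa: np.ndarray = field(default_factory=lambda: np.array([0.64, 0.64]))
    tau: np.ndarray = field(default_factory=lambda: np.array([2.0, 2.0]))
    epsilon: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.25]))
    gamma: float = 0.32
    alpha: float = 0.32
    E0: float = 0.4
    V0: float = 4.0
    lam: np.ndarray = field(default_factory=lambda: np.array([4.0, 4.0]))
    rho: float = 0.2

    @property
    def k1(self) -> float:
        return 7.0 * self.E0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.E0 - 0.2

    @classmethod
    def baseline(cls, self_decay: float = -0.5) -> "DCMParameters":
        """Resting parameters: self-decay only, no coupling or input gains."""
        A = np.diag([self_decay, self_decay]).astype(float)
        B = {name: np.zeros((2, 2)) for name in MODULATORY_INPUTS}
        return cls(A=A, B=B, C=np.zeros((2, 4)))

    def copy(self) -> "DCMParameters":
        return DCMParameters(
            A=self.A.copy(), B={k: v.copy() for k, v in self.B.items()},
            C=self.C.copy(), kappa=self.kappa.copy(), tau=self.tau.copy(),
            epsilon=self.epsilon.copy(), gamma=self.gamma, alpha=self.alpha,
            E0=self.E0, V0=self.V0, lam=self.lam.copy(), rho=self.rho)

    def validate(self, structure: ModelStructure | None = None) -> None:
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("A diagonal (self-decay) must be negative")
        if np.any(self.kappa <= 0) or np.any(self.tau <= 0) or self.E0 <= 0:
            raise ValueError("kappa, tau and E0 must be positive")
        if structure is not None:
            for name in MODULATORY_INPUTS:
                mask = structure.b_matrix_masks()[name]
                if np.any(self.B[name][~mask] != 0):
                    raise ValueError(f"B_{name} has nonzero masked entries")
            if np.any(self.C[~structure.c_matrix_mask()] != 0):
                raise ValueError("C has nonzero masked entries")

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": {k: v.tolist() for k, v in self.B.items()},
            "C": self.C.tolist(),
            "kappa": self.kappa.tolist(), "tau": self.tau.tolist(),
            "epsilon": self.epsilon.tolist(), "gamma": self.gamma,
            "alpha": self.alpha, "E0": self.E0, "V0": self.V0,
            "lam": self.lam.tolist(), "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMParameters":
        return cls(A=np.asarray(d["A"], float),
                   B={k: np.asarray(v, float) for k, v in d["B"].items()},
                   C=np.asarray(d["C"], float),
                   kappa=np.asarray(d["kappa"], float),
                   tau=np.asarray(d["tau"], float),
                   epsilon=np.asarray(d["epsilon"], float),
                   gamma=d["gamma"], alpha=d["alpha"], E0=d["E0"],
                   V0=d["V0"], lam=np.asarray(d["lam"], float),
                   rho=d["rho"])


@dataclass
class BoldRecord:
    """Region-level BOLD time series for one subject."""

    y: np.ndarray  # (n_scans, 2)
    tr: float
    confounds: np.ndarray | None = None
    subject_id: str = ""
    region_names: tuple[str, str] = REGIONS

    @property
    def n_scans(self) -> int:
        return self.y.shape[0]

    def to_tsv(self, path, sidecar: dict | None = None) -> None:
        path = Path(path)
        cols = {name: self.y[:, i] for i, name in enumerate(self.region_names)}
        if self.confounds is not None:
            for k in range(self.confounds.shape[1]):
                cols[f"confound_{k + 1}"] = self.confounds[:, k]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        meta = {"tr": self.tr, "subject_id": self.subject_id,
                "region_names": list(self.region_names)}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path) -> tuple["BoldRecord", dict]:
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(".json").read_text())
        regions = tuple(meta["region_names"])
        y = df[list(regions)].to_numpy()
        ccols = [c for c in df.columns if c.startswith("confound_")]
        conf = df[ccols].to_numpy() if ccols else None
        rec = cls(y=y, tr=float(meta["tr"]), confounds=conf,
                  subject_id=str(meta.get("subject_id", "")),
                  region_names=regions)  # type: ignore[arg-type]
        return rec, meta


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _pattern_system(params: DCMParameters, inputs: InputSet
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin propagators for the piecewise-constant input train.

    Returns (E, f, pat): for each distinct input pattern k, ``E[k]`` is
    expm(J_k dt) with J_k = A + sum_j u_j B_j and ``f[k]`` the forced
    response over one bin (computed jointly via the augmented-matrix
    exponential); ``pat[b]`` indexes the pattern of bin b.
    """
    patterns, pat = np.unique(inputs.u, axis=0, return_inverse=True)
    K = patterns.shape[0]
    J = np.empty((K, 2, 2))
    c = np.empty((K, 2))
    for k, u in enumerate(patterns):
        Jk = params.A.copy()
        for name in MODULATORY_INPUTS:
            Jk = Jk + u[INPUT_NAMES.index(name)] * params.B[name]
        J[k] = Jk
        c[k] = params.C @ u
    E, f = propagators(J, c, inputs.dt)
    return (np.ascontiguousarray(E), np.ascontiguousarray(f),
            pat.astype(np.int64))


def simulate_neural(params: DCMParameters, inputs: InputSet,
                    structure: ModelStructure | None = None) -> np.ndarray:
    """Integrate the bilinear neural equation over microtime.

    Inputs are held constant within each bin, making the per-bin update
    exact (matrix exponential).  Returns the trajectory at bin ends,
    shape (n_bins, 2), starting from rest x(0) = 0.

    Raises
    ------
    FloatingPointError
        If the trajectory diverges, naming the first divergent bin.
    """
    params.validate(structure)
    E, f, pat = _pattern_system(params, inputs)
    x = np.zeros(2)
    out = np.empty((inputs.n_bins, 2))
    for b in range(inputs.n_bins):
        k = pat[b]
        x = E[k] @ x + f[k]
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e6):
            raise FloatingPointError(
                f"neural trajectory diverged at microtime bin {b}")
        out[b] = x
    return out


def simulate_bold(params: DCMParameters, inputs: InputSet,
                  structure: ModelStructure | None = None,
                  subject_id: str = "") -> BoldRecord:
    """Noise-free BOLD from the neural + balloon forward model.

    The output has one sample per scan (states at times n*TR) and is zero
    at baseline (x = 0 is a fixed point of the haemodynamic cascade).
    """
    params.validate(structure)
    E, f, pat = _pattern_system(params, inputs)
    y = np.empty((1, inputs.n_scans, 2))
    status = _kernel.forward_batch(
        E[None], f[None], pat,
        np.asarray(params.kappa, float)[None],
        np.asarray(params.tau, float)[None],
        np.asarray(params.epsilon, float)[None],
        params.gamma, params.alpha, params.E0, params.V0,
        params.k1, params.k2, params.k3,
        inputs.dt, inputs.bins_per_scan, y)
    if status[0] != _kernel.OK:
        raise FloatingPointError(
            f"forward model diverged at microtime bin {status[0]}")
    return BoldRecord(y=y[0], tr=inputs.tr, subject_id=subject_id)


def add_noise(record: BoldRecord, lam, rho: float, seed: int) -> BoldRecord:
    """Add stationary AR(1) Gaussian noise to a BOLD record.

    ``lam`` is the log-precision per region: the stationary noise variance
    is exp(-lam).  Seeded and reproducible.
    """
    lam = np.broadcast_to(np.asarray(lam, float), (record.y.shape[1],))
    if not np.all(np.isfinite(lam)):
        raise ValueError("lam must be finite")
    if abs(rho) >= 1:
        raise ValueError(f"AR(1) coefficient must satisfy |rho| < 1, got {rho}")
    rng = np.random.default_rng(seed)
    n, r = record.y.shape
    sd = np.exp(-lam / 2.0)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    eps = rng.standard_normal((n, r))
    noise = np.empty((n, r))
    noise[0] = sd * eps[0]
    for t in range(1, n):
        noise[t] = rho * noise[t - 1] + innov_sd * eps[t]
    return BoldRecord(y=record.y + noise, tr=record.tr,
                      confounds=record.confounds,
                      subject_id=record.subject_id,
                      region_names=record.region_names)
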
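"""Random-effects Bayesian model selection and parameter averaging.

Given a subjects x models matrix of free energies (log-evidence
approximations), the random-effects (RFX) model treats the model
generating each subject's data as drawn from unknown population
frequencies r with a Dirichlet prior.  A variational fixed point yields
Dirichlet counts alpha and per-subject model responsibilities; Monte-Carlo
sampling of the Dirichlet posterior gives exceedance probabilities
phi_k = P(r_k > r_j for all j != k).

The Bayes omnibus risk (BOR) is the posterior probability of the null
hypothesis that all models are equally frequent; it protects the
exceedance probabilities:

    pxp_k = phi_k * (1 - BOR) + BOR / M.

Families (groups of models sharing a structural feature, here the
modulation pattern) are compared by equalising the prior mass per family
and summing sampled model frequencies within each family.

Bayesian parameter averaging (BPA) combines subject-level Gaussian
posteriors of one model by precision weighting into a group posterior,
with per-parameter posterior probabilities Pp = max(P(theta>0), P(theta<0)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, ndtr

from .estimation import DCMResults, Posterior

__all__ = [
    "EvidenceMatrix", "BMSResult", "FamilyResult", "BPAResult",
    "RandomEffectsBMS", "FamilyBMS", "rfx_bms", "exceedance",
    "protected_exceedance", "family_bms", "bpa",
]

_MC_WARN_THRESHOLD = 10_000


@dataclass
class EvidenceMatrix:
    """Subjects x models free energies (nats)."""

    F: np.ndarray
    subject_ids: tuple = ()
    model_ids: tuple = ()

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, float)
        if self.F.ndim != 2:
            raise ValueError("F must be 2-D (subjects x models)")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("free energies must be finite")
        n, m = self.F.shape
        if n < 1 or m < 2:
            raise ValueError("need >= 1 subject and >= 2 models")
        if not self.subject_ids:
            self.subject_ids = tuple(f"sub-{i + 1:02d}" for i in range(n))
        if not self.model_ids:
            self.model_ids = tuple(range(m))
        if len(self.subject_ids) != n or len(self.model_ids) != m:
            raise ValueError("id lengths do not match F")

    @property
    def n_subjects(self) -> int:
        return self.F.shape[0]

    @property
    def n_models(self) -> int:
        return self.F.shape[1]

    @classmethod
    def from_results(cls, results: list[list[DCMResults | Posterior]]
                     ) -> "EvidenceMatrix":
        """Build from per-subject lists of fit results (same model order)."""
        F = np.array([[r.free_energy for r in row] for row in results])
        sids = tuple(getattr(row[0], "posterior", row[0]).subject_id or
                     f"sub-{i + 1:02d}" for i, row in enumerate(results))
        mids = tuple(getattr(r, "posterior", r).model_id
                     for r in results[0])
        return cls(F=F, subject_ids=sids, model_ids=mids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.F, index=list(self.subject_ids),
                     columns=[str(m) for m in self.model_ids]) \
            .rename_axis("subject").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "EvidenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(F=df.to_numpy(), subject_ids=tuple(df.index),
                   model_ids=tuple(int(c) if c.isdigit() else c
                                   for c in df.columns))


@dataclass
class BMSResult:
    """Group-level RFX BMS inference over models."""

    alpha: np.ndarray          # Dirichlet counts
    alpha0: np.ndarray         # prior counts
    r: np.ndarray              # expected frequencies
    g: np.ndarray              # responsibilities (subjects x models)
    converged: bool
    n_iterations: int
    xp: np.ndarray | None = None    # exceedance probabilities
    bor: float | None = None        # Bayes omnibus risk
    pxp: np.ndarray | None = None   # protected exceedance
    F1: float | None = None         # RFX model free energy
    F0: float | None = None         # null (equal frequencies) evidence
    mc_samples: int = 0
    seed: int | None = None
    mc_warning: bool = False

    @property
    def n_models(self) -> int:
        return self.alpha.size

    def summary(self) -> str:
        lines = ["Random-effects BMS",
                 f"models: {self.n_models}   "
                 f"subjects: {int(round(self.alpha.sum() - self.alpha0.sum()))}",
                 f"converged: {self.converged} ({self.n_iterations} iterations)"]
        if self.bor is not None:
            lines.append(f"Bayes omnibus risk: {self.bor:.4f}")
        header = f"{'model':>6}{'alpha':>10}{'E[r]':>8}"
        if self.xp is not None:
            header += f"{'xp':>8}"
        if self.pxp is not None:
            header += f"{'pxp':>8}"
        lines.append(header)
        for k in range(self.n_models):
            row = f"{k:>6}{self.alpha[k]:>10.3f}{self.r[k]:>8.3f}"
            if self.xp is not None:
                row += f"{self.xp[k]:>8.3f}"
            if self.pxp is not None:
                row += f"{self.pxp[k]:>8.3f}"
            lines.append(row)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {"alpha": self.alpha.tolist(), "alpha0": self.alpha0.tolist(),
             "r": self.r.tolist(), "converged": self.converged,
             "n_iterations": self.n_iterations, "mc_samples": self.mc_samples,
             "seed": self.seed, "bor": self.bor, "F1": self.F1, "F0": self.F0}
        for k in ("xp", "pxp"):
            v = getattr(self, k)
            d[k] = None if v is None else v.tolist()
        return d


def rfx_bms(evidence: EvidenceMatrix | np.ndarray,
            a0: np.ndarray | float | None = None,
            tol: float = 1e-6, max_iter: int = 200) -> BMSResult:
    """Variational Dirichlet fixed point for RFX model frequencies.

    Iterates responsibilities g_nk proportional to
    exp(F_nk + psi(alpha_k) - psi(sum alpha)) and counts
    alpha_k = a0_k + sum_n g_nk until max|d alpha| < ``tol``.
    Count conservation sum(alpha) = sum(a0) + N holds exactly.
    """
    F = evidence.F if isinstance(evidence, EvidenceMatrix) else \
        np.asarray(evidence, float)
    n, m = F.shape
    if a0 is None:
        a0 = np.ones(m)
    else:
        a0 = np.broadcast_to(np.asarray(a0, float), (m,)).copy()
    if np.any(a0 <= 0):
        raise ValueError("prior counts must be positive")

    alpha = a0 + n / m
    converged = False
    it = 0
    g = np.full((n, m), 1.0 / m)
    for it in range(1, max_iter + 1):
        logu = F + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        delta = np.max(np.abs(alpha_new - alpha))
        alpha = alpha_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"RFX BMS fixed point did not converge in {max_iter} "
                      "iterations", RuntimeWarning, stacklevel=2)
    return BMSResult(alpha=alpha, alpha0=a0, r=alpha / alpha.sum(), g=g,
                     converged=converged, n_iterations=it)


def exceedance(alpha: np.ndarray, n_samples: int = 100_000,
               seed: int | None = None) -> tuple[np.ndarray, bool]:
    """Monte-Carlo exceedance probabilities under Dirichlet(alpha).

    Returns (phi, warned); ``warned`` records that fewer than 10^4 samples
    were requested (higher Monte-Carlo error).
    """
    alpha = np.asarray(alpha, float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet counts must be positive")
    warned = n_samples < _MC_WARN_THRESHOLD
    if warned:
        warnings.warn(f"exceedance estimated from only {n_samples} samples",
                      RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    phi = np.bincount(winners, minlength=alpha.size) / n_samples
    return phi, warned


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    asum, a0sum = alpha.sum(), alpha0.sum()
    return float(
        gammaln(asum) - gammaln(a0sum)
        - np.sum(gammaln(alpha) - gammaln(alpha0))
        + np.sum((alpha - alpha0) * (digamma(alpha) - digamma(asum))))


def protected_exceedance(evidence: EvidenceMatrix | np.ndarray,
                         result: BMSResult) -> tuple[float, np.ndarray]:
    """Bayes omnibus risk and protected exceedance probabilities.

    The null model assumes equal frequencies: its evidence is
    F0 = sum_n log mean_k exp(F_nk).  The RFX alternative's variational
    free energy F1 is computed from the fitted Dirichlet posterior; then
    BOR = 1 / (1 + exp(F1 - F0)) and pxp = xp (1 - BOR) + BOR / M.
    """
    if result.xp is None:
        raise ValueError("compute exceedance probabilities first")
    F = evidence.F if isinstance(evidence, EvidenceMatrix) else \
        np.asarray(evidence, float)
    n, m = F.shape
    F0 = float(np.sum(logsumexp(F, axis=1) - np.log(m)))
    logu = F + digamma(result.alpha) - digamma(result.alpha.sum())
    g = result.g
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    F1 = float(np.sum(g * logu) + entropy
               - _dirichlet_kl(result.alpha, result.alpha0))
    bor = float(1.0 / (1.0 + np.exp(np.clip(F1 - F0, -700, 700))))
    pxp = result.xp * (1.0 - bor) + bor / m
    result.bor, result.pxp, result.F0, result.F1 = bor, pxp, F0, F1
    return bor, pxp


class RandomEffectsBMS:
    """Model object for group-level RFX BMS on an evidence matrix."""

    def __init__(self, evidence: EvidenceMatrix | np.ndarray,
                 a0: np.ndarray | float | None = None):
        self.evidence = evidence if isinstance(evidence, EvidenceMatrix) \
            else EvidenceMatrix(F=np.asarray(evidence, float))
        self.a0 = a0

    def fit(self, n_samples: int = 100_000, seed: int | None = None,
            tol: float = 1e-6, max_iter: int = 200,
            compute_pxp: bool = True) -> BMSResult:
        res = rfx_bms(self.evidence, a0=self.a0, tol=tol, max_iter=max_iter)
        res.xp, res.mc_warning = exceedance(res.alpha, n_samples, seed)
        res.mc_samples, res.seed = n_samples, seed
        if compute_pxp:
            protected_exceedance(self.evidence, res)
        return res


# ---------------------------------------------------------------------------
# Family inference
# ---------------------------------------------------------------------------

@dataclass
class FamilyResult:
    """Family-level RFX inference (prior mass equalised across families)."""

    family_ids: tuple
    partition: dict
    expected_freq: np.ndarray
    exceedance: np.ndarray
    model_result: BMSResult
    mc_samples: int
    seed: int | None

    @property
    def winning_family(self):
        return self.family_ids[int(np.argmax(self.exceedance))]

    def summary(self) -> str:
        lines = ["Family-level RFX BMS",
                 f"{'family':>8}{'size':>6}{'E[r]':>8}{'xp':>8}"]
        for i, fid in enumerate(self.family_ids):
            lines.append(f"{str(fid):>8}{len(self.partition[fid]):>6}"
                         f"{self.expected_freq[i]:>8.3f}"
                         f"{self.exceedance[i]:>8.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"family_ids": [str(f) for f in self.family_ids],
                "expected_freq": self.expected_freq.tolist(),
                "exceedance": self.exceedance.tolist(),
                "winning_family": str(self.winning_family),
                "mc_samples": self.mc_samples, "seed": self.seed}


def family_bms(evidence: EvidenceMatrix | np.ndarray, partition: dict,
               n_samples: int = 100_000, seed: int | None = None,
               tol: float = 1e-6, max_iter: int = 200) -> FamilyResult:
    """Family-level RFX BMS.

    ``partition`` maps family id -> list of model column indices (into the
    evidence matrix); it must cover all models disjointly.  Model-level
    prior counts are set to 1/|family| so every family carries equal prior
    mass; family frequencies are sums of sampled model frequencies.
    """
    ev = evidence if isinstance(evidence, EvidenceMatrix) \
        else EvidenceMatrix(F=np.asarray(evidence, float))
    m = ev.n_models
    seen: set[int] = set()
    for fid, members in partition.items():
        if len(members) == 0:
            raise ValueError(f"family {fid!r} is empty")
        if seen & set(members):
            raise ValueError("families are not disjoint")
        seen |= set(members)
    if seen != set(range(m)):
        raise ValueError("partition does not cover all models")

    a0 = np.empty(m)
    for members in partition.values():
        a0[list(members)] = 1.0 / len(members)
    res = rfx_bms(ev, a0=a0, tol=tol, max_iter=max_iter)
    res.xp, res.mc_warning = exceedance(res.alpha, n_samples, seed)
    res.mc_samples, res.seed = n_samples, seed

    family_ids = tuple(partition.keys())
    agg = np.zeros((len(family_ids), m))
    for i, fid in enumerate(family_ids):
        agg[i, list(partition[fid])] = 1.0
    expected = agg @ res.r

    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(res.alpha, size=n_samples)  # (S, m)
    fam_freq = draws @ agg.T
    winners = np.argmax(fam_freq, axis=1)
    phi = np.bincount(winners, minlength=len(family_ids)) / n_samples
    return FamilyResult(family_ids=family_ids,
                        partition={k: list(v) for k, v in partition.items()},
                        expected_freq=expected, exceedance=phi,
                        model_result=res, mc_samples=n_samples, seed=seed)


class FamilyBMS:
    """Model-object wrapper around :func:`family_bms`."""

    def __init__(self, evidence: EvidenceMatrix | np.ndarray, partition: dict):
        self.evidence = evidence
        self.partition = partition

    def fit(self, n_samples: int = 100_000, seed: int | None = None,
            **kw) -> FamilyResult:
        return family_bms(self.evidence, self.partition,
                          n_samples=n_samples, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Bayesian parameter averaging
# ---------------------------------------------------------------------------

@dataclass
class BPAResult:
    """Precision-weighted group-average posterior of one model."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    pp: np.ndarray                    # max(P(theta>0), P(theta<0))
    significant: np.ndarray
    threshold: float
    n_subjects: int

    def marginal(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.mean[i]), float(np.sqrt(self.cov[i, i]))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(self.names),
            "mean": self.mean,
            "sd": np.sqrt(np.diag(self.cov)),
            "posterior_probability": self.pp,
            "significant": self.significant,
        })

    def summary(self) -> str:
        lines = [f"Bayesian parameter averaging over {self.n_subjects} "
                 f"subjects (Pp threshold {self.threshold})",
                 f"{'parameter':<28}{'mean':>10}{'sd':>9}{'Pp':>8}  "]
        for _, row in self.frame().iterrows():
            mark = "*" if row["significant"] else " "
            lines.append(f"{row['parameter']:<28}{row['mean']:>10.4f}"
                         f"{row['sd']:>9.4f}{row['posterior_probability']:>8.4f} {mark}")
        return "\n".join(lines)


def bpa(posteriors: list[Posterior | DCMResults],
        threshold: float = 0.95) -> BPAResult:
    """Fixed-effects Bayesian parameter averaging across subjects.

    Combined precision is the sum of subject precisions; the combined mean
    is the precision-weighted average.  Per-parameter posterior
    probabilities come from the Gaussian marginals of the combined
    posterior.
    """
    if not posteriors:
        raise ValueError("no posteriors given")
    posts = [p.posterior if isinstance(p, DCMResults) else p
             for p in posteriors]
    names = posts[0].names
    for p in posts[1:]:
        if p.names != names:
            raise ValueError("posteriors do not share a parameter name map")
    Lam_sum = np.zeros((len(names), len(names)))
    eta_sum = np.zeros(len(names))
    for p in posts:
        try:
            Lam = np.linalg.inv(p.cov)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"singular posterior covariance for subject "
                f"{p.subject_id!r}") from err
        Lam_sum += Lam
        eta_sum += Lam @ p.mean
    cov = np.linalg.inv(Lam_sum)
    cov = 0.5 * (cov + cov.T)
    mean = cov @ eta_sum
    sd = np.sqrt(np.diag(cov))
    p_pos = ndtr(mean / sd)
    pp = np.maximum(p_pos, 1.0 - p_pos)
    return BPAResult(names=names, mean=mean, cov=cov, pp=pp,
                     significant=pp >= threshold, threshold=threshold,
                     n_subjects=len(posts))
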
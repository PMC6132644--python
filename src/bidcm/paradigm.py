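"""Sternberg item-recognition task design, DCM input functions and GLM regressors.

The modelled paradigm interleaves four conditions -- novel, practiced,
low-load control and rest -- each presented four times in a counterbalanced
pseudo-random order.  A trial consists of an encoding phase (a five-letter
target set shown for 3.5 s), a short jittered inter-stimulus interval, and a
retrieval phase of ten single-letter probes (1.4 s each, followed by a 0.8 s
fixation cross), i.e. a 22 s probe train.  BOLD is sampled at TR = 1.79 s.

Three representations of the same design are produced here:

* :class:`TaskDesign` -- the timed event list (serialisable as a
  BIDS-events-style TSV),
* :class:`InputSet` -- binary driving-input functions on a microtime grid
  (columns EN, EP, RN, RP: encoding/retrieval x novel/practiced), consumed
  by the neural model,
* :class:`RegressorMatrix` -- HRF-convolved GLM regressors sampled at TR
  (sticks for encoding, boxcars for retrieval), used for time-series
  adjustment and confound handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "CONDITIONS",
    "INPUT_NAMES",
    "DesignConfig",
    "Trial",
    "TaskDesign",
    "InputSet",
    "RegressorMatrix",
    "build_design",
    "design_to_inputs",
    "build_regressors",
    "canonical_hrf",
    "dct_highpass_basis",
]

#: Task conditions, in canonical order.
CONDITIONS = ("novel", "practiced", "control", "rest")

#: Driving-input columns: encoding/retrieval phases of the two memory conditions.
INPUT_NAMES = ("EN", "EP", "RN", "RP")

#: Conditions that contribute driving inputs to the DCM.
_INPUT_CONDITIONS = ("novel", "practiced")


@dataclass(frozen=True)
class DesignConfig:
    """Timing parameters of the task, in seconds unless noted.

    Defaults reproduce the study paradigm; the inter-trial interval and the
    rest padding at the end of the session are free choices (the session is
    auto-sized, a fixed length is not enforced).
    """

    tr: float = 1.79
    encoding_duration: float = 3.5
    probe_duration: float = 1.4
    fixation_duration: float = 0.8
    n_probes: int = 10
    isi_choices: tuple[float, ...] = (0.358, 0.716, 1.074, 1.432, 1.790)
    iti: float = 5.37  # inter-trial interval (3 TRs); free choice
    trials_per_condition: int = 4
    n_scans: int | None = None  # None -> auto-size to fit all trials
    rest_padding_scans: int = 4

    def __post_init__(self) -> None:
        for name in ("tr", "encoding_duration", "probe_duration",
                     "fixation_duration", "iti"):
            if getattr(self, name) < 0 or (name == "tr" and self.tr <= 0):
                raise ValueError(f"config timing {name!r} must be positive")
        if any(s <= 0 for s in self.isi_choices):
            raise ValueError("ISI choices must be positive")
        if self.n_probes < 1 or self.trials_per_condition < 1:
            raise ValueError("n_probes and trials_per_condition must be >= 1")

    @property
    def retrieval_duration(self) -> float:
        """Duration of the probe train (probes + fixations)."""
        return self.n_probes * (self.probe_duration + self.fixation_duration)


@dataclass(frozen=True)
class Trial:
    """One trial: encoding phase, ISI, then a train of retrieval probes."""

    condition: str
    encoding_onset: float
    encoding_duration: float
    isi: float
    probe_onsets: tuple[float, ...]
    probe_duration: float
    fixation_duration: float

    @property
    def retrieval_onset(self) -> float:
        return self.probe_onsets[0]

    @property
    def retrieval_end(self) -> float:
        return self.probe_onsets[-1] + self.probe_duration + self.fixation_duration

    @property
    def retrieval_duration(self) -> float:
        return self.retrieval_end - self.retrieval_onset

    @property
    def end(self) -> float:
        return self.retrieval_end


@dataclass(frozen=True)
class TaskDesign:
    """A realised task design: ordered trials plus the scan geometry."""

    trials: tuple[Trial, ...]
    tr: float
    n_scans: int
    seed: int
    config: DesignConfig = field(default_factory=DesignConfig)

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            counts[t.condition] = counts.get(t.condition, 0) + 1
        return counts

    def validate(self) -> None:
        prev_end = -np.inf
        for i, t in enumerate(self.trials):
            if t.encoding_onset < prev_end - 1e-9:
                raise ValueError(f"trial {i} overlaps the preceding trial")
            if t.encoding_onset + t.encoding_duration > t.retrieval_onset + 1e-9:
                raise ValueError(f"trial {i}: encoding overlaps retrieval")
            if t.end > self.duration + 1e-9:
                raise ValueError(
                    f"trial {i} ({t.condition}) ends at {t.end:.2f} s, after "
                    f"the last scan ({self.duration:.2f} s)")
            prev_end = t.end

    # -- BIDS-events-style serialisation ---------------------------------
    def events_frame(self) -> pd.DataFrame:
        """Events table with columns onset, duration, trial_type.

        Memory and control trials contribute ``<condition>_enc`` and
        ``<condition>_ret`` events; rest trials are a single ``rest`` event
        spanning the whole trial.
        """
        rows = []
        for t in self.trials:
            if t.condition == "rest":
                rows.append((t.encoding_onset, t.end - t.encoding_onset, "rest"))
            else:
                rows.append((t.encoding_onset, t.encoding_duration,
                             f"{t.condition}_enc"))
                rows.append((t.retrieval_onset, t.retrieval_duration,
                             f"{t.condition}_ret"))
        df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
        return df.sort_values("onset", kind="stable").reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.events_frame().to_csv(path, sep="\t", index=False)


def build_design(seed: int, config: DesignConfig | None = None,
                 **overrides) -> TaskDesign:
    """Build a pseudo-randomised, counterbalanced task design.

    Condition order is randomised within blocks of four trials such that
    every condition appears exactly once per block (counterbalancing); the
    inter-stimulus interval of each trial is drawn uniformly from the
    jitter set.  Deterministic for a fixed ``seed`` and config.

    Parameters
    ----------
    seed
        Seed for the order/jitter randomisation.
    config
        Timing parameters; keyword ``overrides`` are applied on top.
    """
    cfg = config or DesignConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(seed)

    order: list[str] = []
    for _ in range(cfg.trials_per_condition):
        order.extend(rng.permutation(CONDITIONS))

    trials: list[Trial] = []
    cursor = 0.0
    for cond in order:
        isi = float(rng.choice(cfg.isi_choices))
        enc_onset = cursor
        ret_onset = enc_onset + cfg.encoding_duration + isi
        probe_onsets = tuple(
            ret_onset + k * (cfg.probe_duration + cfg.fixation_duration)
            for k in range(cfg.n_probes))
        trials.append(Trial(
            condition=cond,
            encoding_onset=enc_onset,
            encoding_duration=cfg.encoding_duration,
            isi=isi,
            probe_onsets=probe_onsets,
            probe_duration=cfg.probe_duration,
            fixation_duration=cfg.fixation_duration,
        ))
        cursor = trials[-1].end + cfg.iti

    if cfg.n_scans is None:
        n_scans = int(np.ceil(trials[-1].end / cfg.tr)) + cfg.rest_padding_scans
    else:
        n_scans = cfg.n_scans
        session = n_scans * cfg.tr
        for i, t in enumerate(trials):
            if t.end > session + 1e-9:
                raise ValueError(
                    f"session of {n_scans} scans ({session:.2f} s) is too "
                    f"short: trial {i} ({t.condition}) ends at {t.end:.2f} s")

    design = TaskDesign(trials=tuple(trials), tr=cfg.tr, n_scans=n_scans,
                        seed=int(seed), config=cfg)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Driving inputs on the microtime grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputSet:
    """Binary driving-input functions on the microtime grid.

    ``u[b, j]`` is 1 when input ``names[j]`` is active during microtime bin
    ``b`` (bins of width ``dt``, bin midpoint convention).  EN/EP cover the
    encoding phases of novel/practiced trials; RN/RP cover the retrieval
    probe trains.  Control and rest trials drive no input, mirroring the
    four-input DCM.
    """

    u: np.ndarray
    dt: float
    tr: float
    n_scans: int
    names: tuple[str, ...] = INPUT_NAMES

    @property
    def bins_per_scan(self) -> int:
        return round(self.tr / self.dt)

    @property
    def n_bins(self) -> int:
        return self.u.shape[0]

    def on_time(self, name: str) -> float:
        """Total active time of one input column, in seconds."""
        return float(self.u[:, self.names.index(name)].sum() * self.dt)


def _phase_intervals(design: TaskDesign) -> dict[str, list[tuple[float, float]]]:
    """Event intervals [start, end) per driving input."""
    iv: dict[str, list[tuple[float, float]]] = {n: [] for n in INPUT_NAMES}
    for t in design.trials:
        if t.condition not in _INPUT_CONDITIONS:
            continue
        tag = "N" if t.condition == "novel" else "P"
        iv["E" + tag].append((t.encoding_onset,
                              t.encoding_onset + t.encoding_duration))
        iv["R" + tag].append((t.retrieval_onset, t.retrieval_end))
    return iv


def design_to_inputs(design: TaskDesign, dt: float | None = None,
                     snap: float | None = None) -> InputSet:
    """Rasterise the design's driving inputs onto a microtime grid.

    A bin is active when its midpoint falls inside an event interval, so
    each column's total on-time matches the summed event durations to
    within one ``dt``.

    Parameters
    ----------
    dt
        Microtime bin width; must divide the TR exactly.  Default TR/16.
    snap
        Optionally quantise event boundaries to multiples of ``snap``
        before rasterising; used to isolate integrator error from input
        re-quantisation when comparing runs at different ``dt``.
    """
    if dt is None:
        dt = design.tr / 16.0
    ratio = design.tr / dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(f"dt={dt} does not divide TR={design.tr}")
    n_bins = design.n_scans * round(ratio)
    mid = (np.arange(n_bins) + 0.5) * dt

    u = np.zeros((n_bins, len(INPUT_NAMES)))
    for j, name in enumerate(INPUT_NAMES):
        for start, end in _phase_intervals(design)[name]:
            if snap is not None:
                start = round(start / snap) * snap
                end = round(end / snap) * snap
            u[(mid >= start) & (mid < end), j] = 1.0
    return InputSet(u=u, dt=dt, tr=design.tr, n_scans=design.n_scans)


# ---------------------------------------------------------------------------
# HRF and GLM regressors
# ---------------------------------------------------------------------------

def canonical_hrf(t: np.ndarray, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function.

    Difference of two gamma densities (unit dispersion): a response peaking
    ~5-6 s post-stimulus minus an undershoot peaking ~15 s later, scaled by
    1/``ratio``.  Normalised to unit peak.
    """
    t = np.asarray(t, dtype=float)
    h = (_gamma_dist.pdf(t, peak_delay)
         - _gamma_dist.pdf(t, undershoot_delay) / ratio)
    h[t < 0] = 0.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def dct_highpass_basis(n_scans: int, tr: float,
                       cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis spanning periods longer than ``cutoff`` s.

    Returns the DCT components with period 2*N*TR/k > cutoff (constant
    excluded); the standard high-pass confound set.
    """
    total = n_scans * tr
    k_max = int(np.floor(2.0 * total / cutoff))
    t = np.arange(n_scans)
    cols = [np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans))
            for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


@dataclass(frozen=True)
class RegressorMatrix:
    """GLM design matrix sampled at TR: task regressors plus confounds."""

    X: np.ndarray
    names: tuple[str, ...]
    tr: float
    n_task: int

    @property
    def task(self) -> np.ndarray:
        return self.X[:, :self.n_task]

    @property
    def confounds(self) -> np.ndarray:
        return self.X[:, self.n_task:]

    @property
    def confound_names(self) -> tuple[str, ...]:
        return self.names[self.n_task:]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.names))


def build_regressors(design: TaskDesign, include_confounds: bool = True,
                     motion: np.ndarray | None = None,
                     oversample: int = 16) -> RegressorMatrix:
    """Build the first-level task regressors for the four-condition design.

    One encoding and one retrieval regressor per condition (8 task columns
    for the standard design): encoding phases enter as delta (stick)
    functions at the encoding onsets, retrieval phases as boxcars spanning
    the probe train; both are convolved with the canonical HRF on a
    microtime grid (``oversample`` bins per TR) and sampled at scan onsets.
    Confounds are the 128-s DCT high-pass basis, optional motion columns
    and a constant.
    """
    design.validate()
    dt = design.tr / oversample
    n_bins = design.n_scans * oversample
    tgrid = np.arange(n_bins) * dt
    hrf = canonical_hrf(np.arange(0, 32.0, dt))

    conditions = [c for c in CONDITIONS
                  if any(t.condition == c for t in design.trials)]
    cols, names = [], []
    for cond in conditions:
        for phase in ("enc", "ret"):
            x = np.zeros(n_bins)
            for t in design.trials:
                if t.condition != cond:
                    continue
                if phase == "enc":
                    x[min(int(round(t.encoding_onset / dt)), n_bins - 1)] = 1.0
                else:
                    mid = tgrid + 0.5 * dt
                    x[(mid >= t.retrieval_onset) & (mid < t.retrieval_end)] = 1.0
            conv = np.convolve(x, hrf)[:n_bins]
            cols.append(conv[::oversample][:design.n_scans])
            names.append(f"{cond}_{phase}")
    n_task = len(cols)

    if include_confounds:
        dct = dct_highpass_basis(design.n_scans, design.tr)
        for k in range(dct.shape[1]):
            cols.append(dct[:, k])
            names.append(f"dct_{k + 1:03d}")
        if motion is not None:
            motion = np.atleast_2d(np.asarray(motion, dtype=float))
            if motion.shape[0] != design.n_scans:
                raise ValueError("motion confounds must have n_scans rows")
            for k in range(motion.shape[1]):
                cols.append(motion[:, k])
                names.append(f"motion_{k + 1}")
    cols.append(np.ones(design.n_scans))
    names.append("constant")

    X = np.column_stack(cols) if cols else np.ones((design.n_scans, 1))
    if not np.all(np.isfinite(X)):
        raise ValueError("regressor matrix contains non-finite values")
    return RegressorMatrix(X=X, names=tuple(names), tr=design.tr, n_task=n_task)
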
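"""Synthetic data generators with known ground truth.

Two families of generators mirror the two inputs of the analysis:

* :func:`simulate_behavior` draws continuous-report working-memory trials —
  three target locations per trial sampled on an isoeccentric hemifield arc
  under minimum-gap and meridian-exclusion constraints, with each report
  drawn from the target / non-target / guess mixture at configurable
  (kappa, gamma, beta) and the true generating component stored per report.

* :func:`simulate_group_spectra` draws multi-subject, multi-condition
  source timecourses from the conductance-based network model: each
  subject's extrinsic connectivity deviates from the base parameters by
  random log-scalings, condition-specific modulations are added on masked
  edges, and observed signals are stochastic integrations of the network
  dynamics plus observation noise.

* :func:`simulate_peb_subjects` is a conjugate (linear-Gaussian) fixture
  for the hierarchical group model: first-level posteriors generated
  directly from the second-level generative equation.

All randomness flows from one root seed through named substreams, so every
generated dataset is reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .behavior import kappa_to_sigma, sigma_to_kappa, wrap_angle
from .microcircuit import Edge, MicrocircuitParams, NetworkArchitecture, NetworkModel

__all__ = [
    "substream",
    "BehaviorSimSpec",
    "simulate_behavior",
    "GroupSimSpec",
    "GroupDataset",
    "simulate_group_spectra",
    "draw_subject_parameters",
    "simulate_peb_subjects",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one root seed."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class BehaviorSimSpec:
    """Ground truth and task constraints for behavioral simulation.

    Report dispersion may be given either as the Von Mises concentration
    ``kappa`` or as the circular SD ``sigma`` (radians); exactly one must
    be set.  ``min_gap`` and ``meridian_exclusion`` are in degrees of polar
    angle on the isoeccentric (semi)circle.
    """

    n_trials: int
    kappa: float | None = None
    sigma: float | None = None
    gamma: float = 0.0
    beta: float = 0.0
    n_items: int = 3
    hemifield: str = "right"
    min_gap: float = 15.0
    meridian_exclusion: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials <= 0 or self.n_items <= 0:
            raise ValueError("n_trials and n_items must be positive")
        if (self.kappa is None) == (self.sigma is None):
            raise ValueError("specify exactly one of kappa / sigma")
        if self.kappa is not None and self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.gamma < 0 or self.beta < 0 or self.gamma + self.beta > 1:
            raise ValueError("need gamma, beta >= 0 and gamma + beta <= 1")
        if self.hemifield not in ("left", "right"):
            raise ValueError("hemifield must be 'left' or 'right'")
        usable = 180.0 - 2.0 * self.meridian_exclusion
        if self.min_gap * self.n_items >= usable:
            raise ValueError(
                f"infeasible constraints: {self.n_items} items with gap "
                f"{self.min_gap} deg exceed the {usable} deg usable arc"
            )

    @property
    def kappa_value(self) -> float:
        return self.kappa if self.kappa is not None else sigma_to_kappa(self.sigma)

    @property
    def sigma_value(self) -> float:
        return float(kappa_to_sigma(self.kappa_value))


def _sample_locations(spec: BehaviorSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Item polar angles (radians) honouring gap/meridian constraints.

    The hemifield arc excludes ``meridian_exclusion`` degrees on each side
    of the vertical meridian (+-90 deg polar angle); items are drawn by
    rejection sampling with a retry cap.
    """
    excl = np.radians(spec.meridian_exclusion)
    gap = np.radians(spec.min_gap)
    if spec.hemifield == "right":
        lo, hi = -np.pi / 2 + excl, np.pi / 2 - excl
    else:
        lo, hi = np.pi / 2 + excl, 3 * np.pi / 2 - excl
    for _ in range(10_000):
        angles = rng.uniform(lo, hi, size=spec.n_items)
        if spec.n_items == 1 or np.diff(np.sort(angles)).min() >= gap:
            return wrap_angle(angles)
    raise RuntimeError("location rejection sampling exceeded retry cap")


COMPONENTS = ("target", "guess", "nontarget")


def simulate_behavior(spec: BehaviorSimSpec) -> pd.DataFrame:
    """Simulate a table of reports with stored ground-truth components.

    One row per report (``n_items`` reports per trial).  Columns: trial,
    report_index, hemifield, target, nontarget_1..m, report,
    true_component.  With probability 1 - beta - gamma a report is the
    target plus Von Mises noise, with probability gamma a uniform guess,
    and with probability beta a uniformly chosen non-target plus Von Mises
    noise sharing the same concentration.
    """
    rng = substream(spec.seed, "behavior")
    kappa = spec.kappa_value
    m = spec.n_items - 1
    rows = []
    for trial in range(spec.n_trials):
        items = _sample_locations(spec, rng)
        for ridx in range(spec.n_items):
            target = items[ridx]
            nontargets = np.delete(items, ridx)
            u = rng.random()
            if u < spec.gamma:
                component = "guess"
                report = rng.uniform(-np.pi, np.pi)
            elif u < spec.gamma + spec.beta:
                component = "nontarget"
                centre = nontargets[rng.integers(m)] if m else target
                report = centre + rng.vonmises(0.0, kappa)
            else:
                component = "target"
                report = target + rng.vonmises(0.0, kappa)
            row = {
                "trial": trial,
                "report_index": ridx + 1,
                "hemifield": spec.hemifield,
                "target": float(target),
                "report": float(wrap_angle(report)),
                "true_component": component,
            }
            for k, nt in enumerate(nontargets, start=1):
                row[f"nontarget_{k}"] = float(nt)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group spectra


@dataclass
class GroupSimSpec:
    """Multi-subject, multi-condition generative specification.

    ``condition_effects`` maps (edge, condition label) to the ground-truth
    group-level modulation in log-scaling units; the baseline condition
    carries no modulation by convention.  ``between_subject_sd`` scales the
    random per-subject log-scaling deviations of extrinsic strengths and of
    the condition modulations.
    """

    architecture: NetworkArchitecture
    base_params: MicrocircuitParams = field(default_factory=MicrocircuitParams)
    n_subjects: int = 5
    conditions: tuple[str, ...] = ("baseline", "early_delay")
    condition_effects: dict[tuple[Edge, str], float] = field(default_factory=dict)
    between_subject_sd: float = 0.0
    epoch_length_s: float = 0.8
    n_epochs: int = 64
    sampling_rate_hz: float = 1000.0
    max_analysis_hz: float = 100.0
    seed: int = 0
    max_resample_attempts: int = 5

    def __post_init__(self):
        if self.sampling_rate_hz <= 2 * self.max_analysis_hz:
            raise ValueError("sampling rate must exceed twice the analysis band")
        for (edge, cond), _ in self.condition_effects.items():
            if edge not in self.architecture.b_mask:
                raise ValueError(f"condition effect on non-modulable edge {edge}")
            if cond not in self.conditions:
                raise ValueError(f"condition effect for unknown condition {cond!r}")


@dataclass
class GroupDataset:
    """Per-subject, per-condition epoched timecourses plus ground truth."""

    epochs: dict[tuple[int, str], np.ndarray]  # (n_epochs, n_nodes, n_samples)
    fs: float
    nodes: tuple[str, ...]
    truth: dict

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["fs"] = self.fs
            fh.attrs["nodes"] = ",".join(self.nodes)
            fh.attrs["seed"] = self.truth.get("seed", -1)
            for (subj, cond), arr in sorted(self.epochs.items()):
                grp = fh.require_group(f"subject_{subj:03d}/{cond}")
                grp.create_dataset("epochs", data=arr, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "GroupDataset":
        epochs = {}
        with h5py.File(path, "r") as fh:
            fs = float(fh.attrs["fs"])
            nodes = tuple(fh.attrs["nodes"].split(","))
            for sname, sgrp in fh.items():
                subj = int(sname.split("_")[1])
                for cond, cgrp in sgrp.items():
                    epochs[(subj, cond)] = cgrp["epochs"][()]
        return cls(epochs, fs, nodes, {})


def _subject_model(
    spec: GroupSimSpec, cond: str, a_log: dict, b_dev: dict
) -> NetworkModel:
    b = {}
    if cond != "baseline":
        for edge in spec.architecture.b_mask:
            val = spec.condition_effects.get((edge, cond), 0.0) + b_dev.get(
                (edge, cond), 0.0
            )
            if val:
                b[edge] = val
    return NetworkModel(spec.architecture, spec.base_params, a_log=a_log, b=b)


def draw_subject_parameters(
    spec: GroupSimSpec, subject: int
) -> tuple[dict, dict, dict[str, NetworkModel]]:
    """One subject's log-scaling draws and stable per-condition models.

    Resamples unstable draws (with a warning) up to
    ``max_resample_attempts`` times before raising.  Returns
    (a_log, b_deviations, condition -> NetworkModel).
    """
    subj_rng = substream(spec.seed, f"subject_{subject}")
    edges = spec.architecture.edges
    for attempt in range(spec.max_resample_attempts):
        a_log = {
            e: float(spec.between_subject_sd * subj_rng.standard_normal())
            for e in edges
        }
        b_dev = {
            (e, c): float(spec.between_subject_sd * subj_rng.standard_normal())
            for e in spec.architecture.b_mask
            for c in spec.conditions
            if c != "baseline"
        }
        models = {c: _subject_model(spec, c, a_log, b_dev) for c in spec.conditions}
        if all(m.stability()[0] for m in models.values()):
            return a_log, b_dev, models
        warnings.warn(
            f"unstable draw for subject {subject} (attempt {attempt + 1}); "
            "resampling"
        )
    raise RuntimeError(
        f"no stable parameter draw for subject {subject} after "
        f"{spec.max_resample_attempts} attempts"
    )


def simulate_group_spectra(spec: GroupSimSpec) -> GroupDataset:
    """Generate epoched source timecourses for every subject and condition.

    Each subject's extrinsic log-scalings are drawn from
    N(0, between_subject_sd^2); condition modulations add the ground-truth
    group effect plus a subject-level deviation of the same scale on masked
    edges.  Unstable parameter draws are resampled (with a warning) up to
    ``max_resample_attempts`` times.  Epochs are cut from one continuous
    integration per (subject, condition).
    """
    base_model = NetworkModel(spec.architecture, spec.base_params)
    ok, absc = base_model.stability()
    if not ok:
        raise RuntimeError(
            f"base parameters are unstable (spectral abscissa {absc:.3g})"
        )
    n_samp = int(round(spec.epoch_length_s * spec.sampling_rate_hz))
    duration = spec.n_epochs * spec.epoch_length_s

    epochs: dict[tuple[int, str], np.ndarray] = {}
    truth: dict = {
        "seed": spec.seed,
        "subjects": {},
        "condition_effects": {
            (str(e), c): v for (e, c), v in spec.condition_effects.items()
        },
    }
    for subj in range(spec.n_subjects):
        a_log, b_dev, models = draw_subject_parameters(spec, subj)
        truth["subjects"][subj] = {
            "a_log": {str(e): v for e, v in a_log.items()},
            "b_dev": {(str(e), c): v for (e, c), v in b_dev.items()},
        }
        for cond in spec.conditions:
            noise_rng = substream(spec.seed, f"noise_{subj}_{cond}")
            y = models[cond].simulate_timecourses(
                duration, fs=spec.sampling_rate_hz, seed=noise_rng
            )
            y = y[:, : spec.n_epochs * n_samp]
            epochs[(subj, cond)] = (
                y.reshape(len(spec.architecture.nodes), spec.n_epochs, n_samp)
                .transpose(1, 0, 2)
                .copy()
            )
    return GroupDataset(epochs, spec.sampling_rate_hz, spec.architecture.nodes, truth)


# ---------------------------------------------------------------------------
# conjugate hierarchical fixture


def simulate_peb_subjects(
    n_subjects: int,
    n_params: int,
    effect: np.ndarray | dict[int, float] | None = None,
    common: np.ndarray | None = None,
    between_sd: float = 0.2,
    first_level_sd: float = 0.1,
    covariate: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Linear-Gaussian first-level posteriors from a known group model.

    True subject parameters follow theta_i = common + x_i * effect +
    N(0, between_sd^2 I); reported first-level posterior means add
    N(0, first_level_sd^2 I) estimation noise with matching diagonal
    posterior covariance.  ``covariate`` defaults to a mean-centred +-0.5
    group split.  Returns (means, covariances, design matrix, truth).
    """
    rng = substream(seed, "peb_subjects")
    if covariate is None:
        covariate = np.where(np.arange(n_subjects) % 2 == 0, 0.5, -0.5).astype(float)
    covariate = np.asarray(covariate, dtype=float)
    eff = np.zeros(n_params)
    if isinstance(effect, dict):
        for k, v in effect.items():
            eff[k] = v
    elif effect is not None:
        eff = np.asarray(effect, dtype=float)
    com = np.zeros(n_params) if common is None else np.asarray(common, dtype=float)

    theta = (
        com[None, :]
        + covariate[:, None] * eff[None, :]
        + between_sd * rng.standard_normal((n_subjects, n_params))
    )
    means = theta + first_level_sd * rng.standard_normal((n_subjects, n_params))
    covs = np.broadcast_to(
        first_level_sd**2 * np.eye(n_params), (n_subjects, n_params, n_params)
    ).copy()
    design = np.column_stack([np.ones(n_subjects), covariate])
    truth = {"effect": eff, "common": com, "theta": theta, "covariate": covariate}
    return means, covs, design, truth
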
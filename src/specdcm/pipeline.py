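"""Configuration-driven orchestration of the full synthetic analysis.

One run = one immutable output directory.  Stages: simulate behavioral
trials -> fit/classify the mixture -> simulate group source timecourses ->
estimate cross-spectral densities -> invert the network model per subject
and delay condition -> hierarchical (PEB) contrast across conditions ->
effect report.  Every artifact is stamped into a manifest with a
content hash, the root seed and the configuration hash, so a rerun with an
identical configuration reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from .inversion import PriorSpec, SpectralDCM
from .microcircuit import (
    Edge,
    MicrocircuitParams,
    NetworkArchitecture,
    build_chain_network,
    build_default_network,
    build_sfg_top_network,
    load_architecture,
)
from .peb import PEB, contrast_report, loo_cv
from .simulate import BehaviorSimSpec, GroupSimSpec, simulate_behavior, simulate_group_spectra
from .spectra import CrossSpectrum, FrequencyGrid, estimate_csd

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

ARCHITECTURES = {
    "default": build_default_network,
    "sfg_top": build_sfg_top_network,
    "chain3": lambda: build_chain_network(3),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML/JSON serializable)."""

    seed: int = 0
    out_dir: str = "runs/run"
    # behavior stage
    n_trials: int = 400
    kappa: float = 8.0
    gamma: float = 0.10
    beta: float = 0.15
    target_threshold: float = 0.9
    nontarget_threshold: float = 0.7
    # group simulation stage
    architecture: str = "chain3"
    n_subjects: int = 5
    delay_conditions: tuple[str, ...] = ("delay_typeA", "delay_typeB")
    condition_effects: dict[str, float] = field(default_factory=dict)
    between_subject_sd: float = 0.1
    n_epochs: int = 48
    epoch_length_s: float = 0.8
    sampling_rate_hz: float = 1000.0
    # spectra stage
    f_min: float = 2.0
    f_max: float = 100.0
    f_step: float = 1.0
    half_bandwidth_hz: float = 2.0
    # inversion stage
    inversion_max_iter: int = 32
    # peb stage
    pp_threshold: float = 0.95
    loo_alpha: float = 0.05
    # stage toggles
    run_behavior: bool = True
    run_spectra: bool = True

    def __post_init__(self):
        for name in ("target_threshold", "nontarget_threshold", "pp_threshold", "loo_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.architecture not in ARCHITECTURES and not Path(self.architecture).exists():
            raise ValueError(
                f"unknown architecture {self.architecture!r} (presets: "
                f"{sorted(ARCHITECTURES)}) and no such file"
            )
        self.delay_conditions = tuple(self.delay_conditions)

    def build_architecture(self) -> NetworkArchitecture:
        if self.architecture in ARCHITECTURES:
            return ARCHITECTURES[self.architecture]()
        return load_architecture(self.architecture)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _parse_effects(
    cfg: PipelineConfig, arch: NetworkArchitecture
) -> dict[tuple[Edge, str], float]:
    """Keys look like 'n1->n2:feedforward@delay_typeA'."""
    effects = {}
    by_key = {f"{e.source}->{e.target}:{e.kind}": e for e in arch.edges}
    for key, val in cfg.condition_effects.items():
        edge_key, _, cond = key.partition("@")
        if edge_key not in by_key:
            raise ValueError(f"unknown edge in condition effect: {edge_key!r}")
        if cond not in cfg.delay_conditions:
            raise ValueError(f"unknown condition in effect key: {cond!r}")
        effects[(by_key[edge_key], cond)] = float(val)
    return effects


def _hash_array(h: "hashlib._Hash", arr: np.ndarray) -> None:
    h.update(np.ascontiguousarray(arr).tobytes())


def _artifact_hash(path: Path) -> str:
    """Content hash; HDF5 files are hashed by walking datasets in order."""
    h = hashlib.sha256()
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:

            def visit(name, obj):
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    _hash_array(h, obj[()])

            for k in sorted(fh.attrs):
                h.update(str(fh.attrs[k]).encode())
            fh.visititems(visit)
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _write_csd_h5(path: Path, csds: dict[tuple[int, str], CrossSpectrum]) -> None:
    with h5py.File(path, "w") as fh:
        for (subj, cond), cs in sorted(csds.items()):
            grp = fh.require_group(f"subject_{subj:03d}/{cond}")
            grp.create_dataset("values", data=cs.values, track_times=False)
            grp.create_dataset("frequencies", data=cs.frequencies, track_times=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; returns a summary with artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": {},
        "stages": [],
    }
    t_start = time.time()
    result: dict = {"out_dir": str(out)}

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest["stages"].append(
            {"stage": stage, "elapsed_s": round(time.time() - t0, 3)}
        )
        for p in paths:
            manifest["artifacts"][p.name] = _artifact_hash(p)

    try:
        if cfg.run_behavior:
            t0 = time.time()
            spec = BehaviorSimSpec(
                n_trials=cfg.n_trials,
                kappa=cfg.kappa,
                gamma=cfg.gamma,
                beta=cfg.beta,
                seed=cfg.seed,
            )
            reports = simulate_behavior(spec)
            reports_path = out / "reports.csv"
            reports.to_csv(reports_path, index=False)

            fit = bhv.fit_mixture(reports, random_state=cfg.seed)
            params = pd.DataFrame(
                [
                    {
                        "kappa": fit.kappa_,
                        "sigma": fit.sigma_,
                        "gamma": fit.gamma_,
                        "beta": fit.beta_,
                        "log_likelihood": fit.log_likelihood_,
                        "n_restarts": fit.n_restarts,
                    }
                ]
            )
            params_path = out / "mixture_params.csv"
            params.to_csv(params_path, index=False)
            resp = bhv.responsibilities(reports, fit)
            labels = bhv.classify_trials(
                resp, cfg.target_threshold, cfg.nontarget_threshold
            )
            labels_path = out / "labels.csv"
            labels.to_csv(labels_path, index=False)
            summary = bhv.behavior_summary(reports, labels)
            summary_path = out / "behavior_summary.csv"
            summary.to_csv(summary_path, index=False)
            record(
                "behavior", [reports_path, params_path, labels_path, summary_path], t0
            )
            result["behavior_summary"] = summary

        if cfg.run_spectra:
            arch = cfg.build_architecture()
            grid = FrequencyGrid(cfg.f_min, cfg.f_max, cfg.f_step)

            t0 = time.time()
            gspec = GroupSimSpec(
                architecture=arch,
                n_subjects=cfg.n_subjects,
                conditions=("baseline",) + cfg.delay_conditions,
                condition_effects=_parse_effects(cfg, arch),
                between_subject_sd=cfg.between_subject_sd,
                n_epochs=cfg.n_epochs,
                epoch_length_s=cfg.epoch_length_s,
                sampling_rate_hz=cfg.sampling_rate_hz,
                seed=cfg.seed,
            )
            group = simulate_group_spectra(gspec)
            group_path = out / "group_timecourses.h5"
            group.to_hdf5(group_path)
            record("simulate_spectra", [group_path], t0)

            t0 = time.time()
            csds = {
                key: estimate_csd(
                    ep, group.fs, grid, half_bandwidth_hz=cfg.half_bandwidth_hz
                )
                for key, ep in group.epochs.items()
            }
            csd_path = out / "csd.h5"
            _write_csd_h5(csd_path, csds)
            record("estimate_csd", [csd_path], t0)

            t0 = time.time()
            rows, row_means, row_covs = [], [], []
            b_names = None
            for subj in range(cfg.n_subjects):
                for cond in cfg.delay_conditions:
                    dcm = SpectralDCM(
                        arch, max_iter=cfg.inversion_max_iter
                    ).fit(csds[(subj, "baseline")], csds[(subj, cond)])
                    b_idx = [
                        i for i, n in enumerate(dcm.names_) if n.startswith("b:")
                    ]
                    if b_names is None:
                        b_names = tuple(dcm.names_[i] for i in b_idx)
                    row_means.append(dcm.mu_[b_idx])
                    row_covs.append(dcm.Sigma_[np.ix_(b_idx, b_idx)])
                    rows.append(
                        {
                            "subject": subj,
                            "condition": cond,
                            "free_energy": dcm.free_energy_,
                            "r_modulus": dcm.r_modulus_,
                            "r_squared": dcm.r_squared_,
                            "converged": dcm.converged_,
                        }
                    )
            inv_path = out / "inversions.csv"
            pd.DataFrame(rows).to_csv(inv_path, index=False)
            post_path = out / "posteriors.h5"
            with h5py.File(post_path, "w") as fh:
                fh.create_dataset(
                    "means", data=np.asarray(row_means), track_times=False
                )
                fh.create_dataset(
                    "covs", data=np.asarray(row_covs), track_times=False
                )
                fh.attrs["b_names"] = ",".join(b_names)
            record("invert", [inv_path, post_path], t0)

            t0 = time.time()
            contrast = np.array(
                [
                    0.5 if cond == cfg.delay_conditions[0] else -0.5
                    for _ in range(cfg.n_subjects)
                    for cond in cfg.delay_conditions
                ]
            )
            design = np.column_stack([np.ones(contrast.size), contrast])
            means = np.asarray(row_means)
            covs = np.asarray(row_covs)
            peb = PEB(param_names=b_names).fit(means, covs, design)
            loo = (
                loo_cv(means, covs, design)
                if means.shape[0] >= 5
                else None
            )
            label = f"{cfg.delay_conditions[0]} vs {cfg.delay_conditions[1]}" if len(
                cfg.delay_conditions
            ) > 1 else cfg.delay_conditions[0]
            report = contrast_report(
                peb,
                loo,
                threshold_pp=cfg.pp_threshold,
                loo_alpha=cfg.loo_alpha,
                contrast_label=label,
            )
            report_path = out / "effect_report.csv"
            report.to_csv(report_path, index=False)
            record("peb", [report_path], t0)
            result["effect_report"] = report
            result["loo"] = loo

        manifest["elapsed_s"] = round(time.time() - t_start, 3)
        status = {"status": "ok"}
    except Exception as exc:  # machine-readable error record, then re-raise
        status = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
        (out / "error.json").write_text(json.dumps(status, indent=1))
        raise
    finally:
        manifest["status"] = status
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)

    result["manifest"] = manifest
    return result
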
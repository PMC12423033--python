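"""End-to-end runs: ingest -> decompose -> band profile -> FC -> reproducibility.

A `PipelineConfig` captures everything needed to reproduce a run (inputs
or simulation settings, solver and statistics parameters, seed); the run
directory it produces contains per-participant mode-set directories,
a band-profile table, per-mode FC matrices with significance masks, a
reproducibility table, and a JSON manifest with a config hash so a rerun
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import (
    BandDefinitions,
    band_profiles,
    default_band_definitions,
    select_neurophysiological,
)
from .connectivity import composite_matrix, mode_fc_analysis, order_by_module
from .datatypes import MultivariateSignal, MVMDParams, ValidationError
from .io import read_timeseries, save_modeset
from .mvmd import mvmd_decompose
from .reproducibility import pairwise_similarity
from .synthetic import default_cohort_spec, generate_cohort

log = logging.getLogger("modeconn")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Flat, serialisable description of one pipeline run."""

    # inputs: either delimited-text paths or a built-in simulated cohort
    input_paths: list[str] = field(default_factory=list)
    modules_path: str = ""  # optional (roi_label, module) table for ordering
    simulate: bool = False
    sim_participants: int = 4
    sim_rois: int = 12
    sim_samples: int = 600
    dt: float = 0.72
    # solver
    K: int = 10
    alpha: float = 1000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500
    init: str = "log"
    boundary: str = "mirror"
    pin_first_mode_dc: bool = False
    # statistics
    n_perm: int = 200
    q: float = 0.001
    n_stat_perm: int = 2000
    # misc
    seed: int = 0
    out_dir: str = "modeconn_run"
    log_level: str = "INFO"

    def mvmd_params(self) -> MVMDParams:
        return MVMDParams(
            K=self.K, alpha=self.alpha, tau=self.tau, tol=self.tol,
            max_iter=self.max_iter, init=self.init, seed=self.seed,
            pin_first_mode_dc=self.pin_first_mode_dc, boundary=self.boundary,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if not self.simulate:
            if not self.input_paths:
                raise ValidationError("no input_paths and simulate=False")
            missing = [p for p in self.input_paths if not Path(p).exists()]
            if missing:
                raise ValidationError(f"input paths do not exist: {missing}")
        if self.modules_path and not Path(self.modules_path).exists():
            raise ValidationError(f"modules_path not found: {self.modules_path}")
        if not (0 < self.q < 1):
            raise ValidationError("q must lie in (0, 1)")


def _write_matrix(path: Path, matrix: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure raises :class:`PipelineError` naming the stage,
    and the manifest marks the run incomplete.
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages_completed": [],
        "complete": False,
    }

    def checkpoint(stage: str) -> None:
        manifest["stages_completed"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        stage = "ingest"
        signals = _load_inputs(config)
        checkpoint(stage)

        stage = "decompose"
        params = config.mvmd_params()
        mode_sets = []
        for sig in signals:
            ms = mvmd_decompose(sig, params)
            save_modeset(ms, out / "modesets" / (sig.participant_id or "p"))
            mode_sets.append(ms)
            log.info("decomposed %s: omega=%s Hz", sig.participant_id,
                     np.round(ms.omega, 4))
        checkpoint(stage)

        stage = "profile"
        defs = default_band_definitions(0.5 / config.dt)
        _write_profiles(mode_sets, defs, out / "band_profiles.tsv")
        checkpoint(stage)

        stage = "fc"
        selected = select_neurophysiological(mode_sets[0], defs)
        if not selected:
            selected = list(range(mode_sets[0].K))
        results = mode_fc_analysis(
            mode_sets, selected, n_perm=config.n_perm, q=config.q,
            n_stat_perm=config.n_stat_perm, seed=config.seed,
        )
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        labels = mode_sets[0].channel_labels
        ordering = None
        if config.modules_path:
            from .io import read_modules

            ordering = read_modules(config.modules_path, roi_labels=labels)
            labels = ordering.ordered_labels

        def arranged(m: np.ndarray) -> np.ndarray:
            return order_by_module(m, ordering) if ordering else m

        for res in results:
            k = res.mode_index
            _write_matrix(fc_dir / f"mode_{k}_mean_z.tsv",
                          arranged(res.group_mean_z), labels)
            _write_matrix(fc_dir / f"mode_{k}_significant.tsv",
                          arranged(res.significant).astype(int), labels)
            _write_matrix(
                fc_dir / f"mode_{k}_composite.tsv",
                composite_matrix(arranged(res.group_mean_z),
                                 arranged(res.significant)), labels,
            )
        checkpoint(stage)

        stage = "reproducibility"
        rows = []
        for res in results:
            rep = pairwise_similarity(res.per_participant_z, res.mode_index)
            rows.append({
                "mode": res.mode_index, "n_pairs": rep.n_pairs,
                "median": rep.median, "q1": rep.q1, "q3": rep.q3,
                "mean": rep.mean,
            })
        pd.DataFrame(rows).to_csv(out / "reproducibility.tsv", sep="\t",
                                  index=False, float_format="%.17g")
        checkpoint(stage)
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _load_inputs(config: PipelineConfig) -> list[MultivariateSignal]:
    if config.simulate:
        spec = default_cohort_spec(
            n_participants=config.sim_participants, n_rois=config.sim_rois,
            T=config.sim_samples, dt=config.dt, seed=config.seed,
        )
        signals, _ = generate_cohort(spec)
        return signals
    return [read_timeseries(p, config.dt) for p in config.input_paths]


def _write_profiles(mode_sets, defs: BandDefinitions, path: Path) -> None:
    """Cohort band-profile table: per-mode mean central frequency and
    mean +/- sd bandwidth, mean relative energy, band label."""
    per_mode: dict[int, dict[str, list[float]]] = {}
    for ms in mode_sets:
        for prof in band_profiles(ms, defs):
            d = per_mode.setdefault(
                prof.mode_index, {"f": [], "bw": [], "e": [], "band": []}
            )
            d["f"].append(prof.central_freq_hz)
            d["bw"].append(prof.bandwidth_hz)
            d["e"].append(prof.rel_energy)
            d["band"].append(prof.band)
    rows = []
    for k in sorted(per_mode):
        d = per_mode[k]
        rows.append({
            "mode": k,
            "mean_central_freq_hz": np.mean(d["f"]),
            "sd_central_freq_hz": np.std(d["f"]),
            "mean_bandwidth_hz": np.mean(d["bw"]),
            "sd_bandwidth_hz": np.std(d["bw"]),
            "mean_rel_energy": np.mean(d["e"]),
            "band": max(set(d["band"]), key=d["band"].count),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


def _versions() -> dict:
    import scipy
    return {
        "modeconn": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
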
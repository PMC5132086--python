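"""End-to-end synthetic-mode pipeline: simulate -> fit maps -> synthesize ->
evaluate.

Each stage is a plain function operating on a :class:`RunConfig` and the
files under its output directory, so the CLI subcommands and
:func:`run_pipeline` compose identically.  Every random draw is governed by
the seeds in the config; rerunning with the same config reproduces the
report bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .flash import SpoilingCorrection, default_protocol
from .mapfit import fit_maps
from .phantom import (CorruptionPlan, PhantomSpec, build_phantom,
                      corrupt_session, simulate_mpm_session)
from .relaxometry import (RelaxometryCoefficients, fit_model, plan_correction,
                          residual_map, synthesize_mt, synthesize_r1)
from .volumes import QuantitativeMap

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunConfig", "run_pipeline",
           "stage_evaluate", "stage_fitmaps", "stage_simulate",
           "stage_synthesize"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one synthetic-mode pipeline run (YAML-serializable)."""

    out_dir: str = "synthmpm_run"
    grid_shape: tuple = (32, 32, 32)
    noise_sigma: float = 1.0
    residual_sigma: float = 0.01
    phantom_seed: int = 0
    session_seed: int = 1
    noise_model: str = "rician"
    b1_field: dict = field(default_factory=lambda: {"center": 1.0, "radial": 0.0})
    beta: tuple = (0.32, 0.22, 0.009)
    corrupted: tuple = ()
    severity: float = 1.0
    corruption_seed: int = 2
    phase_axis: int = 1
    coefficient_source: str = "fit"      # "fit" | "values"
    coefficient_values: tuple = None
    mtsat_b1_correction_c: float = 0.0
    spoiling_correction: str = "identity"  # "identity" | path to JSON

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.beta = tuple(float(b) for b in self.beta)
        self.corrupted = tuple(self.corrupted)
        if self.coefficient_source not in ("fit", "values"):
            raise ValueError("coefficient_source must be 'fit' or 'values'")
        if self.coefficient_source == "values" and self.coefficient_values is None:
            raise ValueError("coefficient_source 'values' requires coefficient_values")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @property
    def out(self) -> Path:
        return Path(self.out_dir)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(grid_shape=self.grid_shape,
                           noise_sigma=self.noise_sigma,
                           residual_sigma=self.residual_sigma,
                           b1_field_params=dict(self.b1_field),
                           beta=self.beta, seed=self.phantom_seed)

    def corruption_plan(self) -> CorruptionPlan:
        return CorruptionPlan(target_contrast=self.corrupted,
                              severity=self.severity,
                              phase_axis=self.phase_axis,
                              seed=self.corruption_seed)

    def spoiling(self) -> SpoilingCorrection:
        if self.spoiling_correction == "identity":
            return SpoilingCorrection.identity()
        return SpoilingCorrection.from_json(self.spoiling_correction)


def _stage(name):
    def deco(fn):
        def wrapped(cfg, *a, **k):
            try:
                return fn(cfg, *a, **k)
            except Exception as exc:  # re-tag with the stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return deco


def _truth_dir(cfg):
    return cfg.out / "truth"


def _vol_dir(cfg, clean=False):
    return cfg.out / ("volumes_clean" if clean else "volumes")


def _map_dir(cfg, clean=False):
    return cfg.out / ("maps_clean" if clean else "maps")


_CONTRAST_FILES = {"PD": "pdw.nii", "T1": "t1w.nii", "MT": "mtw.nii"}


def _save_session(session, directory, truth):
    directory.mkdir(parents=True, exist_ok=True)
    vx = truth.spec.voxel_size_mm
    for contrast, fname in _CONTRAST_FILES.items():
        mio.save_weighted_volume(session.volume(contrast), directory / fname, vx)
    np.save(directory / "se.npy", np.stack(session.se_images))
    np.save(directory / "ste.npy", np.stack(session.ste_images))
    (directory / "b1_nominal_rad.json").write_text(
        json.dumps(list(session.b1_nominal_rad)))


def _load_session(cfg, clean=False):
    from .phantom import MPMSession
    directory = _vol_dir(cfg, clean)
    vols = {c: mio.read_weighted_volume(directory / f)
            for c, f in _CONTRAST_FILES.items()}
    se = list(np.load(directory / "se.npy"))
    ste = list(np.load(directory / "ste.npy"))
    nominal = tuple(json.loads((directory / "b1_nominal_rad.json").read_text()))
    return MPMSession(pd_w=vols["PD"], t1_w=vols["T1"], mt_w=vols["MT"],
                      se_images=se, ste_images=ste, b1_nominal_rad=nominal,
                      protocol=default_protocol())


@_stage("simulate")
def stage_simulate(cfg: RunConfig):
    """Build the phantom, simulate the session, apply any corruption plan.

    Writes ground truth under ``truth/``, the (possibly corrupted) session
    under ``volumes/`` and, when corruption is active, the clean session
    under ``volumes_clean/`` for evaluation.
    """
    truth = build_phantom(cfg.phantom_spec())
    session = simulate_mpm_session(truth, default_protocol(),
                                   noise_sigma=cfg.noise_sigma,
                                   seed=cfg.session_seed,
                                   noise_model=cfg.noise_model)
    tdir = _truth_dir(cfg)
    tdir.mkdir(parents=True, exist_ok=True)
    vx = truth.spec.voxel_size_mm
    for kind, values in (("R1", truth.r1), ("R2star", truth.r2star),
                         ("MTsat", truth.mtsat), ("PDstar", truth.pd),
                         ("efficiency", truth.b1)):
        mio.save_map(QuantitativeMap(values, kind=kind, provenance="ground_truth"),
                     tdir / f"{kind}.nii", vx)
    np.save(tdir / "labels.npy", truth.labels)

    if cfg.corrupted:
        _save_session(session, _vol_dir(cfg, clean=True), truth)
        session = corrupt_session(session, cfg.corruption_plan())
    _save_session(session, _vol_dir(cfg), truth)
    return truth, session


@_stage("fitmaps")
def stage_fitmaps(cfg: RunConfig):
    """Fit R2*, B1, R1, PD* and MTsat from the volumes on disk."""
    for clean in ([False, True] if cfg.corrupted else [False]):
        session = _load_session(cfg, clean)
        maps = fit_maps(session, spoiling=cfg.spoiling(),
                        b1_correction_c=cfg.mtsat_b1_correction_c)
        mdir = _map_dir(cfg, clean)
        mdir.mkdir(parents=True, exist_ok=True)
        for key in ("r2star", "r1", "pdstar", "mtsat"):
            mio.save_map(maps[key], mdir / f"{key}.nii")
        mio.save_map(maps["b1"].as_map(), mdir / "b1.nii")
    return maps


def _load_fitted(cfg, clean=False):
    mdir = _map_dir(cfg, clean)
    return {key: mio.load_map(mdir / f"{key}.nii")
            for key in ("r2star", "r1", "pdstar", "mtsat")}


def _tissue_mask(cfg):
    return np.load(_truth_dir(cfg) / "labels.npy") > 0


def _coefficients(cfg, maps, mask) -> RelaxometryCoefficients:
    if cfg.coefficient_source == "values":
        b0, b1, b2 = cfg.coefficient_values
        return RelaxometryCoefficients(beta0=float(b0), beta1=float(b1),
                                       beta2=float(b2),
                                       provenance="user_supplied")
    return fit_model(maps["r1"], maps["mtsat"], maps["r2star"], mask)


@_stage("synthesize")
def stage_synthesize(cfg: RunConfig):
    """Decide the scenario, obtain coefficients, synthesize and write maps."""
    decision = plan_correction(cfg.corrupted)
    maps = _load_fitted(cfg)
    mask = _tissue_mask(cfg)
    coeffs = _coefficients(cfg, maps, mask)
    coeffs.to_json(cfg.out / "coefficients.json")

    mdir = _map_dir(cfg)
    synths = {}
    if decision.action in ("synthesize_MT", "none", "limited_correction"):
        synths["mtsat_synthetic"] = synthesize_mt(maps["r1"], maps["r2star"], coeffs)
    if decision.action in ("synthesize_R1", "none", "limited_correction"):
        synths["r1_synthetic"] = synthesize_r1(maps["mtsat"], maps["r2star"], coeffs)
    for name, qmap in synths.items():
        mio.save_map(qmap, mdir / f"{name}.nii")
    eps = residual_map(maps["r1"], maps["mtsat"], maps["r2star"], coeffs)
    mio.save_map(eps, mdir / "residual.nii")
    (cfg.out / "decision.json").write_text(json.dumps(
        {"corrupted": list(decision.corrupted), "action": decision.action,
         "rationale": decision.rationale}, indent=2))
    return decision, coeffs, synths


def _rmse(values, reference, mask):
    d = (values - reference)[mask]
    d = d[np.isfinite(d)]
    return float(np.sqrt(np.mean(d ** 2)))


@_stage("evaluate")
def stage_evaluate(cfg: RunConfig) -> dict:
    """Compare measured and synthetic maps with ground truth; write report."""
    decision = json.loads((cfg.out / "decision.json").read_text())
    coeffs = RelaxometryCoefficients.from_json(cfg.out / "coefficients.json")
    maps = _load_fitted(cfg)
    mask = _tissue_mask(cfg)
    truth = {kind: np.asarray(
        mio.load_map(_truth_dir(cfg) / f"{kind}.nii").values)
        for kind in ("R1", "R2star", "MTsat", "PDstar")}

    report = {"decision": decision,
              "coefficients": {"beta0": coeffs.beta0, "beta1": coeffs.beta1,
                               "beta2": coeffs.beta2,
                               "provenance": coeffs.provenance},
              "n_tissue_voxels": int(mask.sum()),
              "rmse": {}}
    for key, kind in (("r1", "R1"), ("r2star", "R2star"), ("mtsat", "MTsat"),
                      ("pdstar", "PDstar")):
        report["rmse"][f"{key}_measured"] = _rmse(maps[key].values, truth[kind], mask)

    mdir = _map_dir(cfg)
    for name, kind in (("mtsat_synthetic", "MTsat"), ("r1_synthetic", "R1")):
        path = mdir / f"{name}.nii"
        if path.exists():
            synth = mio.load_map(path)
            report["rmse"][name] = _rmse(synth.values, truth[kind], mask)

    eps = mio.load_map(mdir / "residual.nii")
    finite = mask & np.isfinite(eps.values)
    report["residual_std"] = float(eps.values[finite].std())

    if cfg.corrupted:
        clean = _load_fitted(cfg, clean=True)
        for key, kind in (("r1", "R1"), ("mtsat", "MTsat")):
            report["rmse"][f"{key}_measured_clean"] = _rmse(
                clean[key].values, truth[kind], mask)
        # artefact magnitude in map space: |corrupted - clean| of the map the
        # corrupted contrast feeds; correlate with |model residual|
        target = "mtsat" if "MT" in cfg.corrupted else "r1"
        art = np.abs(maps[target].values - clean[target].values)
        ok = finite & np.isfinite(art)
        if ok.sum() > 2:
            report["residual_artefact_correlation"] = float(
                np.corrcoef(np.abs(eps.values[ok]), art[ok])[0, 1])

    (cfg.out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> fitmaps -> synthesize -> evaluate; return report."""
    config.out.mkdir(parents=True, exist_ok=True)
    stage_simulate(config)
    stage_fitmaps(config)
    stage_synthesize(config)
    return stage_evaluate(config)
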
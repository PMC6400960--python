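"""Dataset container, run configuration, seed fan-out and the pipeline.

One HDF5 file holds everything a run produces — ground-truth scenes,
simulated measurements and reconstructions — so inputs and outputs stay
atomically paired:

::

    /scenes/<id>/intensity, lifetime, mask      (+ attrs: level)
    /measurements/<id>/data                     (+ attrs: axis, bank, noisy)
    /recons/<method>/<id>/intensity, lifetime
    attrs: schema, config_hash, seed

The global seed fans out into named per-stage streams (phantoms, noise,
training) so each stage can be re-seeded independently without
correlating with the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import yaml

from . import phantoms
from .phantoms import LifetimeScene
from . import forward as fwd
from .forward import MeasurementSet, TemporalAxis
from . import tvrecon as tvr
from . import network as net
from . import evaluation as ev

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "seed_streams",
    "write_dataset",
    "read_dataset",
    "simulate_dataset",
    "run_pipeline",
]

SCHEMA_VERSION = "netflics-dataset-1"
STAGES = ("simulate", "tvrecon", "train", "predict", "evaluate")

log = logging.getLogger("netflics")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a full simulate->reconstruct->evaluate run."""

    # generator
    n_test: int = 40
    level_mix: dict = field(default_factory=lambda: {"full": 1.0})
    seed: int = 0
    # temporal axis
    n_gates: int = 256
    gate_width: float = 0.040
    # IRF
    irf_fwhm: float = 0.2
    irf_t0: float = 1.0
    irf_file: str | None = None
    # pattern bank
    hadamard_order: int = 1024
    n_patterns: int = 512
    ranking: str = "sequency"
    bank_source: str = "hadamard_pos"
    noisy: bool = True
    # TV reconstruction
    tv_mu: float = 0.25
    tv_beta: float = 32.0
    tv_tol: float = 1e-4
    tv_max_iter: int = 150
    tv_nonneg: bool = True
    # fitting
    tail_start: int = 5
    bg_threshold: float = 0.1
    # network training
    preset: str = "smoke"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def axis(self) -> TemporalAxis:
        return TemporalAxis(n_gates=self.n_gates, gate_width=self.gate_width)

    def irf(self) -> fwd.IRF:
        ax = self.axis()
        if self.irf_file:
            return fwd.load_irf(self.irf_file, ax)
        return fwd.gaussian_irf(ax, fwhm=self.irf_fwhm, t0=self.irf_t0)

    def bank(self) -> fwd.PatternBank:
        return fwd.build_hadamard_bank(
            order=self.hadamard_order, k=self.n_patterns,
            ranking=self.ranking, source=self.bank_source)

    def tv_config(self) -> tvr.TVConfig:
        return tvr.TVConfig(mu=self.tv_mu, beta=self.tv_beta, tol=self.tv_tol,
                            max_iter=self.tv_max_iter, nonneg=self.tv_nonneg)

    def fit_config(self) -> tvr.FitConfig:
        return tvr.FitConfig(tail_start=self.tail_start, bg_threshold=self.bg_threshold)


_STREAM_NAMES = ("phantoms", "noise", "training")


def seed_streams(global_seed: int) -> dict[str, int]:
    """Fan a global seed out into independent named module streams."""
    root = np.random.SeedSequence(global_seed)
    children = root.spawn(len(_STREAM_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STREAM_NAMES, children)
    }


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_dataset(
    path: str,
    scenes: list[LifetimeScene],
    measurements: list[MeasurementSet] | None = None,
    recons: list[tvr.ReconResult] | None = None,
    overwrite: bool = False,
    attrs: dict | None = None,
) -> None:
    """Write scenes (and optionally measurements/reconstructions) to HDF5.

    Every measurement and reconstruction must reference an existing scene
    id.  Refuses to clobber an existing file unless ``overwrite``.
    """
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    scene_ids = {s.scene_id for s in scenes}
    for m in measurements or []:
        if m.scene_id not in scene_ids:
            raise ValueError(f"measurement references unknown scene {m.scene_id!r}")
    for r in recons or []:
        if r.scene_id not in scene_ids:
            raise ValueError(f"reconstruction references unknown scene {r.scene_id!r}")
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        for key, val in (attrs or {}).items():
            f.attrs[key] = val
        gs = f.create_group("scenes")
        for i, s in enumerate(scenes):
            g = gs.create_group(s.scene_id)
            g.attrs["order"] = i
            g.attrs["level"] = s.level or ""
            g.create_dataset("intensity", data=s.intensity)
            g.create_dataset("lifetime", data=s.lifetime)
            g.create_dataset("mask", data=s.mask.astype(np.uint8))
        if measurements:
            gm = f.create_group("measurements")
            for m in measurements:
                g = gm.create_group(m.scene_id)
                g.create_dataset("data", data=m.data)
                g.attrs.update({
                    "n_gates": m.axis.n_gates, "gate_width": m.axis.gate_width,
                    "origin": m.axis.origin, "bank_id": m.bank_id,
                    "irf_id": m.irf_id, "noisy": m.noisy,
                })
        if recons:
            gr = f.create_group("recons")
            for r in recons:
                g = gr.create_group(f"{r.method}/{r.scene_id}")
                g.create_dataset("intensity", data=r.intensity)
                g.create_dataset("lifetime", data=r.lifetime)


@dataclass
class Dataset:
    """In-memory view of a dataset file."""

    scenes: list[LifetimeScene]
    measurements: dict[str, MeasurementSet]
    recons: dict[str, list[tvr.ReconResult]]
    attrs: dict


def read_dataset(path: str) -> Dataset:
    """Read and validate a dataset container; ids come back in stored order."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"{path} is not a readable HDF5 dataset: {exc}") from exc
    with f:
        schema = f.attrs.get("schema")
        if schema != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported dataset schema {schema!r} (expected {SCHEMA_VERSION!r})")
        scene_items = sorted(
            f["scenes"].items(), key=lambda kv: kv[1].attrs.get("order", 0))
        scenes = []
        for sid, g in scene_items:
            scenes.append(LifetimeScene(
                intensity=g["intensity"][()],
                lifetime=g["lifetime"][()],
                mask=g["mask"][()].astype(bool),
                scene_id=sid,
                level=(g.attrs.get("level") or None),
            ))
        measurements: dict[str, MeasurementSet] = {}
        for sid, g in (f["measurements"].items() if "measurements" in f else []):
            a = g.attrs
            measurements[sid] = MeasurementSet(
                data=g["data"][()],
                axis=TemporalAxis(n_gates=int(a["n_gates"]),
                                  gate_width=float(a["gate_width"]),
                                  origin=float(a["origin"])),
                bank_id=str(a["bank_id"]), irf_id=str(a["irf_id"]),
                noisy=bool(a["noisy"]), scene_id=sid,
            )
        recons: dict[str, list[tvr.ReconResult]] = {}
        if "recons" in f:
            for method, gm in f["recons"].items():
                recons[method] = [
                    tvr.ReconResult(intensity=g["intensity"][()],
                                    lifetime=g["lifetime"][()],
                                    method=method, scene_id=sid)
                    for sid, g in gm.items()
                ]
        attrs = dict(f.attrs)
    return Dataset(scenes=scenes, measurements=measurements, recons=recons, attrs=attrs)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def simulate_dataset(
    n: int,
    split: str,
    cfg: RunConfig,
    seed: int,
    noise_seed: int,
) -> tuple[list[LifetimeScene], list[MeasurementSet]]:
    """Generate scenes for a split and push them through the forward model."""
    scenes = phantoms.make_dataset(n, split, level_mix=cfg.level_mix, rng_seed=seed)
    axis, irf, bank = cfg.axis(), cfg.irf(), cfg.bank()
    noise_root = np.random.SeedSequence(noise_seed)
    measurements = []
    for s, child in zip(scenes, noise_root.spawn(len(scenes))):
        m, _ = fwd.simulate_sample(
            s, bank, irf, axis,
            rng_seed=int(child.generate_state(1)[0] % (2**31)),
            noisy=cfg.noisy)
        measurements.append(m)
    return scenes, measurements


def run_pipeline(cfg: RunConfig, stages: list[str], workdir: str = ".") -> dict:
    """Execute pipeline stages in order, logging seeds/configs/timings.

    Artifacts land in ``workdir``: ``test.h5`` (scenes+measurements and any
    reconstructions), ``model.npz/.json`` and ``report_<method>.csv/json``.
    Returns a dict of artifact paths and aggregate metrics.
    """
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; choose from {STAGES}")
    stages = [st for st in STAGES if st in stages]
    os.makedirs(workdir, exist_ok=True)
    streams = seed_streams(cfg.seed)
    chash = cfg.config_hash()
    log.info("run %s: stages=%s seeds=%s", chash, stages, streams)
    test_path = os.path.join(workdir, "test.h5")
    model_path = os.path.join(workdir, "model")
    artifacts: dict = {"config_hash": chash}

    scenes = measurements = None
    recons: dict[str, list[tvr.ReconResult]] = {}

    def ensure_test_data():
        nonlocal scenes, measurements, recons
        if scenes is None:
            if os.path.exists(test_path):
                ds = read_dataset(test_path)
                scenes, measurements = ds.scenes, [ds.measurements[s.scene_id] for s in ds.scenes]
                recons = ds.recons
            else:
                raise RuntimeError(
                    "stage requires simulated data: run the 'simulate' stage first")

    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            scenes, measurements = simulate_dataset(
                cfg.n_test, "test", cfg, streams["phantoms"], streams["noise"])
            write_dataset(test_path, scenes, measurements, overwrite=True,
                          attrs={"config_hash": chash, "seed": cfg.seed})
            artifacts["test"] = test_path
        elif stage == "tvrecon":
            ensure_test_data()
            bank = cfg.bank()
            recons["tvrecon"] = tvr.reconstruct_batch(
                measurements, bank, cfg.axis(), cfg.tv_config(), cfg.fit_config())
            write_dataset(test_path, scenes, measurements, recons=sum(recons.values(), []),
                          overwrite=True, attrs={"config_hash": chash, "seed": cfg.seed})
        elif stage == "train":
            ncfg, n_train, n_val = net.preset_config(
                cfg.preset, n_meas=cfg.n_patterns, n_gates=cfg.n_gates,
                rng_seed=streams["training"])
            tr = simulate_dataset(n_train, "train", cfg, streams["phantoms"], streams["noise"])
            va = simulate_dataset(n_val, "val", cfg, streams["phantoms"], streams["noise"])
            model = net.build_model(ncfg, cfg.bank())
            trained = net.train(
                model,
                net.make_training_arrays(list(zip(tr[1], tr[0]))),
                net.make_training_arrays(list(zip(va[1], va[0]))),
                verbose=True)
            trained.save(model_path)
            artifacts["model"] = model_path + ".npz"
        elif stage == "predict":
            ensure_test_data()
            if not os.path.exists(model_path + ".npz"):
                raise RuntimeError("stage 'predict' requires a model: run 'train' first")
            trained = net.TrainedModel.load(model_path)
            recons["netflics"] = net.predict(trained, measurements)
            write_dataset(test_path, scenes, measurements, recons=sum(recons.values(), []),
                          overwrite=True, attrs={"config_hash": chash, "seed": cfg.seed})
        elif stage == "evaluate":
            ensure_test_data()
            if not recons:
                raise RuntimeError(
                    "stage 'evaluate' requires reconstructions: run 'tvrecon' or 'predict'")
            for method, rs in recons.items():
                report = ev.evaluate(rs, scenes, method=method)
                csv_path = os.path.join(workdir, f"report_{method}.csv")
                json_path = os.path.join(workdir, f"report_{method}.json")
                report.to_csv(csv_path)
                report.to_json(json_path)
                artifacts[f"report_{method}"] = csv_path
                artifacts[f"aggregates_{method}"] = report.aggregates
        log.info("stage %s done in %.1f s", stage, time.time() - t0)
    return artifacts
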
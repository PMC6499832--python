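"""Run configuration and stage orchestration for the command-line tool.

The pipeline runs backbone → intra-TAD → assembly → evaluation, writing
every intermediate as CSV so each stage can be re-run independently from
cached files.  One global seed determines all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as cio
from .assembly import AssemblyParams, assemble, fit_distance_powerlaw
from .backbone import BackboneProblem, optimize_backbone
from .datamodel import ContactMap, Conformation, InputError
from .evaluation import evaluate_model
from .intratad import TadProblem, estimate_target_rg, optimize_tad
from .optim import OptimizerConfig

logger = logging.getLogger("chromofold")

__all__ = ["RunConfig", "run_pipeline", "stage_backbone", "stage_tads",
           "stage_assemble", "stage_evaluate"]


@dataclass
class RunConfig:
    """Fully serializable run configuration; defaults follow the published
    weight selection for raw Hi-C counts (override per dataset — the `tune`
    subcommand runs the grid search)."""

    # inputs
    tads: str = "tads.bed"
    hic_tad: str = "hic_tad.csv"
    hic_full: str = "hic_full.csv"
    fish: str = "fish.csv"
    # weights
    lambda_e_backbone: float = 5e12
    lambda_f: float = 1e-8
    lambda_e_tad: float = 5e11
    lambda_r: float = 1e-7
    # assembly
    alpha_exponent: float = -0.25
    try_reflection: bool = True
    rescale_linkers: bool = False
    # optimizer
    max_iter: int = 20000
    rel_tol: float = 1e-7
    # misc
    resolution: int = 5000
    seed: int = 0
    out: str = "chromofold_out"
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat = {}
        for key, val in data.items():
            if isinstance(val, dict):  # tolerate sectioned configs
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        flat.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**flat)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "config_resolved.json", "w") as fh:
            json.dump(self.resolved(), fh, indent=2, sort_keys=True)


def _outdir(cfg: RunConfig) -> Path:
    p = Path(cfg.out)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _load_inputs(cfg: RunConfig, need_fish: bool = True):
    tads = cio.load_tads(cfg.tads)
    fish = None
    if need_fish:
        if not Path(cfg.fish).exists():
            raise InputError(
                f"FISH file {cfg.fish} not found but the C3 term has λF > 0"
            )
        fish = cio.load_fish_matrix(cfg.fish)
    return tads, fish


def stage_backbone(cfg: RunConfig) -> Conformation:
    tads, fish = _load_inputs(cfg)
    cmap = cio.load_contact_map(cfg.hic_tad, bins=tads, resolution="TAD")
    vals = fish.matrix[fish.defined]
    scale = float(np.mean(vals)) if vals.size else 1.0
    opt = OptimizerConfig(
        learning_rate=0.05 * scale, max_iter=cfg.max_iter,
        rel_tol=cfg.rel_tol, seed=cfg.seed, init_scale=0.5 * scale,
    )
    problem = BackboneProblem(
        tad_contacts=cmap, fish=fish,
        lambda_E=cfg.lambda_e_backbone, lambda_F=cfg.lambda_f, opt=opt,
    )
    conf = optimize_backbone(problem)
    cio.write_conformation(conf, _outdir(cfg) / "backbone.csv")
    logger.info("backbone: %d TADs embedded", len(conf))
    return conf


def _tad_bin_offsets(tads, resolution: int) -> list[int]:
    sizes = [max(1, round(t.length / resolution)) for t in tads]
    return list(np.concatenate([[0], np.cumsum(sizes)]))


def stage_tads(cfg: RunConfig) -> list[Conformation]:
    tads, fish = _load_inputs(cfg)
    full = cio.load_contact_map(cfg.hic_full, resolution=cfg.resolution)
    offsets = _tad_bin_offsets(tads, cfg.resolution)
    if offsets[-1] != full.n:
        raise InputError(
            f"full-resolution map has {full.n} bins; TADs at {cfg.resolution} bp "
            f"imply {offsets[-1]}"
        )
    c, beta = fit_distance_powerlaw(fish, tads)
    outdir = _outdir(cfg)
    models = []
    for t in tads:
        sub = full.matrix[offsets[t.index]:offsets[t.index + 1],
                          offsets[t.index]:offsets[t.index + 1]]
        rg_hat = estimate_target_rg(t, (c, beta))
        opt = OptimizerConfig(
            learning_rate=0.05 * rg_hat, max_iter=cfg.max_iter,
            rel_tol=cfg.rel_tol, seed=cfg.seed + 1 + t.index,
            init_scale=rg_hat,
        )
        problem = TadProblem(
            tad=t, contacts=ContactMap(sub, resolution=cfg.resolution),
            target_rg=rg_hat, lambda_E=cfg.lambda_e_tad,
            lambda_R=cfg.lambda_r, opt=opt,
        )
        model = optimize_tad(problem)
        models.append(model)
        cio.write_conformation(model, outdir / f"tad_{t.index:04d}.csv")
    logger.info("intra-TAD: %d models computed (c=%.4g, beta=%.4g)",
                len(models), c, beta)
    return models


def stage_assemble(cfg: RunConfig) -> Conformation:
    tads, fish = _load_inputs(cfg)
    outdir = _outdir(cfg)
    backbone = cio.read_conformation(outdir / "backbone.csv")
    models = [
        cio.read_conformation(outdir / f"tad_{t.index:04d}.csv") for t in tads
    ]
    full = cio.load_contact_map(cfg.hic_full, resolution=cfg.resolution)
    c, beta = fit_distance_powerlaw(fish, tads)
    params = AssemblyParams(
        alpha_exponent=cfg.alpha_exponent, c=c, beta=beta,
        try_reflection=cfg.try_reflection, rescale_linkers=cfg.rescale_linkers,
    )
    result = assemble(backbone, models, full, params)
    final = result.conformation
    cio.write_conformation(final, outdir / "final.csv")
    cio.write_conformation(final, outdir / "final.pdb", format="pdb")
    logger.info("assembly: junction cost %.6g after %d sweeps",
                result.cost, len(result.cost_history) - 1)
    return final


def stage_evaluate(cfg: RunConfig) -> dict:
    tads, fish = _load_inputs(cfg)
    outdir = _outdir(cfg)
    final_path = outdir / "final.csv"
    if final_path.exists():
        conf = cio.read_conformation(final_path)
        mode = "final"
    else:
        conf = cio.read_conformation(outdir / "backbone.csv")
        mode = "tad_level"
    tad_cmap = None
    if Path(cfg.hic_tad).exists():
        tad_cmap = cio.load_contact_map(cfg.hic_tad, bins=tads)
    report = evaluate_model(conf, fish, tads=tads, mode=mode,
                            tad_contacts=tad_cmap)
    summary = report.summary()
    with open(outdir / "report.csv", "w") as fh:
        fh.write("metric,value\n")
        for k, v in summary.items():
            fh.write(f"{k},{v}\n")
        fh.write(
            "compartment_labels,"
            + ";".join(str(x) for x in report.compartment_labels) + "\n"
        )
    np.savetxt(outdir / "re_matrix.csv", report.re_matrix, delimiter=",",
               fmt="%.9g")
    logger.info("evaluation: mean RE (%s) = %.4f", mode, report.mean_re)
    return summary


def run_pipeline(cfg: RunConfig) -> dict:
    """backbone → intra-TAD → assemble → evaluate, with the resolved config
    and a log echoed to the output directory."""
    outdir = _outdir(cfg)
    cfg.echo(outdir)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.log_level.upper())
    try:
        stage_backbone(cfg)
        stage_tads(cfg)
        stage_assemble(cfg)
        return stage_evaluate(cfg)
    finally:
        logger.removeHandler(handler)
        handler.close()
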
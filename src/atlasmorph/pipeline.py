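"""End-to-end orchestration: configuration, job planning, and local runs.

``plan`` enumerates the jobs a stage would execute without running them
(the atlas stage schedules all n*(n-1) ordered pairwise affine
registrations plus the per-iteration non-linear jobs); ``run`` executes a
stage locally, skipping jobs whose outputs already exist, so a rerun after
completion executes nothing.  ``--emit-scripts`` writes one portable shell
script per job for cluster use instead of executing.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .preprocess import background_threshold, minmax_normalize
from .propagate import dice, propagate_landmarks, propagate_segmentation
from .register import build_atlas, ncc, register_pair
from .volio import (
    read_composite,
    read_tag,
    read_volume,
    write_composite,
    write_landmark_csv,
    write_tag,
    write_volume,
)


def _standard_preprocess(v):
    """Intensity chain applied before registration: [0,1] scaling, then
    zeroing the background so the uncentered NCC tracks anatomy rather
    than the background offset."""
    v = minmax_normalize(v)
    v, _ = background_threshold(v, dilation_radius=2)
    return v


@dataclass
class PipelineConfig:
    workdir: Path
    outdir: Path
    seed: int = 1
    workers: int = 1
    n_specimens: int = 8
    levels: int = 3
    nl_iterations: int = 4
    reg_sigma: float = 0.2
    iters_per_level: int = 30
    atlas_name: str = "Synthetic_Atlas"
    params: dict = dfield(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc["workdir"] = Path(doc.get("workdir", "."))
        doc["outdir"] = Path(doc.get("outdir", "out"))
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in doc.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.params.update(extra)
        return cfg

    def validate(self) -> None:
        if not Path(self.workdir).exists():
            raise FileNotFoundError(f"workdir does not exist: {self.workdir}")


@dataclass
class Job:
    kind: str
    inputs: list[str]
    outputs: list[str]
    deps: list[str] = dfield(default_factory=list)

    @property
    def job_id(self) -> str:
        return f"{self.kind}:{','.join(Path(o).name for o in self.outputs)}"


@dataclass
class JobPlan:
    stage: str
    jobs: list[Job]

    def __len__(self) -> int:
        return len(self.jobs)


def _specimen_ids(cfg: PipelineConfig) -> list[str]:
    import re

    vols = sorted(Path(cfg.workdir).glob("phantom_*.nii.gz"))
    ids = [
        v.name[: -len(".nii.gz")]
        for v in vols
        if re.fullmatch(r"phantom_\d+\.nii\.gz", v.name)
    ]
    return sorted(ids)


def plan(cfg: PipelineConfig, stage: str) -> JobPlan:
    """Enumerate the jobs of a stage deterministically (sorted ids)."""
    out = Path(cfg.outdir)
    if stage == "atlas":
        ids = _specimen_ids(cfg) or [f"phantom_{i + 1:03d}" for i in range(cfg.n_specimens)]
        jobs = []
        for mid in ids:
            for fid in ids:
                if mid != fid:
                    jobs.append(Job("affine_register", [f"{mid}.nii.gz", f"{fid}.nii.gz"],
                                    [f"{mid}_to_{fid}_affine.txt"]))
        for it in range(1, cfg.nl_iterations + 1):
            for sid in ids:
                jobs.append(Job(
                    "nonlinear_register",
                    [f"{sid}.nii.gz", f"template_it{it - 1}.nii.gz"],
                    [f"{sid}_it{it}_grid.nii.gz"],
                    deps=[f"template_it{it - 1}"],
                ))
        return JobPlan("atlas", jobs)
    if stage == "register":
        ids = _specimen_ids(cfg)
        jobs = [
            Job("register_pair",
                [f"{sid}.nii.gz", f"{cfg.atlas_name}.nii.gz"],
                [str(out / f"{sid}_composite.txt")])
            for sid in ids
        ]
        return JobPlan("register", jobs)
    if stage == "propagate":
        ids = _specimen_ids(cfg)
        jobs = [
            Job("propagate",
                [str(out / f"{sid}_composite.txt"),
                 f"{cfg.atlas_name}_Landmarks.tag", f"{cfg.atlas_name}_Segs.nii.gz"],
                [str(out / f"{sid}_Head_Landmarks.tag"), str(out / f"{sid}_Segs.nii.gz")])
            for sid in ids
        ]
        return JobPlan("propagate", jobs)
    raise ValueError(f"unknown stage {stage!r}")


def emit_scripts(plan_: JobPlan, outdir) -> list[Path]:
    """Write one portable shell script per job (cluster hand-off)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, job in enumerate(plan_.jobs):
        p = outdir / f"job_{plan_.stage}_{i:04d}.sh"
        p.write_text(
            "#!/bin/sh\n"
            f"# {job.job_id}\n"
            f"atlasmorph {job.kind.replace('_', '-')} "
            + " ".join(job.inputs) + " " + " ".join(job.outputs) + "\n"
        )
        written.append(p)
    return written


def run_phantom(cfg: PipelineConfig, group_effect=None) -> Path:
    pert = ph.PerturbationSpec(**cfg.params.get("perturbation", {}))
    atlas, lms, seg, specimens, meta = ph.make_population(
        cfg.n_specimens, pert, cfg.seed, group_effect=group_effect
    )
    ph.write_population(cfg.workdir, atlas, lms, seg, specimens, meta)
    return Path(cfg.workdir)


def run_register(cfg: PipelineConfig, log=print) -> dict[str, float]:
    """Register every specimen volume to the atlas; resumable."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = _standard_preprocess(read_volume(Path(cfg.workdir) / f"{cfg.atlas_name}.nii.gz"))
    nccs: dict[str, float] = {}
    for sid in _specimen_ids(cfg):
        manifest = out / f"{sid}_composite.txt"
        if manifest.exists():
            log(f"skip {sid} (done)")
            comp = read_composite(manifest)
            nccs[sid] = float((out / f"{sid}_ncc.txt").read_text())
            continue
        vol = _standard_preprocess(read_volume(Path(cfg.workdir) / f"{sid}.nii.gz"))
        res = register_pair(
            vol, atlas, levels=cfg.levels, reg_sigma=cfg.reg_sigma,
            iters_per_level=cfg.iters_per_level,
        )
        write_composite(res.composite, out / sid)
        (out / f"{sid}_ncc.txt").write_text(f"{res.final_ncc:.6f}\n")
        nccs[sid] = res.final_ncc
        log(f"register {sid} ncc={res.final_ncc:.4f}")
    pd.DataFrame({"id": list(nccs), "ncc": list(nccs.values())}).to_csv(
        out / "registration_ncc.csv", index=False
    )
    return nccs


def run_propagate(cfg: PipelineConfig, log=print) -> list[str]:
    cfg.validate()
    out = Path(cfg.outdir)
    atlas_lms = read_tag(Path(cfg.workdir) / f"{cfg.atlas_name}_Landmarks.tag")
    seg_path = Path(cfg.workdir) / f"{cfg.atlas_name}_Segs.nii.gz"
    atlas_seg = read_volume(seg_path) if seg_path.exists() else None
    done = []
    propagated = []
    for sid in _specimen_ids(cfg):
        tag_out = out / f"{sid}_Head_Landmarks.tag"
        if tag_out.exists():
            log(f"skip {sid} (done)")
            done.append(sid)
            continue
        comp = read_composite(out / f"{sid}_composite.txt")
        vol = read_volume(Path(cfg.workdir) / f"{sid}.nii.gz")
        lms = propagate_landmarks(atlas_lms, comp, vol, specimen_id=sid)
        write_tag(lms, tag_out)
        propagated.append(lms)
        if atlas_seg is not None:
            seg = propagate_segmentation(atlas_seg, comp, vol)
            write_volume(seg, out / f"{sid}_Segs.nii.gz", dtype=np.int16)
        done.append(sid)
        log(f"propagate {sid}")
    if propagated:
        write_landmark_csv(propagated, out / "propagated_landmarks.csv")
    return done


def run_atlas_build(cfg: PipelineConfig, log=print):
    cfg.validate()
    vols = {
        sid: _standard_preprocess(read_volume(Path(cfg.workdir) / f"{sid}.nii.gz"))
        for sid in _specimen_ids(cfg)
    }
    build = build_atlas(
        vols, levels=cfg.levels, nl_iterations=cfg.nl_iterations,
        reg_sigma=cfg.reg_sigma, iters_per_level=cfg.iters_per_level,
        progress=log,
    )
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(build.template, out / "template.nii.gz")
    for sid, res in build.results.items():
        write_composite(res.composite, out / f"{sid}_atlasbuild")
    return build
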
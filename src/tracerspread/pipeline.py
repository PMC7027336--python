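"""End-to-end orchestration: phantoms -> registration -> segmentation ->
spread statistics -> lymph nodes -> statistical report.

A RunConfig fully determines a run; two runs from the same config produce
bit-identical CSV outputs. Per-brain random seeds are derived from the
config seed and the brain's position, so adding a brain does not reshuffle
the others.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import registration as reg
from . import segmentation as seg
from . import spread as spr
from . import synthetic as syn
from .regions import group_tracer_comparison, quantify_lymphnode
from .stats import wilcoxon_signed_rank

logger = logging.getLogger("tracerspread")

__all__ = ["RunConfig", "run_pipeline", "demo_config"]

VALID_GROUPS = set(spr.GROUPS)
ALL_STAGES = ("simulate", "register", "reconstruct", "segment", "spread",
              "lymphnode", "stats")


@dataclass
class BrainConfig:
    brain_id: str
    group: str
    mode: str  # "advective" (living) or "diffusive" (sacrificed)
    time_min: float


@dataclass
class RunConfig:
    """Structured run configuration (YAML-serializable)."""

    outdir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    shape: tuple[int, int, int] = (12, 64, 64)
    in_plane_um: float = syn.BRAIN_PIXEL_UM
    axial_um: float = syn.BRAIN_SLICE_UM
    translation_sigma_px: float = 2.0
    rotation_sigma_deg: float = 1.0
    noise_sigma: float = 2.0
    threshold: str | float = "auto"
    sample_n: int | str = 400
    brains: list[BrainConfig] = field(default_factory=list)
    lymphnodes: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        if not self.brains:
            raise ValueError("config lists no brains")
        for b in self.brains:
            if b.group not in VALID_GROUPS:
                raise ValueError(
                    f"brain {b.brain_id!r}: group {b.group!r} not in "
                    f"{sorted(VALID_GROUPS)}")
        for st in self.stages:
            if st not in ALL_STAGES:
                raise ValueError(f"unknown stage {st!r}")

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["brains"] = [BrainConfig(**b) for b in raw.get("brains", [])]
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return RunConfig(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["shape"] = list(self.shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def demo_config(outdir: str, seed: int = 0) -> RunConfig:
    """Small packaged demonstration: four phantom brains, two lymph nodes."""
    brains = [
        BrainConfig("L90-1", "L90", "advective", 90.0),
        BrainConfig("S90-1", "S90", "diffusive", 90.0),
    ]
    nodes = [
        {"node_class": "DCLN-left", "group": "L90", "n_tracer": 5,
         "n_autofluor": 12},
        {"node_class": "DCLN-left", "group": "S90", "n_tracer": 0,
         "n_autofluor": 12},
    ]
    return RunConfig(outdir=outdir, seed=seed, brains=brains,
                     lymphnodes=nodes)


def _brain_spec(cfg: RunConfig, i: int, b: BrainConfig) -> syn.PhantomSpec:
    return syn.PhantomSpec(
        shape=cfg.shape, in_plane_um=cfg.in_plane_um, axial_um=cfg.axial_um,
        mode=b.mode, time_min=b.time_min,
        translation_sigma_px=cfg.translation_sigma_px,
        rotation_sigma_deg=cfg.rotation_sigma_deg,
        noise_sigma=cfg.noise_sigma,
        seed=(cfg.seed * 1009 + 13 * i) % (2**31 - 1))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in order; returns the result bundle.

    Writes per-stage CSV outputs, a spread boxplot and a plain-text
    statistics report under ``cfg.outdir``. Any stage failure aborts with
    the stage name and cause.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    bundle: dict = {"config": cfg}
    stage = "setup"
    try:
        stacks: dict[str, reg.SliceStack] = {}
        truths: dict[str, syn.GroundTruth] = {}
        if "simulate" in cfg.stages:
            stage = "simulate"
            for i, b in enumerate(cfg.brains):
                spec = _brain_spec(cfg, i, b)
                slices, truth = syn.make_phantom(spec)
                stacks[b.brain_id] = reg.SliceStack(
                    slices=slices, in_plane_um=spec.in_plane_um,
                    axial_um=spec.axial_um)
                truths[b.brain_id] = truth
            bundle["truths"] = truths

        volumes: dict[str, reg.VolumeGrid] = {}
        if "register" in cfg.stages or "reconstruct" in cfg.stages:
            stage = "register"
            rows = []
            registered: dict[str, reg.SliceStack] = {}
            for bid, stack in stacks.items():
                rstack, transforms = reg.register_stack(stack, "nuclei")
                rstack = reg.equalize_brightness(rstack, "nuclei")
                registered[bid] = rstack
                for i, t in enumerate(transforms):
                    rows.append({"brain_id": bid, "slice_index": i,
                                 **t.as_dict()})
            pd.DataFrame(rows).to_csv(
                os.path.join(cfg.outdir, "transforms.csv"), index=False,
                float_format="%.6f")
            stage = "reconstruct"
            for bid, rstack in registered.items():
                volumes[bid] = reg.assemble_volume(rstack)
            bundle["volumes"] = volumes

        binaries: dict[str, seg.BinaryVolume] = {}
        if "segment" in cfg.stages:
            stage = "segment"
            rows = []
            groups_of = {b.brain_id: b.group for b in cfg.brains}
            for bid, vol in volumes.items():
                bin_vol = seg.binarize_tracer(vol, "tracer", cfg.threshold)
                binaries[bid] = bin_vol
                split = seg.split_hemispheres(
                    bin_vol, seg.vertical_midline(vol.shape))
                rows.append({"brain_id": bid, "group": groups_of[bid],
                             "ipsi": split.ipsi, "contra": split.contra,
                             "on_surface": split.on_surface,
                             "total": seg.count_positive_voxels(bin_vol),
                             "threshold": bin_vol.threshold,
                             "method": bin_vol.method})
            counts_df = pd.DataFrame(rows)
            counts_df.to_csv(os.path.join(cfg.outdir, "hemisphere_counts.csv"),
                             index=False)
            bundle["hemisphere_counts"] = counts_df

        samples: list[spr.DistanceSample] = []
        if "spread" in cfg.stages:
            stage = "spread"
            groups_of = {b.brain_id: b.group for b in cfg.brains}
            for j, (bid, bin_vol) in enumerate(binaries.items()):
                samples.append(spr.measure_spread(
                    bin_vol, brain_id=bid, group=groups_of[bid],
                    sample_n=cfg.sample_n,
                    seed=(cfg.seed * 2003 + j) % (2**31 - 1)))
            spr.distances_to_frame(samples).to_csv(
                os.path.join(cfg.outdir, "distances.csv"), index=False,
                float_format="%.4f")
            summary = spr.summarize_spread(samples)
            summary["groups"].to_csv(
                os.path.join(cfg.outdir, "spread_summary.csv"), index=False,
                float_format="%.4f")
            summary["brains"].to_csv(
                os.path.join(cfg.outdir, "spread_per_brain.csv"), index=False,
                float_format="%.4f")
            _boxplot(samples, os.path.join(cfg.outdir, "spread_boxplot.png"))
            bundle["spread_samples"] = samples
            bundle["spread_summary"] = summary

        if "lymphnode" in cfg.stages and cfg.lymphnodes:
            stage = "lymphnode"
            rows = []
            for j, node in enumerate(cfg.lymphnodes):
                img, truth = syn.generate_lymphnode_image(
                    n_tracer=node["n_tracer"],
                    n_autofluor=node["n_autofluor"],
                    seed=(cfg.seed * 4001 + j) % (2**31 - 1))
                q = quantify_lymphnode(img, node_class=node["node_class"])
                rows.append({"image_id": f"node{j}", "group": node["group"],
                             "node_class": q.node_class,
                             "pixel_count": q.pixel_count,
                             "threshold": q.threshold,
                             "true_tracer_px": truth.n_tracer_px,
                             "degenerate": q.degenerate})
            node_df = pd.DataFrame(rows)
            node_df.to_csv(os.path.join(cfg.outdir, "lymphnode_counts.csv"),
                           index=False)
            bundle["lymphnode_counts"] = node_df

        if "stats" in cfg.stages:
            stage = "stats"
            report_lines = []
            stats_rows = []
            if samples:
                by_group: dict[str, list[np.ndarray]] = {}
                for s in samples:
                    by_group.setdefault(s.group, []).append(s.distances_um)
                pooled = {g: np.concatenate(v) for g, v in by_group.items()
                          if sum(len(a) for a in v) >= 2}
                if len(pooled) >= 2:
                    cmp = spr.compare_spread(pooled)
                    report_lines.append("== spread distance comparison "
                                        "(pooled voxel distances) ==")
                    for g, t in cmp["normality"].items():
                        report_lines.append(
                            f"normality[{g}]: {t.name} stat={t.statistic:.4f}"
                            f" p={t.pvalue:.4g}")
                    om = cmp["omnibus"]
                    report_lines.append(
                        f"kruskal-wallis: H={om.statistic:.4f} df={om.df}"
                        f" p={om.pvalue:.4g} significant={om.significant}")
                    stats_rows.append({"test": "kruskal-wallis",
                                       "statistic": om.statistic,
                                       "p": om.pvalue})
                    ph = cmp["posthoc"].pairwise
                    report_lines.append(ph.to_string(index=False))
                    report_lines.append(
                        "caveat: voxel-level pooling across brains is "
                        "pseudo-replicated; see spread_per_brain.csv")
                    ph.to_csv(os.path.join(cfg.outdir, "dunn_pairwise.csv"),
                              index=False, float_format="%.6g")
                    bundle["spread_stats"] = cmp
            if "hemisphere_counts" in bundle:
                hc = bundle["hemisphere_counts"]
                report_lines.append("\n== hemisphere voxel counts "
                                    "(ipsi vs contra) ==")
                try:
                    w = wilcoxon_signed_rank(hc["ipsi"].to_numpy(float),
                                             hc["contra"].to_numpy(float))
                    report_lines.append(
                        f"wilcoxon signed-rank: W+={w.statistic:.1f}"
                        f" p={w.pvalue:.4g} (n={len(hc)} brains; small-n "
                        "caveat: interpret with caution)")
                    stats_rows.append({"test": "wilcoxon-ipsi-contra",
                                       "statistic": w.statistic,
                                       "p": w.pvalue})
                except ValueError as exc:
                    report_lines.append(
                        f"wilcoxon signed-rank not computable: {exc}")
            if "lymphnode_counts" in bundle:
                nd = bundle["lymphnode_counts"]
                living = nd.loc[nd.group.str.startswith("L"), "pixel_count"]
                dead = nd.loc[nd.group.str.startswith("S"), "pixel_count"]
                if len(living) >= 1 and len(dead) >= 1 \
                        and len(nd) >= 3:
                    mw = group_tracer_comparison(living, dead)
                    report_lines.append(
                        f"\nlymph nodes L vs S: U={mw.statistic:.1f}"
                        f" p={mw.pvalue:.4g} ({mw.notes['caveat']})")
                    stats_rows.append({"test": "mann-whitney-lymphnode",
                                       "statistic": mw.statistic,
                                       "p": mw.pvalue})
            with open(os.path.join(cfg.outdir, "stats_report.txt"), "w") as fh:
                fh.write("\n".join(report_lines) + "\n")
            pd.DataFrame(stats_rows).to_csv(
                os.path.join(cfg.outdir, "stats_report.csv"), index=False,
                float_format="%.6g")
            bundle["report"] = "\n".join(report_lines)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(cfg.outdir, "run_log.json"), "w") as fh:
        json.dump({"seed": cfg.seed, "stages": list(cfg.stages),
                   "threshold": str(cfg.threshold),
                   "sample_n": str(cfg.sample_n),
                   "n_brains": len(cfg.brains)}, fh, indent=2)
    return bundle


def _boxplot(samples: list, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_group: dict[str, list[np.ndarray]] = {}
    for s in samples:
        by_group.setdefault(s.group, []).append(s.distances_um)
    labels = sorted(by_group)
    data = [np.concatenate(by_group[g]) for g in labels]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.set_ylabel("distance to nearest tracer-positive voxel (um)")
    ax.set_title("tracer spread by group (shorter = more spread)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
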
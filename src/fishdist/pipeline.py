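"""End-to-end orchestration of the image-analysis pipeline.

One run executes, per field of view: normalisation -> nucleus seeding ->
3D segmentation -> nucleus filtering -> spot detection in FITC and TRITC
-> candidate-pair graph -> top-2 assignment -> score-ratio acceptance.
After all FOVs, the chromatic shift is corrected per slide cohort and the
corrected distances are compiled into one table per condition.  Every
nucleus that drops out is logged with a reason code, and the run manifest
reconciles all counts.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .detect import DetectionParams, MaskTooSmallError, detect_spots
from .geometry import MultiChannelStack
from .pair import (DEFAULT_ACCEPT_RATIO, DEFAULT_RADIUS_UM,
                   correct_chromatic_shift, pair_nucleus)
from .segment import SegmentationParams, normalize_stack, segment_field
from .stats import (DEFAULT_BIN_WIDTH_UM, DEFAULT_BOOT_ALPHA,
                    DEFAULT_BOOT_CRITERION, DEFAULT_N_BOOT, DistanceDataset,
                    bootstrap_min_cells, ks_compare, rosin_threshold,
                    split_at, tail_quantile_flag)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "process_fov",
           "compare_conditions"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with their standard defaults.

    Defaults mirror the published protocol: 5 μm candidate radius, 0.5
    acceptance ratio, sigma 3.75 μm seed filter, 45 μm boxes, 0.6 global
    threshold factor, amplitude-test alpha in [0.05, 0.1], 500 bootstrap
    resamples at the 98% criterion.
    """

    inputs: List[str] = field(default_factory=list)  # paths or globs
    voxel_um: Optional[Sequence[float]] = None  # override TIFF metadata
    segmentation: SegmentationParams = field(
        default_factory=SegmentationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    pairing_radius_um: float = DEFAULT_RADIUS_UM
    acceptance_ratio: float = DEFAULT_ACCEPT_RATIO
    fixed_threshold_um: Optional[float] = 0.9  # interaction cutoff
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM
    bootstrap_n: int = DEFAULT_N_BOOT
    bootstrap_alpha: float = DEFAULT_BOOT_ALPHA
    bootstrap_criterion: float = DEFAULT_BOOT_CRITERION
    # chromatic correction cohort: slide id parsed from the file name
    group_pattern: str = r"(slide[\w-]*)"
    seed: int = 0
    outdir: str = "fishdist_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        det = DetectionParams(**raw.pop("detection", {}))
        cfg = cls(segmentation=seg, detection=det, **raw)
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    fovs: List[dict] = field(default_factory=list)
    totals: Dict[str, int] = field(default_factory=dict)

    def reconcile(self) -> bool:
        """Accepted + every rejection reason must sum to the totals."""
        ok = True
        for fov in self.fovs:
            n = fov["nuclei"]
            ok &= n["seeded"] == n["accepted"] + sum(n["rejected"].values())
            p = fov["pairings"]
            ok &= p["attempted"] == p["accepted"] + sum(
                p["rejected"].values())
        return ok


def _slide_key(name: str, pattern: str) -> str:
    m = re.search(pattern, name)
    return m.group(1) if m else "default"


def process_fov(stack: MultiChannelStack, config: PipelineConfig,
                fov_id: str = "fov") -> dict:
    """Run segmentation, detection and pairing on one stack.

    Returns a dict with accepted masks, detection/pairing tables (raw,
    uncorrected displacements) and the per-FOV count block for the
    manifest.
    """
    norm = normalize_stack(stack)
    accepted, rejected = segment_field(norm["DAPI"], norm.geometry,
                                       config.segmentation)
    nuc_rej: Dict[str, int] = {}
    for m in rejected:
        nuc_rej[m.reason or "unknown"] = nuc_rej.get(m.reason or "unknown",
                                                     0) + 1

    det_rows, pair_rows = [], []
    pair_rej: Dict[str, int] = {}
    n_pair_ok = 0
    for mask in accepted:
        try:
            fitc = detect_spots(norm, "FITC", mask, config.detection)
            tritc = detect_spots(norm, "TRITC", mask, config.detection)
        except MaskTooSmallError:
            pair_rej["mask_too_small"] = pair_rej.get("mask_too_small", 0) + 1
            continue
        for det in (*fitc, *tritc):
            det_rows.append({
                "fov": fov_id, "nucleus_id": mask.id,
                "channel": det.channel,
                "x_um": det.pos_um[0], "y_um": det.pos_um[1],
                "z_um": det.pos_um[2],
                "amplitude": det.amplitude, "background": det.background,
                "sigma_res": det.sigma_res, "p_value": det.p_value,
            })
        pairing = pair_nucleus(fitc, tritc, mask.id,
                               config.pairing_radius_um,
                               config.acceptance_ratio)
        if not pairing.accepted:
            pair_rej[pairing.reason or "rejected"] = \
                pair_rej.get(pairing.reason or "rejected", 0) + 1
            continue
        n_pair_ok += 1
        for rank, cp in enumerate(pairing.pairs):
            pair_rows.append({
                "fov": fov_id, "nucleus_id": mask.id, "pair_rank": rank,
                "fitc_index": cp.i, "tritc_index": cp.j,
                "dx_um": cp.displacement_um[0],
                "dy_um": cp.displacement_um[1],
                "dz_um": cp.displacement_um[2],
                "distance_um": cp.distance_um,
                "intensity_fitc": cp.intensity_i,
                "intensity_tritc": cp.intensity_j,
                "score": cp.score,
            })

    counts = {
        "fov": fov_id,
        "nuclei": {
            "seeded": len(accepted) + len(rejected),
            "accepted": len(accepted),
            "rejected": nuc_rej,
        },
        "pairings": {
            "attempted": len(accepted),
            "accepted": n_pair_ok,
            "rejected": pair_rej,
        },
        "spots": len(det_rows),
    }
    return {
        "masks": accepted,
        "detections": pd.DataFrame(det_rows),
        "pairings": pd.DataFrame(pair_rows),
        "counts": counts,
    }


def _correct_groups(pairings: pd.DataFrame, group_of: Dict[str, str]
                    ) -> pd.DataFrame:
    """Per-slide chromatic correction of the pairing table."""
    if pairings.empty:
        return pairings.assign(group=[], cdx_um=[], cdy_um=[], cdz_um=[],
                               corrected_distance_um=[])
    pairings = pairings.copy()
    pairings["group"] = [group_of[f] for f in pairings["fov"]]
    out = []
    for _, grp in pairings.groupby("group", sort=True):
        disp = grp[["dx_um", "dy_um", "dz_um"]].to_numpy()
        corr = correct_chromatic_shift(disp)
        grp = grp.assign(
            cdx_um=corr.corrected_displacements_um[:, 0],
            cdy_um=corr.corrected_displacements_um[:, 1],
            cdz_um=corr.corrected_displacements_um[:, 2],
            corrected_distance_um=corr.corrected_distances_um,
        )
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def run_pipeline(config: PipelineConfig,
                 stacks: Optional[Dict[str, MultiChannelStack]] = None
                 ) -> RunManifest:
    """Execute the full pipeline.

    ``stacks`` allows in-memory input (name -> stack), e.g. straight from
    the simulator; otherwise ``config.inputs`` paths/globs are read from
    disk.  Results (detections.csv, pairings.csv, manifest.json) are
    written to ``config.outdir``.
    """
    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), version=__version__)

    if stacks is None:
        import glob as _glob

        paths: List[Path] = []
        for pat in config.inputs:
            hits = sorted(Path(p) for p in _glob.glob(pat)) if any(
                ch in pat for ch in "*?[") else [Path(pat)]
            paths.extend(hits)
        if not paths:
            raise FileNotFoundError("no input stacks found")
        stacks = {}
        for p in paths:
            try:
                stacks[p.stem] = fio.read_stack(p, voxel_um=config.voxel_um)
            except Exception as exc:  # unreadable stack: skip and log
                manifest.fovs.append({
                    "fov": p.stem, "error": str(exc),
                    "nuclei": {"seeded": 0, "accepted": 0, "rejected": {}},
                    "pairings": {"attempted": 0, "accepted": 0,
                                 "rejected": {}},
                    "spots": 0,
                })

    det_tables, pair_tables = [], []
    for name in sorted(stacks):
        res = process_fov(stacks[name], config, fov_id=name)
        manifest.fovs.append(res["counts"])
        det_tables.append(res["detections"])
        pair_tables.append(res["pairings"])

    detections = pd.concat(det_tables, ignore_index=True) if det_tables \
        else pd.DataFrame()
    pairings = pd.concat(pair_tables, ignore_index=True) if pair_tables \
        else pd.DataFrame()
    group_of = {name: _slide_key(name, config.group_pattern)
                for name in stacks}
    pairings = _correct_groups(pairings, group_of)

    manifest.totals = {
        "fovs": len(manifest.fovs),
        "nuclei_accepted": sum(f["nuclei"]["accepted"]
                               for f in manifest.fovs),
        "pairings_accepted": sum(f["pairings"]["accepted"]
                                 for f in manifest.fovs),
        "spots": int(sum(f["spots"] for f in manifest.fovs)),
    }

    detections.to_csv(outdir / "detections.csv", index=False)
    pairings.to_csv(outdir / "pairings.csv", index=False)
    fio.write_json(outdir / "manifest.json", {
        "config": manifest.config, "version": manifest.version,
        "fovs": manifest.fovs, "totals": manifest.totals,
        "counts_reconcile": manifest.reconcile(),
    })
    if manifest.totals["nuclei_accepted"] == 0:
        raise RuntimeError("no nuclei accepted in any field of view")
    return manifest


def dataset_from_pairings(pairings: pd.DataFrame,
                          label: str) -> DistanceDataset:
    """Distance dataset (corrected distances, cell ids) from a pairing
    table produced by :func:`run_pipeline`."""
    ids = (pairings["fov"].astype(str) + "/"
           + pairings["nucleus_id"].astype(str))
    return DistanceDataset(label,
                           pairings["corrected_distance_um"].to_numpy(),
                           ids.to_numpy())


def compare_conditions(a: DistanceDataset, b: DistanceDataset,
                       config: Optional[PipelineConfig] = None,
                       bootstrap_sizes: Optional[Sequence[int]] = None
                       ) -> dict:
    """Condition comparison: KS test, interaction splits, tail fraction,
    and (optionally) the bootstrap minimum-cell-number curve."""
    config = config or PipelineConfig()
    d_stat, p = ks_compare(a, b)
    report = {
        "labels": [a.label, b.label],
        "n": [int(a.distances_um.size), int(b.distances_um.size)],
        "n_cells": [a.n_cells, b.n_cells],
        "ks": {"D": d_stat, "p": p},
        "tail_fraction_beyond_ref_q99": tail_quantile_flag(a, b, q=0.99),
    }
    for ds, tag in ((a, "a"), (b, "b")):
        entry = {}
        if config.fixed_threshold_um:
            sp = split_at(ds.distances_um, config.fixed_threshold_um)
            entry["fixed"] = {"threshold_um": sp.threshold_um,
                              "interacting_fraction":
                              sp.interacting_fraction}
        try:
            rs = rosin_threshold(ds.distances_um, config.bin_width_um)
            entry["rosin"] = {"threshold_um": rs.threshold_um,
                              "interacting_fraction":
                              rs.interacting_fraction}
        except ValueError as exc:
            entry["rosin"] = {"error": str(exc)}
        report[f"split_{tag}"] = entry
    if bootstrap_sizes is not None:
        br = bootstrap_min_cells(
            a, b, bootstrap_sizes, n_boot=config.bootstrap_n,
            alpha=config.bootstrap_alpha,
            criterion=config.bootstrap_criterion, seed=config.seed)
        report["bootstrap"] = {
            "sizes": br.sizes.tolist(),
            "fraction_significant": br.fraction_significant.tolist(),
            "min_cells": br.min_cells,
            "n_boot": br.n_boot, "alpha": br.alpha,
            "criterion": br.criterion,
        }
    return report
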
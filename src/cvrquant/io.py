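"""File I/O: NIfTI volumes, delimited capnograph traces, truth/result sidecars.

Dual-echo data are written as two 4D NIfTI files suffixed ``_e1`` / ``_e2``;
the capnograph trace is tab-separated text with columns ``time_s`` and
``co2_mmHg``; ground-truth parameters and analysis results go to JSON/YAML
sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import (
    AcquisitionTimeline,
    CapnoTrace,
    DualEchoSeries,
    PCImagePair,
    TissueMasks,
)
from .synthetic import GroundTruthParams, SubjectData

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_trace",
    "load_trace",
    "save_subject",
    "load_subject",
    "load_cohort_csv",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), zooms


def save_trace(path, trace: CapnoTrace) -> None:
    df = pd.DataFrame({"time_s": trace.time, "co2_mmHg": trace.co2})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_trace(path, sample_rate: float | None = None) -> CapnoTrace:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy(dtype=float)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return CapnoTrace(
        time=t, co2=df["co2_mmHg"].to_numpy(dtype=float), sample_rate=sample_rate
    )


def save_subject(out_dir, data: SubjectData) -> None:
    """Write one subject's session to ``out_dir`` (NIfTI + TSV + YAML truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = data.masks.voxel_size
    save_nifti(out / "dualecho_e1.nii.gz", data.dual_echo.echo1, vs)
    save_nifti(out / "dualecho_e2.nii.gz", data.dual_echo.echo2, vs)
    for name in ("gm", "wm", "wb"):
        save_nifti(out / f"mask_{name}.nii.gz", getattr(data.masks, name), vs)
    for pair, tag in ((data.pc_ra, "ra"), (data.pc_hc, "hc")):
        area_side = float(np.sqrt(pair.voxel_area)) * 10.0  # cm^2 -> mm side
        save_nifti(
            out / f"pc_{tag}_cd.nii.gz",
            pair.cd_magnitude[..., None],
            (area_side, area_side, 1.0),
        )
        save_nifti(
            out / f"pc_{tag}_velocity.nii.gz",
            pair.velocity[..., None],
            (area_side, area_side, 1.0),
        )
    save_trace(out / "capnograph.tsv", data.trace)
    tl = data.dual_echo.timeline
    meta = {
        "timeline": {
            "tr": tl.tr,
            "n_volumes": tl.n_volumes,
            "gas_switch_time": tl.gas_switch_time,
            "ra_window": list(tl.ra_window),
            "hc_window": list(tl.hc_window),
            "first_volume_type": tl.first_volume_type,
        },
        "pc": {"voxel_area_cm2": data.pc_ra.voxel_area, "venc": data.pc_ra.venc},
    }
    if data.truth is not None:
        meta["truth"] = dataclasses.asdict(data.truth)
    with open(out / "subject.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_subject(in_dir) -> SubjectData:
    """Read a subject session previously written by :func:`save_subject`."""
    src = Path(in_dir)
    with open(src / "subject.yaml") as fh:
        meta = yaml.safe_load(fh)
    tl_meta = meta["timeline"]
    timeline = AcquisitionTimeline(
        tr=tl_meta["tr"],
        n_volumes=tl_meta["n_volumes"],
        gas_switch_time=tl_meta["gas_switch_time"],
        ra_window=tuple(tl_meta["ra_window"]),
        hc_window=tuple(tl_meta["hc_window"]),
        first_volume_type=tl_meta["first_volume_type"],
    )
    e1, vs = load_nifti(src / "dualecho_e1.nii.gz")
    e2, _ = load_nifti(src / "dualecho_e2.nii.gz")
    dual = DualEchoSeries(echo1=e1, echo2=e2, timeline=timeline)
    masks = TissueMasks(
        gm=load_nifti(src / "mask_gm.nii.gz")[0] > 0.5,
        wm=load_nifti(src / "mask_wm.nii.gz")[0] > 0.5,
        wb=load_nifti(src / "mask_wb.nii.gz")[0] > 0.5,
        voxel_size=vs,
    )
    pc_meta = meta["pc"]
    pairs = {}
    for tag, state in (("ra", "RA"), ("hc", "HC")):
        cd, _ = load_nifti(src / f"pc_{tag}_cd.nii.gz")
        vel, _ = load_nifti(src / f"pc_{tag}_velocity.nii.gz")
        pairs[tag] = PCImagePair(
            cd_magnitude=cd[..., 0],
            velocity=vel[..., 0],
            voxel_area=pc_meta["voxel_area_cm2"],
            venc=pc_meta["venc"],
            state=state,
        )
    truth = None
    if "truth" in meta:
        truth = GroundTruthParams(**meta["truth"])
    return SubjectData(
        dual_echo=dual,
        masks=masks,
        trace=load_trace(src / "capnograph.tsv"),
        pc_ra=pairs["ra"],
        pc_hc=pairs["hc"],
        truth=truth,
    )


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a tidy cohort CVR table (see :func:`cvrquant.stats.summarize_cohort`)."""
    return pd.read_csv(path)


def save_result_json(path, result_dict: dict) -> None:
    with open(path, "w") as fh:
        json.dump(result_dict, fh, indent=2)
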
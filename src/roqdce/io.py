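"""Serialization: curve CSV, phantom-cohort directories, NIfTI maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicCurve, TimeGrid
from .protocol import ClinicalProtocol, MultiPhasicSample, PhantomCohort, PhantomSubject
from .pk import AIFModelParams

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_cohort",
    "read_cohort",
    "write_param_maps_nifti",
    "read_dynamic_nifti",
]


def write_curve_csv(curve: DynamicCurve, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind={curve.kind}\n")
        pd.DataFrame({"time_s": curve.grid.times, "value": curve.values}).to_csv(
            fh, index=False
        )


def read_curve_csv(path) -> DynamicCurve:
    path = Path(path)
    kind = "concentration"
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# kind="):
            kind = first.strip().split("=", 1)[1]
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    t = df["time_s"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    grid = TimeGrid(n_steps=len(t), dt=dt, t0=float(t[0]))
    return DynamicCurve(grid, df["value"].to_numpy(), kind=kind)


def write_cohort(cohort: PhantomCohort, outdir, config_hash: str = "") -> None:
    """One directory per subject: long-format curves.csv and truth.csv,
    plus a cohort-level JSON manifest with the seed and config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "rng_seed": cohort.rng_seed,
        "config_hash": config_hash,
        "noise_sigma": cohort.noise_sigma,
        "grid": {"n_steps": cohort.grid.n_steps, "dt": cohort.grid.dt, "t0": cohort.grid.t0},
        "protocol": {
            "n_post_phases": cohort.protocol.n_post_phases,
            "acq_window_s": cohort.protocol.acq_window_s,
            "gap_s": cohort.protocol.gap_s,
            "precontrast_time_s": cohort.protocol.precontrast_time_s,
            "arterial_offset_s": cohort.protocol.arterial_offset_s,
        },
        "subjects": [],
    }
    for s in cohort.subjects:
        sdir = outdir / s.subject_id
        sdir.mkdir(exist_ok=True)
        V, T = s.ref_curves.shape
        long = pd.DataFrame(
            {
                "voxel_id": np.repeat(np.arange(V), T),
                "time_s": np.tile(cohort.grid.times, V),
                "ref": s.ref_curves.ravel(),
            }
        )
        for j in range(4):
            long[f"phase{j}"] = np.repeat(s.samples[:, j], T)
        long.to_csv(sdir / "curves.csv", index=False)
        truth = pd.DataFrame(s.truth, columns=["ktrans", "kep", "ve"])
        truth.insert(0, "voxel_id", np.arange(V))
        truth["group"] = s.roi
        truth.to_csv(sdir / "truth.csv", index=False)
        pd.DataFrame({"time_s": cohort.grid.times, "value": s.aif_values}).to_csv(
            sdir / "aif.csv", index=False
        )
        manifest["subjects"].append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "aif_peak_time_s": s.aif_peak_time_s,
                "phase_times_s": list(map(float, s.phase_times_s)),
                "aif_phase_values": list(map(float, s.aif_sample.phase_values)),
                "n_voxels": int(V),
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_cohort(indir) -> PhantomCohort:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    grid = TimeGrid(**manifest["grid"])
    protocol = ClinicalProtocol(**manifest["protocol"])
    subjects = []
    for meta in manifest["subjects"]:
        sdir = indir / meta["subject_id"]
        truth_df = pd.read_csv(sdir / "truth.csv")
        long = pd.read_csv(sdir / "curves.csv")
        V = meta["n_voxels"]
        ref = long["ref"].to_numpy().reshape(V, grid.n_steps)
        samples = (
            long.groupby("voxel_id")[[f"phase{j}" for j in range(4)]].first().to_numpy()
        )
        aif_values = pd.read_csv(sdir / "aif.csv")["value"].to_numpy()
        phase_times = np.array(meta["phase_times_s"])
        subjects.append(
            PhantomSubject(
                subject_id=meta["subject_id"],
                group=meta["group"],
                aif_params=AIFModelParams(),
                aif_values=aif_values,
                aif_peak_time_s=meta["aif_peak_time_s"],
                phase_times_s=phase_times,
                aif_sample=MultiPhasicSample(
                    np.array(meta["aif_phase_values"]), phase_times, source_kind="aif"
                ),
                roi=truth_df["group"].to_numpy(),
                truth=truth_df[["ktrans", "kep", "ve"]].to_numpy(),
                ref_curves=ref,
                samples=samples,
            )
        )
    return PhantomCohort(
        grid, protocol, subjects, manifest["noise_sigma"], manifest["rng_seed"]
    )


def write_param_maps_nifti(maps: dict[str, np.ndarray], path_prefix, affine=None) -> list[Path]:
    """Write one 3-D NIfTI volume per parameter (ktrans/kep/ve)."""
    affine = np.eye(4) if affine is None else affine
    out = []
    for name, vol in maps.items():
        p = Path(f"{path_prefix}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), p)
        out.append(p)
    return out


def read_dynamic_nifti(path, dt_s: float = 2.0) -> tuple[np.ndarray, TimeGrid]:
    """Read a 4-D dynamic volume; returns (X, Y, Z, T) data and its grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D dynamic volume, got shape {data.shape}")
    return data, TimeGrid(n_steps=data.shape[3], dt=dt_s)
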
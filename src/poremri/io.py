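"""Readers and writers: radius CSVs, series CSVs, NIfTI datasets, reports.

File conventions
----------------
* Radius samples: CSV with a required header, column ``radius_um`` and an
  optional ``count`` column (binned histograms act as weighted samples).
* Spherical-mean series: CSV with an axis column named ``TE_ms`` or
  ``b_s_mm2`` (the name fixes the axis kind), a ``signal`` column and an
  optional ``sd`` column.
* Imaging datasets: 4D NIfTI with FSL-style ``bval``/``bvec`` text files
  (one row of b-values; three rows of direction components) plus a TE table
  CSV (``volume_index, TE_ms, b_s_mm2``) because no standard sidecar encodes
  per-volume TE; optional binary NIfTI mask.

Readers apply range sanity checks so silently wrong units (b in ms/um^2,
TE in seconds) are rejected unless explicitly overridden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core_models import RadiusSample
from .estimation import SphericalMeanSeries

__all__ = [
    "read_radius_sample",
    "write_radius_sample",
    "read_series",
    "write_series",
    "write_simulated_dataset",
    "load_dataset",
    "DatasetSeries",
    "write_report",
]

_AXIS_COLUMNS = {"TE_ms": "TE", "b_s_mm2": "b"}


def read_radius_sample(path: str | Path, label: str | None = None) -> RadiusSample:
    """Read a radius sample CSV (columns ``radius_um``, optional ``count``)."""
    path = Path(path)
    df = pd.read_csv(path)
    if "radius_um" not in df.columns:
        raise ValueError(
            f"{path}: expected a 'radius_um' column, found {list(df.columns)}"
        )
    radii = df["radius_um"].to_numpy(float)
    if radii.size and np.nanmax(radii) > 1000:
        raise ValueError(
            f"{path}: radii up to {np.nanmax(radii):.3g} um look like nm; "
            "convert to micrometres"
        )
    counts = df["count"].to_numpy(float) if "count" in df.columns else None
    return RadiusSample(radii=radii, counts=counts, label=label or path.stem)


def write_radius_sample(sample: RadiusSample, path: str | Path) -> None:
    df = pd.DataFrame({"radius_um": sample.radii})
    if sample.counts is not None:
        df["count"] = sample.counts
    df.to_csv(path, index=False)


def read_series(path: str | Path, allow_unit_override: bool = False) -> SphericalMeanSeries:
    """Read a spherical-mean series CSV; the axis column name sets the kind."""
    path = Path(path)
    df = pd.read_csv(path)
    axis_cols = [c for c in df.columns if c in _AXIS_COLUMNS]
    if len(axis_cols) != 1:
        raise ValueError(
            f"{path}: expected exactly one axis column among "
            f"{sorted(_AXIS_COLUMNS)}, found {list(df.columns)}"
        )
    axis_col = axis_cols[0]
    kind = _AXIS_COLUMNS[axis_col]
    if "signal" not in df.columns:
        raise ValueError(f"{path}: missing 'signal' column")
    axis = df[axis_col].to_numpy(float)
    if not allow_unit_override:
        if kind == "b" and axis.max() < 100:
            raise ValueError(
                f"{path}: b-values up to {axis.max():.3g} look like ms/um^2; "
                "expected s/mm^2 (pass allow_unit_override to accept)"
            )
        if kind == "TE" and axis.max() < 1:
            raise ValueError(
                f"{path}: TEs up to {axis.max():.3g} look like seconds; "
                "expected ms (pass allow_unit_override to accept)"
            )
    sd = df["sd"].to_numpy(float) if "sd" in df.columns else None
    return SphericalMeanSeries(
        axis_kind=kind, axis=axis, mean_signal=df["signal"].to_numpy(float),
        sd_signal=sd,
    )


def write_series(series: SphericalMeanSeries, path: str | Path) -> None:
    axis_col = "TE_ms" if series.axis_kind == "TE" else "b_s_mm2"
    df = pd.DataFrame({axis_col: series.axis, "signal": series.mean_signal})
    if series.sd_signal is not None:
        df["sd"] = series.sd_signal
    df.to_csv(path, index=False)


def write_simulated_dataset(dataset, outdir: str | Path, sample: RadiusSample | None = None) -> dict:
    """Write a simulated acquisition in the reader formats.

    Produces ``dwi.nii.gz`` (voxels along the first axis), ``dwi.bval``,
    ``dwi.bvec``, ``te_table.csv``, ``mask.nii.gz`` and, when a sample is
    given, ``radii.csv``.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = dataset.scheme
    n_vox, n_vol = dataset.data.shape
    img = dataset.data.reshape(n_vox, 1, 1, n_vol).astype(np.float32)
    affine = np.eye(4)
    paths = {
        "dwi": outdir / "dwi.nii.gz",
        "bval": outdir / "dwi.bval",
        "bvec": outdir / "dwi.bvec",
        "te_table": outdir / "te_table.csv",
        "mask": outdir / "mask.nii.gz",
    }
    nib.save(nib.Nifti1Image(img, affine), paths["dwi"])
    np.savetxt(paths["bval"], scheme["b_s_mm2"].to_numpy()[None, :], fmt="%.1f")
    np.savetxt(paths["bvec"], scheme[["gx", "gy", "gz"]].to_numpy().T, fmt="%.8f")
    pd.DataFrame(
        {
            "volume_index": np.arange(n_vol),
            "TE_ms": scheme["TE_ms"].to_numpy(),
            "b_s_mm2": scheme["b_s_mm2"].to_numpy(),
        }
    ).to_csv(paths["te_table"], index=False)
    mask = np.ones((n_vox, 1, 1), dtype=np.uint8)
    nib.save(nib.Nifti1Image(mask, affine), paths["mask"])
    if sample is not None:
        paths["radii"] = outdir / "radii.csv"
        write_radius_sample(sample, paths["radii"])
    return {k: str(v) for k, v in paths.items()}


@dataclass
class DatasetSeries:
    """Spherical-mean summaries of a loaded 4D acquisition.

    ``table`` has one row per (b, TE) diffusion-weighted shell with the
    across-voxel mean and SD of the per-voxel spherical means; ``b0_data``
    holds the per-voxel b0 values (n_voxels, n_b0) with their TEs in
    ``b0_TE``.
    """

    table: pd.DataFrame
    b0_data: np.ndarray
    b0_TE: np.ndarray
    n_voxels: int

    def te_series(self, b: float | None = None) -> SphericalMeanSeries:
        """Series vs TE at fixed b (default: the b with the most TE points)."""
        t = self.table
        if b is None:
            counts = t.groupby("b_s_mm2")["TE_ms"].nunique()
            b = float(counts.idxmax())
        sel = t[np.isclose(t["b_s_mm2"], b)].sort_values("TE_ms")
        if len(sel) < 1:
            raise ValueError(f"no shells at b={b}")
        return SphericalMeanSeries(
            axis_kind="TE",
            axis=sel["TE_ms"].to_numpy(),
            mean_signal=sel["mean"].to_numpy(),
            sd_signal=sel["sd"].to_numpy(),
            n_voxels=self.n_voxels,
        )

    def b_series(self, TE: float | None = None) -> SphericalMeanSeries:
        """Series vs b at fixed TE (default: the TE with the most b shells)."""
        t = self.table
        if TE is None:
            counts = t.groupby("TE_ms")["b_s_mm2"].nunique()
            TE = float(counts.idxmax())
        sel = t[np.isclose(t["TE_ms"], TE)].sort_values("b_s_mm2")
        if len(sel) < 1:
            raise ValueError(f"no shells at TE={TE}")
        return SphericalMeanSeries(
            axis_kind="b",
            axis=sel["b_s_mm2"].to_numpy(),
            mean_signal=sel["mean"].to_numpy(),
            sd_signal=sel["sd"].to_numpy(),
            n_voxels=self.n_voxels,
        )


def load_dataset(
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    te_table_path: str | Path,
    mask_path: str | Path | None = None,
    b0_threshold: float = 50.0,
    allow_unit_override: bool = False,
) -> DatasetSeries:
    """Load a 4D acquisition and reduce it to spherical-mean series.

    Volumes are grouped by (b, TE); per-voxel spherical means (arithmetic
    mean over the directions of each group) are aggregated across masked
    voxels into per-shell mean and SD.  Volume counts must agree across the
    NIfTI, bval, bvec and TE table; the mask must be binary.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected a 4D volume, got {data.ndim}D")
    n_vol = data.shape[3]
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape == (n_vol, 3):
        bvecs = bvecs.T
    if bvecs.shape != (3, n_vol) or bvals.size != n_vol:
        raise ValueError(
            f"volume count mismatch: nifti has {n_vol}, bval {bvals.size}, "
            f"bvec {bvecs.shape}"
        )
    te = pd.read_csv(te_table_path)
    for col in ("volume_index", "TE_ms"):
        if col not in te.columns:
            raise ValueError(f"{te_table_path}: missing column {col!r}")
    te = te.set_index("volume_index")
    if not set(range(n_vol)) <= set(te.index):
        missing = sorted(set(range(n_vol)) - set(te.index))[:5]
        raise ValueError(f"TE table misses volume indices, e.g. {missing}")
    TE_ms = te.loc[np.arange(n_vol), "TE_ms"].to_numpy(float)
    if not allow_unit_override:
        if bvals.max() > 0 and bvals.max() < 100:
            raise ValueError(
                "b-values look like ms/um^2; expected s/mm^2 "
                "(pass allow_unit_override to accept)"
            )
        if TE_ms.max() < 1:
            raise ValueError(
                "TEs look like seconds; expected ms "
                "(pass allow_unit_override to accept)"
            )

    flat = data.reshape(-1, n_vol)
    if mask_path is not None:
        m = np.asarray(nib.load(str(mask_path)).dataobj)
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{mask_path}: mask must be binary, found {vals[:5]}")
        mflat = m.reshape(-1).astype(bool)
        if mflat.size != flat.shape[0]:
            raise ValueError("mask grid does not match the data grid")
        flat = flat[mflat]
    if flat.shape[0] == 0:
        raise ValueError("no voxels inside the mask")

    is_b0 = bvals <= b0_threshold
    recs = []
    key = pd.DataFrame({"b": bvals, "TE": TE_ms, "vol": np.arange(n_vol)})
    for (b, TE), g in key[~is_b0].groupby(["b", "TE"], sort=True):
        per_voxel = flat[:, g["vol"].to_numpy()].mean(axis=1)
        recs.append(
            (b, TE, per_voxel.mean(),
             per_voxel.std(ddof=1) if per_voxel.size > 1 else 0.0, len(g))
        )
    table = pd.DataFrame(
        recs, columns=["b_s_mm2", "TE_ms", "mean", "sd", "n_directions"]
    )
    b0_cols = key[is_b0]["vol"].to_numpy()
    return DatasetSeries(
        table=table,
        b0_data=flat[:, b0_cols],
        b0_TE=TE_ms[b0_cols],
        n_voxels=flat.shape[0],
    )


def write_report(path: str | Path, payload: dict) -> None:
    """Write a deterministic JSON report (sorted keys, no timestamps)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
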
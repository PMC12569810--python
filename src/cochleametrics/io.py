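"""Readers/writers for the pipeline's interchange formats.

* photon traces — two-column text ``(bin_start_s, counts)`` with a ``#``-header
  carrying bin width and background rate, or an HDF5 container with
  ``/counts``, ``/bin_width`` and a metadata group;
* images — single-plane or stacked 16-bit TIFF;
* ROIs — JSON: a header block with ``pixel_size_um`` plus named vertex lists in
  pixel coordinates;
* waveforms — two-column text ``(time_s, volts)`` with a sample-rate header;
* tidy tables — CSV with explicit schema validation (missing columns and dtype
  violations are named).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile

from cochleametrics.fcs import PhotonTrace
from cochleametrics.morphometry import SectionGeometry

__all__ = [
    "write_photon_trace_text", "read_photon_trace_text",
    "write_photon_trace_h5", "read_photon_trace_h5",
    "write_image", "read_image",
    "write_rois", "read_rois",
    "write_waveform", "read_waveform",
    "write_table", "read_table",
]


# -- photon traces -----------------------------------------------------------

def write_photon_trace_text(path: str | Path, trace: PhotonTrace) -> None:
    path = Path(path)
    header = (
        f"# bin_width_s={trace.bin_width!r}\n"
        f"# background_rate_hz={trace.background_rate!r}\n"
        f"# site_label={trace.site_label or ''}\n"
        "# columns: bin_start_s counts\n"
    )
    starts = np.arange(trace.counts.size) * trace.bin_width
    body = np.column_stack([starts, trace.counts])
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=["%.9g", "%d"])


def read_photon_trace_text(path: str | Path) -> PhotonTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("photon-trace text file must have two columns")
    return PhotonTrace(
        counts=data[:, 1].astype(int),
        bin_width=float(meta["bin_width_s"]),
        background_rate=float(meta.get("background_rate_hz", 0.0)),
        site_label=meta.get("site_label") or None,
    )


def write_photon_trace_h5(path: str | Path, trace: PhotonTrace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=trace.counts.astype(np.int64))
        f.create_dataset("bin_width", data=trace.bin_width)
        g = f.create_group("metadata")
        g.attrs["background_rate_hz"] = trace.background_rate
        g.attrs["site_label"] = trace.site_label or ""
        if trace.ground_truth is not None:
            g.attrs["ground_truth_json"] = json.dumps(
                {k: v for k, v in trace.ground_truth.items() if not isinstance(v, np.ndarray)},
                default=str,
            )


def read_photon_trace_h5(path: str | Path) -> PhotonTrace:
    with h5py.File(path, "r") as f:
        g = f["metadata"]
        gt = g.attrs.get("ground_truth_json")
        return PhotonTrace(
            counts=f["counts"][()],
            bin_width=float(f["bin_width"][()]),
            background_rate=float(g.attrs.get("background_rate_hz", 0.0)),
            site_label=g.attrs.get("site_label") or None,
            ground_truth=json.loads(gt) if gt else None,
        )


# -- images ------------------------------------------------------------------

def write_image(path: str | Path, image: np.ndarray, pixel_size_um: float | None = None) -> None:
    meta = {"pixel_size_um": pixel_size_um} if pixel_size_um else None
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint16), metadata=meta)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


# -- ROIs --------------------------------------------------------------------

def write_rois(path: str | Path, geometry: SectionGeometry) -> None:
    doc = {
        "pixel_size_um": geometry.pixel_size,
        "rois": {
            "tm": geometry.tm_roi.tolist(),
            "ooc": geometry.ooc_roi.tolist(),
            "reticular_lamina": geometry.reticular_lamina.tolist(),
        },
    }
    if geometry.width_line is not None:
        doc["rois"]["width_line"] = np.asarray(geometry.width_line).tolist()
    if geometry.basilar_membrane is not None:
        doc["rois"]["basilar_membrane"] = np.asarray(geometry.basilar_membrane).tolist()
    Path(path).write_text(json.dumps(doc, indent=1))


def read_rois(path: str | Path) -> SectionGeometry:
    doc = json.loads(Path(path).read_text())
    for key in ("pixel_size_um", "rois"):
        if key not in doc:
            raise ValueError(f"ROI file missing {key!r}")
    rois = doc["rois"]
    for key in ("tm", "ooc", "reticular_lamina"):
        if key not in rois:
            raise ValueError(f"ROI file missing roi {key!r}")
    return SectionGeometry(
        tm_roi=np.asarray(rois["tm"], float),
        ooc_roi=np.asarray(rois["ooc"], float),
        reticular_lamina=np.asarray(rois["reticular_lamina"], float),
        width_line=np.asarray(rois["width_line"], float) if "width_line" in rois else None,
        basilar_membrane=(
            np.asarray(rois["basilar_membrane"], float) if "basilar_membrane" in rois else None
        ),
        pixel_size=float(doc["pixel_size_um"]),
    )


# -- waveforms ---------------------------------------------------------------

def write_waveform(path: str | Path, waveform: np.ndarray, rate: float) -> None:
    t = np.arange(len(waveform)) / rate
    with Path(path).open("w") as fh:
        fh.write(f"# sample_rate_hz={rate!r}\n# columns: time_s volts\n")
        np.savetxt(fh, np.column_stack([t, waveform]), fmt="%.12g")


def read_waveform(path: str | Path) -> tuple[np.ndarray, float]:
    rate = None
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "sample_rate_hz=" in line:
                rate = float(line.split("=", 1)[1])
    if rate is None:
        raise ValueError("waveform file is missing the sample_rate_hz header")
    data = np.loadtxt(path, comments="#")
    return data[:, 1], rate


# -- tidy tables -------------------------------------------------------------

def write_table(path: str | Path, table: pd.DataFrame, schema: Mapping[str, str] | None = None) -> None:
    if schema is not None:
        _validate_schema(table, schema)
    table.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if schema is not None:
        _validate_schema(df, schema)
    return df


def _validate_schema(df: pd.DataFrame, schema: Mapping[str, str]) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    kinds = {"float": "fc", "int": "iu", "str": "OUS", "bool": "b"}
    for col, want in schema.items():
        kind = df[col].dtype.kind
        if want in kinds and kind not in kinds[want]:
            # integers are acceptable where floats are requested
            if not (want == "float" and kind in "iu"):
                raise ValueError(f"column {col!r} has dtype kind {kind!r}; expected {want}")
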
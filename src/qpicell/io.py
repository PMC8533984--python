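"""Reading and writing pipeline artefacts.

Rasters travel as 32-bit float TIFF (tifffile); acquisition metadata as
sidecar JSON; feature tables and ground truth as CSV; fitted classifiers as
joblib binaries with a JSON sidecar recording spec, task and feature names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CarrierSpec, InterferogramFrame, PhaseImage


def write_phase_tiff(path, phase: PhaseImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, phase.phase.astype(np.float32))
    meta = dict(
        pixel_pitch_um=phase.pixel_pitch_um,
        wavelength_nm=phase.wavelength_nm,
        units="radians",
    )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_phase_tiff(path, meta_path=None) -> PhaseImage:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    kwargs = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = dict(
            pixel_pitch_um=meta.get("pixel_pitch_um", 0.35),
            wavelength_nm=meta.get("wavelength_nm", 633.0),
        )
    return PhaseImage(data, **kwargs)


def read_interferogram(path, meta_path=None) -> InterferogramFrame:
    """Read an 8/16-bit grayscale TIFF/PNG hologram with JSON metadata."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        from PIL import Image

        data = np.asarray(Image.open(path).convert("I"))
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    kwargs = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = dict(
            pixel_pitch_um=meta.get("pixel_pitch_um", 0.35),
            wavelength_nm=meta.get("wavelength_nm", 633.0),
        )
        if "carrier_fx" in meta:
            kwargs["carrier_hint"] = CarrierSpec(
                fx=meta["carrier_fx"], fy=meta["carrier_fy"]
            )
    return InterferogramFrame(np.asarray(data, dtype=float), **kwargs)


def write_interferogram(path, frame: InterferogramFrame) -> None:
    path = Path(path)
    tifffile.imwrite(path, frame.intensity.astype(np.float32))
    meta = dict(
        pixel_pitch_um=frame.pixel_pitch_um, wavelength_nm=frame.wavelength_nm
    )
    if frame.carrier_hint is not None:
        meta["carrier_fx"] = frame.carrier_hint.fx
        meta["carrier_fy"] = frame.carrier_hint.fy
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_labels_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.int32))


def write_dataset(items, outdir, spec=None) -> None:
    """Write a labeled phantom dataset: phase TIFFs, ground-truth CSV, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for item in items:
        write_phase_tiff(outdir / f"{item.cell_id}_phase.tif", item.phase)
        rows.append(
            dict(
                cell_id=item.cell_id,
                line_label=item.line,
                state_label=item.state,
                true_volume_um3=item.phantom.true_volume,
                true_mean_height_um=item.phantom.true_mean_height,
                true_surface_area_um2=item.phantom.true_surface_area,
                projected_area_um2=item.phantom.projected_area_um2,
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "ground_truth.csv", index=False)
    manifest = dict(n_cells=len(rows))
    if spec is not None:
        manifest["spec"] = {
            k: v
            for k, v in dataclasses.asdict(spec).items()
            if isinstance(v, (int, float, str, bool, list, tuple)) or v is None
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def save_model(path, model) -> None:
    import joblib

    path = Path(path)
    joblib.dump(model, path)
    sidecar = dict(
        task=model.task,
        feature_names=list(model.feature_names),
        classes=list(model.classes),
        spec=dataclasses.asdict(model.spec),
    )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path):
    import joblib

    return joblib.load(Path(path))
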
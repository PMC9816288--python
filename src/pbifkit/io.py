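"""Readers and writers for the package's on-disk formats.

Conventions: times are minutes inside the package; NIfTI frame-timing
sidecars use seconds (converted on read).  TAC CSV files carry the header
``frame_start_min,frame_end_min,value_kBq_ml`` with '.' decimals; floats
are written with shortest round-trip formatting so read(write(x)) is
value-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .input_function import FengParams, SampledCurve
from .pbif import PopulationInputFunction, ScaledPBIF, dense_grid
from .synthetic import FrameSchedule

__all__ = [
    "read_tac_csv",
    "write_tac_csv",
    "read_feng_params",
    "write_feng_params",
    "read_pbif",
    "write_pbif",
    "write_dynamic_nifti",
    "read_dynamic_nifti",
    "write_label_map",
    "read_label_map",
]

TAC_HEADER = "frame_start_min,frame_end_min,value_kBq_ml"


def write_tac_csv(curve: SampledCurve, path) -> Path:
    path = Path(path)
    lines = [TAC_HEADER]
    for s, e, v in zip(curve.frame_start, curve.frame_end, curve.value):
        lines.append(f"{float(s)!r},{float(e)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_tac_csv(path, label: str | None = None) -> SampledCurve:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").strip().splitlines()
    if not lines or lines[0].strip() != TAC_HEADER:
        raise ValueError(f"{path}: expected header '{TAC_HEADER}', got '{lines[0] if lines else ''}'")
    data = np.array([[float(x) for x in ln.split(",")] for ln in lines[1:]])
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError(f"{path}: malformed TAC rows")
    return SampledCurve(data[:, 0], data[:, 1], data[:, 2], label or path.stem)


def write_feng_params(params: FengParams, path) -> Path:
    path = Path(path)
    doc = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def read_feng_params(path) -> FengParams:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return FengParams.from_dict(doc)


def write_pbif(pbif: PopulationInputFunction | ScaledPBIF, path, curve_csv=None) -> Path:
    """Persist a PBIF (or sPBIF) as YAML, optionally with its dense-curve CSV."""
    path = Path(path)
    if isinstance(pbif, ScaledPBIF):
        doc = {
            "kind": "sPBIF",
            "scale_factor": float(pbif.scale_factor),
            "window_min": [float(w) for w in pbif.window],
            "label": pbif.label,
            "base": _pbif_doc(pbif.base),
        }
        curve = pbif.curve
    else:
        doc = {"kind": "PBIF", **_pbif_doc(pbif)}
        curve = pbif.curve
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    if curve_csv is not None:
        write_tac_csv(curve, curve_csv)
    return path


def _pbif_doc(pbif: PopulationInputFunction) -> dict:
    return {
        "params": pbif.params.to_dict(),
        "mean_delay_min": float(pbif.mean_delay),
        "n_subjects": int(pbif.n_subjects),
        "T_ref_min": float(pbif.T_ref),
    }


def _pbif_from_doc(doc: dict) -> PopulationInputFunction:
    params = FengParams.from_dict(doc["params"])
    T_ref = float(doc["T_ref_min"])
    from .input_function import feng_eval, sampled_auc

    grid = dense_grid(T_ref)
    values = feng_eval(params, grid)
    n = grid.size
    edges = np.linspace(0.0, T_ref, n + 1)
    curve = SampledCurve(edges[:-1], edges[1:], values, "PBIF")
    curve = curve.scaled(1.0 / sampled_auc(curve, 0.0, T_ref))
    return PopulationInputFunction(
        params=params,
        mean_delay=float(doc["mean_delay_min"]),
        n_subjects=int(doc["n_subjects"]),
        curve=curve,
        T_ref=T_ref,
    )


def read_pbif(path) -> PopulationInputFunction | ScaledPBIF:
    """Load a PBIF/sPBIF YAML; the dense curve is re-tabulated from the params."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if doc.get("kind") == "sPBIF":
        base = _pbif_from_doc(doc["base"])
        return ScaledPBIF(
            base=base,
            scale_factor=float(doc["scale_factor"]),
            window=tuple(float(w) for w in doc["window_min"]),
            label=doc.get("label", ""),
        )
    return _pbif_from_doc(doc)


def write_dynamic_nifti(volume: np.ndarray, schedule: FrameSchedule, path) -> Path:
    """Write a 4D volume with a JSON frame-timing sidecar (seconds)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), np.eye(4)), path)
    sidecar = {
        "FrameTimesStart": [float(s) for s in schedule.start_s],
        "FrameDuration": [float(d) for d in schedule.duration_s],
        "Units": "s",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2) + "\n", encoding="utf-8")
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_dynamic_nifti(path) -> tuple[np.ndarray, FrameSchedule]:
    path = Path(path)
    volume = np.asarray(nib.load(path).get_fdata(), dtype=float)
    sidecar = json.loads(_sidecar_path(path).read_text(encoding="utf-8"))
    schedule = FrameSchedule(
        np.asarray(sidecar["FrameTimesStart"], dtype=float),
        np.asarray(sidecar["FrameDuration"], dtype=float),
    )
    if volume.ndim != 4 or volume.shape[-1] != schedule.n_frames:
        raise ValueError(
            f"{path}: volume shape {volume.shape} does not match sidecar "
            f"({schedule.n_frames} frames)"
        )
    return volume, schedule


def write_label_map(labels: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), np.eye(4)), path)
    return path


def read_label_map(path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).get_fdata(), dtype=np.int16)
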
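"""On-disk formats: HDF5 stores for cubes and RDM sequences, JSON/CSV
manifests.

Layouts
-------
Cube store: one group per sample, datasets ``real``/``imag`` (the complex
cube split into paired real arrays), attributes ``subject_id``, ``scene``,
``activity_class``, ``label``, ``seed``; the radar config is stored as JSON
on the root.

RDM store: one group per sample, dataset ``rdm`` (float32), the same
metadata attributes plus ``primary_bin`` and the pipeline provenance
(``doppler_window``, ``doppler_step``, ``band_width``, ``log_offset``).
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile

import h5py
import numpy as np
import pandas as pd

from .config import PipelineConfig, RadarConfig
from .pipeline import RDMSequence
from .simulate import DatasetManifest, ManifestRecord, RawRadarCube

_CUBE_ATTRS = ("subject_id", "scene", "activity_class", "label", "seed")


def atomic_write(path, write_fn):
    """Write to a temp file in the target directory, then rename."""
    path = str(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def _require_attr(group, name, sample_id):
    if name not in group.attrs:
        raise KeyError(f"missing attribute: {name} (sample {sample_id})")
    return group.attrs[name]


def write_cube_store(path, cubes, radar_cfg: RadarConfig | None = None):
    """``cubes`` yields either RawRadarCube or (ManifestRecord, RawRadarCube)."""
    radar_cfg = radar_cfg or RadarConfig()

    def _write(tmp):
        with h5py.File(tmp, "w") as fh:
            fh.attrs["radar_config"] = json.dumps(dataclasses.asdict(radar_cfg))
            for i, item in enumerate(cubes):
                record, cube = item if isinstance(item, tuple) else (None, item)
                sid = record.sample_id if record is not None else f"sample_{i:05d}"
                grp = fh.create_group(sid)
                grp.create_dataset("real", data=cube.data.real)
                grp.create_dataset("imag", data=cube.data.imag)
                grp.attrs["subject_id"] = cube.subject_id
                grp.attrs["scene"] = cube.scene
                grp.attrs["activity_class"] = cube.activity_class
                grp.attrs["label"] = int(cube.label)
                grp.attrs["seed"] = -1 if cube.seed is None else int(cube.seed)

    atomic_write(path, _write)


def read_cube_store(path) -> dict[str, RawRadarCube]:
    out = {}
    with h5py.File(path, "r") as fh:
        for sid in sorted(fh.keys()):
            grp = fh[sid]
            for attr in _CUBE_ATTRS:
                _require_attr(grp, attr, sid)
            if "real" not in grp or "imag" not in grp:
                raise KeyError(f"missing datasets real/imag (sample {sid})")
            data = grp["real"][()] + 1j * grp["imag"][()]
            seed = int(grp.attrs["seed"])
            out[sid] = RawRadarCube(
                data=data,
                subject_id=str(grp.attrs["subject_id"]),
                scene=str(grp.attrs["scene"]),
                activity_class=str(grp.attrs["activity_class"]),
                label=int(grp.attrs["label"]),
                seed=None if seed == -1 else seed,
            )
    return out


def write_rdm_store(path, sequences: dict[str, RDMSequence],
                    pipeline_cfg: PipelineConfig | None = None):
    pipeline_cfg = pipeline_cfg or PipelineConfig()

    def _write(tmp):
        with h5py.File(tmp, "w") as fh:
            fh.attrs["pipeline_config"] = json.dumps(
                dataclasses.asdict(pipeline_cfg))
            for sid, seq in sequences.items():
                grp = fh.create_group(sid)
                grp.create_dataset("rdm", data=seq.data.astype(np.float32))
                grp.create_dataset("frame_times", data=seq.frame_times)
                grp.attrs["subject_id"] = seq.subject_id
                grp.attrs["scene"] = seq.scene
                grp.attrs["activity_class"] = seq.activity_class
                grp.attrs["label"] = int(seq.label)
                grp.attrs["seed"] = -1 if seq.seed is None else int(seq.seed)
                grp.attrs["primary_bin"] = int(seq.primary_bin)
                grp.attrs["doppler_window"] = pipeline_cfg.doppler_window
                grp.attrs["doppler_step"] = pipeline_cfg.doppler_step
                grp.attrs["band_width"] = pipeline_cfg.band_width
                grp.attrs["log_offset"] = pipeline_cfg.log_offset

    atomic_write(path, _write)


def read_rdm_store(path, expected_shape=None) -> dict[str, RDMSequence]:
    out = {}
    with h5py.File(path, "r") as fh:
        for sid in sorted(fh.keys()):
            grp = fh[sid]
            for attr in _CUBE_ATTRS + ("primary_bin",):
                _require_attr(grp, attr, sid)
            data = grp["rdm"][()]
            if expected_shape is not None and data.shape != tuple(expected_shape):
                raise ValueError(
                    f"sample {sid}: shape {data.shape} != expected "
                    f"{tuple(expected_shape)}"
                )
            seed = int(grp.attrs["seed"])
            out[sid] = RDMSequence(
                data=data,
                primary_bin=int(grp.attrs["primary_bin"]),
                frame_times=grp["frame_times"][()],
                subject_id=str(grp.attrs["subject_id"]),
                scene=str(grp.attrs["scene"]),
                activity_class=str(grp.attrs["activity_class"]),
                label=int(grp.attrs["label"]),
                seed=None if seed == -1 else seed,
            )
    return out


def read_rdm_provenance(path) -> dict:
    with h5py.File(path, "r") as fh:
        return json.loads(fh.attrs["pipeline_config"])


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def manifest_to_json(manifest: DatasetManifest, path):
    payload = {
        "master_seed": manifest.master_seed,
        "records": [dataclasses.asdict(r) for r in manifest.records],
    }

    def _write(tmp):
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=1)

    atomic_write(path, _write)


def manifest_from_json(path) -> DatasetManifest:
    with open(path) as fh:
        payload = json.load(fh)
    records = [ManifestRecord(**r) for r in payload["records"]]
    return DatasetManifest(records, master_seed=payload["master_seed"])


def manifest_to_csv(manifest: DatasetManifest, path):
    df = pd.DataFrame([dataclasses.asdict(r) for r in manifest.records])
    atomic_write(path, lambda tmp: df.to_csv(tmp, index=False))
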
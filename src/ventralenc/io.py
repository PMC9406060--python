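"""Readers and writers: vim-1-layout datasets, checkpoints, reports.

The vim-1 release stores stimuli and estimated responses as MAT v7.3
(HDF5) files; dataset key names vary slightly by release, so the reader
takes a small key map with documented defaults instead of hard-coding.
Synthetic datasets are written in the same layout and re-read with the
same reader (drop-in).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import DatasetBundle, StimulusSet, VoxelResponses

__all__ = [
    "DEFAULT_KEYMAP",
    "DEFAULT_ROI_CODES",
    "EXPECTED_S1_SIZES",
    "read_vim1",
    "write_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "write_report",
    "SCHEMA_VERSION",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

#: HDF5 dataset names; ``{subject}`` is substituted (e.g. S1).
DEFAULT_KEYMAP = {
    "stim_train": "stimTrn",
    "stim_val": "stimVal",
    "resp_train": "dataTrn{subject}",
    "resp_val": "dataVal{subject}",
    "roi": "roi{subject}",
}

#: vim-1 ROI index codes -> labels (codes absent here are dropped).
DEFAULT_ROI_CODES = {1: "V1", 2: "V2", 6: "V4", 7: "LO"}

#: Published S1 voxel counts used for a sanity warning on read.
EXPECTED_S1_SIZES = {"V2": 2083, "V4": 1535, "LO": 928}


def _require(h5: h5py.File, key: str, path: Path) -> np.ndarray:
    if key not in h5:
        raise KeyError(
            f"{path}: missing dataset {key!r}; available top-level keys: {list(h5)}"
        )
    return np.asarray(h5[key])


def _open_hdf5(path) -> h5py.File:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(
            f"{path} is not an HDF5 (MAT v7.3) file; convert older MAT files "
            "with e.g. MATLAB's save -v7.3 or scipy + rewrite"
        ) from exc


def _orient_responses(resp: np.ndarray, n_samples: int) -> np.ndarray:
    """Return (n_samples, n_voxels), transposing if stored voxels-first."""
    if resp.shape[0] == n_samples:
        return resp
    if resp.shape[1] == n_samples:
        return resp.T
    raise ValueError(
        f"response matrix {resp.shape} matches neither orientation for {n_samples} samples"
    )


def read_vim1(
    stimuli_path,
    responses_path,
    subject: str = "S1",
    *,
    keymap: dict | None = None,
    roi_codes: dict | None = None,
) -> DatasetBundle:
    """Read a vim-1-layout dataset into a :class:`DatasetBundle`.

    Voxels with any missing (NaN) response are dropped with a logged
    count; ROI sizes deviating from the published S1 counts produce a
    warning, not an error.
    """
    km = {**DEFAULT_KEYMAP, **(keymap or {})}
    codes = dict(roi_codes or DEFAULT_ROI_CODES)
    spath, rpath = Path(stimuli_path), Path(responses_path)
    with _open_hdf5(spath) as h5:
        stim_train = np.asarray(_require(h5, km["stim_train"], spath), dtype=np.float64)
        stim_val = np.asarray(_require(h5, km["stim_val"], spath), dtype=np.float64)
    stimuli = StimulusSet(train=stim_train, val=stim_val)
    with _open_hdf5(rpath) as h5:
        resp_train = _require(h5, km["resp_train"].format(subject=subject), rpath)
        resp_val = _require(h5, km["resp_val"].format(subject=subject), rpath)
        roi_vec = np.ravel(_require(h5, km["roi"].format(subject=subject), rpath))
    resp_train = _orient_responses(np.asarray(resp_train, dtype=np.float64), stimuli.n_train)
    resp_val = _orient_responses(np.asarray(resp_val, dtype=np.float64), stimuli.n_val)
    if roi_vec.shape[0] != resp_train.shape[1]:
        raise ValueError(
            f"ROI vector length {roi_vec.shape[0]} does not match voxel count {resp_train.shape[1]}"
        )
    responses: dict[str, VoxelResponses] = {}
    for code, label in codes.items():
        idx = np.flatnonzero(roi_vec == code)
        if idx.size == 0:
            continue
        tr, va = resp_train[:, idx], resp_val[:, idx]
        good = np.isfinite(tr).all(axis=0) & np.isfinite(va).all(axis=0)
        dropped = int((~good).sum())
        if dropped:
            log.info("%s/%s: dropped %d voxels with missing data", subject, label, dropped)
        if not good.any():
            continue
        responses[label] = VoxelResponses(
            roi=label, train=tr[:, good], val=va[:, good], voxel_ids=idx[good]
        )
        expected = EXPECTED_S1_SIZES.get(label)
        if subject == "S1" and expected is not None and int(good.sum()) != expected:
            warnings.warn(
                f"{subject}/{label}: {int(good.sum())} voxels, expected {expected}",
                stacklevel=2,
            )
    return DatasetBundle(
        stimuli=stimuli,
        responses=responses,
        subject=subject,
        provenance={"stimuli_path": str(spath), "responses_path": str(rpath)},
    )


def write_dataset(bundle: DatasetBundle, path, *, keymap: dict | None = None) -> None:
    """Write a bundle in the vim-1 layout (single HDF5 file, both stimulus
    and response keys) so :func:`read_vim1` can re-read it."""
    km = {**DEFAULT_KEYMAP, **(keymap or {})}
    subject = bundle.subject
    rois = bundle.rois
    n_total = sum(bundle[r].n_voxels for r in rois)
    roi_vec = np.empty(n_total, dtype=np.int64)
    label_to_code = {v: k for k, v in DEFAULT_ROI_CODES.items()}
    tr = np.concatenate([bundle[r].train for r in rois], axis=1)
    va = np.concatenate([bundle[r].val for r in rois], axis=1)
    pos = 0
    for r in rois:
        nv = bundle[r].n_voxels
        roi_vec[pos : pos + nv] = label_to_code[r]
        pos += nv
    with h5py.File(path, "w") as h5:
        h5.create_dataset(km["stim_train"], data=bundle.stimuli.train)
        h5.create_dataset(km["stim_val"], data=bundle.stimuli.val)
        h5.create_dataset(km["resp_train"].format(subject=subject), data=tr)
        h5.create_dataset(km["resp_val"].format(subject=subject), data=va)
        h5.create_dataset(km["roi"].format(subject=subject), data=roi_vec)
        h5.attrs["provenance"] = json.dumps(bundle.provenance, sort_keys=True)


def save_checkpoint(state: dict[str, np.ndarray], path, header: dict | None = None) -> None:
    """Named-array checkpoint with a JSON header attribute."""
    with h5py.File(path, "w") as h5:
        for name, arr in state.items():
            h5.create_dataset(name, data=np.asarray(arr))
        h5.attrs["header"] = json.dumps(header or {}, sort_keys=True, default=str)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with h5py.File(path, "r") as h5:
        state = {name: np.asarray(h5[name]) for name in h5}
        header = json.loads(h5.attrs.get("header", "{}"))
    return state, header


def write_report(results: dict, out_dir) -> dict[str, Path]:
    """Write evaluation results: per-voxel CSV + JSON summary.

    ``results`` keys (all optional except ``summary``):
      per_voxel — DataFrame or dict of columns (voxel id, ROI, rho per
      model, validity); summary — JSON-serializable dict; config — dict
      snapshot written to YAML.
    Field ordering is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary = dict(results.get("summary", {}))
    summary["schema_version"] = SCHEMA_VERSION
    spath = out_dir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    written["summary"] = spath
    if "per_voxel" in results:
        df = pd.DataFrame(results["per_voxel"])
        cpath = out_dir / "per_voxel.csv"
        df.to_csv(cpath, index=False)
        written["per_voxel"] = cpath
    if "config" in results:
        import yaml

        ypath = out_dir / "config.yaml"
        ypath.write_text(yaml.safe_dump(results["config"], sort_keys=True))
        written["config"] = ypath
    return written
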
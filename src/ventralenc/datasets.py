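"""Shared data containers for stimulus/response datasets.

The layout mirrors the CRCNS vim-1 convention: grayscale stimulus arrays
split into a training and a validation set, paired with per-ROI voxel
response matrices (samples x voxels). ROI labels follow the ventral-stream
order V1 < V2 < V4 < LO.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Ventral-stream ordering used to validate source -> target directions.
ROI_ORDER = ("V1", "V2", "V4", "LO")


def roi_rank(roi: str) -> int:
    """Position of *roi* in the ventral-stream order (V1=0 ... LO=3)."""
    try:
        return ROI_ORDER.index(roi)
    except ValueError:
        raise ValueError(f"unknown ROI {roi!r}; expected one of {ROI_ORDER}") from None


@dataclass
class StimulusSet:
    """Grayscale images with a train/validation split.

    Arrays are shaped (n, side, side) with values in [0, 1].
    """

    train: np.ndarray
    val: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=np.float64)
        self.val = np.asarray(self.val, dtype=np.float64)
        if self.train.ndim != 3 or self.val.ndim != 3:
            raise ValueError("stimulus arrays must be (n, side, side)")
        if self.train.shape[1:] != self.val.shape[1:]:
            raise ValueError("train/val image sizes differ")

    @property
    def side(self) -> int:
        return self.train.shape[1]

    @property
    def n_train(self) -> int:
        return self.train.shape[0]

    @property
    def n_val(self) -> int:
        return self.val.shape[0]


@dataclass
class VoxelResponses:
    """Response matrices for one ROI: (n_samples, n_voxels) per split."""

    roi: str
    train: np.ndarray
    val: np.ndarray
    voxel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.train = np.atleast_2d(np.asarray(self.train, dtype=np.float64))
        self.val = np.atleast_2d(np.asarray(self.val, dtype=np.float64))
        if self.train.shape[1] != self.val.shape[1]:
            raise ValueError(
                f"{self.roi}: train has {self.train.shape[1]} voxels, "
                f"val has {self.val.shape[1]}"
            )
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.train.shape[1])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.shape[0] != self.train.shape[1]:
                raise ValueError("voxel_ids length mismatch")

    @property
    def n_voxels(self) -> int:
        return self.train.shape[1]


@dataclass
class DatasetBundle:
    """A stimulus set plus per-ROI responses, as one experiment's data."""

    stimuli: StimulusSet
    responses: Mapping[str, VoxelResponses]
    subject: str = "S1"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for roi, resp in self.responses.items():
            roi_rank(roi)  # validates label
            if resp.train.shape[0] != self.stimuli.n_train:
                raise ValueError(f"{roi}: train sample count mismatch")
            if resp.val.shape[0] != self.stimuli.n_val:
                raise ValueError(f"{roi}: val sample count mismatch")

    def __getitem__(self, roi: str) -> VoxelResponses:
        return self.responses[roi]

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(sorted(self.responses, key=roi_rank))
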
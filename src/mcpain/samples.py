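"""Per-participant ROI voxel samples and regional gray-matter volume.

The raw material of the pipeline is, for every participant and ROI, the
vector of smoothed modulated gray-matter intensities at the voxels the atlas
assigns to that ROI. Samples can be extracted from NIfTI images against an
integer-labeled atlas on the same grid, or loaded from a long-format TSV /
HDF5 table. Regional gray-matter volume (GMV) is the intensity sum times the
voxel volume (or the mean intensity, per configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .parcellation import Parcellation

#: Minimum voxels per ROI below which density estimation is refused.
DEFAULT_MIN_VOXELS = 10


@dataclass
class ROISampleSet:
    """Mapping (participant_id, roi_id) -> vector of voxel intensities.

    Participants are kept sorted by id so downstream results are invariant
    to input file ordering. Every participant must cover every roi_id.
    """

    data: dict[str, dict[int, np.ndarray]]
    roi_ids: tuple[int, ...]
    min_voxels: int = DEFAULT_MIN_VOXELS
    _participants: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._participants = tuple(sorted(self.data))
        for pid in self._participants:
            cell = self.data[pid]
            missing = [r for r in self.roi_ids if r not in cell]
            if missing:
                raise FormatError(f"participant {pid} missing ROIs {missing}")
            for rid in self.roi_ids:
                v = np.asarray(cell[rid], dtype=float).ravel()
                if v.size < self.min_voxels:
                    raise FormatError(
                        f"ROI {rid} of participant {pid} has {v.size} voxels "
                        f"(min_voxels={self.min_voxels})"
                    )
                if not np.all(np.isfinite(v)):
                    raise FormatError(
                        f"non-finite intensity in ROI {rid} of participant {pid}"
                    )
                cell[rid] = v

    @property
    def participants(self) -> tuple[str, ...]:
        return self._participants

    @property
    def n_participants(self) -> int:
        return len(self._participants)

    def samples(self, participant_id: str, roi_id: int) -> np.ndarray:
        return self.data[participant_id][roi_id]

    def participant_samples(self, participant_id: str) -> dict[int, np.ndarray]:
        return self.data[participant_id]

    # ---------------------------------------------------------------- IO ---

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self._participants:
            for rid in self.roi_ids:
                v = self.data[pid][rid]
                rows.append(
                    pd.DataFrame(
                        {"participant_id": pid, "roi_id": rid, "value": v}
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_frame(
        cls, frame: pd.DataFrame, min_voxels: int = DEFAULT_MIN_VOXELS
    ) -> "ROISampleSet":
        required = {"participant_id", "roi_id", "value"}
        if not required.issubset(frame.columns):
            raise FormatError(f"long table needs columns {sorted(required)}")
        data: dict[str, dict[int, np.ndarray]] = {}
        for (pid, rid), grp in frame.groupby(["participant_id", "roi_id"], sort=False):
            data.setdefault(str(pid), {})[int(rid)] = grp["value"].to_numpy(float)
        roi_ids = tuple(sorted({int(r) for r in frame["roi_id"]}))
        return cls(data=data, roi_ids=roi_ids, min_voxels=min_voxels)

    @classmethod
    def from_tsv(cls, path: str | Path, min_voxels: int = DEFAULT_MIN_VOXELS):
        return cls.from_long_frame(pd.read_csv(path, sep="\t"), min_voxels=min_voxels)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["roi_ids"] = list(self.roi_ids)
            for pid in self._participants:
                grp = f.create_group(pid)
                for rid in self.roi_ids:
                    grp.create_dataset(str(rid), data=self.data[pid][rid])

    @classmethod
    def from_hdf5(cls, path: str | Path, min_voxels: int = DEFAULT_MIN_VOXELS):
        import h5py

        data: dict[str, dict[int, np.ndarray]] = {}
        with h5py.File(path, "r") as f:
            roi_ids = tuple(int(r) for r in f.attrs["roi_ids"])
            for pid in f:
                data[pid] = {int(rid): f[pid][rid][()] for rid in f[pid]}
        return cls(data=data, roi_ids=roi_ids, min_voxels=min_voxels)


def extract_roi_samples(
    gm_images: Mapping[str, str | Path] | Sequence[str | Path],
    atlas_image: str | Path,
    parc: Parcellation,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> ROISampleSet:
    """Extract per-ROI voxel intensity vectors from NIfTI gray-matter images.

    Parameters
    ----------
    gm_images
        Mapping participant_id -> NIfTI path, or a sequence of paths (ids are
        then the file stems). Each image must share grid dimensions with the
        atlas.
    atlas_image
        Integer-labeled NIfTI whose labels cover all parcellation roi_ids.
    """
    import nibabel as nib

    if not isinstance(gm_images, Mapping):
        gm_images = {Path(p).name.split(".")[0]: p for p in gm_images}

    atlas = nib.load(str(atlas_image))
    labels = np.asarray(atlas.dataobj).round().astype(int)
    present = set(np.unique(labels).tolist())
    missing = [r for r in parc.roi_ids if r not in present]
    if missing:
        raise FormatError(f"atlas has no voxels for roi_ids {missing}")
    masks = {rid: labels == rid for rid in parc.roi_ids}
    for rid, mask in masks.items():
        if mask.sum() < min_voxels:
            raise FormatError(
                f"ROI {rid} has {int(mask.sum())} voxels in the atlas "
                f"(min_voxels={min_voxels})"
            )

    data: dict[str, dict[int, np.ndarray]] = {}
    for pid, path in gm_images.items():
        img = nib.load(str(path))
        if img.shape != labels.shape:
            raise FormatError(
                f"grid mismatch for participant {pid}: image {img.shape} "
                f"vs atlas {labels.shape}"
            )
        vol = np.asarray(img.dataobj, dtype=float)
        if np.isnan(vol[labels > 0]).any():
            raise FormatError(f"NaN gray-matter intensity in image of {pid}")
        data[str(pid)] = {rid: vol[mask].ravel() for rid, mask in masks.items()}
    return ROISampleSet(data=data, roi_ids=tuple(parc.roi_ids), min_voxels=min_voxels)


def compute_gmv(
    sample_set: ROISampleSet,
    parc: Parcellation,
    voxel_volume: float = 1.0,
    mode: str = "sum",
) -> pd.DataFrame:
    """Regional gray-matter volume table (participants x ROIs).

    ``mode="sum"`` (default) gives intensity sum x voxel volume in mm^3, the
    conventional modulated-VBM regional volume; ``mode="mean"`` gives the mean
    voxel intensity.
    """
    if mode not in ("sum", "mean"):
        raise InvalidParameterError(f"mode must be 'sum' or 'mean', got {mode!r}")
    if voxel_volume <= 0:
        raise InvalidParameterError("voxel_volume must be positive")
    rows = []
    for pid in sample_set.participants:
        vals = []
        for rid in parc.roi_ids:
            v = sample_set.samples(pid, rid)
            if v.size == 0:
                raise InvalidParameterError(f"empty sample vector for ROI {rid}")
            vals.append(v.sum() * voxel_volume if mode == "sum" else v.mean())
        rows.append(vals)
    table = pd.DataFrame(
        rows, index=list(sample_set.participants), columns=parc.names
    )
    table.index.name = "participant_id"
    return table
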
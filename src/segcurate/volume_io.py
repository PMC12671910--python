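"""Data model and I/O for labeled and intensity volumes.

Axis order is (Z, Y, X) throughout, with 0-based indices and half-open ROI
bounds.  Label value 0 is background and is never treated as an object.
Voxel sizes are physical edge lengths in micrometres, ordered (z, y, x).

ROI extraction / paste-back implements bounding-box-targeted processing:
operators work on a small sub-volume around the selected objects and the
result is written back under an explicit collision policy, so unselected
objects are never silently modified.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import tifffile

from .selection import Selection, as_selection

VoxelSize = tuple[float, float, float]


def _validate_voxel_size(vs) -> VoxelSize:
    vs = tuple(float(v) for v in vs)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 strictly positive lengths, got {vs}")
    return vs


@dataclass
class LabeledVolume:
    """One time point's 3D integer label image.

    ``data`` holds one integer id per voxel; 0 is background.  Ids need not
    be consecutive, and an id may cover several connected components until
    :func:`~segcurate.curation_ops.split_disconnected` is applied.
    """

    data: np.ndarray
    voxel_size: VoxelSize = (1.0, 1.0, 1.0)
    time: int = 0
    channel: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.floating) and np.all(
                self.data == np.round(self.data)
            ):
                self.data = self.data.astype(np.int64)
            else:
                raise ValueError("label volume must hold integer values")
        if self.data.size and self.data.min() < 0:
            raise ValueError("label values must be >= 0 (0 = background)")
        self.voxel_size = _validate_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def max_label(self) -> int:
        return int(self.data.max(initial=0))

    def copy(self) -> "LabeledVolume":
        return dataclasses.replace(self, data=self.data.copy())

    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class IntensityVolume:
    """A 3D numeric acquisition image co-registered with a label volume."""

    data: np.ndarray
    voxel_size: VoxelSize = (1.0, 1.0, 1.0)
    time: int = 0
    channel: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"intensity volume must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.number):
            raise ValueError("intensity volume must be numeric")
        self.voxel_size = _validate_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "IntensityVolume":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass
class Dataset:
    """Time-indexed collection of labeled + intensity volumes per channel."""

    labels: dict[tuple[int, int], LabeledVolume] = field(default_factory=dict)
    intensities: dict[tuple[int, int], IntensityVolume] = field(default_factory=dict)
    lineage: "object | None" = None  # LineageGraph, kept untyped to avoid a cycle
    properties: "object | None" = None  # RegionPropertyTable

    def times(self) -> list[int]:
        return sorted({t for t, _ in self.labels})

    def channels(self) -> list[int]:
        return sorted({c for _, c in self.labels})

    def label_volume(self, time: int, channel: int = 0) -> LabeledVolume:
        return self.labels[(time, channel)]

    def intensity_volume(self, time: int, channel: int = 0) -> IntensityVolume:
        return self.intensities[(time, channel)]

    def add(self, vol: LabeledVolume | IntensityVolume) -> None:
        key = (vol.time, vol.channel)
        if isinstance(vol, LabeledVolume):
            self.labels[key] = vol
        else:
            self.intensities[key] = vol

    def validate(self) -> None:
        times = self.times()
        if times and times != list(range(times[0], times[-1] + 1)):
            raise ValueError(f"times must form a contiguous range, got {times}")
        for (t, c), lab in self.labels.items():
            inten = self.intensities.get((t, c))
            if inten is not None and inten.shape != lab.shape:
                raise ValueError(
                    f"label/intensity shape mismatch at (t={t}, c={c}): "
                    f"{lab.shape} vs {inten.shape}"
                )

    def copy(self) -> "Dataset":
        return Dataset(
            labels={k: v.copy() for k, v in self.labels.items()},
            intensities={k: v.copy() for k, v in self.intensities.items()},
            lineage=self.lineage.copy() if self.lineage is not None else None,
            properties=self.properties,
        )

    def max_label(self) -> int:
        return max((v.max_label() for v in self.labels.values()), default=0)


@dataclass(frozen=True)
class RoiPlacement:
    """Where an extracted sub-volume sits inside its parent volume."""

    offset: tuple[int, int, int]
    shape: tuple[int, int, int]
    margin: int = 0

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(
            slice(o, o + s) for o, s in zip(self.offset, self.shape)
        )  # type: ignore[return-value]


# --------------------------------------------------------------------- I/O

def read_volume(
    path,
    role: Literal["label", "intensity"] = "label",
    voxel_size: VoxelSize | None = None,
    time: int = 0,
    channel: int = 0,
) -> LabeledVolume | IntensityVolume:
    """Read a multi-page TIFF (or NIfTI ``.nii``/``.nii.gz``) as a volume.

    TIFF resolution tags are used for the (y, x) voxel size when present and
    no explicit ``voxel_size`` is given; otherwise an isotropic 1 µm grid is
    assumed.  Label volumes must hold integer values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".nii", ".gz"}:
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"expected 3 spatial dims, got shape {arr.shape}")
        arr = np.transpose(arr, (2, 1, 0))  # nibabel is (x, y, z)
        if voxel_size is None:
            z = img.header.get_zooms()[:3]
            voxel_size = (float(z[2]), float(z[1]), float(z[0]))
    else:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            if voxel_size is None:
                voxel_size = _tiff_voxel_size(tf)
    if arr.ndim == 2:
        raise ValueError("2D input: a 3D multi-page volume is required")
    if arr.ndim != 3:
        raise ValueError(f"expected 3 spatial dims, got shape {arr.shape}")
    voxel_size = voxel_size or (1.0, 1.0, 1.0)
    if role == "label":
        if np.issubdtype(arr.dtype, np.floating) and not np.all(arr == np.round(arr)):
            raise ValueError(
                f"{path.name}: non-integer values cannot be read as labels"
            )
        return LabeledVolume(arr.astype(np.int64), voxel_size, time, channel)
    return IntensityVolume(arr, voxel_size, time, channel)


def _tiff_voxel_size(tf: "tifffile.TiffFile") -> VoxelSize | None:
    try:
        page = tf.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is None or yres is None:
            return None
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr <= 0 or yr <= 0:
            return None
        return (1.0, 1.0 / yr, 1.0 / xr)
    except Exception:
        return None


def write_volume(vol: LabeledVolume | IntensityVolume, path) -> None:
    """Write a volume as a multi-page TIFF, choosing a compact integer dtype
    for labels."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, LabeledVolume):
        mx = vol.max_label()
        dtype = np.uint8 if mx < 2**8 else np.uint16 if mx < 2**16 else np.uint32
        data = data.astype(dtype)
    tifffile.imwrite(str(path), data, photometric="minisblack")


# ------------------------------------------------------------------- ROIs

def bounding_box(
    vol: LabeledVolume, labels: Iterable[int]
) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """Tight half-open bounding box (start, stop) of the union of labels."""
    labels = list(labels)
    mask = np.isin(vol.data, labels)
    if not mask.any():
        raise ValueError(f"labels {labels} absent from volume at t={vol.time}")
    idx = np.nonzero(mask)
    start = tuple(int(i.min()) for i in idx)
    stop = tuple(int(i.max()) + 1 for i in idx)
    return start, stop


def extract_roi(
    vol: LabeledVolume | IntensityVolume,
    selection: Selection | Iterable[int],
    margin: int = 10,
    reference: LabeledVolume | None = None,
):
    """Extract the sub-volume covering the selected labels' bounding boxes.

    The box is the union of the tight bounding boxes of the selected labels,
    dilated by ``margin`` voxels and clamped to the volume bounds.  For an
    intensity volume, pass the co-registered label volume as ``reference``.

    Returns ``(sub_volume, RoiPlacement)``; the sub-volume is a copy.
    """
    ref = reference if reference is not None else vol
    if not isinstance(ref, LabeledVolume):
        raise TypeError("extract_roi needs a LabeledVolume (or reference=)")
    selection = as_selection(selection, time=ref.time, channel=ref.channel)
    labels = sorted(selection.labels_at(ref.time, ref.channel))
    if not labels:
        raise ValueError(f"selection is empty at t={ref.time}")
    present = set(ref.labels().tolist())
    missing = [l for l in labels if l not in present]
    if missing:
        raise ValueError(f"selection labels absent from volume: {missing}")
    start, stop = bounding_box(ref, labels)
    shape = vol.data.shape
    start = tuple(max(0, s - margin) for s in start)
    stop = tuple(min(n, s + margin) for s, n in zip(stop, shape))
    placement = RoiPlacement(
        offset=start, shape=tuple(b - a for a, b in zip(start, stop)), margin=margin
    )
    sub = vol.data[placement.slices()].copy()
    out = dataclasses.replace(vol, data=sub)
    return out, placement


def paste_roi(
    vol: LabeledVolume,
    sub: LabeledVolume | np.ndarray,
    placement: RoiPlacement,
    policy: Literal["replace_selected", "replace_all", "background_only"] = "replace_selected",
    selected: Selection | Iterable[int] | None = None,
) -> LabeledVolume:
    """Write an edited sub-volume back into the parent label volume.

    Policies:

    ``replace_selected``
        only voxels that previously belonged to a selected label are
        overwritten (including erasure to 0); all other labels are untouched.
    ``background_only``
        writes only where the parent volume is background.
    ``replace_all``
        the sub-volume replaces the box wholesale.

    New ids in ``sub`` must either reuse selected ids or be fresh (greater
    than the parent's current maximum); a collision with an unselected
    existing label is an error.
    """
    sub_data = sub.data if isinstance(sub, LabeledVolume) else np.asarray(sub)
    if tuple(sub_data.shape) != tuple(placement.shape):
        raise ValueError(
            f"sub-volume shape {sub_data.shape} != placement shape {placement.shape}"
        )
    if any(o < 0 for o in placement.offset) or any(
        o + s > n for o, s, n in zip(placement.offset, placement.shape, vol.data.shape)
    ):
        raise ValueError("placement exceeds volume bounds")

    sel_labels: set[int] = set()
    if selected is not None:
        selected = as_selection(selected, time=vol.time, channel=vol.channel)
        sel_labels = selected.labels_at(vol.time, vol.channel)

    new_ids = set(np.unique(sub_data).tolist()) - {0}
    existing = set(vol.labels().tolist())
    if policy != "replace_all":
        collisions = sorted((new_ids & existing) - sel_labels)
        # ids untouched inside the box are not collisions: they may simply
        # still be present in the extracted sub-volume
        box = vol.data[placement.slices()]
        collisions = [
            l
            for l in collisions
            if not np.array_equal(box == l, sub_data == l)
        ]
        if collisions:
            raise ValueError(
                f"sub-volume ids collide with unselected existing labels: {collisions}"
            )

    out = vol.copy()
    box = out.data[placement.slices()]
    if policy == "replace_all":
        box[...] = sub_data
    elif policy == "background_only":
        write = box == 0
        box[write] = sub_data[write]
    elif policy == "replace_selected":
        if selected is None:
            raise ValueError("replace_selected requires a selection")
        write = np.isin(box, sorted(sel_labels))
        box[write] = sub_data[write]
    else:
        raise ValueError(f"unknown paste policy {policy!r}")
    return out


def fresh_label(*vols: LabeledVolume, dataset: Dataset | None = None) -> int:
    """Allocate a label id greater than every id currently in use."""
    mx = max((v.max_label() for v in vols), default=0)
    if dataset is not None:
        mx = max(mx, dataset.max_label())
    return mx + 1
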
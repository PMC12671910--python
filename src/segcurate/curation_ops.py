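"""Object-level editing operators for labeled volumes.

Every operator takes a volume (or dataset) plus a selection and returns an
:class:`EditResult` carrying the edited volume, the exact set of label ids
whose voxel sets changed, and a JSON-serializable action log.  Operators
never mutate their inputs.

Families covered: correction (fuse / delete / size filter / split by
connectivity, Gaussian mixture or axis plane), shape transforms
(dilate / erode / open / close / convex hull), seed generation (intensity
minima, distance maxima, long-axis cuts, erosion splitting), seeded
watershed in several domains, intensity thresholding, temporal propagation
and copy-paste.  Growth operators (dilate, convex, paste) only ever write
background voxels: neighbouring objects are never overwritten.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.morphology import ball, local_minima
from skimage.segmentation import watershed as _sk_watershed

from .selection import Selection, as_selection
from .volume_io import Dataset, IntensityVolume, LabeledVolume, fresh_label

_FULL = np.ones((3, 3, 3), bool)  # 26-connectivity structuring element
_FACE = ndi.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class SeedSet:
    """Seed points (t, z, y, x voxel coords) with optional parent labels."""

    seeds: list[tuple[int, int, int, int]]
    parents: list[int | None] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.parents:
            self.parents = [None] * len(self.seeds)
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be unique")

    def coords_at(self, time: int) -> np.ndarray:
        return np.array(
            [(z, y, x) for t, z, y, x in self.seeds if t == time], dtype=int
        ).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.seeds)


@dataclass
class EditResult:
    """Outcome of one editing action.

    ``changed_labels`` is exactly the set of ids whose voxel sets differ
    between input and output (created, deleted or modified).
    """

    volume: LabeledVolume
    changed_labels: set[int]
    log: dict

    @property
    def warnings(self) -> list[str]:
        return self.log.get("warnings", [])


def diff_labels(before: LabeledVolume, after: LabeledVolume) -> set[int]:
    """Ids whose voxel sets differ between two volumes (background excluded)."""
    changed = before.data != after.data
    ids = set(np.unique(before.data[changed]).tolist())
    ids |= set(np.unique(after.data[changed]).tolist())
    ids.discard(0)
    return ids


def _result(before: LabeledVolume, after: LabeledVolume, op: str, params: dict,
            warnings_: list[str] | None = None) -> EditResult:
    changed = diff_labels(before, after)
    log = {"op": op, "params": params, "changed_labels": sorted(changed),
           "n_changed": len(changed)}
    if warnings_:
        log["warnings"] = warnings_
    return EditResult(after, changed, log)


def _sel_labels(vol: LabeledVolume, selection) -> list[int]:
    sel = as_selection(selection, time=vol.time, channel=vol.channel)
    if sel is None:
        return sorted(vol.labels().tolist())
    return sorted(sel.labels_at(vol.time, vol.channel))


def _grown_slices(sl, shape, pad):
    return tuple(
        slice(max(0, s.start - pad), min(n, s.stop + pad))
        for s, n in zip(sl, shape)
    )


# ------------------------------------------------------------- correction

def fuse_labels(vol: LabeledVolume, selection) -> EditResult:
    """Fuse the selected objects into one: all selected voxels take the
    smallest selected id.  With label groups, fusion is applied per group.
    Total foreground voxel count is conserved."""
    sel = as_selection(selection, time=vol.time, channel=vol.channel)
    groups: list[list[int]]
    if sel is not None and sel.groups:
        groups = [
            sorted({l for t, c, l in sub if t == vol.time and c == vol.channel})
            for sub in sel.groups.values()
        ]
    else:
        groups = [_sel_labels(vol, sel)]
    out = vol.copy()
    warns: list[str] = []
    for labs in groups:
        labs = [l for l in labs if l in out.data]
        if len(labs) < 2:
            warns.append(f"fuse needs >= 2 labels, got {labs}: no-op")
            continue
        target = min(labs)
        out.data[np.isin(out.data, labs)] = target
    return _result(vol, out, "fuse", {"groups": groups}, warns)


def delete_labels(vol: LabeledVolume, selection) -> EditResult:
    """Replace the selected objects' voxels by background (0)."""
    labs = _sel_labels(vol, selection)
    present = set(vol.labels().tolist())
    warns = [f"label {l} absent: no change" for l in labs if l not in present]
    out = vol.copy()
    out.data[np.isin(out.data, labs)] = 0
    return _result(vol, out, "delete", {"labels": labs}, warns)


def _contact_counts(data: np.ndarray, mask: np.ndarray) -> dict[int, int]:
    """Contact surface (26-neighbourhood voxel-pair count) between ``mask``
    and each neighbouring label."""
    counts: dict[int, int] = {}
    for axis in range(3):
        for sign in (1, -1):
            shifted = np.roll(mask, sign, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if sign == 1 else slice(-1, None)
            shifted[tuple(edge)] = False
            touch = shifted & ~mask
            labs, c = np.unique(data[touch], return_counts=True)
            for l, n in zip(labs, c):
                if l > 0:
                    counts[int(l)] = counts.get(int(l), 0) + int(n)
    # add edge/corner contacts at lower weight is unnecessary: face counts
    # already dominate for surface-sharing neighbours; include diagonals so
    # diagonal-only neighbours still count
    dil = ndi.binary_dilation(mask, structure=_FULL) & ~mask
    labs, c = np.unique(data[dil], return_counts=True)
    for l, n in zip(labs, c):
        if l > 0 and int(l) not in counts:
            counts[int(l)] = 0  # diagonal-only: counted as 0 faces but known
    return counts


def remove_small_labels(
    vol: LabeledVolume,
    min_volume: int,
    mode: Literal["delete", "fuse_to_max_contact"] = "delete",
) -> EditResult:
    """Remove every object smaller than ``min_volume`` voxels.

    ``delete`` zeroes them; ``fuse_to_max_contact`` reassigns each small
    object to the neighbouring label sharing the largest contact surface
    (deleted if isolated).  Iterates until no small object remains."""
    if min_volume < 1:
        raise ValueError("min_volume must be >= 1")
    out = vol.copy()
    warns: list[str] = []
    for _ in range(1000):
        labs, counts = np.unique(out.data[out.data > 0], return_counts=True)
        small = [int(l) for l, n in zip(labs, counts) if n < min_volume]
        if not small:
            break
        # process smallest first so cascading fusions settle deterministically
        order = sorted(small, key=lambda l: (counts[list(labs).index(l)], l))
        for lab in order:
            mask = out.data == lab
            if not mask.any():
                continue
            if mode == "delete":
                out.data[mask] = 0
                continue
            sl = ndi.find_objects(mask.astype(np.int8))[0]
            grown = _grown_slices(sl, out.data.shape, 1)
            crop = out.data[grown]
            contacts = _contact_counts(crop, crop == lab)
            contacts.pop(lab, None)
            if not contacts:
                out.data[mask] = 0
                warns.append(f"small label {lab} isolated: deleted")
            else:
                target = max(contacts, key=lambda l: (contacts[l], -l))
                out.data[mask] = target
        if mode == "delete":
            break
    return _result(vol, out, "remove_small",
                   {"min_volume": min_volume, "mode": mode}, warns)


def split_disconnected(
    vol: LabeledVolume,
    selection=None,
    connectivity: Literal[6, 26] = 26,
) -> EditResult:
    """Give each connected component of each processed label its own id;
    the largest component keeps the original id.  Idempotent."""
    structure = _FACE if connectivity == 6 else _FULL
    labs = _sel_labels(vol, selection)
    out = vol.copy()
    next_id = fresh_label(vol)
    for lab in labs:
        mask = out.data == lab
        if not mask.any():
            continue
        comp, n = ndi.label(mask, structure=structure)
        if n <= 1:
            continue
        sizes = ndi.sum_labels(mask, comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        for k in range(1, n + 1):
            if k == keep:
                continue
            out.data[comp == k] = next_id
            next_id += 1
    return _result(vol, out, "split_disconnected",
                   {"labels": labs, "connectivity": connectivity})


def gmm_split(
    vol: LabeledVolume,
    intensity: IntensityVolume | None,
    selection,
    n_components: int = 2,
    seed: int = 0,
    min_size_frac: float = 0.02,
) -> EditResult:
    """Split each selected object by a Gaussian mixture on its voxel
    coordinates.

    Intensity weighting is realised by fitting the mixture on a resample of
    the in-object coordinates drawn with probability proportional to
    intensity, then assigning every voxel to its most probable component.
    If any component collapses below ``min_size_frac`` of the object, the
    fit falls back to a coordinate-only mixture.  Initialisation is
    deterministic k-means++ from the supplied seed."""
    from sklearn.mixture import GaussianMixture

    labs = _sel_labels(vol, selection)
    out = vol.copy()
    warns: list[str] = []
    next_id = fresh_label(vol)
    rng = np.random.default_rng(seed)
    for lab in labs:
        mask = out.data == lab
        nvox = int(mask.sum())
        if nvox < n_components:
            warns.append(f"label {lab}: {nvox} voxels < {n_components} components")
            continue
        coords = np.argwhere(mask).astype(float)

        def _fit(X):
            gm = GaussianMixture(
                n_components=n_components,
                covariance_type="full",
                init_params="k-means++",
                random_state=int(rng.integers(2**31 - 1)),
                reg_covar=1e-4,
                max_iter=200,
            )
            gm.fit(X)
            if not gm.converged_ and gm.n_iter_ >= 200:
                raise RuntimeError(
                    f"GMM failed to converge on label {lab} "
                    f"(lower bound {gm.lower_bound_:.3g})"
                )
            return gm

        assign = None
        if intensity is not None:
            w = np.asarray(intensity.data[mask], dtype=float)
            w = w - w.min()
            if w.sum() > 0:
                p = w / w.sum()
                take = rng.choice(len(coords), size=min(4 * nvox, 20000), p=p)
                gm = _fit(coords[take])
                cand = gm.predict(coords)
                sizes = np.bincount(cand, minlength=n_components)
                if sizes.min() >= max(1, min_size_frac * nvox):
                    assign = cand
        if assign is None:
            gm = _fit(coords)
            assign = gm.predict(coords)
            sizes = np.bincount(assign, minlength=n_components)
            if sizes.min() == 0:
                warns.append(f"label {lab}: degenerate mixture, left unsplit")
                continue
        ids = [lab] + [next_id + k for k in range(n_components - 1)]
        next_id += n_components - 1
        flat = np.flatnonzero(mask.ravel())
        outflat = out.data.ravel()
        for k, new_id in enumerate(ids):
            outflat[flat[assign == k]] = new_id
    return _result(vol, out, "gmm_split",
                   {"labels": labs, "n_components": n_components, "seed": seed},
                   warns)


def _major_axis_direction(coords: np.ndarray) -> np.ndarray:
    cov = np.cov(coords.T, bias=True)
    eigval, eigvec = np.linalg.eigh(cov)
    v = eigvec[:, np.argmax(eigval)]
    # deterministic sign: first nonzero component positive
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        v = -v
    return v


def split_along_axis(
    vol: LabeledVolume,
    selection,
    axis: Literal["major", "z", "y", "x"] = "major",
) -> EditResult:
    """Split each selected object in two at the midpoint plane of the given
    axis (``major`` = principal axis of the shape).  For odd extents the
    lower half is the smaller side."""
    labs = _sel_labels(vol, selection)
    out = vol.copy()
    warns: list[str] = []
    next_id = fresh_label(vol)
    for lab in labs:
        mask = out.data == lab
        if not mask.any():
            continue
        coords = np.argwhere(mask)
        if axis == "major":
            if len(coords) < 2:
                warns.append(f"label {lab}: too small to split")
                continue
            direction = _major_axis_direction(coords.astype(float))
            proj = coords.astype(float) @ direction
        else:
            ax = {"z": 0, "y": 1, "x": 2}[axis]
            proj = coords[:, ax].astype(float)
        lo, hi = proj.min(), proj.max()
        if hi - lo < 1:
            warns.append(f"label {lab}: extent < 2 along {axis}: no-op")
            continue
        mid = 0.5 * (lo + hi)
        upper = proj >= mid  # boundary plane to upper: lower half is the smaller side
        if not upper.any() or upper.all():
            warns.append(f"label {lab}: degenerate split along {axis}: no-op")
            continue
        sel_coords = coords[upper]
        out.data[tuple(sel_coords.T)] = next_id
        next_id += 1
    return _result(vol, out, "split_along_axis", {"labels": labs, "axis": axis},
                   warns)


# -------------------------------------------------------- shape transform

def morphology_transform(
    vol: LabeledVolume,
    selection,
    op_kind: Literal["dilate", "erode", "open", "close", "convex"],
    radius: int = 1,
) -> EditResult:
    """Apply a morphological operator (ball structuring element) to each
    selected object individually.

    Dilation, closing and convex-hull growth only claim background voxels --
    other labels are never overwritten.  Erosion may remove an object
    entirely; it is then deleted and logged."""
    if op_kind != "convex" and radius < 1:
        raise ValueError("radius must be >= 1")
    labs = _sel_labels(vol, selection)
    out = vol.copy()
    warns: list[str] = []
    selem = ball(radius)
    pad = radius + 1
    for lab in labs:
        mask_full = out.data == lab
        if not mask_full.any():
            continue
        sl = ndi.find_objects(mask_full.astype(np.int8))[0]
        grown = _grown_slices(sl, out.data.shape, pad + (0 if op_kind != "convex" else 64))
        crop = out.data[grown]
        mask = crop == lab
        if op_kind == "dilate":
            new = ndi.binary_dilation(mask, structure=selem)
        elif op_kind == "erode":
            new = ndi.binary_erosion(mask, structure=selem, border_value=0)
        elif op_kind == "open":
            new = ndi.binary_opening(mask, structure=selem, border_value=0)
        elif op_kind == "close":
            m = np.pad(mask, pad)
            new = ndi.binary_closing(m, structure=selem)[
                tuple(slice(pad, pad + s) for s in mask.shape)
            ]
            new |= mask
        elif op_kind == "convex":
            new = _convex_mask(mask)
        else:
            raise ValueError(f"unknown op_kind {op_kind!r}")
        if not new.any():
            warns.append(f"label {lab} vanished under {op_kind}: deleted")
        removed = mask & ~new
        added = new & ~mask & (crop == 0)  # growth constrained to background
        crop[removed] = 0
        crop[added] = lab
    return _result(vol, out, op_kind, {"labels": labs, "radius": radius}, warns)


def _convex_mask(mask: np.ndarray) -> np.ndarray:
    from skimage.morphology import convex_hull_image

    if mask.sum() < 4:
        return mask.copy()
    try:
        return convex_hull_image(mask)
    except Exception:
        return mask.copy()


# ------------------------------------------------------------------ seeds

def generate_seeds(
    vol: LabeledVolume,
    intensity: IntensityVolume | None = None,
    strategy: Literal[
        "intensity_minima_inside", "intensity_minima_background",
        "distance_maxima", "long_axis", "erosion",
    ] = "distance_maxima",
    selection=None,
    n_seeds: int | None = None,
    min_distance: int = 2,
) -> SeedSet:
    """Generate watershed seeds.

    Strategies:
      - ``intensity_minima_inside``: local intensity minima (3x3x3
        neighbourhood; a plateau yields one seed at its centroid) inside each
        selected object;
      - ``intensity_minima_background``: intensity minima where no label is;
      - ``distance_maxima``: up to ``n_seeds`` maxima of the in-object
        Euclidean distance transform, suppressed within ``min_distance``
        voxels of each other;
      - ``long_axis``: the object's major-axis segment is cut into
        ``n_seeds + 1`` pieces and seeds placed at the internal cut points;
      - ``erosion``: the object is eroded (1-voxel ball steps) until it falls
        apart; seeds at the barycentre of each part.
    """
    t = vol.time
    seeds: list[tuple[int, int, int, int]] = []
    parents: list[int | None] = []
    warns: list[str] = []

    def _add(pts: Iterable[Sequence[int]], parent: int | None) -> None:
        for p in pts:
            key = (t, int(p[0]), int(p[1]), int(p[2]))
            if key not in seeds:
                seeds.append(key)
                parents.append(parent)

    if strategy in ("intensity_minima_inside", "intensity_minima_background"):
        if intensity is None:
            raise ValueError(f"strategy {strategy} requires an intensity volume")
        if strategy == "intensity_minima_background":
            region_masks: list[tuple[int | None, np.ndarray]] = [
                (None, vol.data == 0)
            ]
        else:
            region_masks = [
                (lab, vol.data == lab) for lab in _sel_labels(vol, selection)
            ]
        for parent, mask in region_masks:
            if not mask.any():
                continue
            field_img = np.asarray(intensity.data, dtype=float)
            minima = local_minima(
                np.where(mask, field_img, field_img.max() + 1),
                connectivity=3, allow_borders=True,
            ) & mask
            pts = _plateau_centroids(minima)
            pts = _suppress(pts, field_img, min_distance, n_seeds, ascending=True)
            _add(pts, parent)
    elif strategy == "distance_maxima":
        for lab in _sel_labels(vol, selection):
            mask = vol.data == lab
            if not mask.any():
                continue
            edt = ndi.distance_transform_edt(mask)
            k = n_seeds if n_seeds else 1
            pts = peak_local_max(
                edt, min_distance=max(1, min_distance), num_peaks=k,
                exclude_border=False, labels=mask.astype(np.uint8),
            )
            _add(pts, lab)
    elif strategy == "long_axis":
        k = n_seeds if n_seeds else 2
        for lab in _sel_labels(vol, selection):
            mask = vol.data == lab
            coords = np.argwhere(mask)
            if len(coords) < 2:
                warns.append(f"label {lab}: too small for long_axis seeds")
                continue
            direction = _major_axis_direction(coords.astype(float))
            proj = coords.astype(float) @ direction
            lo, hi = proj.min(), proj.max()
            for j in range(1, k + 1):
                target = lo + (hi - lo) * j / (k + 1)
                idx = int(np.argmin(np.abs(proj - target)))
                _add([coords[idx]], lab)
    elif strategy == "erosion":
        for lab in _sel_labels(vol, selection):
            mask = vol.data == lab
            if not mask.any():
                continue
            parts = _erode_until_split(mask)
            if parts is None:
                warns.append(
                    f"label {lab}: eroded to nothing before disconnecting; no seeds"
                )
                continue
            comp, n = parts
            for kk in range(1, n + 1):
                cc = np.argwhere(comp == kk)
                centre = cc.mean(axis=0)
                idx = int(np.argmin(((cc - centre) ** 2).sum(axis=1)))
                _add([cc[idx]], lab)
    else:
        raise ValueError(f"unknown seed strategy {strategy!r}")

    if warns:
        warnings.warn("; ".join(warns), stacklevel=2)
    return SeedSet(
        seeds=seeds,
        parents=parents,
        provenance={"strategy": strategy, "n_seeds": n_seeds,
                    "min_distance": min_distance, "warnings": warns},
    )


def _plateau_centroids(minima: np.ndarray) -> list[np.ndarray]:
    comp, n = ndi.label(minima, structure=_FULL)
    pts = []
    for k in range(1, n + 1):
        cc = np.argwhere(comp == k)
        centre = cc.mean(axis=0)
        idx = int(np.argmin(((cc - centre) ** 2).sum(axis=1)))
        pts.append(cc[idx])
    return pts


def _suppress(pts, field_img, min_distance, n_seeds, ascending=True):
    """Order candidate points by field value and drop any within
    ``min_distance`` of an accepted one; cap at ``n_seeds``."""
    if not pts:
        return []
    pts = sorted(pts, key=lambda p: (field_img[tuple(p)], tuple(p)),
                 reverse=not ascending)
    accepted: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(np.asarray(p) - a) >= min_distance for a in accepted):
            accepted.append(np.asarray(p))
        if n_seeds and len(accepted) >= n_seeds:
            break
    return accepted


def _erode_until_split(mask: np.ndarray):
    """Erode with a 1-voxel ball until the object disconnects (26-conn).
    Returns (component image, n) at the first disconnecting step, or None if
    the mask vanishes first."""
    selem = ball(1)
    current = mask
    for _ in range(int(max(mask.shape))):
        nxt = ndi.binary_erosion(current, structure=selem, border_value=0)
        if not nxt.any():
            return None
        comp, n = ndi.label(nxt, structure=_FULL)
        if n >= 2:
            return comp, n
        current = nxt
    return None


# -------------------------------------------------------------- watershed

def seeded_watershed(
    vol: LabeledVolume,
    intensity: IntensityVolume | None,
    seeds: SeedSet,
    landscape: Literal["intensity", "inverse_distance"] = "intensity",
    domain: Literal["selected_objects", "background", "box"] = "selected_objects",
    selection=None,
    box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
    min_volume: int = 0,
) -> EditResult:
    """Flood a landscape from the seeds, restricted to a domain mask.

    Domains: the union of selected objects (which the result replaces), the
    image background, or the background inside a (start, stop) box.  The
    landscape is the intensity image or the negated distance transform of
    the domain.  Regions smaller than ``min_volume`` are not created: their
    voxels revert to the prior content (selected-objects domain) or to 0.
    New objects always receive fresh ids."""
    if landscape == "intensity" and intensity is None:
        raise ValueError("intensity landscape requires an intensity volume")
    out = vol.copy()
    if domain == "selected_objects":
        labs = _sel_labels(vol, selection)
        mask = np.isin(vol.data, labs)
    elif domain == "background":
        mask = vol.data == 0
    elif domain == "box":
        if box is None:
            raise ValueError("box domain requires box=(start, stop)")
        mask = np.zeros(vol.shape, bool)
        mask[tuple(slice(a, b) for a, b in zip(*box))] = True
        mask &= vol.data == 0
    else:
        raise ValueError(f"unknown domain {domain!r}")

    coords = seeds.coords_at(vol.time)
    inside = [p for p in coords if mask[tuple(p)]]
    if not inside:
        raise ValueError("no seed inside the watershed domain")
    markers = np.zeros(vol.shape, dtype=np.int32)
    for i, p in enumerate(inside, start=1):
        markers[tuple(p)] = i

    if landscape == "intensity":
        land = np.asarray(intensity.data, dtype=float)
    else:
        land = -ndi.distance_transform_edt(mask)
    ws = _sk_watershed(land, markers=markers, mask=mask)

    next_id = fresh_label(vol)
    warns: list[str] = []
    region_ids, counts = np.unique(ws[ws > 0], return_counts=True)
    keep_map: dict[int, int] = {}
    for rid, n in zip(region_ids, counts):
        if n < min_volume:
            warns.append(f"watershed region of {int(n)} voxels < min_volume: dropped")
            continue
        keep_map[int(rid)] = next_id
        next_id += 1
    if domain == "selected_objects":
        out.data[mask] = 0  # replaced objects disappear; dropped regions revert below
        revert = (~np.isin(ws, list(keep_map))) & mask
        out.data[revert] = vol.data[revert]
    for rid, new_id in keep_map.items():
        out.data[ws == rid] = new_id
    return _result(
        vol, out, "seeded_watershed",
        {"landscape": landscape, "domain": domain, "min_volume": min_volume,
         "n_seeds": len(inside), "new_labels": sorted(keep_map.values())},
        warns,
    )


# ------------------------------------------------------------- threshold

def threshold_segment(
    vol: LabeledVolume,
    intensity: IntensityVolume,
    threshold: float,
    scope: Literal["whole", "mask", "box", "per_object"] = "whole",
    mask: np.ndarray | None = None,
    box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None,
    selection=None,
    radius: int | None = None,
) -> EditResult:
    """Create fresh labels from the 26-connected components of
    ``intensity > threshold`` within the scope.

    Scopes: the whole image, an arbitrary boolean mask, a (start, stop) box,
    or -- for cross-channel segmentation -- each selected object's own mask
    (``per_object``; with ``radius`` set, a box of that half-width around
    each object's centroid instead).  Voxels below threshold are untouched."""
    warns: list[str] = []
    data = np.asarray(intensity.data)
    if threshold >= data.max():
        warns.append("threshold above intensity maximum: nothing segmented")
    if threshold < data.min():
        warns.append("threshold below intensity minimum: scope fully foreground")
    if scope == "whole":
        scope_mask = np.ones(vol.shape, bool)
    elif scope == "mask":
        if mask is None:
            raise ValueError("scope='mask' requires mask=")
        scope_mask = np.asarray(mask, bool)
    elif scope == "box":
        if box is None:
            raise ValueError("scope='box' requires box=(start, stop)")
        scope_mask = np.zeros(vol.shape, bool)
        scope_mask[tuple(slice(a, b) for a, b in zip(*box))] = True
    elif scope == "per_object":
        labs = _sel_labels(vol, selection)
        scope_mask = np.zeros(vol.shape, bool)
        for lab in labs:
            m = vol.data == lab
            if not m.any():
                continue
            if radius is None:
                scope_mask |= m
            else:
                centre = np.argwhere(m).mean(axis=0).round().astype(int)
                sl = tuple(
                    slice(max(0, c - radius), min(n, c + radius + 1))
                    for c, n in zip(centre, vol.shape)
                )
                scope_mask[sl] = True
    else:
        raise ValueError(f"unknown scope {scope!r}")

    fg = (data > threshold) & scope_mask
    comp, n = ndi.label(fg, structure=_FULL)
    out = vol.copy()
    next_id = fresh_label(vol)
    for k in range(1, n + 1):
        out.data[comp == k] = next_id
        next_id += 1
    return _result(vol, out, "threshold_segment",
                   {"threshold": threshold, "scope": scope, "n_created": n},
                   warns)


# ------------------------------------------------------------ propagation

def propagate_labels(
    ds: Dataset,
    selection: Selection,
    direction: Literal["forward", "backward"] = "forward",
    mode: Literal["erode_fit", "fill_empty"] = "erode_fit",
    use_intensity: bool = False,
    time_range: tuple[int, int] | None = None,
    channel: int = 0,
) -> tuple[list[EditResult], list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Propagate a trusted segmentation through time.

    ``erode_fit``: the source objects are eroded (1-voxel ball steps) until
    each lies entirely inside the union of the destination objects at the
    next time, then a watershed over that destination region (intensity
    landscape if ``use_intensity``, else negated distance transform) splits
    it; the destination objects are replaced.  ``fill_empty``: the source
    masks are copied to the target time minus existing foreground and grown
    by watershed into the background.  Temporal links source -> result are
    returned alongside the per-time edit results."""
    times = sorted(selection.times()) if time_range is None else list(
        range(time_range[0], time_range[1] + 1)
    )
    if len(times) < 2:
        raise ValueError("propagation needs at least 2 time points")
    if direction == "backward":
        times = times[::-1]
    results: list[EditResult] = []
    links: list[tuple[tuple[int, int], tuple[int, int]]] = []
    src_time = times[0]
    src_labels = sorted(selection.labels_at(src_time, channel)) or sorted(
        ds.label_volume(src_time, channel).labels().tolist()
    )
    for target_time in times[1:]:
        src_vol = ds.label_volume(src_time, channel)
        tgt_vol = ds.label_volume(target_time, channel)
        inten = (
            ds.intensities.get((target_time, channel)) if use_intensity else None
        )
        if mode == "erode_fit":
            res, new_ids = _propagate_erode_fit(
                src_vol, tgt_vol, src_labels, selection, inten, channel
            )
        else:
            res, new_ids = _propagate_fill_empty(src_vol, tgt_vol, src_labels, inten)
        ds.labels[(target_time, channel)] = res.volume
        results.append(res)
        for s_lab, t_lab in new_ids.items():
            links.append(((src_time, s_lab), (target_time, t_lab)))
        src_time = target_time
        src_labels = sorted(new_ids.values())
        if not src_labels:
            break
    return results, links


def _propagate_erode_fit(src_vol, tgt_vol, src_labels, selection, inten, channel):
    dest_labels = sorted(selection.labels_at(tgt_vol.time, channel)) or sorted(
        tgt_vol.labels().tolist()
    )
    dest_mask = np.isin(tgt_vol.data, dest_labels)
    selem = ball(1)
    markers = np.zeros(tgt_vol.shape, dtype=np.int32)
    marker_src: dict[int, int] = {}
    warns: list[str] = []
    mid = 0
    for lab in src_labels:
        mask = src_vol.data == lab
        ok = False
        for _ in range(int(max(src_vol.shape))):
            if not mask.any():
                break
            if bool(np.all(dest_mask[mask])):
                ok = True
                break
            mask = ndi.binary_erosion(mask, structure=selem, border_value=0)
        if not ok or not mask.any():
            warns.append(f"source {lab}: erosion exhausted before fitting; skipped")
            continue
        mid += 1
        markers[mask] = mid
        marker_src[mid] = lab
    out = tgt_vol.copy()
    if mid == 0:
        res = _result(tgt_vol, out, "propagate_erode_fit", {}, warns)
        return res, {}
    land = (
        np.asarray(inten.data, dtype=float)
        if inten is not None
        else -ndi.distance_transform_edt(dest_mask)
    )
    ws = _sk_watershed(land, markers=markers, mask=dest_mask)
    next_id = fresh_label(src_vol, tgt_vol)
    new_ids: dict[int, int] = {}
    out.data[dest_mask] = 0
    for m, s_lab in marker_src.items():
        region = ws == m
        new_lab = s_lab if s_lab not in out.data else next_id
        if new_lab == next_id:
            next_id += 1
        out.data[region] = new_lab
        new_ids[s_lab] = new_lab
    # voxels of the destination not reached by any marker stay background
    res = _result(tgt_vol, out, "propagate_erode_fit",
                  {"sources": src_labels, "destinations": dest_labels}, warns)
    return res, new_ids


def _propagate_fill_empty(src_vol, tgt_vol, src_labels, inten):
    out = tgt_vol.copy()
    background = tgt_vol.data == 0
    markers = np.zeros(tgt_vol.shape, dtype=np.int32)
    marker_src: dict[int, int] = {}
    warns: list[str] = []
    mid = 0
    for lab in src_labels:
        copied = (src_vol.data == lab) & background
        if not copied.any():
            warns.append(f"source {lab}: no background at target; skipped")
            continue
        mid += 1
        markers[copied] = mid
        marker_src[mid] = lab
    if mid == 0:
        res = _result(tgt_vol, out, "propagate_fill_empty", {}, warns)
        return res, {}
    land = (
        np.asarray(inten.data, dtype=float)
        if inten is not None
        else -ndi.distance_transform_edt(background)
    )
    ws = _sk_watershed(land, markers=markers, mask=background)
    next_id = fresh_label(src_vol, tgt_vol)
    new_ids: dict[int, int] = {}
    for m, s_lab in marker_src.items():
        region = ws == m
        new_lab = s_lab if s_lab not in tgt_vol.data else next_id
        if new_lab == next_id:
            next_id += 1
        out.data[region] = new_lab
        new_ids[s_lab] = new_lab
    res = _result(tgt_vol, out, "propagate_fill_empty",
                  {"sources": src_labels}, warns)
    return res, new_ids


# ------------------------------------------------------------- copy-paste

def copy_paste_label(
    ds: Dataset,
    source: tuple[int, int],
    target_time: int,
    rotation: np.ndarray | None = None,
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    scale: float = 1.0,
    channel: int = 0,
) -> EditResult:
    """Copy one object to another time point under a rigid rotation +
    translation + isotropic scale (nearest-neighbour resampling of the mask,
    rotation about the object centroid).

    The pasted object gets a fresh id and is written to background only;
    voxels colliding with existing labels are dropped and counted in the
    log.  An object left empty after collision removal is an error."""
    t0, lab = source
    src = ds.label_volume(t0, channel)
    tgt = ds.label_volume(target_time, channel)
    mask = src.data == lab
    if not mask.any():
        raise ValueError(f"source label {lab} absent at t={t0}")
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    centroid = np.argwhere(mask).mean(axis=0)
    # inverse map for ndi.affine_transform: input = A @ output + offset
    A = np.linalg.inv(R * scale)
    shift = centroid + np.asarray(translation, dtype=float)
    offset = centroid - A @ shift
    moved = ndi.affine_transform(
        mask.astype(np.uint8), A, offset=offset, output_shape=tgt.shape,
        order=0, mode="constant", cval=0,
    ).astype(bool)
    if not moved.any():
        raise ValueError("transformed object falls outside the volume")
    collisions = int(np.count_nonzero(moved & (tgt.data != 0)))
    write = moved & (tgt.data == 0)
    if not write.any():
        raise ValueError("pasted object empty after collision removal")
    out = tgt.copy()
    new_id = fresh_label(src, tgt, dataset=ds)
    out.data[write] = new_id
    ds.labels[(target_time, channel)] = out
    return _result(tgt, out, "copy_paste",
                   {"source": source, "target_time": target_time,
                    "scale": scale, "collision_voxels": collisions,
                    "new_label": new_id})


def rotation_matrix(axis: Literal["z", "y", "x"], degrees: float) -> np.ndarray:
    """Rotation about one volume axis, in (z, y, x) coordinates."""
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    if axis == "z":  # rotate in the (y, x) plane
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])
    if axis == "x":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"unknown axis {axis!r}")
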
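"""Synthetic 3D(+t) ground truth with controlled error injection.

Two regimes mirror the data the curation operators target:

* **nuclei** -- fields of non-overlapping ellipsoidal nuclei with a
  Gaussian intensity peak at each centre over a dark background, optional
  per-frame motion and binary divisions (time-lapse), and optionally pairs
  of nuclei in contact along a shared long axis (the configuration that
  produces elongated under-segmentations when fused);
* **cells** -- space-filling Voronoi tessellations with bright
  membrane-like interfaces, the regime of whole-cell membrane segmentation.

:func:`inject_errors` corrupts a ground-truth dataset with the standard
error taxonomy (under-/over-segmentation, missing objects, disconnected
labels, boundary jitter, missed divisions, broken temporal links) and
returns a manifest from which every injected error can be located, so
detector recall and corrector accuracy are measurable without real data.

The generator does not simulate optics (no PSF, no anisotropic blur); its
defaults give a bright-object/dark-background contrast where a fixed
intensity threshold of 100 is robustly between background and peak.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .lineage import LineageGraph
from .volume_io import Dataset, IntensityVolume, LabeledVolume


@dataclass
class SynthConfig:
    """Generation parameters; defaults give ~10 well-separated nuclei of
    radius 6 voxels in a 48x64x64 grid with 8-bit-like intensities."""

    shape: tuple[int, int, int] = (48, 64, 64)
    n_objects: int = 10
    kind: Literal["nuclei", "cells"] = "nuclei"
    radius_mean: float = 6.0
    radius_cv: float = 0.10
    elongation: float = 1.2        # max random per-axis stretch of a nucleus
    pair_elongation: float = 1.4   # stretch of touching-pair nuclei along contact
    n_touching_pairs: int = 0
    peak: float = 200.0
    background: float = 20.0
    noise_sigma: float = 5.0
    motion: float = 1.0            # max per-frame displacement, voxels
    division_rate: float = 0.0     # per nucleus per frame transition
    force_division_at: int | None = None  # deterministic division of one nucleus
    n_frames: int = 1
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 1 or self.n_frames < 1:
            raise ValueError("n_objects and n_frames must be positive")
        if min(self.radius_mean, self.peak, self.radius_cv + 1) <= 0:
            raise ValueError("rates and sizes must be positive")


@dataclass
class ErrorManifest:
    """Reproducible record of every injected error."""

    entries: list[dict] = field(default_factory=list)
    seed: int | None = None

    def add(self, error_kind: str, labels, time: int, **params) -> None:
        self.entries.append(
            {"error_kind": error_kind, "labels": [int(l) for l in labels],
             "time": int(time), "params": params}
        )

    def of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.entries if e["error_kind"] == kind]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "ErrorManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(entries=d["entries"], seed=d.get("seed"))


# ----------------------------------------------------------------- nuclei

@dataclass
class _Nucleus:
    label: int
    center: np.ndarray          # (z, y, x) float
    semi_axes: np.ndarray       # (z, y, x) float


def _sample_nuclei(cfg: SynthConfig, rng: np.random.Generator) -> list[_Nucleus]:
    shape = np.asarray(cfg.shape, dtype=float)
    mean_vol = 4.0 / 3.0 * np.pi * cfg.radius_mean**3
    if cfg.n_objects * mean_vol > 0.3 * float(np.prod(shape)):
        raise ValueError(
            "infeasible packing: n_objects x mean volume exceeds 30% of the grid"
        )
    nuclei: list[_Nucleus] = []
    label = 1

    def radius() -> float:
        return float(max(2.0, cfg.radius_mean * (1 + cfg.radius_cv * rng.normal())))

    def fits(center, semi) -> bool:
        margin = semi.max() + 1
        if np.any(center < margin) or np.any(center > shape - margin):
            return False
        for n in nuclei:
            gap = np.linalg.norm(center - n.center)
            if gap < semi.max() + n.semi_axes.max() + 2.0:
                return False
        return True

    # touching pairs first: two nuclei elongated along a shared axis, in contact
    for _ in range(cfg.n_touching_pairs):
        for _attempt in range(2000):
            r1, r2 = radius(), radius()
            axis = int(rng.integers(3))
            s1 = np.full(3, r1)
            s2 = np.full(3, r2)
            s1[axis] *= cfg.pair_elongation
            s2[axis] *= cfg.pair_elongation
            c1 = rng.uniform(0, 1, 3) * shape
            direction = np.zeros(3)
            direction[axis] = 1.0
            c2 = c1 + direction * (s1[axis] + s2[axis] - 0.5)
            pair_ok = True
            for c, s in ((c1, s1), (c2, s2)):
                margin = s.max() + 1
                if np.any(c < margin) or np.any(c > shape - margin):
                    pair_ok = False
            if pair_ok:
                for n in nuclei:
                    for c, s in ((c1, s1), (c2, s2)):
                        if np.linalg.norm(c - n.center) < s.max() + n.semi_axes.max() + 2:
                            pair_ok = False
            if pair_ok:
                nuclei.append(_Nucleus(label, c1, s1))
                nuclei.append(_Nucleus(label + 1, c2, s2))
                label += 2
                break
        else:
            raise ValueError("could not place a touching pair; grid too crowded")

    n_single = cfg.n_objects - 2 * cfg.n_touching_pairs
    for _ in range(max(0, n_single)):
        for _attempt in range(5000):
            r = radius()
            semi = np.full(3, r)
            semi[int(rng.integers(3))] *= rng.uniform(1.0, cfg.elongation)
            center = rng.uniform(0, 1, 3) * shape
            if fits(center, semi):
                nuclei.append(_Nucleus(label, center, semi))
                label += 1
                break
        else:
            raise ValueError("could not place all nuclei; grid too crowded")
    return nuclei


def _rasterize(nuclei: list[_Nucleus], shape) -> np.ndarray:
    data = np.zeros(shape, dtype=np.int32)
    for n in nuclei:
        lo = np.maximum(0, np.floor(n.center - n.semi_axes - 1)).astype(int)
        hi = np.minimum(shape, np.ceil(n.center + n.semi_axes + 2)).astype(int)
        zz, yy, xx = np.meshgrid(
            *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"
        )
        d = (
            ((zz - n.center[0]) / n.semi_axes[0]) ** 2
            + ((yy - n.center[1]) / n.semi_axes[1]) ** 2
            + ((xx - n.center[2]) / n.semi_axes[2]) ** 2
        )
        inside = d <= 1.0
        crop = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        write = inside & (crop == 0)  # earlier nuclei keep contested voxels
        crop[write] = n.label
    return data


def _intensity(nuclei: list[_Nucleus], cfg: SynthConfig,
               rng: np.random.Generator) -> np.ndarray:
    img = np.full(cfg.shape, cfg.background, dtype=float)
    for n in nuclei:
        sigma = n.semi_axes / 2.0
        lo = np.maximum(0, np.floor(n.center - 3 * n.semi_axes)).astype(int)
        hi = np.minimum(cfg.shape, np.ceil(n.center + 3 * n.semi_axes) + 1).astype(int)
        zz, yy, xx = np.meshgrid(
            *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"
        )
        g = np.exp(
            -0.5 * (
                ((zz - n.center[0]) / sigma[0]) ** 2
                + ((yy - n.center[1]) / sigma[1]) ** 2
                + ((xx - n.center[2]) / sigma[2]) ** 2
            )
        )
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (cfg.peak - cfg.background) * g
    img += rng.normal(0, cfg.noise_sigma, size=img.shape)
    return np.clip(img, 0, None)


def generate_nuclei_timelapse(cfg: SynthConfig) -> tuple[Dataset, LineageGraph]:
    """Deterministic (given the seed) nuclei field, optionally time-lapse.

    Labels exactly cover the ellipsoids; the intensity image has one peak
    per nucleus.  Divisions replace a nucleus by two adjacent daughters with
    the corresponding lineage edges; without divisions the lineage is a set
    of disjoint single-cell chains."""
    rng = np.random.default_rng(cfg.seed)
    nuclei = _sample_nuclei(cfg, rng)
    shape = np.asarray(cfg.shape)
    ds = Dataset()
    graph = LineageGraph()
    next_label = max(n.label for n in nuclei) + 1
    for t in range(cfg.n_frames):
        data = _rasterize(nuclei, cfg.shape)
        ds.add(LabeledVolume(data, cfg.voxel_size, time=t))
        ds.add(IntensityVolume(_intensity(nuclei, cfg, rng), cfg.voxel_size, time=t))
        for n in nuclei:
            graph.add_node((t, n.label))
        if t == cfg.n_frames - 1:
            break
        moved: list[_Nucleus] = []
        forced = (
            min(n.label for n in nuclei)
            if cfg.force_division_at == t else None
        )
        for n in nuclei:
            if n.label == forced or rng.random() < cfg.division_rate:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                r_d = n.semi_axes / 2 ** (1.0 / 3.0)
                offset = axis * 0.7 * float(n.semi_axes.max())
                for k in range(2):
                    c = np.clip(
                        n.center + offset * (1 if k == 0 else -1),
                        r_d.max() + 1, shape - r_d.max() - 1,
                    )
                    moved.append(_Nucleus(next_label, c, r_d))
                    graph.add_link((t, n.label), (t + 1, next_label))
                    next_label += 1
            else:
                step = rng.uniform(-cfg.motion, cfg.motion, 3)
                c = np.clip(
                    n.center + step, n.semi_axes.max() + 1,
                    shape - n.semi_axes.max() - 1,
                )
                moved.append(_Nucleus(n.label, c, n.semi_axes))
                graph.add_link((t, n.label), (t + 1, n.label))
        nuclei = moved
    ds.lineage = graph
    return ds, graph


# ------------------------------------------------------------------ cells

def generate_cell_tessellation(
    cfg: SynthConfig,
    mask: np.ndarray | None = None,
) -> tuple[LabeledVolume, IntensityVolume]:
    """Voronoi tessellation of random seed points with bright interfaces.

    Labels partition the mask (default: the whole grid) by nearest seed;
    the intensity image is ``background`` inside cells and ``peak`` on the
    one-voxel interface shell between cells (plus noise), emulating
    membrane staining."""
    if cfg.n_objects < 2:
        raise ValueError("a tessellation needs >= 2 cells")
    rng = np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape)
    if mask is None:
        mask = np.ones(cfg.shape, bool)
    seeds = []
    while len(seeds) < cfg.n_objects:
        p = np.floor(rng.uniform(0, 1, 3) * shape).astype(int)
        if not mask[tuple(p)]:
            continue
        if all(np.linalg.norm(p - q) >= 3 for q in seeds):
            seeds.append(p)
    seeds = np.array(seeds)
    from scipy.spatial import cKDTree

    coords = np.argwhere(mask)
    _, idx = cKDTree(seeds).query(coords)
    data = np.zeros(cfg.shape, dtype=np.int32)
    data[tuple(coords.T)] = idx + 1
    labels = LabeledVolume(data, cfg.voxel_size)

    interface = np.zeros(cfg.shape, bool)
    for axis in range(3):
        d = np.diff(data, axis=axis) != 0
        inner = (
            np.take(data, range(0, data.shape[axis] - 1), axis=axis) > 0
        ) & (np.take(data, range(1, data.shape[axis]), axis=axis) > 0)
        d &= inner
        pad_lo = [(0, 0)] * 3
        pad_hi = [(0, 0)] * 3
        pad_lo[axis] = (0, 1)
        pad_hi[axis] = (1, 0)
        interface |= np.pad(d, pad_lo)
        interface |= np.pad(d, pad_hi)
    img = np.full(cfg.shape, cfg.background, dtype=float)
    img[interface] = cfg.peak
    img = ndi.gaussian_filter(img, sigma=0.7)
    img += rng.normal(0, cfg.noise_sigma, size=img.shape)
    intensity = IntensityVolume(np.clip(img, 0, None), cfg.voxel_size)
    return labels, intensity


def voronoi_reference(
    seeds: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Direct nearest-seed assignment (independent check of the tessellation)."""
    coords = np.indices(shape).reshape(3, -1).T.astype(float)
    d = ((coords[:, None, :] - seeds[None, :, :].astype(float)) ** 2).sum(axis=2)
    return (np.argmin(d, axis=1) + 1).reshape(shape).astype(np.int32)


# -------------------------------------------------------------- injection

def inject_errors(
    ds: Dataset,
    error_spec: list[tuple[str, int]],
    seed: int = 0,
    time: int = 0,
    channel: int = 0,
    merge_max_distance: float | None = None,
) -> tuple[Dataset, ErrorManifest]:
    """Corrupt a ground-truth dataset with the requested error counts.

    Kinds: ``merge`` fuses adjacent ground-truth pairs (under-segmentation);
    ``split`` bisects objects across their major axis (over-segmentation);
    ``delete`` removes objects; ``disconnect`` carves an object into several
    components that keep one id (plus a small fragment); ``boundary_jitter``
    transfers interface voxels between touching neighbours;
    ``missed_division`` fuses the two daughters of a ground-truth division;
    ``broken_link`` removes lineage edges.  Every action is recorded in the
    returned :class:`ErrorManifest`."""
    rng = np.random.default_rng(seed)
    out = ds.copy()
    manifest = ErrorManifest(seed=seed)
    for kind, count in error_spec:
        if count <= 0:
            continue
        if kind == "merge":
            _inject_merge(out, count, rng, manifest, time, channel,
                          merge_max_distance)
        elif kind == "split":
            _inject_split(out, count, rng, manifest, time, channel)
        elif kind == "delete":
            vol = out.label_volume(time, channel)
            labs = rng.choice(vol.labels(), size=min(count, len(vol.labels())),
                              replace=False)
            for lab in labs:
                vol.data[vol.data == lab] = 0
                manifest.add("delete", [lab], time)
        elif kind == "disconnect":
            _inject_disconnect(out, count, rng, manifest, time, channel)
        elif kind == "boundary_jitter":
            _inject_jitter(out, count, rng, manifest, time, channel)
        elif kind == "missed_division":
            _inject_missed_division(out, count, rng, manifest, channel)
        elif kind == "broken_link":
            if out.lineage is None or not out.lineage.edges():
                raise ValueError("broken_link requires a lineage with edges")
            edges = out.lineage.edges()
            take = rng.choice(len(edges), size=min(count, len(edges)),
                              replace=False)
            for i in take:
                a, b = edges[int(i)]
                out.lineage.remove_link(a, b)
                manifest.add("broken_link", [a[1], b[1]], a[0], target=list(b))
        else:
            raise ValueError(f"unknown error kind {kind!r}")
    return out, manifest


def _centroids(vol: LabeledVolume) -> dict[int, np.ndarray]:
    labs = vol.labels().tolist()
    cents = ndi.center_of_mass(vol.data > 0, vol.data, labs)
    return {int(l): np.asarray(c) for l, c in zip(labs, cents)}


def _touching_pairs(vol: LabeledVolume) -> list[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    data = vol.data
    for axis in range(3):
        a = np.take(data, range(0, data.shape[axis] - 1), axis=axis)
        b = np.take(data, range(1, data.shape[axis]), axis=axis)
        touch = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[touch].ravel(), b[touch].ravel()):
            pairs.add((int(min(x, y)), int(max(x, y))))
    return sorted(pairs)


def _inject_merge(ds, count, rng, manifest, time, channel, max_distance):
    vol = ds.label_volume(time, channel)
    used: set[int] = set()
    chosen: list[tuple[int, int]] = []
    touching = _touching_pairs(vol)
    rng.shuffle(touching)
    for a, b in touching:
        if len(chosen) == count:
            break
        if a not in used and b not in used:
            chosen.append((a, b))
            used |= {a, b}
    if len(chosen) < count:
        cents = _centroids(vol)
        labs = [l for l in cents if l not in used]
        while len(chosen) < count and len(labs) >= 2:
            a = labs[int(rng.integers(len(labs)))]
            others = [l for l in labs if l != a]
            dists = [np.linalg.norm(cents[a] - cents[o]) for o in others]
            j = int(np.argmin(dists))
            if max_distance is not None and dists[j] > max_distance:
                labs.remove(a)
                continue
            b = others[j]
            chosen.append((min(a, b), max(a, b)))
            used |= {a, b}
            labs = [l for l in labs if l not in used]
    if len(chosen) < count:
        raise ValueError(
            f"merge: only {len(chosen)} adjacent pairs available, {count} requested"
        )
    for a, b in chosen:
        vol.data[vol.data == b] = a
        manifest.add("merge", [a, b], time, kept=a)


def _inject_split(ds, count, rng, manifest, time, channel):
    from .curation_ops import split_along_axis

    vol = ds.label_volume(time, channel)
    labs = vol.labels()
    take = rng.choice(labs, size=min(count, len(labs)), replace=False)
    for lab in take:
        before = set(vol.labels().tolist())
        res = split_along_axis(vol, [int(lab)], axis="major")
        ds.labels[(time, channel)] = res.volume
        vol = res.volume
        new = sorted(set(vol.labels().tolist()) - before)
        manifest.add("split", [lab], time, new_labels=[int(n) for n in new])


def _inject_disconnect(ds, count, rng, manifest, time, channel):
    vol = ds.label_volume(time, channel)
    labs = vol.labels()
    sizes = ndi.sum_labels(vol.data > 0, vol.data, labs)
    order = np.argsort(sizes)[::-1]
    done = 0
    for i in order:
        if done == count:
            break
        lab = int(labs[i])
        mask = vol.data == lab
        coords = np.argwhere(mask)
        from .curation_ops import _major_axis_direction

        direction = _major_axis_direction(coords.astype(float))
        proj = coords.astype(float) @ direction
        cut = np.quantile(proj, 0.25)
        # half-width 0.9 > sqrt(3)/2: no 26-adjacency can bridge the carve
        carve = np.abs(proj - cut) <= 0.9
        keep_lo = proj < cut - 0.9
        keep_hi = proj > cut + 0.9
        if not (carve.any() and keep_lo.any() and keep_hi.any()):
            continue
        vol.data[tuple(coords[carve].T)] = 0
        comp, n = ndi.label(vol.data == lab, structure=np.ones((3, 3, 3), bool))
        if n < 2:  # carve failed to disconnect; restore
            vol.data[tuple(coords[carve].T)] = lab
            continue
        manifest.add("disconnect", [lab], time,
                     carved_voxels=int(carve.sum()), n_components=int(n))
        done += 1
    if done < count:
        raise ValueError(f"disconnect: only {done} feasible, {count} requested")


def _inject_jitter(ds, count, rng, manifest, time, channel, frac: float = 0.3):
    vol = ds.label_volume(time, channel)
    pairs = _touching_pairs(vol)
    if not pairs:
        raise ValueError("boundary_jitter requires touching objects")
    take = rng.choice(len(pairs), size=min(count, len(pairs)), replace=False)
    for i in take:
        a, b = pairs[int(i)]
        mask_a = vol.data == a
        ring = ndi.binary_dilation(vol.data == b,
                                   structure=np.ones((3, 3, 3), bool))
        border = np.argwhere(mask_a & ring)
        k = max(1, int(frac * len(border)))
        sel = border[rng.choice(len(border), size=k, replace=False)]
        vol.data[tuple(sel.T)] = b
        manifest.add("boundary_jitter", [a, b], time, moved_voxels=int(k))


def _inject_missed_division(ds, count, rng, manifest, channel, duration: int = 2):
    """Fuse the two daughters of a division for ``duration`` frames.

    While fused, the second daughter's label is absorbed into the first and
    its lineage nodes are removed.  When the window ends the daughters
    separate again: the fused cell's volume halves without a division edge
    (the detectable signature of the missed division) and the re-appearing
    sibling starts a chain with no predecessor."""
    graph = ds.lineage
    if graph is None:
        raise ValueError("missed_division requires a ground-truth lineage")
    divisions = graph.divisions()
    if len(divisions) < count:
        raise ValueError(
            f"missed_division: {len(divisions)} divisions available, {count} requested"
        )
    take = rng.choice(len(divisions), size=count, replace=False)
    for i in take:
        mother = divisions[int(i)]
        d1, d2 = graph.successors(mother)[:2]
        t = d1[0]
        lab1, lab2 = d1[1], d2[1]
        separation_time = None
        for _ in range(duration):
            vol = ds.labels.get((t, channel))
            if vol is None:
                break
            vol.data[vol.data == lab2] = lab1
            s1 = graph.successors((t, lab1))
            s2 = graph.successors((t, lab2))
            if (t, lab2) in graph.g:
                graph.g.remove_node((t, lab2))
            if len(s1) == 1 and len(s2) == 1 and s1[0][1] != s2[0][1]:
                t, lab1, lab2 = t + 1, s1[0][1], s2[0][1]
                separation_time = t
            else:
                separation_time = None
                break
        manifest.add("missed_division", [mother[1], d1[1], d2[1]], mother[0],
                     division_time=d1[0], fused_label=d1[1],
                     separation_time=separation_time)
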
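"""Marker-less object identification by gradient attractors.

Every in-mask voxel is linked to the neighbouring voxel that maximises the
intensity slope (I_neigh - I_current) / |x_neigh - x_current|, with distances
measured in physical units so anisotropic z-spacing is respected. Voxels
whose best slope is non-positive are their own attractors (local maxima;
flat plateaus deliberately fragment and are reunified by the merge steps).
The connected parent trees are the basins of attraction — the initial
objects — and a set of merge/removal heuristics repairs over-segmentation:
distance-based attractor merging, intensity-depth merging of shallow
neighbouring basins, absorption of small fragments into their nearest large
object, and removal by volume or mean intensity. Per-label morphological
operations are available for label cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .stack import ImageStack

__all__ = [
    "Neighborhood",
    "LabelMap",
    "steepest_ascent_label",
    "merge_by_distance",
    "merge_by_depth",
    "merge_small_to_closest",
    "remove_by_size",
    "remove_by_intensity",
    "morph_labels",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Neighborhood:
    """Voxel neighbourhood: spherical, cubical or cross-shaped.

    ``radius`` is in voxels by default, or in micrometres when
    ``physical=True`` (then converted per axis with the image spacing).
    The generated offsets exclude the voxel itself.
    """

    kind: str = "cross"
    radius: float = 1.0
    physical: bool = False

    def __post_init__(self):
        if self.kind not in ("spherical", "cubical", "cross"):
            raise ValueError(f"unknown neighborhood kind {self.kind!r}")
        if self.radius < 1 and not self.physical:
            raise ValueError("radius must be >= 1 voxel")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def offsets(self, spacing: tuple[float, float, float]) -> np.ndarray:
        """Integer (z, y, x) offsets, lexicographically sorted.

        The lexicographic order is the tie-break order for equal slopes,
        making labeling deterministic and visiting-order independent.
        """
        if self.physical:
            reach = [int(np.floor(self.radius / s)) for s in spacing]
            r_phys = self.radius
        else:
            reach = [int(np.floor(self.radius))] * 3
            r_phys = None
        rng = [np.arange(-r, r + 1) for r in reach]
        zz, yy, xx = np.meshgrid(*rng, indexing="ij")
        offs = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        offs = offs[np.any(offs != 0, axis=1)]
        if self.kind == "cross":
            offs = offs[np.sum(offs != 0, axis=1) == 1]
        elif self.kind == "spherical":
            if r_phys is not None:
                d = np.linalg.norm(offs * np.asarray(spacing), axis=1)
                offs = offs[d <= r_phys + 1e-9]
            else:
                d = np.linalg.norm(offs, axis=1)
                offs = offs[d <= self.radius + 1e-9]
        # lexicographic (z, y, x) sort
        order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
        return offs[order]


@dataclass
class LabelMap:
    """Integer object id per voxel; 0 is background.

    ``attractors`` maps each object id to the flat index of its attractor —
    the highest-intensity voxel in the basin. ``spacing`` carries physical
    voxel size so size/distance thresholds can be given in micrometres.
    """

    labels: np.ndarray
    attractors: dict[int, int] = field(default_factory=dict)
    attractor_intensity: dict[int, float] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return len(self.ids)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volumes_voxels(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def attractor_coords_um(self) -> dict[int, np.ndarray]:
        """Physical (z, y, x) coordinates of each attractor voxel center."""
        sp = np.asarray(self.spacing)
        out = {}
        for lab, flat in self.attractors.items():
            idx = np.array(np.unravel_index(flat, self.shape), dtype=float)
            out[lab] = (idx + 0.5) * sp
        return out

    def object_table(self) -> pd.DataFrame:
        vols = self.volumes_voxels()
        rows = []
        for lab in self.ids:
            z, y, x = np.unravel_index(self.attractors[lab], self.shape)
            rows.append(
                {
                    "id": int(lab),
                    "attractor_z": int(z),
                    "attractor_y": int(y),
                    "attractor_x": int(x),
                    "volume_voxels": vols.get(int(lab), 0),
                    "max_intensity": self.attractor_intensity.get(int(lab), np.nan),
                }
            )
        return pd.DataFrame(rows, columns=[
            "id", "attractor_z", "attractor_y", "attractor_x",
            "volume_voxels", "max_intensity",
        ])


def _as_image(image) -> tuple[np.ndarray, tuple[float, float, float]]:
    if isinstance(image, ImageStack):
        if image.n_channels != 1:
            raise ValueError("segmentation expects a single-channel image")
        arr = image.voxels if image.voxels.ndim == 3 else image.voxels[..., 0]
        return np.asarray(arr, dtype=float), image.spacing
    return np.asarray(image, dtype=float), (1.0, 1.0, 1.0)


def steepest_ascent_label(
    image,
    mask: np.ndarray | None = None,
    neighborhood: Neighborhood = Neighborhood("cross", 1),
) -> LabelMap:
    """Label basins of attraction by steepest intensity ascent.

    For each in-mask voxel the parent is the in-mask neighbour maximising
    (I_neigh - I_current) / d, with d the Euclidean distance between voxel
    centers in physical units. Non-positive best slope means the voxel is
    its own parent (a local attractor). Parents are defined pointwise, so
    the result is independent of any visiting order; slope ties resolve to
    the lexicographically smallest (z, y, x) offset.
    """
    img, spacing = _as_image(image)
    if not np.all(np.isfinite(img)):
        raise ValueError("intensities must be finite")
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("image and mask shapes differ")

    shape = img.shape
    n = img.size
    flat_idx = np.arange(n).reshape(shape)
    parent = flat_idx.copy()  # background voxels point at themselves

    if not mask.any():
        return LabelMap(labels=np.zeros(shape, dtype=np.int32), spacing=spacing)

    best_slope = np.full(shape, 0.0)  # only strictly positive slopes beat self
    sp = np.asarray(spacing)

    for off in neighborhood.offsets(spacing):
        dist = float(np.linalg.norm(off * sp))
        # source region in the current array whose neighbour at `off` is in bounds
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        valid = mask[src] & mask[dst]
        slope = (img[dst] - img[src]) / dist
        better = valid & (slope > best_slope[src])
        # strict > keeps the first (lexicographically smallest) offset on ties
        bs = best_slope[src]
        bs[better] = slope[better]
        best_slope[src] = bs
        pr = parent[src]
        pr[better] = flat_idx[dst][better]
        parent[src] = pr

    # collapse parent pointers to roots (path doubling; ascent graph is acyclic)
    flat_parent = parent.ravel()
    while True:
        grand = flat_parent[flat_parent]
        if np.array_equal(grand, flat_parent):
            break
        flat_parent = grand

    roots = flat_parent.reshape(shape)
    labels = np.zeros(shape, dtype=np.int32)
    root_ids = np.unique(roots[mask])
    lut = {r: i + 1 for i, r in enumerate(root_ids.tolist())}
    labels[mask] = np.vectorize(lut.__getitem__, otypes=[np.int32])(roots[mask])

    attractors = {lut[r]: int(r) for r in root_ids.tolist()}
    flat_img = img.ravel()
    intensities = {lab: float(flat_img[flat]) for lab, flat in attractors.items()}
    return LabelMap(
        labels=labels,
        attractors=attractors,
        attractor_intensity=intensities,
        spacing=spacing,
    )


def _relabel_by_union(lm: LabelMap, groups: list[list[int]]) -> LabelMap:
    """Merge each group of ids into one object (attractor = brightest)."""
    old_ids = lm.ids
    mapping = {}
    new_attractors = {}
    new_intensity = {}
    grouped = set()
    next_id = 1
    for group in groups:
        best = max(group, key=lambda g: lm.attractor_intensity.get(g, -np.inf))
        for g in group:
            mapping[g] = next_id
            grouped.add(g)
        new_attractors[next_id] = lm.attractors[best]
        new_intensity[next_id] = lm.attractor_intensity.get(best, np.nan)
        next_id += 1
    for lab in old_ids.tolist():
        if lab not in grouped:
            mapping[lab] = next_id
            new_attractors[next_id] = lm.attractors[lab]
            new_intensity[next_id] = lm.attractor_intensity.get(lab, np.nan)
            next_id += 1
    lut = np.zeros(int(old_ids.max()) + 1 if len(old_ids) else 1, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    return LabelMap(
        labels=lut[lm.labels],
        attractors=new_attractors,
        attractor_intensity=new_intensity,
        spacing=lm.spacing,
    )


def merge_by_distance(lm: LabelMap, max_distance: float) -> LabelMap:
    """Merge objects whose attractors lie within ``max_distance`` (um).

    Closeness is transitive: chains of attractors each within the threshold
    collapse into one object whose attractor is the brightest of the union.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    ids = lm.ids
    if len(ids) < 2:
        return lm
    coords = lm.attractor_coords_um()
    pts = np.array([coords[i] for i in ids])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(max_distance, output_type="ndarray")
    if len(pairs) == 0:
        return lm
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(ids), len(ids))
    )
    n_comp, comp = connected_components(adj, directed=False)
    groups = []
    for c in range(n_comp):
        members = ids[comp == c].tolist()
        if len(members) > 1:
            groups.append(members)
    return _relabel_by_union(lm, groups)


def merge_by_depth(
    lm: LabelMap,
    image,
    depth_threshold: float,
    neighborhood: Neighborhood = Neighborhood("cross", 1),
    mode: str = "min",
) -> LabelMap:
    """Merge neighbouring basins separated by a shallow intensity valley.

    For each pair of adjacent objects the intensity depth is
    ``f(max_A, max_B) - min(boundary intensity)`` where the boundary is the
    set of voxels of either object adjacent to the other. ``mode`` selects
    ``f``: "min" (default — the weaker object's depth governs, merging
    shallow sub-peaks) or "max". Pairs with depth strictly below the
    threshold merge; merging repeats until no pair qualifies.
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    img, _ = _as_image(image)
    offsets = neighborhood.offsets(lm.spacing)

    current = lm
    while True:
        labels = current.labels
        ids = current.ids
        if len(ids) < 2:
            return current
        shape = labels.shape
        max_int = ndimage.maximum(img, labels=labels, index=ids)
        max_of = dict(zip(ids.tolist(), max_int))

        # min boundary intensity per adjacent pair, across all offsets
        pair_min: dict[tuple[int, int], float] = {}
        for off in offsets:
            src = tuple(slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape))
            dst = tuple(slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape))
            a = labels[src]
            b = labels[dst]
            touching = (a > 0) & (b > 0) & (a != b)
            if not touching.any():
                continue
            pa = a[touching]
            pb = b[touching]
            # both sides of the interface are boundary voxels
            inten_a = img[src][touching]
            inten_b = img[dst][touching]
            lo = np.minimum(pa, pb)
            hi = np.maximum(pa, pb)
            both = np.minimum(inten_a, inten_b)
            df = pd.DataFrame({"lo": lo, "hi": hi, "v": both})
            for (l_, h_), v in df.groupby(["lo", "hi"])["v"].min().items():
                key = (int(l_), int(h_))
                pair_min[key] = min(pair_min.get(key, np.inf), float(v))

        to_merge = []
        for (a_id, b_id), bmin in pair_min.items():
            regional = (
                min(max_of[a_id], max_of[b_id])
                if mode == "min"
                else max(max_of[a_id], max_of[b_id])
            )
            depth = regional - bmin
            if depth < depth_threshold:
                to_merge.append((a_id, b_id))
        if not to_merge:
            return current

        idx = {i: k for k, i in enumerate(ids.tolist())}
        rows = [idx[a] for a, _ in to_merge]
        cols = [idx[b] for _, b in to_merge]
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
        )
        n_comp, comp = connected_components(adj, directed=False)
        groups = [
            ids[comp == c].tolist()
            for c in range(n_comp)
            if np.count_nonzero(comp == c) > 1
        ]
        current = _relabel_by_union(current, groups)


def merge_small_to_closest(
    lm: LabelMap, size_threshold: float, max_merge_distance: float = np.inf
) -> LabelMap:
    """Absorb small objects into the nearest sufficiently large object.

    Objects with volume (um^3) below ``size_threshold`` merge into the
    nearest object at or above the threshold, by attractor-to-attractor
    distance, unless that distance exceeds ``max_merge_distance`` — then the
    small object is left as is. If no large object exists nothing happens.
    """
    if size_threshold < 0 or max_merge_distance < 0:
        raise ValueError("thresholds must be non-negative")
    vols = lm.volumes_voxels()
    vv = lm.voxel_volume()
    small = [i for i in lm.ids if vols.get(int(i), 0) * vv < size_threshold]
    large = [i for i in lm.ids if vols.get(int(i), 0) * vv >= size_threshold]
    if not small:
        return lm
    if not large:
        logger.warning(
            "merge_small_to_closest: no object reaches the %.3g um^3 threshold; "
            "leaving %d small objects unchanged", size_threshold, len(small)
        )
        return lm
    coords = lm.attractor_coords_um()
    big_pts = np.array([coords[i] for i in large])
    tree = cKDTree(big_pts)
    groups: dict[int, list[int]] = {int(i): [int(i)] for i in large}
    for s in small:
        d, j = tree.query(coords[s])
        if d <= max_merge_distance:
            groups[int(large[j])].append(int(s))
    merged = [g for g in groups.values() if len(g) > 1]
    return _relabel_by_union(lm, merged)


def remove_by_size(lm: LabelMap, min_volume: float) -> LabelMap:
    """Delete objects with volume (um^3) below ``min_volume``."""
    if min_volume < 0:
        raise ValueError("min_volume must be non-negative")
    vols = lm.volumes_voxels()
    vv = lm.voxel_volume()
    keep = [int(i) for i in lm.ids if vols.get(int(i), 0) * vv >= min_volume]
    return _keep_only(lm, keep)


def remove_by_intensity(lm: LabelMap, image, min_mean_intensity: float) -> LabelMap:
    """Delete objects whose mean intensity falls below the threshold."""
    img, _ = _as_image(image)
    ids = lm.ids
    if len(ids) == 0:
        return lm
    means = ndimage.mean(img, labels=lm.labels, index=ids)
    keep = [int(i) for i, m in zip(ids, means) if m >= min_mean_intensity]
    return _keep_only(lm, keep)


def _keep_only(lm: LabelMap, keep: list[int]) -> LabelMap:
    keep_set = set(keep)
    lut = np.zeros(int(lm.labels.max()) + 1 if lm.labels.size else 1, dtype=np.int32)
    new_attr = {}
    new_int = {}
    for new_id, old in enumerate(sorted(keep_set), start=1):
        lut[old] = new_id
        new_attr[new_id] = lm.attractors[old]
        new_int[new_id] = lm.attractor_intensity.get(old, np.nan)
    return LabelMap(
        labels=lut[lm.labels],
        attractors=new_attr,
        attractor_intensity=new_int,
        spacing=lm.spacing,
    )


def morph_labels(lm: LabelMap, operation: str, radius: int = 1) -> LabelMap:
    """Per-label morphological erosion / dilation / opening / closing.

    Each label is processed as its own binary mask (within a padded
    bounding box). Dilation and closing never overwrite another label: a
    voxel claimed by more than one label, or already owned, keeps its
    original value. Labels that erode away vanish.
    """
    from skimage.morphology import erosion, dilation, ball

    if operation not in ("erode", "dilate", "open", "close"):
        raise ValueError(f"unknown operation {operation!r}")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    selem = ball(radius)
    labels = lm.labels
    shape = labels.shape
    new = np.zeros_like(labels)
    claims = np.zeros(shape, dtype=np.int16)
    results: dict[int, tuple[tuple[slice, ...], np.ndarray]] = {}

    objects = ndimage.find_objects(labels)
    for lab in lm.ids:
        sl = objects[int(lab) - 1]
        if sl is None:
            continue
        pad = 2 * radius
        psl = tuple(
            slice(max(0, s.start - pad), min(dim, s.stop + pad))
            for s, dim in zip(sl, shape)
        )
        m = labels[psl] == lab
        ops = {
            "erode": [erosion],
            "dilate": [dilation],
            "open": [erosion, dilation],
            "close": [dilation, erosion],
        }[operation]
        for op in ops:
            m = op(m, selem).astype(bool)
        results[int(lab)] = (psl, m)
        claims[psl] += m.astype(np.int16)

    new_attr = {}
    new_int = {}
    for lab, (psl, m) in results.items():
        region = np.zeros(shape, dtype=bool)
        region[psl] = m
        # uncontested new ground, plus own original voxels still covered
        ok = region & (
            ((labels == 0) & (claims == 1)) | (labels == lab)
        )
        if not ok.any():
            continue
        new[ok] = lab
        flat = lm.attractors.get(lab)
        if flat is not None and ok.ravel()[flat]:
            new_attr[lab] = flat
            new_int[lab] = lm.attractor_intensity.get(lab, np.nan)
        else:
            new_attr[lab] = int(np.flatnonzero(ok.ravel())[0])
            new_int[lab] = np.nan
    # voxels owned before and claimed by several dilations keep their owner
    contested = (claims > 1) & (labels > 0)
    new[contested] = labels[contested]
    keep = [int(i) for i in np.unique(new) if i > 0]
    out = LabelMap(
        labels=new,
        attractors={k: v for k, v in new_attr.items() if k in keep},
        attractor_intensity={k: v for k, v in new_int.items() if k in keep},
        spacing=lm.spacing,
    )
    return _keep_only(out, keep)
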
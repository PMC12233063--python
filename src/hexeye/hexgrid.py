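"""Hexagonal-grid segmentation of ommatidia on a facet probability map.

Every ommatidium carries an integer axial coordinate ``(x_hex, y_hex)`` on
the hexagonal lattice and a continuous image coordinate ``(x, y)``. The grid
is seeded from three mutually adjacent facets at the eye center and grown
one ommatidium at a time: each registered triplet (omtd1, omtd2, omtd3) of
mutually adjacent facets predicts a fourth by point reflection of omtd1
through the omtd2–omtd3 midpoint,

    hex4 = hex2 + hex3 - hex1,      pos4 = pos2 + pos3 - pos1,

and the prediction is refined by fitting a three-circle ("Mickey") template
to the facet probability map: the two known neighbors are the "ears", the
candidate is the "face". Because each new facet is placed relative to its
immediate neighbors, the expansion adapts to the gradual change of facet
spacing and orientation across the curved eye, including the compressed rim.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "HEX_NEIGHBOR_OFFSETS",
    "Ommatidium",
    "HexGrid",
    "MickeyTemplate",
    "CandidateFit",
    "ExpansionConfig",
    "seed_grid",
    "auto_seed",
    "mirror_predict",
    "grid_edge_length",
    "build_mickey_template",
    "affine_from_anchors",
    "slant_from_affine",
    "fit_candidate",
    "expand_grid",
    "add_manual",
    "remove",
]

#: Axial-coordinate offsets of the six hexagonal neighbors.
HEX_NEIGHBOR_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))

_OFFSET_SET = frozenset(HEX_NEIGHBOR_OFFSETS)


@dataclass
class Ommatidium:
    """One facet: lattice coordinate, image position, optional altitude/slant."""

    hex: tuple[int, int]
    pos: np.ndarray
    z: float | None = None
    slant: float | None = None  # apparent tilt from normal view, degrees
    origin: str = "auto"  # {"seed", "auto", "manual"}

    def __post_init__(self) -> None:
        self.hex = (int(self.hex[0]), int(self.hex[1]))
        self.pos = np.asarray(self.pos, dtype=float)


def _is_adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return (a[0] - b[0], a[1] - b[1]) in _OFFSET_SET


def _cross2(a, b) -> float:
    """z-component of the cross product of two 2D vectors."""
    return float(a[0] * b[1] - a[1] * b[0])


class HexGrid:
    """A growing set of ommatidia with unique hexagonal coordinates.

    Two ommatidia are neighbors iff their hex difference is one of the six
    axial offsets; every interior facet therefore has exactly six neighbors.
    """

    def __init__(self) -> None:
        self._by_hex: dict[tuple[int, int], Ommatidium] = {}

    def __len__(self) -> int:
        return len(self._by_hex)

    def __contains__(self, hex_: tuple[int, int]) -> bool:
        return (int(hex_[0]), int(hex_[1])) in self._by_hex

    def __getitem__(self, hex_: tuple[int, int]) -> Ommatidium:
        return self._by_hex[(int(hex_[0]), int(hex_[1]))]

    def __iter__(self):
        return iter(self._by_hex.values())

    def add(self, omtd: Ommatidium) -> None:
        if omtd.hex in self._by_hex:
            raise ValueError(f"hex coordinate {omtd.hex} already occupied")
        self._by_hex[omtd.hex] = omtd

    def discard(self, hex_: tuple[int, int]) -> Ommatidium:
        hex_ = (int(hex_[0]), int(hex_[1]))
        if hex_ not in self._by_hex:
            raise ValueError(f"no ommatidium at hex {hex_}")
        return self._by_hex.pop(hex_)

    def hexes(self) -> list[tuple[int, int]]:
        return list(self._by_hex.keys())

    def positions(self) -> np.ndarray:
        """(N, 2) array of image positions, in insertion order."""
        if not self._by_hex:
            return np.empty((0, 2))
        return np.array([o.pos for o in self._by_hex.values()])

    def neighbors(self, hex_: tuple[int, int]) -> list[Ommatidium]:
        x, y = int(hex_[0]), int(hex_[1])
        out = []
        for dx, dy in HEX_NEIGHBOR_OFFSETS:
            o = self._by_hex.get((x + dx, y + dy))
            if o is not None:
                out.append(o)
        return out

    def adjacent_pairs(self) -> list[tuple[Ommatidium, Ommatidium]]:
        """All unordered hex-adjacent pairs (each once)."""
        pairs = []
        for (x, y), o in self._by_hex.items():
            for dx, dy in ((1, 0), (0, 1), (1, -1)):  # half the offsets: each pair once
                n = self._by_hex.get((x + dx, y + dy))
                if n is not None:
                    pairs.append((o, n))
        return pairs

    def copy(self) -> "HexGrid":
        g = HexGrid()
        for o in self:
            g.add(replace(o, pos=o.pos.copy()))
        return g

    @property
    def L_grid(self) -> float:
        return grid_edge_length(self)


def grid_edge_length(grid: HexGrid) -> float:
    """Average center-to-center distance of hex-adjacent ommatidia (px)."""
    pairs = grid.adjacent_pairs()
    if not pairs:
        raise ValueError("grid has no adjacent pairs")
    d = [float(np.linalg.norm(a.pos - b.pos)) for a, b in pairs]
    return float(np.mean(d))


def seed_grid(p0, p1, p2) -> HexGrid:
    """Seed the grid from three mutually adjacent facet centers.

    The three points receive hex coordinates (0,0), (1,0), (0,1); the grid's
    orientation on the image is thereby fixed. Points must be mutually close
    (largest pairwise distance within 3x the smallest) and non-collinear.
    """
    pts = [np.asarray(p, dtype=float) for p in (p0, p1, p2)]
    d = [np.linalg.norm(pts[i] - pts[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
    if min(d) <= 0:
        raise ValueError("seed points must be distinct")
    if max(d) > 3.0 * min(d):
        raise ValueError("seed points are not mutually close")
    area2 = abs(_cross2(pts[1] - pts[0], pts[2] - pts[0]))
    if area2 < 1e-9 * max(d) ** 2:
        raise ValueError("degenerate (collinear) seed triplet")
    grid = HexGrid()
    for hex_, p in zip(((0, 0), (1, 0), (0, 1)), pts):
        grid.add(Ommatidium(hex_, p, origin="seed"))
    return grid


def mirror_predict(
    omtd1: Ommatidium, omtd2: Ommatidium, omtd3: Ommatidium
) -> tuple[tuple[int, int], np.ndarray]:
    """Spawn position of a fourth facet by mirroring omtd1 through omtd2/omtd3.

    Point reflection of omtd1 through the midpoint of the omtd2–omtd3 edge,
    in both lattice and image coordinates:

        hex4 = hex2 + hex3 - hex1,      pos4 = pos2 + pos3 - pos1.

    The operation is an involution: mirroring the result back through the
    same pair returns omtd1 exactly.
    """
    h1, h2, h3 = omtd1.hex, omtd2.hex, omtd3.hex
    if not (_is_adjacent(h1, h2) and _is_adjacent(h1, h3) and _is_adjacent(h2, h3)):
        raise ValueError("omtd1, omtd2, omtd3 must be mutually hex-adjacent")
    hex4 = (h2[0] + h3[0] - h1[0], h2[1] + h3[1] - h1[1])
    pos4 = omtd2.pos + omtd3.pos - omtd1.pos
    return hex4, pos4


# ---------------------------------------------------------------------------
# Mickey template


@dataclass(frozen=True)
class MickeyTemplate:
    """The m x m three-circle template with its NaN ignore region.

    Three identical filled circles of radius 0.225*m whose centers form an
    equilateral triangle of side 0.5*m (two "ears" on top, the "face" below),
    smoothed with a Gaussian of sigma = m/20. Pixels outside the union of
    the circles dilated by 0.05*m are NaN and never scored, so surrounding
    ommatidia cannot interfere with the fit.
    """

    m: int
    image: np.ndarray  # (m, m), NaN outside the scored region
    anchors: np.ndarray  # (3, 2): ear1, ear2, face centers in template (x, y)
    pixels: np.ndarray = field(repr=False, default=None)  # (N, 2) scored (x, y)
    values: np.ndarray = field(repr=False, default=None)  # (N,) template values
    barycentric: np.ndarray = field(repr=False, default=None)  # (N, 3) wrt anchors
    face_region: np.ndarray = field(repr=False, default=None)  # (N,) bool: face circle


@lru_cache(maxsize=64)
def build_mickey_template(m: int) -> MickeyTemplate:
    """Construct (and cache) the three-circle template of side ``m`` px."""
    if m < 20:
        raise ValueError("m must be >= 20 (sigma = m/20 smoothing needs room)")
    L = 0.5 * m
    h = L * np.sqrt(3) / 2.0
    cx, cy = (m - 1) / 2.0, (m - 1) / 2.0
    ear1 = np.array([cx - L / 2.0, cy - h / 3.0])
    ear2 = np.array([cx + L / 2.0, cy - h / 3.0])
    face = np.array([cx, cy + 2.0 * h / 3.0])
    anchors = np.stack([ear1, ear2, face])
    xs, ys = np.meshgrid(np.arange(m), np.arange(m))
    r = 0.225 * m
    d2 = np.stack([(xs - a[0]) ** 2 + (ys - a[1]) ** 2 for a in anchors])
    binary = (d2 <= r * r).any(axis=0).astype(float)
    smooth = ndimage.gaussian_filter(binary, sigma=m / 20.0, mode="constant")
    keep = (d2 <= (r + 0.05 * m) ** 2).any(axis=0)
    image = np.where(keep, smooth, np.nan)
    pix = np.column_stack([xs[keep], ys[keep]]).astype(float)
    vals = smooth[keep]
    # Barycentric coordinates of every scored pixel w.r.t. the three anchors:
    # any affine map of the anchors moves the pixel to the same combination
    # of the mapped anchors, so poses can be evaluated without re-solving.
    T = np.vstack([anchors.T, np.ones(3)])
    bary = np.linalg.solve(T, np.vstack([pix.T, np.ones(len(pix))])).T
    # nearest-anchor assignment of each scored pixel; anchor 2 is the face
    d2keep = np.stack([d[keep] for d in d2])
    face_region = np.argmin(d2keep, axis=0) == 2
    return MickeyTemplate(m=m, image=image, anchors=anchors, pixels=pix,
                          values=vals, barycentric=bary, face_region=face_region)


def affine_from_anchors(template: MickeyTemplate, ear1, ear2, face) -> np.ndarray:
    """The 2x3 affine map sending the template anchors onto three image points.

    Every non-NaN template pixel (i, j) then maps to image coordinate
    ``A @ (i, j, 1)``. Raises on collinear targets (singular transform).
    """
    targets = np.array([ear1, ear2, face], dtype=float)
    src = np.vstack([template.anchors.T, np.ones(3)])  # 3x3
    if abs(np.linalg.det(src)) < 1e-12:
        raise ValueError("template anchors are degenerate")
    area2 = abs(_cross2(targets[1] - targets[0], targets[2] - targets[0]))
    scale2 = max(np.ptp(targets, axis=0).max(), 1.0) ** 2
    if area2 < 1e-9 * scale2:
        raise ValueError("collinear target points: singular transform")
    # A @ src = targets.T  ->  A = targets.T @ inv(src)
    return targets.T @ np.linalg.inv(src)


def slant_from_affine(A: np.ndarray) -> float:
    """Apparent facet tilt (degrees from normal view) of an affine pose.

    A facet viewed at tilt beta is foreshortened by cos(beta) along one axis,
    so the singular values of the linear part satisfy s_min/s_max = cos(beta).
    """
    s = np.linalg.svd(np.asarray(A)[:, :2], compute_uv=False)
    ratio = np.clip(s.min() / s.max(), -1.0, 1.0)
    return float(np.degrees(np.arccos(ratio)))


@dataclass
class CandidateFit:
    """Result of fitting the template for one prospective ommatidium."""

    pos: np.ndarray  # fitted face center (x4, y4)
    delta: float  # objective value; +inf means rejected
    theta: float  # fitted brightness factor
    transform: np.ndarray  # 2x3 affine, template -> image, at the best pose
    slant: float  # apparent tilt of the best pose, degrees
    predicted: np.ndarray = None  # mirror prediction the search centered on


@dataclass
class ExpansionConfig:
    """Tunables of the grid expansion.

    search_radius_frac : candidate face positions are scanned within this
        fraction of L_grid around the mirror prediction; fits farther than
        that are rejected outright (hard constraint of the objective).
    accept_radius_frac : only a fit within this fraction of L_grid of its
        prediction is registered ("closest ommatidium within L_grid/2").
    slant_max : reject fits whose apparent tilt exceeds this (a facet seen
        <20 deg from grazing, i.e. tilted >70 deg from normal view).
    slant_tol : reject fits whose tilt differs from omtd1's by more than this.
    min_separation_frac : never register two ommatidia closer than this
        fraction of L_grid.
    face_mass_ratio : reject fits whose mean probability under the face
        circle is below this fraction of the mean under the ear circles.
        The masked squared error is degenerate when the face region of the
        map is blank (theta is carried by the ears and the empty face adds
        ~0 error), so the face must hold probability mass of its own.
    max_iter : optional cap on the number of accepted ommatidia.
    """

    search_radius_frac: float = 0.3
    accept_radius_frac: float = 0.5
    slant_max: float = 70.0
    slant_tol: float = 30.0
    min_separation_frac: float = 0.5
    face_mass_ratio: float = 0.25
    max_iter: int | None = None
    template_m: int | None = None


def _score_poses(
    facet_prob: np.ndarray,
    template: MickeyTemplate,
    ear1_pos: np.ndarray,
    ear2_pos: np.ndarray,
    candidates: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Delta and theta for a batch of candidate face positions.

    For each pose, theta minimizing sum_(i,j) (I_prob(A(i,j)) - theta *
    I_mouse(i,j))^2 has the closed form theta* = sum(p t) / sum(t^2); the
    minimal objective is then sum(p^2) - (sum(p t))^2 / sum(t^2).
    """
    bary = template.barycentric  # (N, 3)
    t = template.values
    base = bary[:, 0:1] * ear1_pos[None, :] + bary[:, 1:2] * ear2_pos[None, :]
    # coords: (ncand, N, 2)
    coords = base[None, :, :] + bary[None, :, 2:3] * candidates[:, None, :]
    flat = coords.reshape(-1, 2)
    p = ndimage.map_coordinates(
        facet_prob, [flat[:, 1], flat[:, 0]], order=1, mode="constant", cval=0.0
    ).reshape(len(candidates), -1)
    tt = float(t @ t)
    pt = p @ t
    theta = pt / tt
    delta = (p * p).sum(axis=1) - pt * pt / tt
    face = template.face_region
    face_mean = p[:, face].mean(axis=1)
    ear_mean = p[:, ~face].mean(axis=1)
    return np.maximum(delta, 0.0), theta, face_mean, ear_mean


def fit_candidate(
    facet_prob: np.ndarray,
    ear1: Ommatidium,
    ear2: Ommatidium,
    predicted: np.ndarray,
    omtd1: Ommatidium,
    L_grid: float,
    config: ExpansionConfig | None = None,
) -> CandidateFit:
    """Locate a new ommatidium near its mirror prediction by template fitting.

    Candidate face positions (x4, y4) are scanned on the integer-pixel grid
    within a disk of radius ``search_radius_frac * L_grid`` around the
    prediction; each pose maps the template onto (ear1, ear2, candidate) by
    an affine transform and scores the masked squared error against the
    facet probability map with a closed-form brightness factor theta. The
    best pose is refined to sub-pixel precision by parabolic interpolation.

    The returned fit carries ``delta = +inf`` (rejected) when the best pose
    is farther than the search radius from the prediction, or its apparent
    tilt exceeds ``slant_max``, or differs from omtd1's tilt by more than
    ``slant_tol``.
    """
    cfg = config or ExpansionConfig()
    predicted = np.asarray(predicted, dtype=float)
    h, w = facet_prob.shape
    m = cfg.template_m or max(20, int(round(2.0 * L_grid)))
    template = build_mickey_template(m)
    radius = cfg.search_radius_frac * L_grid
    rint = int(np.floor(radius))
    offs = np.array(
        [
            (dx, dy)
            for dy in range(-rint, rint + 1)
            for dx in range(-rint, rint + 1)
            if dx * dx + dy * dy <= radius * radius
        ],
        dtype=float,
    )
    base = np.round(predicted)
    cand = base[None, :] + offs
    # keep the prediction itself in the scan, plus in-image candidates only
    cand = np.vstack([predicted[None, :], cand])
    inside = (
        (cand[:, 0] >= 0) & (cand[:, 0] <= w - 1)
        & (cand[:, 1] >= 0) & (cand[:, 1] <= h - 1)
        & (np.linalg.norm(cand - predicted, axis=1) <= radius + 1e-9)
    )
    cand = cand[inside]
    if len(cand) == 0:
        raise ValueError("no candidate position maps inside the image")
    delta, theta, _, _ = _score_poses(facet_prob, template, ear1.pos, ear2.pos, cand)
    k = int(np.argmin(delta))
    best = cand[k]
    # Parabolic sub-pixel refinement on the integer scan grid around `best`.
    refined = best.copy()
    lookup = {tuple(c): (d,) for c, d in zip(map(tuple, cand), delta)}
    for axis, unit in ((0, np.array([1.0, 0.0])), (1, np.array([0.0, 1.0]))):
        lo = lookup.get(tuple(best - unit))
        hi = lookup.get(tuple(best + unit))
        if lo is not None and hi is not None:
            denom = lo[0] - 2.0 * delta[k] + hi[0]
            if denom > 1e-12:
                shift = 0.5 * (lo[0] - hi[0]) / denom
                refined[axis] += float(np.clip(shift, -0.5, 0.5))
    d_ref, t_ref, fm_ref, em_ref = _score_poses(
        facet_prob, template, ear1.pos, ear2.pos, refined[None, :]
    )
    face_mean, ear_mean = float(fm_ref[0]), float(em_ref[0])
    if d_ref[0] <= delta[k]:
        best, best_delta, best_theta = refined, float(d_ref[0]), float(t_ref[0])
    else:
        best_delta, best_theta = float(delta[k]), float(theta[k])
    A = affine_from_anchors(template, ear1.pos, ear2.pos, best)
    slant = slant_from_affine(A)
    fit = CandidateFit(
        pos=best, delta=best_delta, theta=best_theta, transform=A,
        slant=slant, predicted=predicted,
    )
    if np.linalg.norm(best - predicted) > radius + 1e-9:
        fit.delta = np.inf
    if slant > cfg.slant_max:
        fit.delta = np.inf
    if omtd1.slant is not None and abs(slant - omtd1.slant) > cfg.slant_tol:
        fit.delta = np.inf
    if face_mean < cfg.face_mass_ratio * max(ear_mean, 1e-12):
        fit.delta = np.inf
    return fit


# ---------------------------------------------------------------------------
# Grid expansion


def _triplets_with(grid: HexGrid, omtd: Ommatidium):
    """Mutually adjacent triplets containing `omtd` (pairs of its neighbors)."""
    nbrs = grid.neighbors(omtd.hex)
    for a, b in itertools.combinations(nbrs, 2):
        if _is_adjacent(a.hex, b.hex):
            yield omtd, a, b


def _candidate_entries(grid: HexGrid, triplet, facet_prob, L_grid, cfg):
    """Fit every unoccupied mirror slot of one mutually adjacent triplet."""
    entries = []
    for o1, o2, o3 in (
        (triplet[0], triplet[1], triplet[2]),
        (triplet[1], triplet[0], triplet[2]),
        (triplet[2], triplet[0], triplet[1]),
    ):
        hex4, pos4 = mirror_predict(o1, o2, o3)
        if hex4 in grid:
            continue
        h, w = facet_prob.shape
        if not (0 <= pos4[0] <= w - 1 and 0 <= pos4[1] <= h - 1):
            continue
        fit = fit_candidate(facet_prob, o2, o3, pos4, o1, L_grid, cfg)
        if np.isfinite(fit.delta):
            entries.append((fit.delta, hex4, fit))
    return entries


def expand_grid(grid: HexGrid, maps, config: ExpansionConfig | None = None) -> HexGrid:
    """Grow the grid until no admissible ommatidium remains; returns `grid`.

    Best-first expansion: all unoccupied mirror slots of registered mutually
    adjacent triplets are fitted to the facet probability map and kept in a
    priority queue on the objective value; the best fit is accepted first
    (ties broken by hex coordinate), registered at its fitted position, and
    the new triplets it forms are fitted in turn. A fit is registered only if
    it lies within ``accept_radius_frac * L_grid`` of its mirror prediction,
    its face center falls inside the eye mask, and it is not closer than
    ``min_separation_frac * L_grid`` to an already-registered ommatidium.
    L_grid is recomputed (running mean over all adjacent pairs) after every
    acceptance. The grid is modified in place.

    Parameters
    ----------
    grid : HexGrid
        A seeded (or partially expanded) grid.
    maps : ProbabilityMaps
        Needs ``facet_prob`` and ``eye_mask``.
    """
    cfg = config or ExpansionConfig()
    facet_prob = np.asarray(maps.facet_prob, dtype=float)
    eye_mask = np.asarray(maps.eye_mask, dtype=bool)
    # running L_grid bookkeeping
    pair_sum = 0.0
    pair_n = 0
    for a, b in grid.adjacent_pairs():
        pair_sum += float(np.linalg.norm(a.pos - b.pos))
        pair_n += 1
    if pair_n == 0:
        raise ValueError("grid must contain at least one adjacent pair")
    counter = itertools.count()
    heap: list = []

    def push(entries):
        for delta, hex4, fit in entries:
            heapq.heappush(heap, (delta, hex4, next(counter), fit))

    seen_triplets = set()
    for omtd in list(grid):
        for trip in _triplets_with(grid, omtd):
            key = frozenset(o.hex for o in trip)
            if key not in seen_triplets:
                seen_triplets.add(key)
                push(_candidate_entries(grid, trip, facet_prob, pair_sum / pair_n, cfg))

    accepted = 0
    while heap:
        _, hex4, _, fit = heapq.heappop(heap)
        if hex4 in grid:
            continue
        L = pair_sum / pair_n
        if np.linalg.norm(fit.pos - fit.predicted) > cfg.accept_radius_frac * L:
            continue
        xi, yi = int(round(fit.pos[0])), int(round(fit.pos[1]))
        if not (0 <= yi < eye_mask.shape[0] and 0 <= xi < eye_mask.shape[1]):
            continue
        if not eye_mask[yi, xi]:
            continue
        pos_all = grid.positions()
        if np.min(np.linalg.norm(pos_all - fit.pos[None, :], axis=1)) < cfg.min_separation_frac * L:
            continue
        omtd = Ommatidium(hex4, fit.pos, slant=fit.slant, origin="auto")
        grid.add(omtd)
        for nbr in grid.neighbors(hex4):
            pair_sum += float(np.linalg.norm(nbr.pos - omtd.pos))
            pair_n += 1
        accepted += 1
        if cfg.max_iter is not None and accepted >= cfg.max_iter:
            break
        push_entries = []
        for trip in _triplets_with(grid, omtd):
            push_entries += _candidate_entries(grid, trip, facet_prob, pair_sum / pair_n, cfg)
        push(push_entries)
    return grid


def auto_seed(maps, prob_threshold: float = 0.5) -> HexGrid:
    """Seed from the facet probability map without user input.

    Facet interiors are separated by low-probability boundary ridges, so
    thresholding the facet map inside the eye region splits it into one
    connected blob per facet; blob centroids are facet-center estimates.
    The grid is seeded from the three mutually closest centroids nearest
    the eye centroid (where facets are imaged face-on and most regular).
    """
    from skimage.measure import label as cc_label
    from skimage.measure import regionprops

    facet_prob = np.asarray(maps.facet_prob, dtype=float)
    eye_mask = np.asarray(maps.eye_mask, dtype=bool)
    bw = (facet_prob >= prob_threshold) & eye_mask
    labels = cc_label(bw, connectivity=1)
    props = regionprops(labels)
    areas = np.array([p.area for p in props])
    if len(areas) < 3:
        raise ValueError("not enough facet blobs to auto-seed")
    # drop specks (< 20% of the median blob area)
    keep = areas >= 0.2 * np.median(areas)
    cents = np.array([props[i].centroid[::-1] for i in np.flatnonzero(keep)])  # (x, y)
    if len(cents) < 3:
        raise ValueError("not enough facet blobs to auto-seed")
    ys, xs = np.nonzero(eye_mask)
    centroid = np.array([xs.mean(), ys.mean()])
    p0 = cents[np.argmin(np.linalg.norm(cents - centroid, axis=1))]
    rest = cents[np.linalg.norm(cents - p0, axis=1) > 1e-9]
    p1 = rest[np.argmin(np.linalg.norm(rest - p0, axis=1))]
    rest2 = rest[np.linalg.norm(rest - p1, axis=1) > 1e-9]
    cost = np.linalg.norm(rest2 - p0, axis=1) + np.linalg.norm(rest2 - p1, axis=1)
    for k in np.argsort(cost):
        p2 = rest2[k]
        if abs(_cross2(p1 - p0, p2 - p0)) > 1e-6:
            try:
                return seed_grid(p0, p1, p2)
            except ValueError:
                continue
    raise ValueError("could not find a non-degenerate seed triplet")


# ---------------------------------------------------------------------------
# Manual correction


def _local_frame(grid: HexGrid, omtd: Ommatidium) -> np.ndarray | None:
    """Least-squares linear map from hex offsets to image offsets at `omtd`."""
    nbrs = grid.neighbors(omtd.hex)
    if len(nbrs) < 2:
        return None
    H = np.array([[n.hex[0] - omtd.hex[0], n.hex[1] - omtd.hex[1]] for n in nbrs], float)
    P = np.array([n.pos - omtd.pos for n in nbrs])
    if np.linalg.matrix_rank(H) < 2:
        return None
    F, *_ = np.linalg.lstsq(H, P, rcond=None)
    return F.T  # 2x2: pos_delta = F @ hex_delta


def add_manual(grid: HexGrid, pos) -> HexGrid:
    """Register a manually placed ommatidium, inferring its hex coordinate.

    The coordinate is the unoccupied mirror slot of a registered mutually
    adjacent triplet whose predicted position is nearest to ``pos``; if no
    slot predicts within L_grid, the nearest registered ommatidium's open
    neighbor slot with the smallest positional residual (under its local
    lattice frame) is used instead. The grid is modified in place.
    """
    pos = np.asarray(pos, dtype=float)
    L = grid_edge_length(grid)
    pos_all = grid.positions()
    if np.min(np.linalg.norm(pos_all - pos[None, :], axis=1)) < 0.5 * L:
        raise ValueError("position duplicates an existing ommatidium")
    best_hex, best_d = None, np.inf
    seen = set()
    for omtd in list(grid):
        for trip in _triplets_with(grid, omtd):
            key = frozenset(o.hex for o in trip)
            if key in seen:
                continue
            seen.add(key)
            for o1, o2, o3 in (
                (trip[0], trip[1], trip[2]),
                (trip[1], trip[0], trip[2]),
                (trip[2], trip[0], trip[1]),
            ):
                hex4, pos4 = mirror_predict(o1, o2, o3)
                if hex4 in grid:
                    continue
                d = float(np.linalg.norm(pos4 - pos))
                if d < best_d:
                    best_hex, best_d = hex4, d
    if best_hex is not None and best_d <= L:
        grid.add(Ommatidium(best_hex, pos, origin="manual"))
        return grid
    # fallback: open neighbor slot of the nearest registered ommatidium
    omtds = list(grid)
    nearest = omtds[int(np.argmin([np.linalg.norm(o.pos - pos) for o in omtds]))]
    F = _local_frame(grid, nearest)
    if F is None:
        raise ValueError("cannot infer a hex coordinate near this position")
    best_hex, best_d = None, np.inf
    for dx, dy in HEX_NEIGHBOR_OFFSETS:
        hex4 = (nearest.hex[0] + dx, nearest.hex[1] + dy)
        if hex4 in grid:
            continue
        pred = nearest.pos + F @ np.array([dx, dy], float)
        d = float(np.linalg.norm(pred - pos))
        if d < best_d:
            best_hex, best_d = hex4, d
    if best_hex is None:
        raise ValueError("no open neighbor slot near this position")
    grid.add(Ommatidium(best_hex, pos, origin="manual"))
    return grid


def remove(grid: HexGrid, hex_: tuple[int, int]) -> HexGrid:
    """Remove the ommatidium at a hex coordinate (in place); errors if absent."""
    grid.discard(hex_)
    return grid
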
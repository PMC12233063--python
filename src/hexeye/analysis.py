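"""Morphometrics on a completed hexagonal grid.

Covers the quantitative read-outs of a segmented eye: per-ommatidium
altitude from the focus stack, 3D inter-ommatidial spacing (the lenses of
adjacent ommatidia are juxtaposed, so mean neighbor distance is a proxy for
facet diameter), polynomial contour maps with the location of the enlarged-
ommatidia zone, anterior-posterior column indexing (``x_hex + y_hex`` tracks
the birth order of R8 founder cells behind the morphogenetic furrow), column
profiles, and their alignment/averaging across eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hexeye.hexgrid import HEX_NEIGHBOR_OFFSETS, HexGrid, Ommatidium

__all__ = [
    "ColumnProfile",
    "SpacingMap",
    "SurfaceFit",
    "AlignedProfile",
    "assign_altitude",
    "spacing_per_ommatidium",
    "fit_surface",
    "recenter_and_orient",
    "column_profile",
    "align_profiles",
    "average_spacing_across_eyes",
    "count",
]

_ANTERIOR_VECTORS = {
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
    "up": (0.0, -1.0),  # image y grows downward
    "down": (0.0, 1.0),
}


def _anterior_vector(hint) -> np.ndarray:
    if isinstance(hint, str):
        try:
            v = _ANTERIOR_VECTORS[hint]
        except KeyError:
            raise ValueError(f"unknown anterior direction {hint!r}") from None
        return np.array(v)
    v = np.asarray(hint, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("anterior direction must be non-zero")
    return v / n


def assign_altitude(grid: HexGrid, altitude: np.ndarray, px_size: float) -> HexGrid:
    """Set each ommatidium's z from the altitude map (µm), in place.

    The altitude is sampled at the rounded image position; ``px_size``
    (µm/px) is stored on the grid so 3D distances can be computed in µm.

    Raises
    ------
    ValueError
        If any ommatidium lies outside the altitude map.
    """
    altitude = np.asarray(altitude, dtype=float)
    h, w = altitude.shape
    for omtd in grid:
        xi, yi = int(round(omtd.pos[0])), int(round(omtd.pos[1]))
        if not (0 <= xi < w and 0 <= yi < h):
            raise ValueError(f"ommatidium {omtd.hex} at {omtd.pos} outside altitude map")
        omtd.z = float(altitude[yi, xi])
    grid.px_size = float(px_size)
    return grid


@dataclass
class SpacingMap:
    """Per-ommatidium mean 3D neighbor distance, with optional surface fit."""

    hexes: list
    positions: np.ndarray  # (N, 2) image positions, px
    values: np.ndarray  # (N,) mean 3D neighbor distance, µm
    excluded: list = field(default_factory=list)  # isolated ommatidia
    surface: "SurfaceFit | None" = None


def spacing_per_ommatidium(grid: HexGrid, px_size: float | None = None) -> SpacingMap:
    """Mean 3D Euclidean distance from each ommatidium to its hex neighbors.

    Altitudes must have been assigned (z = 0 is allowed; missing z is
    treated as 0). Ommatidia with no registered neighbor are flagged in
    ``excluded`` and omitted from the map.
    """
    px = float(px_size if px_size is not None else getattr(grid, "px_size", 1.0))
    hexes, positions, values, excluded = [], [], [], []
    for omtd in grid:
        nbrs = grid.neighbors(omtd.hex)
        if not nbrs:
            excluded.append(omtd.hex)
            continue
        z0 = omtd.z or 0.0
        d = [
            float(
                np.sqrt(
                    (px * (n.pos[0] - omtd.pos[0])) ** 2
                    + (px * (n.pos[1] - omtd.pos[1])) ** 2
                    + ((n.z or 0.0) - z0) ** 2
                )
            )
            for n in nbrs
        ]
        hexes.append(omtd.hex)
        positions.append(omtd.pos.copy())
        values.append(float(np.mean(d)))
    return SpacingMap(
        hexes=hexes,
        positions=np.array(positions) if positions else np.empty((0, 2)),
        values=np.array(values),
        excluded=excluded,
    )


@dataclass
class SurfaceFit:
    """A least-squares bivariate polynomial surface over image positions."""

    degree: int
    coeffs: np.ndarray
    center: np.ndarray  # normalization offset
    scale: float  # normalization scale

    def _design(self, pts: np.ndarray) -> np.ndarray:
        q = (np.atleast_2d(pts) - self.center) / self.scale
        cols = [
            q[:, 0] ** a * q[:, 1] ** b
            for a in range(self.degree + 1)
            for b in range(self.degree + 1 - a)
        ]
        return np.column_stack(cols)

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        return self._design(pts) @ self.coeffs

    def raster(self, shape: tuple[int, int], mask: np.ndarray | None = None) -> np.ndarray:
        """Rasterized surface over an image grid; NaN outside `mask`."""
        h, w = shape
        ys, xs = np.mgrid[0:h, 0:w]
        vals = self.evaluate(np.column_stack([xs.ravel(), ys.ravel()])).reshape(h, w)
        if mask is not None:
            vals = np.where(mask, vals, np.nan)
        return vals

    def peak(self, shape: tuple[int, int], mask: np.ndarray | None = None) -> np.ndarray:
        """Image position (x, y) of the surface maximum within the mask."""
        vals = self.raster(shape, mask)
        flat = np.nanargmax(vals)
        y, x = np.unravel_index(flat, vals.shape)
        return np.array([float(x), float(y)])


def fit_surface(positions: np.ndarray, values: np.ndarray, degree: int = 3) -> SurfaceFit:
    """Least-squares bivariate polynomial (default cubic) smoothing.

    Used to turn scattered per-ommatidium altitude or spacing values into a
    smooth contour map; the location of the map's maximum marks the zone of
    enlarged ommatidia.

    Raises
    ------
    ValueError
        If fewer points than polynomial coefficients, or the design is
        rank-deficient.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    n_coef = (degree + 1) * (degree + 2) // 2
    if len(positions) < n_coef:
        raise ValueError(f"need >= {n_coef} points for degree {degree}")
    center = positions.mean(axis=0)
    scale = float(max(np.abs(positions - center).max(), 1.0))
    fit = SurfaceFit(degree=degree, coeffs=np.zeros(n_coef), center=center, scale=scale)
    X = fit._design(positions)
    coeffs, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    if rank < n_coef:
        raise ValueError("rank-deficient design: positions do not constrain the surface")
    fit.coeffs = coeffs
    return fit


def _hex_symmetries() -> list[np.ndarray]:
    """The 12 signed axis permutations of the hexagonal lattice.

    Integer 2x2 matrices that permute the six neighbor offsets: the rotation
    and reflection symmetries of the hexagon in axial coordinates.
    """
    units = [np.array(o) for o in HEX_NEIGHBOR_OFFSETS]
    unit_set = {tuple(u) for u in units}
    syms = []
    for a in units:
        for b in units:
            M = np.column_stack([a, b])
            if abs(round(np.linalg.det(M))) != 1:
                continue
            images = {tuple(M @ u) for u in units}
            if images == unit_set:
                syms.append(M)
    return syms


_SYMMETRIES = _hex_symmetries()


def recenter_and_orient(grid: HexGrid, anterior_hint) -> HexGrid:
    """Re-index the grid for column analysis; returns a new grid.

    The hex origin is shifted to the center-most ommatidium (nearest the
    centroid of all image positions) and one of the 12 lattice symmetries is
    applied so the most anterior ommatidium gets positive x and y hex
    coordinates; the column index ``x_hex + y_hex`` then increases from
    posterior to anterior. Adjacency is preserved exactly (symmetries of the
    lattice permute the neighbor offsets).

    Ambiguity (the most anterior ommatidium landing on a lattice axis, or
    several symmetries qualifying) is resolved deterministically by
    maximizing ``x_hex + y_hex`` then ``x_hex`` of the most anterior
    ommatidium; the applied transform is recorded on the returned grid as
    ``applied_shift`` and ``applied_symmetry``.
    """
    omtds = list(grid)
    if not omtds:
        raise ValueError("empty grid")
    a_vec = _anterior_vector(anterior_hint)
    positions = np.array([o.pos for o in omtds])
    centroid = positions.mean(axis=0)
    center = omtds[int(np.argmin(np.linalg.norm(positions - centroid, axis=1)))]
    shift = np.array(center.hex, dtype=int)
    anterior = omtds[int(np.argmax(positions @ a_vec))]
    target = np.array(anterior.hex, dtype=int) - shift
    best, best_key = None, None
    for M in _SYMMETRIES:
        t = M @ target
        if t[0] < 0 or t[1] < 0 or (t[0] == 0 and t[1] == 0 and np.any(target)):
            continue
        key = (int(t[0] + t[1]), int(t[0]))
        if best_key is None or key > best_key:
            best, best_key = M, key
    if best is None:  # degenerate: anterior ommatidium is the center
        best = np.eye(2, dtype=int)
    out = HexGrid()
    for o in omtds:
        new_hex = best @ (np.array(o.hex, dtype=int) - shift)
        out.add(Ommatidium((int(new_hex[0]), int(new_hex[1])), o.pos.copy(),
                           z=o.z, slant=o.slant, origin=o.origin))
    out.px_size = getattr(grid, "px_size", 1.0)
    out.applied_shift = shift
    out.applied_symmetry = best
    return out


@dataclass
class ColumnProfile:
    """Ommatidia per column; the column index is x_hex + y_hex."""

    indices: np.ndarray  # sorted occupied column indices
    counts: np.ndarray  # ommatidia per occupied column

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_columns(self) -> int:
        return len(self.indices)

    def dense(self) -> tuple[int, np.ndarray]:
        """(first index, contiguous counts array with zeros for gaps)."""
        lo, hi = int(self.indices.min()), int(self.indices.max())
        arr = np.zeros(hi - lo + 1, dtype=float)
        arr[self.indices - lo] = self.counts
        return lo, arr


def column_profile(grid: HexGrid) -> ColumnProfile:
    """Histogram of the column index x_hex + y_hex over the (reindexed) grid."""
    if len(grid) == 0:
        raise ValueError("empty grid")
    cols = np.array([o.hex[0] + o.hex[1] for o in grid])
    indices, counts = np.unique(cols, return_counts=True)
    return ColumnProfile(indices=indices, counts=counts)


@dataclass
class AlignedProfile:
    """Mean ± sd column profile after integer-shift alignment."""

    indices: np.ndarray  # column indices in the first profile's frame
    mean: np.ndarray
    sd: np.ndarray
    shifts: np.ndarray  # applied integer shift per input profile


def align_profiles(profiles: list[ColumnProfile], max_iter: int = 50) -> AlignedProfile:
    """Align column profiles by integer shifts and average them.

    Each profile may start at an arbitrary column index (the recentering
    step fixes only the origin ommatidium), so profiles are shifted by
    integers to minimize the total squared difference to the running mean,
    iterating until the shifts stabilize. The first profile anchors the
    frame.
    """
    if len(profiles) < 2:
        raise ValueError("need >=2 profiles to align")
    dense = [p.dense() for p in profiles]
    starts = np.array([d[0] for d in dense])
    arrays = [d[1] for d in dense]
    n = len(arrays)
    shifts = np.zeros(n, dtype=int)
    span = max(len(a) for a in arrays)

    def stack(shifts):
        lo = min(starts[i] + shifts[i] for i in range(n))
        hi = max(starts[i] + shifts[i] + len(arrays[i]) for i in range(n))
        S = np.zeros((n, hi - lo))
        for i in range(n):
            o = starts[i] + shifts[i] - lo
            S[i, o : o + len(arrays[i])] = arrays[i]
        return lo, S

    for _ in range(max_iter):
        lo, S = stack(shifts)
        mean = S.mean(axis=0)
        new_shifts = shifts.copy()
        for i in range(1, n):
            best_s, best_ssd = shifts[i], np.inf
            for s in range(shifts[i] - span, shifts[i] + span + 1):
                trial = shifts.copy()
                trial[i] = s
                lo_t, S_t = stack(trial)
                m = S_t.mean(axis=0)
                ssd = float(((S_t[i] - m) ** 2).sum())
                if ssd < best_ssd - 1e-12:
                    best_s, best_ssd = s, ssd
            new_shifts[i] = best_s
        if np.array_equal(new_shifts, shifts):
            break
        shifts = new_shifts
    lo, S = stack(shifts)
    occupied = S.sum(axis=0) > 0
    if not occupied.any():
        raise ValueError("profiles do not overlap")
    idx = np.arange(lo, lo + S.shape[1])
    return AlignedProfile(
        indices=idx[occupied],
        mean=S.mean(axis=0)[occupied],
        sd=S.std(axis=0, ddof=0)[occupied],
        shifts=shifts,
    )


def average_spacing_across_eyes(
    grids: list[HexGrid],
    reference: HexGrid,
    coverage: float = 0.5,
):
    """Per-hex-coordinate mean spacing over eyes, on the reference eye.

    Ommatidium measurements from different eyes are pooled by their unique
    hex coordinate (all grids must be reindexed to the common convention).
    Coordinates present in fewer than ``coverage`` of the eyes are dropped
    (rim coordinates vary between individuals and would otherwise dominate);
    the pooled means are projected onto the reference grid's image
    positions.

    Returns
    -------
    (hexes, positions, means) : kept coordinates, their positions on the
        reference eye, and the cross-eye mean spacing.
    """
    pooled: dict[tuple[int, int], list[float]] = {}
    for g in grids:
        sm = spacing_per_ommatidium(g)
        for hx, v in zip(sm.hexes, sm.values):
            pooled.setdefault(hx, []).append(float(v))
    need = coverage * len(grids)
    hexes, positions, means = [], [], []
    for o in reference:
        vals = pooled.get(o.hex)
        if vals is not None and len(vals) >= need:
            hexes.append(o.hex)
            positions.append(o.pos.copy())
            means.append(float(np.mean(vals)))
    if not hexes:
        raise ValueError("no hex coordinate meets the coverage requirement")
    return hexes, np.array(positions), np.array(means)


def count(grid: HexGrid) -> tuple[int, int]:
    """Total ommatidia and number of occupied columns."""
    if len(grid) == 0:
        return 0, 0
    cols = {o.hex[0] + o.hex[1] for o in grid}
    return len(grid), len(cols)
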
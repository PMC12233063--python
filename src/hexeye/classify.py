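"""Pixel classification: eye region and facet probability maps.

Two random-forest pixel classifiers (100 trees each) are trained from sparse
manual annotations — a closed outline of the compound eye and a handful of
ommatidium masks sampled from different eye regions. The eye model separates
eye from background; the facet model separates ommatidium interiors from the
boundaries between them. Applied to a focused 2D image they yield the eye
probability map and the facet probability map I_prob that drive the
hexagonal-grid expansion; the binary eye region is obtained by Otsu
thresholding of the eye probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.measure import label as cc_label
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FEATURE_SIGMAS",
    "TrainingAnnotation",
    "PixelModel",
    "ProbabilityMaps",
    "extract_features",
    "feature_names",
    "train_models",
    "predict_maps",
    "otsu_threshold",
    "eye_mask_from_prob",
]

#: Gaussian scales (px) of the multi-scale filter bank.
FEATURE_SIGMAS = (1.0, 2.0, 4.0, 8.0, 16.0)

#: Default feature recipe identifier, embedded in saved models.
DEFAULT_RECIPE = "gauss-grad-laplace-hessian-var:s1-2-4-8-16:v1"

#: Per-class cap on training pixels (bounded training time, seeded subsample).
MAX_PIXELS_PER_CLASS = 50_000

N_TREES = 100


@dataclass
class TrainingAnnotation:
    """Sparse manual annotation of one training image.

    Parameters
    ----------
    image_id : str
        Identifier of the annotated image.
    eye_outline : ndarray, shape (k, 2)
        Closed polygon delimiting the compound eye, as (x, y) image
        coordinates (0-based, x = column).
    facet_masks : list of ndarray
        Binary masks, one per annotated group/ommatidium, each of the full
        image shape. Interiors are the facet class; boundary pixels are
        derived morphologically.
    """

    image_id: str
    eye_outline: np.ndarray
    facet_masks: list = field(default_factory=list)

    def eye_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the outline polygon to a binary mask of `shape`."""
        poly_rc = np.asarray(self.eye_outline, dtype=float)[:, ::-1]  # (x,y)->(r,c)
        return polygon2mask(shape, poly_rc)


@dataclass
class PixelModel:
    """A trained per-pixel probability model for one task ('eye' or 'facet')."""

    task: str
    forest: RandomForestClassifier
    recipe: str = DEFAULT_RECIPE

    def predict_prob(self, features: np.ndarray) -> np.ndarray:
        """Probability of the positive class for an (H, W, k) feature stack."""
        h, w, k = features.shape
        flat = features.reshape(-1, k)
        prob = self.forest.predict_proba(flat)[:, 1]
        return prob.reshape(h, w)


@dataclass
class ProbabilityMaps:
    """Per-pixel eye / facet probabilities plus the thresholded eye mask."""

    eye_prob: np.ndarray
    facet_prob: np.ndarray
    eye_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (self.eye_prob.shape == self.facet_prob.shape == self.eye_mask.shape):
            raise ValueError("probability maps and mask must share dimensions")


def feature_names() -> list[str]:
    names = ["intensity"]
    for s in FEATURE_SIGMAS:
        si = int(s)
        names += [
            f"gauss_s{si}",
            f"gradmag_s{si}",
            f"laplace_s{si}",
            f"hess_e1_s{si}",
            f"hess_e2_s{si}",
            f"var_s{si}",
        ]
    return names


def extract_features(image: np.ndarray) -> np.ndarray:
    """Multi-scale filter-bank features for every pixel.

    Raw intensity plus, at each scale sigma in FEATURE_SIGMAS: Gaussian blur,
    gradient magnitude, Laplacian of Gaussian, the two Hessian eigenvalues,
    and local variance. Deterministic for a given image.

    Returns
    -------
    ndarray, shape (H, W, 1 + 6 * len(FEATURE_SIGMAS))
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    chans = [img]
    for s in FEATURE_SIGMAS:
        g = ndimage.gaussian_filter(img, s, mode="reflect")
        gx = ndimage.gaussian_filter(img, s, order=(0, 1), mode="reflect")
        gy = ndimage.gaussian_filter(img, s, order=(1, 0), mode="reflect")
        gradmag = np.hypot(gx, gy)
        lap = ndimage.gaussian_laplace(img, s, mode="reflect")
        H = hessian_matrix(img, sigma=s, order="rc", use_gaussian_derivatives=True)
        e1, e2 = hessian_matrix_eigvals(H)
        mean_sq = ndimage.gaussian_filter(img * img, s, mode="reflect")
        var = np.maximum(mean_sq - g * g, 0.0)
        chans += [g, gradmag, lap, e1, e2, var]
    return np.stack(chans, axis=-1)


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Facet-boundary class: morphological gradient of a facet mask.

    Dilation minus erosion with a 3-px square element; the annotations label
    facet interiors only, so boundary pixels must be derived.
    """
    el = np.ones((3, 3), dtype=bool)
    return ndimage.binary_dilation(mask, el) & ~ndimage.binary_erosion(mask, el)


def _subsample(idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if idx.shape[0] > MAX_PIXELS_PER_CLASS:
        sel = rng.choice(idx.shape[0], MAX_PIXELS_PER_CLASS, replace=False)
        return idx[np.sort(sel)]
    return idx


def _fit_forest(X: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=N_TREES, random_state=seed, n_jobs=1, min_samples_leaf=2
    )
    forest.fit(X, y)
    return forest


def train_models(
    annotations: list[TrainingAnnotation],
    images: list[np.ndarray],
    seed: int = 0,
) -> tuple[PixelModel, PixelModel]:
    """Train the eye and facet pixel classifiers from sparse annotations.

    Eye classes: pixels inside vs outside the eye outline. Facet classes:
    annotated facet interiors vs their morphological boundaries. Each class
    is subsampled to at most MAX_PIXELS_PER_CLASS pixels (seeded), keeping
    training time bounded and the run reproducible.

    Raises
    ------
    ValueError
        If no annotations are given or any class ends up empty.
    """
    if not annotations or len(annotations) != len(images):
        raise ValueError("need >=1 annotation with a matching image each")
    rng = np.random.default_rng(seed)
    eye_X, eye_y, fac_X, fac_y = [], [], [], []
    for ann, image in zip(annotations, images):
        feats = extract_features(image)
        h, w, k = feats.shape
        flat = feats.reshape(-1, k)
        emask = ann.eye_mask((h, w)).ravel()
        inside = _subsample(np.flatnonzero(emask), rng)
        outside = _subsample(np.flatnonzero(~emask), rng)
        if inside.size == 0 or outside.size == 0:
            raise ValueError(f"{ann.image_id}: eye annotation has an empty class")
        eye_X += [flat[inside], flat[outside]]
        eye_y += [np.ones(inside.size, dtype=int), np.zeros(outside.size, dtype=int)]
        if not ann.facet_masks:
            raise ValueError(f"{ann.image_id}: no annotated facets")
        interior = np.zeros((h, w), dtype=bool)
        boundary = np.zeros((h, w), dtype=bool)
        for m in ann.facet_masks:
            m = np.asarray(m, dtype=bool)
            interior |= m
            boundary |= _boundary_pixels(m)
        boundary &= ~interior
        ii = _subsample(np.flatnonzero(interior.ravel()), rng)
        bb = _subsample(np.flatnonzero(boundary.ravel()), rng)
        if ii.size == 0 or bb.size == 0:
            raise ValueError(f"{ann.image_id}: facet annotation has an empty class")
        fac_X += [flat[ii], flat[bb]]
        fac_y += [np.ones(ii.size, dtype=int), np.zeros(bb.size, dtype=int)]
    seed_eye = int(rng.integers(2**31 - 1))
    seed_fac = int(rng.integers(2**31 - 1))
    eye_model = PixelModel("eye", _fit_forest(np.vstack(eye_X), np.concatenate(eye_y), seed_eye))
    facet_model = PixelModel("facet", _fit_forest(np.vstack(fac_X), np.concatenate(fac_y), seed_fac))
    return eye_model, facet_model


def predict_maps(
    image: np.ndarray, eye_model: PixelModel, facet_model: PixelModel
) -> ProbabilityMaps:
    """Convert a focused 2D image into eye / facet probability maps.

    The eye mask is obtained from the eye probability map via
    :func:`eye_mask_from_prob` (Otsu threshold + cleanup).
    """
    if eye_model.recipe != facet_model.recipe:
        raise ValueError("models were trained with different feature recipes")
    feats = extract_features(image)
    eye_prob = eye_model.predict_prob(feats)
    facet_prob = facet_model.predict_prob(feats)
    return ProbabilityMaps(eye_prob, facet_prob, eye_mask_from_prob(eye_prob))


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximize between-class variance over a histogram.

    `values` is either a 1D/2D sample of intensities (binned into `nbins`
    equal-width bins over its range) or a precomputed histogram of counts
    (detected by integer dtype and 1D shape, bin centers then taken as
    0..len-1 normalized to [0, 1]).

    Returns the threshold t at the edge between the two classes' bins; the
    foreground is `value >= t`.

    Raises
    ------
    ValueError
        If the input is constant (no threshold separates two classes).
    """
    values = np.asarray(values)
    if values.ndim == 1 and np.issubdtype(values.dtype, np.integer):
        counts = values.astype(float)
        centers = np.linspace(0.0, 1.0, counts.size)
    else:
        flat = values.ravel().astype(float)
        lo, hi = flat.min(), flat.max()
        if hi <= lo:
            raise ValueError("constant input: no threshold exists")
        counts, edges = np.histogram(flat, bins=nbins, range=(lo, hi))
        counts = counts.astype(float)
        centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    if total <= 0 or np.count_nonzero(counts) < 2:
        raise ValueError("need >=2 distinct values")
    # Between-class variance for a split after bin k (background = bins <= k):
    # sigma_b^2(k) = w0 w1 (mu0 - mu1)^2, evaluated at every candidate split.
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    mtot = (counts * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    k = int(np.argmax(sigma_b))
    # Threshold = edge between the last background bin and first foreground bin.
    return float((centers[k] + centers[k + 1]) / 2.0)


def eye_mask_from_prob(eye_prob: np.ndarray) -> np.ndarray:
    """Binary eye region: Otsu threshold, keep largest component, fill holes.

    The cleanup steps suppress satellite regions that boundary over-detection
    can spawn on low-contrast (e.g. unpigmented) eyes.
    """
    t = otsu_threshold(eye_prob)
    mask = eye_prob >= t
    if not mask.any():
        raise ValueError("empty eye mask after thresholding")
    labels = cc_label(mask, connectivity=1)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)
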
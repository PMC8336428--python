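"""Active Appearance Model front-end: shape + texture joint PCA over faces.

A face is represented by *shape features* — the (x, y) pixel coordinates of L
landmarks (default 83) on invariant structures (eyes, brows, nose, mouth,
contour) — and *texture features* — grayscale pixel values of the image
piecewise-affinely warped so its landmarks coincide with the dataset-mean
landmarks. Shapes are first brought into a common frame by generalized
Procrustes alignment; the two blocks are variance-balanced and compressed by
one joint PCA retaining a target fraction of variance (default 98%).

The model is invertible: :func:`decode` reconstructs landmarks and texture
from a PCA code and renders the face, which is what makes feature traversal
(synthesizing faces at equal perceptual-distance steps along one axis of a
fitted metric) possible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay

from .metric import MetricModel

__all__ = [
    "AAMModel",
    "build_model",
    "warp_to_mean",
    "encode",
    "encode_parts",
    "decode",
    "traverse_feature",
    "delta_for_dissimilarity",
    "grayscale",
    "load_landmarks",
    "save_landmarks",
]


class DegenerateTriangleError(ValueError):
    """A warp triangle has (near-)zero area under the source landmarks."""


def grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image array to grayscale in [0, 1] (ITU-R 601 luma for RGB)."""
    img = np.asarray(image, float)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.max() > 1.0:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)


def load_landmarks(path) -> np.ndarray:
    """Read a plain-text landmark file, one ``x y`` pair per line."""
    return np.loadtxt(path, ndmin=2)


def save_landmarks(points: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(points, float), fmt="%.4f")


# ---------------------------------------------------------------------------
# Shape alignment and piecewise-affine warping


def _similarity_align(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Align one shape to a target by translation + rotation + scale (Procrustes)."""
    mu_s, mu_t = shape.mean(0), target.mean(0)
    S = shape - mu_s
    T = target - mu_t
    A = S.T @ T
    U, sv, Vt = np.linalg.svd(A)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # no reflections
        U[:, -1] *= -1
        R = U @ Vt
    scale = (S @ R * T).sum() / (S * S).sum()  # optimal scale for fixed R
    return scale * S @ R + mu_t


def generalized_procrustes(shapes: np.ndarray, n_iter: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively align shapes to their evolving mean; returns (aligned, mean).

    The mean is re-anchored to the original average centroid and scale so the
    aligned coordinates remain in pixel units inside the frame.
    """
    shapes = np.asarray(shapes, float)
    anchor_centroid = shapes.mean(axis=(0, 1))
    anchor_scale = np.mean([np.linalg.norm(s - s.mean(0)) for s in shapes])
    mean = shapes[0]
    aligned = shapes.copy()
    for _ in range(n_iter):
        aligned = np.array([_similarity_align(s, mean) for s in shapes])
        mean = aligned.mean(axis=0)
        mean = (mean - mean.mean(0)) / np.linalg.norm(mean - mean.mean(0)) * anchor_scale + anchor_centroid
    return aligned, mean


def _triangle_areas(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a, b, c = points[simplices[:, 0]], points[simplices[:, 1]], points[simplices[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


def piecewise_affine_map(
    points: np.ndarray,
    src_landmarks: np.ndarray,
    dst_landmarks: np.ndarray,
    simplices: np.ndarray,
    check_degenerate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Map points through the piecewise-affine warp src -> dst over a shared triangulation.

    For each point, find the containing triangle under the *source* landmark
    geometry, compute barycentric coordinates there, and emit the same
    barycentric combination of the destination landmarks. Returns (mapped
    points, boolean mask of points inside the source hull).
    """
    points = np.asarray(points, float)
    if check_degenerate:
        areas = _triangle_areas(src_landmarks, simplices)
        bad = np.flatnonzero(np.abs(areas) < 1e-9)
        if bad.size:
            raise DegenerateTriangleError(
                f"triangle {bad[0]} (vertices {simplices[bad[0]].tolist()}) is degenerate "
                "under the source landmarks"
            )
    out = np.full_like(points, np.nan)
    inside = np.zeros(len(points), dtype=bool)
    eps = 1e-9
    for tri_idx in range(len(simplices)):
        if inside.all():
            break
        idx = simplices[tri_idx]
        s = src_landmarks[idx]
        pend = ~inside
        p = points[pend]
        M = np.array([[s[0, 0] - s[2, 0], s[1, 0] - s[2, 0]], [s[0, 1] - s[2, 1], s[1, 1] - s[2, 1]]])
        det = np.linalg.det(M)
        if abs(det) < 1e-12:
            continue
        Minv = np.linalg.inv(M)
        bary12 = (p - s[2]) @ Minv.T
        bary3 = 1.0 - bary12.sum(1)
        ok = (bary12[:, 0] >= -eps) & (bary12[:, 1] >= -eps) & (bary3 >= -eps)
        if not ok.any():
            continue
        d = dst_landmarks[idx]
        mapped = bary12[ok, 0, None] * d[0] + bary12[ok, 1, None] * d[1] + bary3[ok, None] * d[2]
        pend_idx = np.flatnonzero(pend)[ok]
        out[pend_idx] = mapped
        inside[pend_idx] = True
    return out, inside


# ---------------------------------------------------------------------------
# Model


@dataclass
class AAMModel:
    """Joint shape+texture PCA model of a face dataset."""

    mean_shape: np.ndarray  # (L, 2) pixel coords in the reference frame
    simplices: np.ndarray  # Delaunay triangulation of the mean shape
    texture_coords: np.ndarray  # (T, 2) integer pixel coords inside the mean hull
    frame_size: int
    shape_scale: float  # divide the shape block by this before PCA
    texture_scale: float
    pca_mean: np.ndarray
    basis: np.ndarray  # (n_retained, dim), orthonormal rows
    explained_variance_ratio: np.ndarray  # all components, sums to 1
    n_retained: int
    variance_retained: float
    background: float = 1.0

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def n_components(self) -> int:
        return self.n_retained

    def save(self, path) -> None:
        np.savez(
            path,
            mean_shape=self.mean_shape,
            simplices=self.simplices,
            texture_coords=self.texture_coords,
            pca_mean=self.pca_mean,
            basis=self.basis,
            evr=self.explained_variance_ratio,
            meta=np.frombuffer(
                json.dumps(
                    {
                        "frame_size": self.frame_size,
                        "shape_scale": self.shape_scale,
                        "texture_scale": self.texture_scale,
                        "n_retained": self.n_retained,
                        "variance_retained": self.variance_retained,
                        "background": self.background,
                        "format": "percepspace-aam-v1",
                    }
                ).encode(),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path) -> "AAMModel":
        with np.load(path) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            return cls(
                mean_shape=z["mean_shape"],
                simplices=z["simplices"],
                texture_coords=z["texture_coords"],
                frame_size=meta["frame_size"],
                shape_scale=meta["shape_scale"],
                texture_scale=meta["texture_scale"],
                pca_mean=z["pca_mean"],
                basis=z["basis"],
                explained_variance_ratio=z["evr"],
                n_retained=meta["n_retained"],
                variance_retained=meta["variance_retained"],
                background=meta["background"],
            )


def warp_to_mean(image: np.ndarray, landmarks: np.ndarray, model: AAMModel) -> np.ndarray:
    """Texture vector: the image sampled at the mean-frame texture coordinates
    after warping its landmarks onto the mean shape.

    Equivalently, each mean-frame sample point is carried through the
    piecewise-affine map mean_shape -> landmarks and the image is sampled
    there bilinearly. Values in [0, 1].
    """
    img = grayscale(image)
    src_pts, inside = piecewise_affine_map(
        model.texture_coords, model.mean_shape, np.asarray(landmarks, float), model.simplices
    )
    src_pts[~inside] = 0.0
    vals = map_coordinates(img, [src_pts[:, 1], src_pts[:, 0]], order=1, mode="nearest")
    vals[~inside] = model.background
    return np.clip(vals, 0.0, 1.0)


def build_model(
    images: np.ndarray,
    landmarks: np.ndarray,
    variance_retained: float = 0.98,
    background: float = 1.0,
) -> AAMModel:
    """Build the joint shape+texture PCA model from a training set.

    Shapes are aligned by generalized Procrustes before averaging and PCA.
    The mean shape is triangulated once (Delaunay) and texture is sampled at
    every integer pixel inside its convex hull. Each block is divided by the
    square root of its total training variance so shape and texture
    contribute equal total variance to the joint PCA; the smallest number of
    components whose cumulative explained variance reaches
    ``variance_retained`` is kept.
    """
    images = np.asarray(images, float)
    landmarks = np.asarray(landmarks, float)
    n = len(images)
    if n < 3:
        raise ValueError("need at least 3 training faces")
    if landmarks.ndim != 3 or len(landmarks) != n:
        raise ValueError("landmarks must be (n_faces, L, 2) with one set per image")
    frame_size = images.shape[1]

    aligned, mean_shape = generalized_procrustes(landmarks)
    tri = Delaunay(mean_shape)
    simplices = tri.simplices.copy()

    # integer pixel grid strictly inside the mean-shape hull
    yy, xx = np.mgrid[0:frame_size, 0:frame_size]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    inside = tri.find_simplex(grid) >= 0
    texture_coords = grid[inside]

    proto = AAMModel(
        mean_shape=mean_shape,
        simplices=simplices,
        texture_coords=texture_coords,
        frame_size=frame_size,
        shape_scale=1.0,
        texture_scale=1.0,
        pca_mean=np.zeros(1),
        basis=np.zeros((1, 1)),
        explained_variance_ratio=np.zeros(1),
        n_retained=1,
        variance_retained=variance_retained,
        background=background,
    )
    textures = np.array([warp_to_mean(images[k], landmarks[k], proto) for k in range(n)])
    shapes_flat = aligned.reshape(n, -1)

    # unit total variance per block, but never amplify a (near-)constant
    # block's float noise into a spurious PCA direction
    shape_var = shapes_flat.var(axis=0, ddof=1).sum()
    tex_var = textures.var(axis=0, ddof=1).sum()
    shape_scale = np.sqrt(shape_var) if shape_var > 1e-12 * (shapes_flat**2).mean() else 1.0
    texture_scale = np.sqrt(tex_var) if tex_var > 1e-12 * max((textures**2).mean(), 1e-6) else 1.0

    joint = np.hstack([shapes_flat / shape_scale, textures / texture_scale])
    pca_mean = joint.mean(axis=0)
    centered = joint - pca_mean
    # SVD-based PCA (n_samples << dim)
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    var = svals**2
    total = var.sum()
    evr = var / total if total > 0 else np.ones_like(var) / var.size
    max_rank = min(n - 1, joint.shape[1])
    evr = evr[:max_rank]
    Vt = Vt[:max_rank]
    if variance_retained >= 1.0:
        n_retained = max_rank
    else:
        n_retained = int(np.searchsorted(np.cumsum(evr), variance_retained) + 1)
        n_retained = min(n_retained, max_rank)

    proto.shape_scale = float(shape_scale)
    proto.texture_scale = float(texture_scale)
    proto.pca_mean = pca_mean
    proto.basis = Vt[:n_retained]
    proto.explained_variance_ratio = evr / evr.sum()
    proto.n_retained = n_retained
    return proto


def encode_parts(shape: np.ndarray, texture: np.ndarray, model: AAMModel) -> np.ndarray:
    """Project already-aligned shape and texture blocks into the joint-PCA space.

    The exact algebraic inverse of :func:`decode` on the retained subspace;
    no alignment or warping is applied.
    """
    joint = np.concatenate(
        [np.asarray(shape, float).ravel() / model.shape_scale, np.asarray(texture, float) / model.texture_scale]
    )
    return model.basis @ (joint - model.pca_mean)


def encode(image: np.ndarray, landmarks: np.ndarray, model: AAMModel) -> np.ndarray:
    """Project a face into the joint-PCA space (a FaceCode vector).

    The landmark set is similarity-aligned to the stored mean shape so the
    code is invariant to translation, rotation, and scale of the input.
    """
    aligned = _similarity_align(np.asarray(landmarks, float), model.mean_shape)
    texture = warp_to_mean(image, landmarks, model)
    return encode_parts(aligned, texture, model)


def decode(x: np.ndarray, model: AAMModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reconstruct (landmarks, texture, rendered image) from a PCA code.

    The rendered image paints the reconstructed texture into the decoded
    shape via the inverse piecewise-affine warp; pixels outside the decoded
    hull take the background value. Decoded shapes with inverted
    (negative-area) triangles trigger a warning and a clipped rendering.
    """
    x = np.asarray(x, float)
    if x.shape != (model.n_retained,):
        raise ValueError(f"code must have length {model.n_retained}")
    joint = model.pca_mean + model.basis.T @ x
    L = model.n_landmarks
    shape = joint[: 2 * L].reshape(L, 2) * model.shape_scale
    texture = joint[2 * L :] * model.texture_scale  # clipped only at render time

    areas = _triangle_areas(shape, model.simplices)
    ref_areas = _triangle_areas(model.mean_shape, model.simplices)
    if np.any(np.sign(areas) * np.sign(ref_areas) < 0):
        warnings.warn("decoded shape has inverted triangles; rendering clipped", stacklevel=2)

    # paint the texture into a mean-frame image for resampling
    size = model.frame_size
    mean_img = np.full((size, size), model.background)
    tc = model.texture_coords.astype(int)
    mean_img[tc[:, 1], tc[:, 0]] = texture

    yy, xx = np.mgrid[0:size, 0:size]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    mean_pts, inside = piecewise_affine_map(grid, shape, model.mean_shape, model.simplices,
                                            check_degenerate=False)
    mean_pts[~inside] = 0.0
    vals = map_coordinates(mean_img, [mean_pts[:, 1], mean_pts[:, 0]], order=1, mode="nearest")
    vals[~inside] = model.background
    rendered = np.clip(vals.reshape(size, size), 0.0, 1.0)
    return shape, texture, rendered


def delta_for_dissimilarity(metric: MetricModel, axis: int, target: float) -> float:
    """Step size along eigen-axis ``axis`` whose first step predicts dissimilarity b + target."""
    lam = metric.eigvals[axis]
    if lam <= 0:
        raise ValueError(f"axis {axis} has zero eigenvalue; no perceptual effect")
    return float(np.sqrt(target / lam))


def traverse_feature(
    model: AAMModel,
    metric: MetricModel,
    axis: int,
    delta: float,
    n_steps: int = 2,
    x_mid: np.ndarray | None = None,
) -> dict:
    """Synthesize faces at equal perceptual-distance steps along one metric axis.

    Codes are x_mid + s * delta * u_axis for s in -n_steps..n_steps, where
    u_axis is the unit eigenvector of the fitted metric. The predicted
    dissimilarity between the middle face and the step-s face is
    b + (s*delta)^2 * eigval_axis — symmetric in +/-s and constant per |s|,
    so each left/right face is equally dissimilar from the middle one.
    """
    lam = metric.eigvals[axis]
    if lam <= 0:
        raise ValueError(f"axis {axis} has zero eigenvalue; no perceptual effect")
    if metric.n_dims != model.n_retained:
        raise ValueError("metric was not fitted on this model's code space")
    if x_mid is None:
        x_mid = np.zeros(model.n_retained)
    u = metric.U[axis]
    steps = np.arange(-n_steps, n_steps + 1)
    codes = np.array([x_mid + s * delta * u for s in steps])
    images = []
    shapes = []
    for code in codes:
        shape, _, img = decode(code, model)
        shapes.append(shape)
        images.append(img)
    predicted = metric.b + (steps * delta) ** 2 * lam
    return {
        "steps": steps,
        "codes": codes,
        "images": np.array(images),
        "shapes": np.array(shapes),
        "predicted_dissimilarity": predicted,
    }
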
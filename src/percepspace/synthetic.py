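"""Synthetic worlds: planted metrics, simulated raters, and cartoon faces.

Everything the pipeline consumes can be generated here with known ground
truth, so parameter- and rank-recovery are directly testable:

* :func:`make_world` plants a feature matrix X*, a PSD metric W* of chosen
  rank, and an offset b*, defining true dissimilarities f*(i,j).
* :func:`simulate_ratings` turns true dissimilarities into per-rater 1–9
  Likert similarity scores with per-rater gain/bias/noise, two repetitions
  per pair, catch trials, and optional inattentive raters.
* :func:`make_cartoon_faces` renders smooth grayscale cartoon faces with 83
  analytically-placed landmarks, driven by known latent factors, to exercise
  the warping and joint-PCA code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metric import FeatureSpace, MetricModel
from .ratings import RATING_COLUMNS

__all__ = [
    "SyntheticWorld",
    "RaterModel",
    "make_world",
    "true_dissimilarity",
    "sample_pairs",
    "simulate_ratings",
    "make_cartoon_faces",
    "CARTOON_FACTORS",
]


@dataclass
class SyntheticWorld:
    """A planted ground truth: features X*, PSD metric W* of known rank, offset b*."""

    features: FeatureSpace
    W: np.ndarray
    b: float
    rank: int
    seed: int
    groups: dict[str, str] = field(default_factory=dict)  # image id -> group label

    def model(self) -> MetricModel:
        """The planted metric wrapped as a MetricModel (for prediction helpers)."""
        from .metric import _eigh_desc

        vals, vecs = _eigh_desc(self.W)
        return MetricModel(
            W=self.W, b=self.b, U=vecs.T, eigvals=np.maximum(vals, 0.0), ids=list(self.features.ids)
        )


@dataclass
class RaterModel:
    """Affine-plus-Gaussian distortion of the true dissimilarity for one rater.

    A rater reports raw = gain * f*(i,j) + bias + N(0, sigma), mapped onto the
    1–9 similarity scale. Inattentive raters click uniformly at random and
    fail catch trials half the time.
    """

    gain: float = 1.0
    bias: float = 0.0
    sigma: float = 0.1
    attentive: bool = True
    pairs_per_rater: int = 60
    repetitions: int = 2
    n_catch: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def make_world(
    n_items: int = 200,
    n_dims: int = 20,
    rank: int = 5,
    b: float = 0.4,
    trace: float = 0.25,
    group_spec: dict[str, float] | None = None,
    seed: int = 0,
) -> SyntheticWorld:
    """Plant a synthetic perceptual world.

    X* rows are standard normal. W* = U^T diag(lam) U with a Haar-random
    orthogonal U and ``rank`` equal nonzero eigenvalues summing to ``trace``
    (equal-strength planted axes keep rank recovery well-defined). With the
    default trace, true dissimilarities over standard-normal items have mean
    b + 2*trace and a spread comfortably above typical rater noise.

    ``group_spec`` maps group labels to a cluster offset magnitude; items are
    split evenly among groups and each group's mean is shifted along its own
    random direction by that magnitude.
    """
    if not 0 <= rank <= n_dims:
        raise ValueError(f"rank must be in [0, {n_dims}]")
    if b < 0:
        raise ValueError("b must be >= 0")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_items, n_dims))
    groups: dict[str, str] = {}
    ids = [f"img{k:04d}" for k in range(n_items)]
    if group_spec:
        labels = list(group_spec)
        for k, im in enumerate(ids):
            lab = labels[k % len(labels)]
            groups[im] = lab
        for lab in labels:
            direction = rng.standard_normal(n_dims)
            direction /= np.linalg.norm(direction)
            rows = [k for k, im in enumerate(ids) if groups[im] == lab]
            X[rows] += group_spec[lab] * direction
    if rank == 0:
        W = np.zeros((n_dims, n_dims))
    else:
        Q, _ = np.linalg.qr(rng.standard_normal((n_dims, rank)))
        lam = trace / rank
        W = lam * Q @ Q.T
    return SyntheticWorld(
        features=FeatureSpace(ids, X), W=W, b=float(b), rank=rank, seed=seed, groups=groups
    )


def true_dissimilarity(world: SyntheticWorld, pairs: list[tuple[str, str]]) -> np.ndarray:
    """f*(i,j) = (x_i - x_j)^T W* (x_i - x_j) + b* for each pair."""
    D = world.features.deltas(pairs)
    return np.einsum("pi,ij,pj->p", D, world.W, D) + world.b


def sample_pairs(world: SyntheticWorld, n_pairs: int, seed: int = 0) -> list[tuple[str, str]]:
    """Sample distinct unordered item pairs uniformly without replacement."""
    rng = np.random.default_rng(seed)
    ids = world.features.ids
    n = len(ids)
    total = n * (n - 1) // 2
    if n_pairs > total:
        raise ValueError(f"requested {n_pairs} pairs but only {total} exist")
    flat = rng.choice(total, size=n_pairs, replace=False)
    # unrank the flat index into (i, j), i < j
    pairs = []
    for t in np.sort(flat):
        i = int((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * t)) // 2)
        j = int(t - i * (2 * n - i - 1) // 2 + i + 1)
        pairs.append((ids[i], ids[j]))
    return pairs


def simulate_ratings(
    world: SyntheticWorld,
    raters: list[RaterModel],
    seed: int = 0,
    pair_pool: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Simulate a rater population; returns a canonical ratings table.

    Raw responses are gain * f* + bias + Gaussian noise. They are mapped onto
    the 1–9 similarity scale by one population-level affine map anchoring the
    1st/99th percentiles of attentive raw values to scores 9 and 1
    (similarity inverts dissimilarity), then rounding and clipping. Each
    sampled pair is rated ``repetitions`` times; every rater also sees
    ``n_catch`` identical-image catch trials. Inattentive raters emit uniform
    random scores and answer catch trials "different" with probability 1/2.
    """
    rng = np.random.default_rng(seed)
    ids = world.features.ids
    if pair_pool is None:
        total = len(ids) * (len(ids) - 1) // 2
        pair_pool = sample_pairs(world, min(2000, total), seed=seed + 1)
    pool_f = true_dissimilarity(world, pair_pool)

    # population-level Likert anchors from an attentive-rater preview
    sigmas = [r.sigma for r in raters if r.attentive] or [0.0]
    preview = pool_f[:, None] + rng.normal(0, np.mean(sigmas), size=(len(pool_f), 8))
    lo, hi = np.percentile(preview, [1, 99])
    if hi <= lo:
        hi = lo + 1.0

    def to_likert(raw: np.ndarray) -> np.ndarray:
        scaled = (raw - lo) / (hi - lo)
        return np.clip(np.round(9 - 8 * scaled), 1, 9).astype(int)

    rows = []
    for r_idx, rater in enumerate(raters):
        rid = f"rater{r_idx:03d}"
        k = min(rater.pairs_per_rater, len(pair_pool))
        chosen = rng.choice(len(pair_pool), size=k, replace=False)
        for p_idx in chosen:
            i, j = pair_pool[p_idx]
            f_true = pool_f[p_idx]
            for rep in range(1, rater.repetitions + 1):
                if rater.attentive:
                    raw = rater.gain * f_true + rater.bias + rng.normal(0, rater.sigma)
                    s = int(to_likert(np.array([raw]))[0])
                else:
                    s = int(rng.integers(1, 10))
                rows.append((rid, i, j, s, rep, False, ""))
        for _ in range(rater.n_catch):
            im = ids[int(rng.integers(len(ids)))]
            if rater.attentive:
                s = int(to_likert(np.array([rater.bias + rng.normal(0, rater.sigma)]))[0])
                s = max(s, 8)  # identical images look identical
                rows.append((rid, im, im, s, 1, True, "same"))
            else:
                resp = "different" if rng.random() < 0.5 else "same"
                rows.append((rid, im, im, int(rng.integers(1, 10)), 1, True, resp))
    return pd.DataFrame(rows, columns=RATING_COLUMNS)


# ---------------------------------------------------------------------------
# Procedural cartoon faces


#: latent factors of the cartoon generator, each on roughly [-1, 1]
CARTOON_FACTORS = ("width", "eye_spacing", "mouth_curve", "shading", "darkness")


def _cartoon_landmarks(width: float, eye_spacing: float, mouth_curve: float, size: int) -> np.ndarray:
    """83 landmark positions (x, y) in pixel units, analytic in the factors.

    Layout: 20-point head outline, 2 x 6 brows, 2 x 10 eyes, 11 nose,
    20 mouth; x rightward, y downward, face centered in the frame.
    """
    c = size / 2.0
    rx = size * (0.30 + 0.06 * width)  # head half-width
    ry = size * 0.38
    pts = []
    # head outline: 20 points over the full ellipse
    ang = np.linspace(0, 2 * np.pi, 20, endpoint=False)
    pts += [(c + rx * np.sin(a), c - ry * np.cos(a)) for a in ang]
    eye_dx = size * (0.12 + 0.03 * eye_spacing)
    eye_y = c - size * 0.08
    eye_r = size * 0.045
    for sgn in (-1, 1):
        ex = c + sgn * eye_dx
        # brow: 6 points on an arc above the eye
        for t in np.linspace(-1, 1, 6):
            pts.append((ex + t * eye_r * 1.6, eye_y - size * 0.07 - 0.3 * eye_r * (1 - t * t)))
        # eye: 10 points around an ellipse
        for a in np.linspace(0, 2 * np.pi, 10, endpoint=False):
            pts.append((ex + eye_r * np.cos(a), eye_y + 0.6 * eye_r * np.sin(a)))
    # nose: 11 points down the bridge and across the base
    nose_y0, nose_y1 = eye_y + size * 0.04, c + size * 0.10
    for t in np.linspace(0, 1, 6):
        pts.append((c, nose_y0 + t * (nose_y1 - nose_y0)))
    for t in np.linspace(-1, 1, 5):
        pts.append((c + t * size * 0.05, nose_y1))
    # mouth: 20 points along two curves (upper/lower lip)
    mouth_y = c + size * 0.22
    mouth_w = size * 0.13
    for t in np.linspace(-1, 1, 10):
        bend = mouth_curve * size * 0.04 * (1 - t * t)
        pts.append((c + t * mouth_w, mouth_y + bend))
    for t in np.linspace(-1, 1, 10):
        bend = mouth_curve * size * 0.04 * (1 - t * t)
        pts.append((c + t * mouth_w, mouth_y + size * 0.025 + bend))
    out = np.array(pts)
    assert out.shape == (83, 2)
    return out


def _render_cartoon(landmarks: np.ndarray, factors: dict[str, float], size: int) -> np.ndarray:
    """Smooth grayscale rendering of the cartoon face skeleton, values in [0, 1]."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    c = size / 2.0
    rx = size * (0.30 + 0.06 * factors["width"])
    ry = size * 0.38
    img = np.ones((size, size))
    inside = ((xx - c) / rx) ** 2 + ((yy - c) / ry) ** 2 <= 1.0
    # skin with a vertical shading gradient
    shade = 0.85 - 0.15 * factors["shading"] * (yy - c) / size
    img[inside] = shade[inside]
    dark = 0.35 - 0.2 * factors["darkness"]

    def blot(cx, cy, r, depth, aspect=1.0):
        d2 = ((xx - cx) / r) ** 2 + ((yy - cy) / (r * aspect)) ** 2
        img[:] -= depth * np.exp(-d2 * 2.0)

    eye_dx = size * (0.12 + 0.03 * factors["eye_spacing"])
    eye_y = c - size * 0.08
    for sgn in (-1, 1):
        blot(c + sgn * eye_dx, eye_y, size * 0.045, 0.85 - dark, aspect=0.6)
        blot(c + sgn * eye_dx, eye_y - size * 0.085, size * 0.05, 0.4 - 0.5 * dark, aspect=0.25)
    blot(c, c + size * 0.10, size * 0.04, 0.25, aspect=0.5)  # nose base
    # mouth: sample gaussians along the lip curve
    mouth_y = c + size * 0.22
    mouth_w = size * 0.13
    for t in np.linspace(-1, 1, 15):
        bend = factors["mouth_curve"] * size * 0.04 * (1 - t * t)
        blot(c + t * mouth_w, mouth_y + bend + size * 0.012, size * 0.02, 0.5 - 0.4 * dark)
    return np.clip(img, 0.0, 1.0)


def make_cartoon_faces(
    n: int = 50,
    factor_scale: float = 1.0,
    image_size: int = 64,
    seed: int = 0,
    noise: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render n cartoon faces with known latent factors.

    Returns (images (n, size, size) in [0,1], landmarks (n, 83, 2), factors
    DataFrame with one column per latent factor). Factors are drawn uniform
    on [-factor_scale, factor_scale]; ``noise`` adds i.i.d. pixel noise.
    All landmark positions are analytic in the factors.
    """
    rng = np.random.default_rng(seed)
    factors = rng.uniform(-factor_scale, factor_scale, size=(n, len(CARTOON_FACTORS)))
    images = np.empty((n, image_size, image_size))
    landmarks = np.empty((n, 83, 2))
    for k in range(n):
        fd = dict(zip(CARTOON_FACTORS, factors[k]))
        lm = _cartoon_landmarks(fd["width"], fd["eye_spacing"], fd["mouth_curve"], image_size)
        if lm.min() < 0 or lm.max() >= image_size:
            raise ValueError(f"landmarks outside frame for face {k}")
        img = _render_cartoon(lm, fd, image_size)
        if noise > 0:
            img = np.clip(img + rng.normal(0, noise, img.shape), 0, 1)
        images[k] = img
        landmarks[k] = lm
    fdf = pd.DataFrame(factors, columns=list(CARTOON_FACTORS))
    fdf.insert(0, "image_id", [f"face{k:03d}" for k in range(n)])
    return images, landmarks, fdf
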
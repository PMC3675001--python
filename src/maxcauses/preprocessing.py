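"""LGN-model preprocessing of grayscale images.

The pipeline mirrors retino-thalamic processing before cortex: patches are
extracted at random positions, convolved with a mean-free
difference-of-Gaussians (DoG) kernel modeling center-surround LGN
receptive fields, and contrast-normalized by a single global factor that
scales the dataset into [-10, 10].  Zero-phase PCA whitening (ZCA) and an
independent ON-/OFF-channel separation are provided as the standard
control preprocessings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import convolve2d

from .models import PatchSet

__all__ = [
    "DoGKernel",
    "WhiteningTransform",
    "read_image",
    "read_iml",
    "extract_patches",
    "dog_filter",
    "contrast_scale",
    "variance_normalize",
    "zca_fit",
    "zca_apply",
    "split_on_off",
]

CONTRAST_RANGE = 10.0  # dataset values are scaled to fill [-10, 10]


@dataclass
class DoGKernel:
    """Mean-free center-surround filter: a narrow positive Gaussian minus a
    wider negative one, each normalized to unit mass so the weights sum to
    zero and constant inputs map to zero.

    The surround/center std ratio defaults to 3.0 (configurable).
    """

    size: int = 9
    sigma_center: float = 1.0
    ratio: float = 3.0

    def __post_init__(self) -> None:
        if self.size % 2 == 0 or self.size < 3:
            raise ValueError("kernel size must be odd and >= 3")
        if not (self.sigma_center > 0 and self.ratio > 1):
            raise ValueError("need sigma_center > 0 and ratio > 1")

    @property
    def sigma_surround(self) -> float:
        return self.sigma_center * self.ratio

    @property
    def weights(self) -> np.ndarray:
        r = np.arange(self.size) - self.size // 2
        xx, yy = np.meshgrid(r, r)
        rr = xx**2 + yy**2
        g_c = np.exp(-rr / (2.0 * self.sigma_center**2))
        g_s = np.exp(-rr / (2.0 * self.sigma_surround**2))
        return g_c / g_c.sum() - g_s / g_s.sum()


def read_image(path) -> np.ndarray:
    """Read a grayscale PGM/PNG/TIFF image as a float array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("F"), dtype=float)


def read_iml(path, log_intensity: bool = False) -> np.ndarray:
    """Read a van Hateren raw .iml frame: 16-bit unsigned big-endian,
    1024 rows x 1536 columns, no header."""
    raw = np.fromfile(path, dtype=">u2")
    if raw.size != 1024 * 1536:
        raise ValueError(f"unexpected .iml size {raw.size}, want 1024*1536")
    img = raw.reshape(1024, 1536).astype(float)
    if log_intensity:
        img = np.log1p(img)
    return img


def extract_patches(
    images,
    patch_size: int,
    N: int,
    seed: int | np.random.Generator = 0,
) -> PatchSet:
    """Extract N square patches at uniform random positions.

    Images smaller than the patch are skipped with a warning; positions
    and source indices are kept in the metadata.
    """
    rng = np.random.default_rng(seed)
    images = [np.asarray(im, dtype=float) for im in images]
    usable = [i for i, im in enumerate(images)
              if im.shape[0] >= patch_size and im.shape[1] >= patch_size]
    if len(usable) < len(images):
        warnings.warn("skipping image(s) smaller than the patch size")
    if not usable:
        raise ValueError("no image is large enough for the patch size")
    src = rng.choice(usable, size=N)
    Y = np.empty((N, patch_size * patch_size))
    rows = np.empty(N, dtype=int)
    cols = np.empty(N, dtype=int)
    for n, i in enumerate(src):
        im = images[i]
        r = rng.integers(0, im.shape[0] - patch_size + 1)
        c = rng.integers(0, im.shape[1] - patch_size + 1)
        rows[n], cols[n] = r, c
        Y[n] = im[r : r + patch_size, c : c + patch_size].ravel()
    meta = {"source": src, "row": rows, "col": cols, "stage": "raw"}
    return PatchSet(Y, shape=(patch_size, patch_size), meta=meta)


def dog_filter(
    patches: PatchSet, kernel: DoGKernel, mode: str = "valid"
) -> PatchSet:
    """Convolve each patch with the DoG kernel.

    ``mode='valid'`` (default) keeps only the central region free of
    padding artifacts, shrinking the patch by kernel size - 1 per axis;
    ``mode='same'`` preserves the geometry using symmetric padding.
    """
    if patches.shape is None:
        raise ValueError("patches need a 2-D shape for filtering")
    k = kernel.weights
    rows, cols = patches.shape
    if mode == "valid" and (rows < k.shape[0] or cols < k.shape[1]):
        raise ValueError("patch smaller than kernel in 'valid' mode")
    out = []
    for y in patches.Y:
        im = y.reshape(rows, cols)
        if mode == "valid":
            f = convolve2d(im, k, mode="valid")
        else:
            f = convolve2d(np.pad(im, k.shape[0] // 2, mode="symmetric"),
                           k, mode="valid")
        out.append(f.ravel())
    f0 = out[0]
    new_shape = (
        rows - (k.shape[0] - 1) if mode == "valid" else rows,
        cols - (k.shape[1] - 1) if mode == "valid" else cols,
    )
    meta = dict(patches.meta, stage="dog",
                kernel=dict(size=kernel.size, sigma_center=kernel.sigma_center,
                            ratio=kernel.ratio), mode=mode)
    return PatchSet(np.array(out), shape=new_shape, meta=meta)


def contrast_scale(patches: PatchSet, per_patch: bool = False) -> PatchSet:
    """Scale so the extreme magnitude is exactly 10 — a simple divisive
    contrast normalization.

    One global multiplicative factor by default ("fill the interval
    [-10, 10]" as a dataset-level statement); a per-patch mode is
    available.  All-zero input is rejected.
    """
    Y = patches.Y
    if per_patch:
        m = np.max(np.abs(Y), axis=1, keepdims=True)
        if np.any(m == 0):
            raise ValueError("all-zero patch cannot be contrast-scaled")
        Ys = Y * (CONTRAST_RANGE / m)
    else:
        m = float(np.max(np.abs(Y)))
        if m == 0:
            raise ValueError("all-zero dataset cannot be contrast-scaled")
        Ys = Y * (CONTRAST_RANGE / m)
    meta = dict(patches.meta, stage="scaled", per_patch=per_patch)
    return PatchSet(Ys, shape=patches.shape, meta=meta)


def variance_normalize(patches: PatchSet) -> PatchSet:
    """Alternative normalizer: divide each patch by its std (divisive
    variance normalization)."""
    sd = patches.Y.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant patch cannot be variance-normalized")
    meta = dict(patches.meta, stage="varnorm")
    return PatchSet(patches.Y / sd, shape=patches.shape, meta=meta)


@dataclass
class WhiteningTransform:
    """Zero-phase (symmetric) whitening: x -> A (x - mean) with
    A = C^{-1/2} from the eigendecomposition of the centered covariance C.
    Eigenvalues below ``eigenfloor`` are clipped (rank-deficient data)."""

    matrix: np.ndarray
    mean: np.ndarray
    eigenfloor: float


def zca_fit(patches: PatchSet, eigenfloor: float = 1e-8) -> WhiteningTransform:
    Y = patches.Y
    mean = Y.mean(axis=0)
    C = np.cov(Y - mean, rowvar=False, bias=True)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    floor = eigenfloor * max(evals.max(), 1e-300)
    if np.any(evals < floor):
        warnings.warn("rank-deficient covariance; eigenfloor applied")
    evals = np.maximum(evals, floor)
    A = evecs @ np.diag(evals**-0.5) @ evecs.T
    A = 0.5 * (A + A.T)  # enforce exact symmetry
    return WhiteningTransform(matrix=A, mean=mean, eigenfloor=floor)


def zca_apply(patches: PatchSet, transform: WhiteningTransform) -> PatchSet:
    Yw = (patches.Y - transform.mean) @ transform.matrix.T
    meta = dict(patches.meta, stage="zca")
    return PatchSet(Yw, shape=patches.shape, meta=meta)


def split_on_off(patches: PatchSet) -> PatchSet:
    """Separate positive and negative responses into independent ON/OFF
    channels: output dimension 2D, first block max(y, 0), second block
    max(-y, 0).  The original patch is block1 - block2, and at each pixel
    at most one block is nonzero, so the occlusive max-magnitude rule
    reduces to a plain entrywise max on the separated data."""
    Y = patches.Y
    on = np.maximum(Y, 0.0)
    off = np.maximum(-Y, 0.0)
    meta = dict(patches.meta, stage="onoff", original_shape=patches.shape)
    return PatchSet(np.concatenate([on, off], axis=1), shape=None, meta=meta)
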
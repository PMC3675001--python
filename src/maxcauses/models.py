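"""Generative models for binary sparse coding of image patches.

Two models share a Bernoulli prior over binary hidden units and isotropic
Gaussian pixel noise, and differ only in how active basis functions combine
into the noiseless patch:

* **MCA** (maximal causes analysis): at each pixel the active basis function
  with the largest absolute value sets the pixel — an occlusion-like,
  winner-take-all superposition.
* **BSC** (binary sparse coding): active basis functions sum linearly.

The parameter set is identical for both models: a basis matrix ``W`` of
shape (D pixels, H hidden units), a noise standard deviation ``sigma`` and a
Bernoulli activation probability ``pi``.  ``H * pi`` is the mean number of
active causes per patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "PatchSet",
    "combine_max_magnitude",
    "combine_linear",
    "combine_smooth_max",
    "combine",
    "log_joint",
    "sample_dataset",
]


@dataclass
class ModelParams:
    """Full parameter set Theta = (W, sigma, pi) plus the combination rule.

    Parameters
    ----------
    W : ndarray, shape (D, H)
        Basis functions as columns, in patch intensity units.
    sigma : float
        Standard deviation of the additive Gaussian pixel noise (> 0).
    pi : float
        Bernoulli probability that a hidden unit is active, in (0, 1).
    model_kind : {"MCA", "BSC"}
        Occlusive max-magnitude or linear superposition.
    """

    W: np.ndarray
    sigma: float
    pi: float
    model_kind: str = "MCA"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] < 1 or self.W.shape[1] < 1:
            raise ValueError("W must be a D x H matrix with D, H >= 1")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W must be finite")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must lie in (0, 1)")
        kind = str(self.model_kind).upper()
        if kind not in ("MCA", "BSC"):
            raise ValueError("model_kind must be 'MCA' or 'BSC'")
        self.model_kind = kind

    @property
    def D(self) -> int:
        return self.W.shape[0]

    @property
    def H(self) -> int:
        return self.W.shape[1]

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class PatchSet:
    """N patches as rows of an (N, D) array, with optional 2-D geometry.

    ``shape`` is the (rows, cols) patch geometry with row-major flattening;
    ``meta`` carries provenance (source images, positions, preprocessing).
    """

    Y: np.ndarray
    shape: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("patch values must be finite")
        if self.shape is not None:
            r, c = self.shape
            if r * c != self.Y.shape[1]:
                raise ValueError("shape incompatible with patch dimension")

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def D(self) -> int:
        return self.Y.shape[1]


def _check_state(s: np.ndarray, H: int) -> np.ndarray:
    s = np.asarray(s)
    if s.shape != (H,):
        raise ValueError(f"state has shape {s.shape}, expected ({H},)")
    return s != 0


def combine_max_magnitude(s: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Occlusive superposition: per pixel, the active column with the
    largest absolute value wins (sign preserved).

    Ties go to the lowest unit index; no active unit gives a zero pixel.
    """
    W = np.asarray(W, dtype=float)
    active = np.flatnonzero(_check_state(s, W.shape[1]))
    if active.size == 0:
        return np.zeros(W.shape[0])
    sub = W[:, active]
    win = np.argmax(np.abs(sub), axis=1)  # first max -> lowest index
    return sub[np.arange(W.shape[0]), win]


def combine_linear(s: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Linear superposition: sum of the active columns, W @ s."""
    W = np.asarray(W, dtype=float)
    return W @ _check_state(s, W.shape[1]).astype(float)


def _check_rho(rho: int) -> int:
    rho = int(rho)
    if rho < 3 or rho % 2 == 0:
        raise ValueError("rho must be an odd integer >= 3")
    return rho


def combine_smooth_max(s: np.ndarray, W: np.ndarray, rho: int) -> np.ndarray:
    """Smooth approximation of the max-magnitude rule.

    Pixel d maps to the signed rho-th root of ``sum_h s_h W[d,h]**rho``;
    odd ``rho`` keeps signs real (``sign(T) * |T|**(1/rho)``) and the result
    converges to :func:`combine_max_magnitude` as ``rho -> inf`` whenever
    magnitudes are distinct.
    """
    rho = _check_rho(rho)
    W = np.asarray(W, dtype=float)
    active = np.flatnonzero(_check_state(s, W.shape[1]))
    if active.size == 0:
        return np.zeros(W.shape[0])
    sub = W[:, active]
    # normalize per pixel by the largest magnitude so powers stay in [-1, 1]
    m = np.max(np.abs(sub), axis=1)
    safe = np.where(m > 0, m, 1.0)
    T = np.sum((sub / safe[:, None]) ** rho, axis=1)
    out = safe * np.sign(T) * np.abs(T) ** (1.0 / rho)
    return np.where(m > 0, out, 0.0)


def combine(s: np.ndarray, W: np.ndarray, model_kind: str) -> np.ndarray:
    """Model-appropriate noiseless patch W_bar(s, W)."""
    if model_kind.upper() == "MCA":
        return combine_max_magnitude(s, W)
    return combine_linear(s, W)


def log_joint(y: np.ndarray, s: np.ndarray, params: ModelParams) -> float:
    """log p(y, s | Theta) = log Bernoulli(s; pi) + log N(y; W_bar, sigma^2 I)."""
    y = np.asarray(y, dtype=float)
    if y.shape != (params.D,):
        raise ValueError(f"patch has shape {y.shape}, expected ({params.D},)")
    sb = _check_state(s, params.H)
    k = int(sb.sum())
    mean = combine(sb, params.W, params.model_kind)
    resid = y - mean
    lp_prior = k * np.log(params.pi) + (params.H - k) * np.log1p(-params.pi)
    lp_noise = -0.5 * params.D * np.log(2.0 * np.pi * params.sigma**2)
    lp_noise -= 0.5 * float(resid @ resid) / params.sigma**2
    return float(lp_prior + lp_noise)


def sample_dataset(
    params: ModelParams,
    N: int,
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] | None = None,
) -> tuple[PatchSet, np.ndarray]:
    """Draw N patches from the generative model.

    States are i.i.d. Bernoulli(pi) per unit; patches are the model's
    combination of the active columns plus i.i.d. Gaussian noise of
    standard deviation sigma.  Returns the patches and the (N, H) binary
    state matrix used to generate them.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    S = (rng.random((N, params.H)) < params.pi).astype(np.int8)
    means = np.empty((N, params.D))
    for n in range(N):
        means[n] = combine(S[n], params.W, params.model_kind)
    Y = means + params.sigma * rng.standard_normal((N, params.D))
    meta = {"generator": "sample_dataset", "model_kind": params.model_kind}
    return PatchSet(Y, shape=shape, meta=meta), S
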
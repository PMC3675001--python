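"""Ground-truth generators: the bars benchmark, synthetic Gabor/DoG
fields, and a toy occlusive scene generator.

The bars benchmark is the standard component-extraction test: on a b x b
patch the 2b generating basis functions are the b horizontal and b
vertical bars, each at amplitude +a or -a, two bars active on average
(pi = 2/H), combined under either the occlusive or the linear rule with
additive Gaussian noise.  Recovery of the generating parameters is scored
by greedy max-cosine matching of learned to generating columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ModelParams, PatchSet, sample_dataset
from .rf import DoGFieldParams, GaborParams, dog_field, gabor_field

__all__ = [
    "BarsGroundTruth",
    "RecoveryReport",
    "make_bars_params",
    "generate_bars_dataset",
    "score_recovery",
    "make_synthetic_field",
    "make_occlusive_scene",
]

BAR_AMPLITUDE = 10.0  # matches the [-10, 10] contrast-normalized data scale
BAR_SIGMA = 2.0
# Std of the small Gaussian perturbation on bar pixels.  Besides making the
# benchmark less degenerate, the perturbation decides which bar wins at a
# +a/-a crossing under the occlusive rule; it must exceed the basis
# estimation error (~sigma/sqrt(N*pi)) or the generating winner order is
# unidentifiable and the recovered noise absorbs the crossing mistakes.
BAR_JITTER = 1.0


@dataclass
class BarsGroundTruth:
    """Generating configuration of a bars dataset, kept for scoring."""

    grid_size: int
    W: np.ndarray  # (b*b, 2b) generating basis
    amplitude: float
    signs: np.ndarray  # (+1/-1) per bar
    pi: float
    sigma: float
    model_kind: str


@dataclass
class RecoveryReport:
    """Greedy max-cosine matching of learned to generating bars."""

    matching: np.ndarray  # learned column index per generating bar
    cosines: np.ndarray  # per generating bar
    pi_learned: float
    sigma_learned: float
    pi_true: float
    sigma_true: float
    success: bool

    @property
    def mean_active_learned(self) -> float:
        return self.pi_learned * len(self.matching)

    @property
    def mean_active_true(self) -> float:
        return self.pi_true * len(self.matching)


def make_bars_params(
    b: int = 5,
    amplitude: float = BAR_AMPLITUDE,
    sign_rule: str = "random",
    pi: float | None = None,
    sigma: float = BAR_SIGMA,
    seed: int | np.random.Generator = 0,
    model_kind: str = "MCA",
) -> tuple[ModelParams, BarsGroundTruth]:
    """Generating parameters of the bars benchmark.

    The basis has H = 2b columns on a b x b grid: b horizontal bars (full
    rows) then b vertical bars (full columns), each at +/- amplitude with
    a small additive Gaussian perturbation.  ``sign_rule`` is "random",
    "positive" or "alternating"; ``pi`` defaults to 2/H (two bars active
    on average).
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    rng = np.random.default_rng(seed)
    H = 2 * b
    D = b * b
    if pi is None:
        pi = 2.0 / H
    if sign_rule == "random":
        signs = rng.choice([-1.0, 1.0], size=H)
    elif sign_rule == "positive":
        signs = np.ones(H)
    elif sign_rule == "alternating":
        signs = np.where(np.arange(H) % 2 == 0, 1.0, -1.0)
    else:
        raise ValueError("sign_rule must be random/positive/alternating")
    W = np.zeros((D, H))
    for i in range(b):  # horizontal bars: one full row each
        img = np.zeros((b, b))
        img[i, :] = signs[i] * amplitude
        W[:, i] = img.ravel()
    for j in range(b):  # vertical bars: one full column each
        img = np.zeros((b, b))
        img[:, j] = signs[b + j] * amplitude
        W[:, b + j] = img.ravel()
    W = W + BAR_JITTER * rng.standard_normal(W.shape)
    params = ModelParams(W=W, sigma=sigma, pi=pi, model_kind=model_kind)
    gt = BarsGroundTruth(grid_size=b, W=W.copy(), amplitude=amplitude,
                         signs=signs, pi=pi, sigma=sigma,
                         model_kind=params.model_kind)
    return params, gt


def generate_bars_dataset(
    gt: BarsGroundTruth,
    N: int,
    model_kind: str | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[PatchSet, np.ndarray]:
    """Sample a bars dataset under the requested combination rule.

    Under the linear rule a +a bar crossing a -a bar cancels at the shared
    pixel; under the occlusive rule the max-magnitude bar (tie -> lower
    index) sets it.
    """
    kind = (model_kind or gt.model_kind).upper()
    params = ModelParams(W=gt.W, sigma=gt.sigma, pi=gt.pi, model_kind=kind)
    patches, states = sample_dataset(params, N, seed=seed,
                                     shape=(gt.grid_size, gt.grid_size))
    patches.meta.update(generator="bars", b=gt.grid_size)
    return patches, states


def score_recovery(
    learned: ModelParams, gt: BarsGroundTruth
) -> RecoveryReport:
    """Greedy assignment maximizing cosine similarity between learned and
    generating columns (raw columns: a bar and its negation are distinct
    causes).  Success means every generating bar is matched at cosine
    >= 0.95."""
    Wl, Wg = learned.W, gt.W
    if Wl.shape[0] != Wg.shape[0]:
        raise ValueError("pixel dimensions differ")
    nl = np.linalg.norm(Wl, axis=0)
    ng = np.linalg.norm(Wg, axis=0)
    C = (Wg.T @ Wl) / np.outer(np.maximum(ng, 1e-300),
                               np.maximum(nl, 1e-300))
    Hg, Hl = C.shape
    matching = np.full(Hg, -1)
    cosines = np.full(Hg, -np.inf)
    avail = np.ones(Hl, dtype=bool)
    flat = np.argsort(-C, axis=None, kind="stable")
    assigned = 0
    for idx in flat:
        g, l = divmod(idx, Hl)
        if matching[g] == -1 and avail[l]:
            matching[g] = l
            cosines[g] = C[g, l]
            avail[l] = False
            assigned += 1
            if assigned == min(Hg, Hl):
                break
    success = bool(np.all(cosines >= 0.95)) and Hl >= Hg
    return RecoveryReport(
        matching=matching, cosines=cosines,
        pi_learned=learned.pi, sigma_learned=learned.sigma,
        pi_true=gt.pi, sigma_true=gt.sigma, success=success,
    )


def make_synthetic_field(
    kind: str,
    params: GaborParams | DoGFieldParams,
    shape: tuple[int, int] = (16, 16),
    noise: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Render a noise-free (or noisy) Gabor or DoG field with known
    parameters — the oracle input for fit-recovery tests."""
    if kind == "gabor":
        field = gabor_field(params, shape)
    elif kind == "dog":
        field = dog_field(params, shape)
    else:
        raise ValueError("kind must be 'gabor' or 'dog'")
    if noise > 0:
        rng = np.random.default_rng(seed)
        field = field + noise * rng.standard_normal(shape)
    return field


def make_occlusive_scene(
    num_objects: int,
    size: int = 64,
    seed: int | np.random.Generator = 0,
    background: float = 0.0,
) -> np.ndarray:
    """Layered opaque shapes on a flat background (painter's algorithm).

    Rectangles and ellipses of random intensity are painted back-to-front;
    a pixel always shows the front-most object covering it.  A smoke-test
    stimulus for the full pipeline, not a calibrated dead-leaves model.
    """
    rng = np.random.default_rng(seed)
    img = np.full((size, size), float(background))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(num_objects):
        intensity = rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0])
        cx, cy = rng.uniform(0, size, 2)
        rx, ry = rng.uniform(size / 16, size / 4, 2)
        if rng.random() < 0.5:  # rectangle
            mask = (np.abs(xx - cx) <= rx) & (np.abs(yy - cy) <= ry)
        else:  # ellipse
            mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        img[mask] = intensity
    return img
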
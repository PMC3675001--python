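"""Receptive-field estimation and shape analysis.

A learned basis function is turned into a receptive-field estimate by
convolving it with the same center-surround kernel used for
preprocessing (the linear two-stage mapping: LGN filter followed by the
unit's linear read-out).  Each field is then matched by least squares
against an 8-parameter Gabor wavelet and an 8-parameter
difference-of-Gaussians (DoG) model, classified as globular /
Gabor-like / ambiguous / unspecific, and summarized by the dimensionless
shape coordinates nx = sigma_x * f and ny = sigma_y * f (envelope widths
in units of the spatial wavelength).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import convolve2d

from .preprocessing import DoGKernel

__all__ = [
    "GaborParams",
    "DoGFieldParams",
    "FieldFit",
    "gabor_field",
    "dog_field",
    "estimate_rf",
    "reverse_correlation_rf",
    "fit_gabor",
    "fit_dog",
    "classify_field",
    "analyze_fields",
    "shape_statistics",
    "globular_fraction",
    "canonical_gabor",
    "canonical_dog",
]

EPS_AMBIG = 0.05  # relative residual gap below which a field is ambiguous
UNSPECIFIC_FRAC = 0.5  # both fits explaining < 50% of variance -> unspecific
ASPECT_LIMIT = 2.0  # globular DoG aspect-ratio bound


@dataclass(frozen=True)
class GaborParams:
    """Gabor wavelet: Gaussian envelope times an oriented sinusoid.

    ``sigma_x`` is the envelope std along the wave vector, ``sigma_y``
    orthogonal to it (pixels); ``f`` the spatial frequency in
    cycles/pixel; ``phi`` the phase; ``A`` the amplitude.
    """

    x0: float
    y0: float
    theta: float
    sigma_x: float
    sigma_y: float
    f: float
    phi: float
    A: float

    def to_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.theta, self.sigma_x,
                         self.sigma_y, self.f, self.phi, self.A])


@dataclass(frozen=True)
class DoGFieldParams:
    """Difference of two aligned elliptical Gaussians; ``k > 1`` scales the
    outer Gaussian's widths relative to the inner one."""

    x0: float
    y0: float
    theta: float
    sigma1_x: float
    sigma1_y: float
    k: float
    a1: float
    a2: float

    @property
    def aspect_ratio(self) -> float:
        hi = max(self.sigma1_x, self.sigma1_y)
        lo = min(self.sigma1_x, self.sigma1_y)
        return hi / lo if lo > 0 else np.inf

    def to_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.theta, self.sigma1_x,
                         self.sigma1_y, self.k, self.a1, self.a2])


@dataclass
class FieldFit:
    """Both fits of one field, residual mean-squared errors, the class
    label, and (for Gabor-like fields) the nx/ny shape coordinates."""

    gabor: GaborParams
    gabor_residual: float
    dog: DoGFieldParams
    dog_residual: float
    label: str
    nx: float | None = None
    ny: float | None = None


def _rotated_coords(shape, x0, y0, theta):
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    dx, dy = x - x0, y - y0
    c, s = np.cos(theta), np.sin(theta)
    return dx * c + dy * s, -dx * s + dy * c


def gabor_field(p: GaborParams, shape: tuple[int, int]) -> np.ndarray:
    xr, yr = _rotated_coords(shape, p.x0, p.y0, p.theta)
    env = np.exp(-(xr**2) / (2 * p.sigma_x**2) - (yr**2) / (2 * p.sigma_y**2))
    return p.A * env * np.cos(2 * np.pi * p.f * xr + p.phi)


def dog_field(p: DoGFieldParams, shape: tuple[int, int]) -> np.ndarray:
    xr, yr = _rotated_coords(shape, p.x0, p.y0, p.theta)
    g1 = np.exp(-(xr**2) / (2 * p.sigma1_x**2) - (yr**2) / (2 * p.sigma1_y**2))
    kx, ky = p.k * p.sigma1_x, p.k * p.sigma1_y
    g2 = np.exp(-(xr**2) / (2 * kx**2) - (yr**2) / (2 * ky**2))
    return p.a1 * g1 - p.a2 * g2


def estimate_rf(
    w_col: np.ndarray, kernel: DoGKernel, shape: tuple[int, int]
) -> np.ndarray:
    """Receptive-field estimate: the basis column reshaped to its patch
    geometry and convolved with the preprocessing kernel (same-size)."""
    w_col = np.asarray(w_col, dtype=float)
    if w_col.size != shape[0] * shape[1]:
        raise ValueError("basis column incompatible with patch geometry")
    return convolve2d(w_col.reshape(shape), kernel.weights, mode="same")


def reverse_correlation_rf(
    stimuli: np.ndarray, responses: np.ndarray
) -> np.ndarray:
    """Least-squares linear map from stimuli to unit responses.

    Regresses per-unit posterior means on the preprocessed stimuli
    (with intercept); returns the (D, H) map.  Ill-conditioned designs
    fall back to the minimum-norm solution with a warning.
    """
    S = np.atleast_2d(np.asarray(stimuli, dtype=float))
    R = np.asarray(responses, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if S.shape[0] < S.shape[1]:
        raise ValueError("need at least D stimuli")
    X = np.column_stack([S, np.ones(S.shape[0])])
    sol, _, rank, _ = np.linalg.lstsq(X, R, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("ill-conditioned reverse-correlation design; "
                      "minimum-norm solution used")
    return sol[:-1]


# ---------------------------------------------------------------------------
# canonical forms (parameter equivalences)

def canonical_gabor(p: GaborParams) -> GaborParams:
    """Resolve Gabor parameter equivalences: positive widths, f > 0,
    A > 0 (phase shifted by pi), theta in [0, pi) (rotation by pi negates
    the phase), phi in (-pi, pi]."""
    x0, y0, theta = p.x0, p.y0, p.theta
    sx, sy = abs(p.sigma_x), abs(p.sigma_y)
    f, phi, A = p.f, p.phi, p.A
    if f < 0:
        f, phi = -f, -phi
    if A < 0:
        A, phi = -A, phi + np.pi
    theta = theta % (2 * np.pi)
    if theta >= np.pi:
        theta -= np.pi
        phi = -phi
    phi = (phi + np.pi) % (2 * np.pi) - np.pi
    if phi == -np.pi:
        phi = np.pi
    return GaborParams(x0, y0, theta, sx, sy, f, phi, A)


def canonical_dog(p: DoGFieldParams) -> DoGFieldParams:
    """Resolve DoG equivalences: positive widths, k > 1 (swapping the two
    Gaussians when the fitted k is below 1), major axis on sigma1_x
    (rotating theta by pi/2 otherwise), theta in [0, pi)."""
    sx, sy, k = abs(p.sigma1_x), abs(p.sigma1_y), abs(p.k)
    a1, a2 = p.a1, p.a2
    theta = p.theta
    if k < 1 and k > 0:
        sx, sy = k * sx, k * sy
        k = 1.0 / k
        a1, a2 = -a2, -a1
    if sx < sy:
        sx, sy = sy, sx
        theta = theta + np.pi / 2
    return DoGFieldParams(p.x0, p.y0, theta % np.pi, sx, sy, k, a1, a2)


# ---------------------------------------------------------------------------
# least-squares matching

def _fit_model(field, model, starts, max_nfev=200, n_refine=12):
    """Multi-start Levenberg-Marquardt; keep the best solution.

    All starts are ranked by their initial cost and the best ``n_refine``
    are refined (deterministic order); a refined solution whose residual
    is numerically zero stops the sweep early.
    """
    target = field.ravel()
    power = float(np.mean(target**2))

    def resid(p):
        return model(p).ravel() - target

    init_cost = [float(np.sum(resid(np.asarray(p0)) ** 2)) for p0 in starts]
    order = np.argsort(init_cost, kind="stable")[:n_refine]

    best_p, best_cost = None, np.inf
    for p0 in [starts[i] for i in order]:
        try:
            sol = least_squares(resid, p0, method="lm", max_nfev=max_nfev)
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best_p = sol.cost, sol.x
            if best_cost <= 1e-12 * max(power, 1e-300) * target.size:
                break
    if best_p is None:  # every start failed; fall back to the first guess
        best_p = np.asarray(starts[0], dtype=float)
        best_cost = 0.5 * float(np.sum(resid(best_p) ** 2))
    mse = 2.0 * best_cost / target.size
    return best_p, mse


def _fft_guess(field: np.ndarray):
    """Dominant-frequency initial guess (theta, f) from the 2-D spectrum."""
    F = np.abs(np.fft.fft2(field))
    F[0, 0] = 0.0
    fy = np.fft.fftfreq(field.shape[0])
    fx = np.fft.fftfreq(field.shape[1])
    iy, ix = np.unravel_index(np.argmax(F), F.shape)
    vx, vy = fx[ix], fy[iy]
    f0 = float(np.hypot(vx, vy))
    theta0 = float(np.arctan2(vy, vx)) % np.pi
    return theta0, max(f0, 1e-3)


def fit_gabor(
    field: np.ndarray, n_theta: int = 8, n_phase: int = 4
) -> tuple[GaborParams, float]:
    """Best-of-multi-start least-squares Gabor match.

    Starts combine an FFT-derived (orientation, frequency) guess with a
    deterministic grid of orientations, phases and two center guesses;
    single-start local optimization is known to be insufficient for Gabor
    fitting.  Returns canonical parameters and the residual MSE.
    """
    field = np.asarray(field, dtype=float)
    if not np.any(field):
        warnings.warn("flat field; returning zero-amplitude Gabor")
        p = GaborParams(field.shape[1] / 2, field.shape[0] / 2, 0.0,
                        1.0, 1.0, 0.1, 0.0, 0.0)
        return p, 0.0
    rows, cols = field.shape
    iy, ix = np.unravel_index(np.argmax(np.abs(field)), field.shape)
    A0 = field[iy, ix]
    s0 = max(min(rows, cols) / 6.0, 1.0)
    theta_fft, f_fft = _fft_guess(field)
    centers = [(float(ix), float(iy)), ((cols - 1) / 2.0, (rows - 1) / 2.0)]
    thetas = [theta_fft] + list(np.arange(n_theta) * np.pi / n_theta)
    phases = list(np.arange(n_phase) * 2 * np.pi / n_phase)
    starts = []
    for cx, cy in centers:
        for th in thetas:
            for ph in phases:
                starts.append([cx, cy, th, s0, s0, f_fft, ph, A0])

    def model(p):
        return gabor_field(GaborParams(*p), field.shape)

    best, mse = _fit_model(field, model, starts)
    return canonical_gabor(GaborParams(*best)), mse


def fit_dog(
    field: np.ndarray, n_theta: int = 4
) -> tuple[DoGFieldParams, float]:
    """Best-of-multi-start least-squares difference-of-Gaussians match."""
    field = np.asarray(field, dtype=float)
    if not np.any(field):
        warnings.warn("flat field; returning zero-amplitude DoG")
        p = DoGFieldParams(field.shape[1] / 2, field.shape[0] / 2, 0.0,
                           1.0, 1.0, 2.0, 0.0, 0.0)
        return p, 0.0
    rows, cols = field.shape
    a0 = float(np.abs(field).max())
    # with a strong surround the field's extremum can be the surround ring
    # (off-center, opposite sign), so seed centers from the positive peak,
    # the negative peak and the patch center, and amplitudes of both signs
    # and several scales (the center peak is a1 - a2, not a1)
    hi = np.unravel_index(np.argmax(field), field.shape)
    lo = np.unravel_index(np.argmin(field), field.shape)
    centers = [(float(hi[1]), float(hi[0])), (float(lo[1]), float(lo[0])),
               ((cols - 1) / 2.0, (rows - 1) / 2.0)]
    sigmas = [1.0, max(min(rows, cols) / 8.0, 1.2), max(min(rows, cols) / 4.0, 1.5)]
    amplitudes = [(a0, 0.0), (a0, 0.5 * a0), (2 * a0, 1.5 * a0),
                  (4 * a0, 3.4 * a0)]
    amplitudes += [(-a1, -a2) for a1, a2 in amplitudes]
    starts = []
    for cx, cy in centers:
        for th in np.arange(n_theta) * np.pi / n_theta:
            for s in sigmas:
                for k in (1.5, 2.0, 3.0):
                    for a1, a2 in amplitudes:
                        starts.append([cx, cy, th, s, s, k, a1, a2])

    def model(p):
        return dog_field(DoGFieldParams(*p), field.shape)

    best, mse = _fit_model(field, model, starts, n_refine=24)
    return canonical_dog(DoGFieldParams(*best)), mse


# ---------------------------------------------------------------------------
# classification and statistics

def classify_field(
    gabor_residual: float,
    dog_residual: float,
    dog_params: DoGFieldParams,
    field_power: float,
    eps_ambig: float = EPS_AMBIG,
    unspecific_frac: float = UNSPECIFIC_FRAC,
) -> str:
    """Label a field from its two matches.

    Globular: the DoG match is better than the Gabor match and the DoG
    aspect ratio is below 2.0.  Ambiguous: the two residuals differ by
    less than ``eps_ambig`` relative to the smaller one (neither clearly
    center-surround nor clearly Gabor-like).  Unspecific: both fits leave
    more than ``unspecific_frac`` of the field power unexplained.
    Precedence: unspecific > ambiguous > globular/gabor_like.
    """
    power = max(field_power, 1e-300)
    rel_g = gabor_residual / power
    rel_d = dog_residual / power
    if rel_g > unspecific_frac and rel_d > unspecific_frac:
        return "unspecific"
    lo = max(min(gabor_residual, dog_residual), 1e-300)
    if abs(dog_residual - gabor_residual) / lo < eps_ambig:
        return "ambiguous"
    if dog_residual < gabor_residual and dog_params.aspect_ratio < ASPECT_LIMIT:
        return "globular"
    return "gabor_like"


def analyze_fields(
    fields,
    eps_ambig: float = EPS_AMBIG,
    unspecific_frac: float = UNSPECIFIC_FRAC,
) -> list[FieldFit]:
    """Fit, classify and annotate a sequence of 2-D fields."""
    fits = []
    for field in fields:
        field = np.asarray(field, dtype=float)
        gp, gres = fit_gabor(field)
        dp, dres = fit_dog(field)
        power = float(np.mean(field**2))
        label = classify_field(gres, dres, dp, power,
                               eps_ambig=eps_ambig,
                               unspecific_frac=unspecific_frac)
        fit = FieldFit(gabor=gp, gabor_residual=gres,
                       dog=dp, dog_residual=dres, label=label)
        if label == "gabor_like":
            fit.nx = gp.sigma_x * gp.f
            fit.ny = gp.sigma_y * gp.f
        fits.append(fit)
    return fits


def shape_statistics(fits) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """(nx, ny) per Gabor-like field plus the cloud's center of mass.

    Globular, ambiguous and unspecific fields are excluded first, so
    center-surround fields never have to be summarized by Gabor shape
    parameters.
    """
    rows = [
        {"nx": f.gabor.sigma_x * f.gabor.f, "ny": f.gabor.sigma_y * f.gabor.f}
        for f in fits
        if f.label == "gabor_like"
    ]
    table = pd.DataFrame(rows, columns=["nx", "ny"])
    if len(table) == 0:
        return table, None
    return table, (float(table.nx.mean()), float(table.ny.mean()))


def globular_fraction(
    fits, ambiguous_policy: str = "half"
) -> tuple[float, tuple[float, float]]:
    """Percentage of globular fields under a policy for ambiguous ones.

    ``half`` counts half of the ambiguous fields as globular and reports
    the ``none``/``all`` percentages as interval bounds; ``all``/``none``
    report the corresponding endpoint (with the same bounds).
    """
    total = len(fits)
    if total == 0:
        return 0.0, (0.0, 0.0)
    n_glob = sum(1 for f in fits if f.label == "globular")
    n_amb = sum(1 for f in fits if f.label == "ambiguous")
    lo = 100.0 * n_glob / total
    hi = 100.0 * (n_glob + n_amb) / total
    value = {"half": 100.0 * (n_glob + 0.5 * n_amb) / total,
             "all": hi, "none": lo}[ambiguous_policy]
    return value, (lo, hi)
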
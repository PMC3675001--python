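"""M-step updates and the EM driver for MCA and BSC.

Both models update the basis matrix W, the noise std sigma and the
Bernoulli sparsity pi from truncated posterior expectations.  The BSC
W-update is ordinary least squares of patches on expected states; the MCA
W-update uses finite-``rho`` smooth-max responsibilities (the derivative of
the smoothed combination w.r.t. each basis entry) and an evidence-based
learning rate that slows updates for entries supported by little data.
The pi update solves the stationarity condition A(pi)/B(pi) = mean<|s|>,
where A and B restrict the Bernoulli prior to states with at most gamma
active units; with gamma = H it reduces to pi = mean<|s|>/H.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .inference import EStats, TruncationParams, anneal_schedule, e_step
from .models import ModelParams, PatchSet

__all__ = [
    "SparsityTerms",
    "sparsity_terms",
    "evidence_rate",
    "mca_responsibility",
    "mca_update_W",
    "bsc_update_W",
    "update_sigma",
    "update_pi",
    "initialize",
    "run_em",
    "EMTrace",
]

SIGMA_FLOOR_SCALE = 1e-4  # sigma floor as a fraction of the data RMS scale
PI_CLIP = 1e-6


@dataclass(frozen=True)
class SparsityTerms:
    """Bernoulli prior restricted to states with at most gamma active units.

    ``A_pi`` is the expected active-unit count over those states,
    ``B_pi = P(|s| <= gamma)`` their total prior mass.  gamma = H gives
    B = 1 and A = H*pi.
    """

    A_pi: float
    B_pi: float


def sparsity_terms(pi: float, H: int, gamma: int) -> SparsityTerms:
    g = np.arange(gamma + 1)
    pmf = binom.pmf(g, H, pi)
    return SparsityTerms(A_pi=float((g * pmf).sum()), B_pi=float(pmf.sum()))


def evidence_rate(e: np.ndarray) -> np.ndarray:
    """Learning rate lambda(e) = e^2 / (e^2 + 4).

    Monotone in the evidence mass e; 0.5 when an entry explains two
    patches, ~0.96 above ten, approaching 1 for well-supported entries.
    """
    e = np.asarray(e, dtype=float)
    return e * e / (e * e + 4.0)


def mca_responsibility(s: np.ndarray, W: np.ndarray, rho: int) -> np.ndarray:
    """Per-entry responsibility d W_bar_rho(d) / d W[d,h] for one state.

    Equals ``s_h W[d,h]**(rho-1) (sum_h' s_h' W[d,h']**rho)**(1/rho - 1)``;
    as rho -> inf it concentrates on the max-magnitude active unit at each
    pixel.  Pixels where the smoothed total vanishes get weight 0.
    """
    if rho % 2 == 0 or rho < 3:
        raise ValueError("rho must be an odd integer >= 3")
    W = np.asarray(W, dtype=float)
    D, H = W.shape
    sb = (np.asarray(s) != 0)
    out = np.zeros((D, H))
    active = np.flatnonzero(sb)
    if active.size == 0:
        return out
    sub = W[:, active]
    m = np.max(np.abs(sub), axis=1)
    safe = np.where(m > 0, m, 1.0)
    u = sub / safe[:, None]
    upow = u ** (rho - 1)  # even power, >= 0
    S = np.sum(upow * u, axis=1)
    root = np.sign(S) * np.abs(S) ** (1.0 / rho)
    fac = np.where(S != 0, root / np.where(S != 0, S, 1.0), 0.0)
    # near-cancellation of opposite-sign entries makes the raw derivative
    # blow up; the large-rho limit is an indicator, so clip to its range
    out[:, active] = np.clip(upow * fac[:, None], 0.0, 1.0)
    return out


def _mca_weight_sums(
    Y: np.ndarray,
    stats: EStats,
    W: np.ndarray,
    M: np.ndarray,
    rho: int,
    mode: str = "limit",
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate sum_n <weight>*y and sum_n <weight> over patches in M.

    ``mode='limit'`` (default) uses the large-rho limit of the smooth-max
    derivative — the indicator that unit h carries the max-magnitude value
    at pixel d — which is the form the M-step equations are stated in.
    ``mode='smooth'`` uses the finite-rho derivative (clipped to [0, 1]).
    """
    D, H = W.shape
    Zf = stats.Z.astype(float)
    Hp = Zf.shape[1]
    numT = np.zeros((H, D))
    denT = np.zeros((H, D))
    for lo in range(0, M.size, chunk):
        idx = M[lo : lo + chunk]
        Ic = stats.I[idx]
        Yc = Y[idx]
        Pt = stats.Pt[idx]
        Wg = W[:, Ic].transpose(1, 0, 2)  # (n, D, H')
        if mode == "limit":
            mag = np.abs(Wg)
            masked = mag[:, None, :, :] * Zf[None, :, None, :]  # (n,K,D,H')
            win = np.argmax(masked, axis=-1)
            hit = np.take_along_axis(masked, win[..., None], axis=-1)[..., 0] > 0
            A = np.empty((len(idx), D, Hp))
            for j in range(Hp):
                A[:, :, j] = np.einsum("nk,nkd->nd", Pt,
                                       ((win == j) & hit).astype(float))
        else:
            m = np.max(np.abs(Wg), axis=2, keepdims=True)
            u = Wg / np.where(m > 0, m, 1.0)
            upow = u ** (rho - 1)
            urho = upow * u
            S = np.einsum("kh,ndh->nkd", Zf, urho)
            root = np.sign(S) * np.abs(S) ** (1.0 / rho)
            fac = np.where(S != 0, root / np.where(S != 0, S, 1.0), 0.0)
            wts = np.clip(upow[:, None, :, :] * fac[:, :, :, None], 0.0, 1.0)
            A = np.einsum("nk,kh,nkdh->ndh", Pt, Zf, wts)
        for j in range(Hp):
            np.add.at(numT, Ic[:, j], A[:, :, j] * Yc)
            np.add.at(denT, Ic[:, j], A[:, :, j])
        # out-of-set singletons: responsibility 1 at every pixel
        Po = stats.Pout[idx]
        numT += Po.T @ Yc
        denT += Po.sum(axis=0)[:, None]
    return numT.T, denT.T


def mca_update_W(
    Y: np.ndarray,
    stats: EStats,
    params: ModelParams,
    M: np.ndarray,
    rho: int,
    learning_rate: bool = True,
    mode: str = "limit",
) -> np.ndarray:
    """MCA basis update: responsibility-weighted mean of the data, blended
    with the previous value by the evidence-based learning rate.

    Entries with zero accumulated evidence are left unchanged.
    """
    num, den = _mca_weight_sums(Y, stats, params.W, M, rho, mode=mode)
    candidate = np.where(den > 0, num / np.where(den > 0, den, 1.0), params.W)
    lam = evidence_rate(den) if learning_rate else np.where(den > 0, 1.0, 0.0)
    return (1.0 - lam) * params.W + lam * candidate


def _bsc_suff_stats(
    Y: np.ndarray, stats: EStats, M: np.ndarray, H: int
) -> tuple[np.ndarray, np.ndarray]:
    """(sum_n y <s>^T, sum_n <s s^T>) over patches in M."""
    exp_s = stats.expected_s()[M]
    C = Y[M].T @ exp_s  # (D, H)
    Zf = stats.Z.astype(float)
    G = np.zeros((H, H))
    Msub = np.einsum("nk,kh,kg->nhg", stats.Pt[M], Zf, Zf)
    Ic = stats.I[M]
    np.add.at(G, (Ic[:, :, None], Ic[:, None, :]), Msub)
    G[np.diag_indices(H)] += stats.Pout[M].sum(axis=0)
    return C, G


def bsc_update_W(
    Y: np.ndarray, stats: EStats, params: ModelParams, M: np.ndarray
) -> np.ndarray:
    """BSC basis update: W = (sum y <s>^T)(sum <s s^T>)^-1 — least squares
    of patches on expected states.  Singular Gram matrices fall back to the
    pseudo-inverse with a warning."""
    C, G = _bsc_suff_stats(Y, stats, M, params.H)
    try:
        return np.linalg.solve(G.T, C.T).T
    except np.linalg.LinAlgError:
        warnings.warn("singular Gram matrix in BSC W-update; using pinv")
        return C @ np.linalg.pinv(G)


def _expected_residual_under(
    Y: np.ndarray,
    stats: EStats,
    W: np.ndarray,
    model_kind: str,
    M: np.ndarray,
    chunk: int = 256,
) -> float:
    """sum_{n in M} <||y_n - W_bar(s)||^2> with the posterior from the
    E-step but residuals recomputed under a (possibly updated) basis W."""
    from .inference import _template_means

    Zf = stats.Z.astype(float)
    colnorm = np.einsum("dh,dh->h", W, W)
    total = 0.0
    for lo in range(0, M.size, chunk):
        idx = M[lo : lo + chunk]
        Yc = Y[idx]
        Wg = W[:, stats.I[idx]].transpose(1, 0, 2)
        means = _template_means(Wg, Zf, model_kind)
        diff = Yc[:, None, :] - means
        r2 = np.einsum("nkd,nkd->nk", diff, diff)
        total += float((stats.Pt[idx] * r2).sum())
        ynorm = np.einsum("nd,nd->n", Yc, Yc)
        R1 = ynorm[:, None] - 2.0 * (Yc @ W) + colnorm[None, :]
        total += float((stats.Pout[idx] * np.maximum(R1, 0.0)).sum())
    return total


def update_sigma(
    Y: np.ndarray,
    stats: EStats,
    params: ModelParams,
    M: np.ndarray,
    W_new: np.ndarray | None = None,
) -> float:
    """Noise update sigma^2 = <||y - W_bar(s)||^2> averaged over M and pixels.

    When ``W_new`` is supplied the expected residual is evaluated under
    the updated basis (for BSC in closed form from the cached sufficient
    statistics; for MCA by recomputing the combinations), which keeps the
    W and sigma updates consistent within one M-step.  Floored at a small
    fraction of the data scale.
    """
    D = Y.shape[1]
    if W_new is not None and params.model_kind == "BSC":
        C, G = _bsc_suff_stats(Y, stats, M, params.H)
        ss = float(np.einsum("nd,nd->", Y[M], Y[M]))
        ss -= 2.0 * float(np.einsum("dh,dh->", W_new, C))
        ss += float(np.einsum("dh,dg,hg->", W_new, W_new, G))
        ss = max(ss, 0.0)
    elif W_new is not None:
        ss = _expected_residual_under(Y, stats, W_new, params.model_kind, M)
    else:
        ss = float(stats.expected_residual()[M].sum())
    floor = SIGMA_FLOOR_SCALE * max(float(np.sqrt(np.mean(Y**2))), 1e-12)
    return max(float(np.sqrt(ss / (M.size * D))), floor)


def update_pi(mean_abs_s: float, H: int, gamma: int) -> float:
    """Sparsity update: solve A(pi)/B(pi) = mean<|s|> for pi.

    A/B is the expected number of active units conditioned on at most
    gamma being active; it is monotone increasing in pi, so the root is
    found by bisection.  gamma = H gives the closed form pi = mean<|s|>/H.
    """
    s_bar = float(mean_abs_s)
    lo, hi = PI_CLIP, 1.0 - PI_CLIP
    if gamma >= H:
        return float(np.clip(s_bar / H, lo, hi))

    def resid(p: float) -> float:
        t = sparsity_terms(p, H, gamma)
        return t.A_pi / t.B_pi - s_bar

    if resid(lo) >= 0:
        return lo
    if resid(hi) <= 0:
        return hi
    return float(brentq(resid, lo, hi, xtol=1e-12))


def initialize(
    dataset: PatchSet | np.ndarray,
    H: int,
    seed: int | np.random.Generator = 0,
    model_kind: str = "MCA",
) -> ModelParams:
    """Standard initialization: each basis column is the data mean plus
    unit-variance Gaussian noise; pi corresponds to one active component
    on average (pi = 1/H); sigma^2 is the mean empirical pixel variance."""
    Y = dataset.Y if isinstance(dataset, PatchSet) else np.atleast_2d(dataset)
    rng = np.random.default_rng(seed)
    mean = Y.mean(axis=0)
    W = mean[:, None] + rng.standard_normal((Y.shape[1], H))
    pi = float(np.clip(1.0 / H, PI_CLIP, 1.0 - PI_CLIP))
    var = float(np.mean(Y.var(axis=0)))
    floor = SIGMA_FLOOR_SCALE * max(float(np.sqrt(np.mean(Y**2))), 1e-12)
    sigma = max(np.sqrt(var), floor)
    return ModelParams(W=W, sigma=sigma, pi=pi, model_kind=model_kind)


@dataclass
class EMTrace:
    """Per-iteration EM diagnostics."""

    free_energy: list[float] = field(default_factory=list)
    pi: list[float] = field(default_factory=list)
    sigma: list[float] = field(default_factory=list)
    n_selected: list[int] = field(default_factory=list)
    fraction: list[float] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    wall_time: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.free_energy)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "free_energy": np.array(self.free_energy),
            "pi": np.array(self.pi),
            "sigma": np.array(self.sigma),
            "n_selected": np.array(self.n_selected),
            "fraction": np.array(self.fraction),
            "temperature": np.array(self.temperature),
            "wall_time": np.array(self.wall_time),
        }


def run_em(
    dataset: PatchSet | np.ndarray,
    model_kind: str,
    H: int,
    trunc: TruncationParams,
    iters: int,
    seed: int | np.random.Generator = 0,
    rho: int = 25,
    start_temperature: float = 1.0,
    use_learning_rate: bool = True,
    init_params: ModelParams | None = None,
    start_iteration: int = 1,
    on_iteration=None,
) -> tuple[ModelParams, EMTrace]:
    """Truncated variational EM: alternate the ET E-step with the model's
    M-steps under the thirds-based annealing schedule.

    Deterministic given the seed.  The recorded free energy for iteration
    t is evaluated at the pre-update parameters, so with no truncation it
    is the exact EM objective and must be non-decreasing.  ``init_params``
    and ``start_iteration`` allow resuming a checkpointed run.
    """
    Y = dataset.Y if isinstance(dataset, PatchSet) else np.atleast_2d(dataset)
    trunc.validate(H)
    params = init_params if init_params is not None else initialize(
        Y, H, seed=seed, model_kind=model_kind
    )
    if params.model_kind != model_kind.upper():
        params = params.replace(model_kind=model_kind.upper())
    trace = EMTrace()
    for t in range(start_iteration, iters + 1):
        t0 = time.perf_counter()
        sched = anneal_schedule(t, iters, start_temperature=start_temperature)
        stats = e_step(Y, params, trunc, temperature=sched.temperature)
        B = sparsity_terms(params.pi, params.H, trunc.gamma).B_pi
        target = (1.0 - sched.fraction) + sched.fraction * B
        size = max(1, int(round(Y.shape[0] * target)))
        order = np.argsort(-stats.log_evidence, kind="stable")
        M = np.sort(order[:size])
        F = float(stats.log_evidence[M].sum() - M.size * np.log(B))

        if params.model_kind == "MCA":
            W_new = mca_update_W(Y, stats, params, M, rho,
                                 learning_rate=use_learning_rate)
            sigma_new = update_sigma(Y, stats, params, M, W_new=W_new)
        else:
            W_new = bsc_update_W(Y, stats, params, M)
            sigma_new = update_sigma(Y, stats, params, M, W_new=W_new)
        s_bar = float(stats.expected_abs_s()[M].mean())
        pi_new = update_pi(s_bar, params.H, trunc.gamma)

        if not (np.all(np.isfinite(W_new)) and np.isfinite(sigma_new)
                and np.isfinite(pi_new)):
            raise FloatingPointError(
                f"non-finite parameters at EM iteration {t}; trace so far: "
                f"F={trace.free_energy}"
            )
        params = params.replace(W=W_new, sigma=sigma_new, pi=pi_new)

        trace.free_energy.append(F)
        trace.pi.append(params.pi)
        trace.sigma.append(params.sigma)
        trace.n_selected.append(int(M.size))
        trace.fraction.append(target)
        trace.temperature.append(sched.temperature)
        trace.wall_time.append(time.perf_counter() - t0)
        if on_iteration is not None:
            on_iteration(t, params, trace)
    return params, trace
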
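"""Expectation-truncation (ET) E-step for MCA and BSC.

Exact EM over binary latents needs all 2**H hidden states per patch.  ET
restricts each patch's posterior sums to a small candidate set K_n built
from the H' hidden units with the best selection scores, enumerating the
subsets of those units with at most gamma simultaneously active units, and
always keeping every singleton state so that no unit is starved of data.
With H' = H and gamma = H the truncated quantities reduce exactly to the
full posterior and log-likelihood.

The module offers two surfaces: per-patch objects (:class:`CandidateSet`,
:func:`truncated_expectations`) used for inspection and testing, and a
batched :func:`e_step` producing the sufficient statistics the M-steps in
:mod:`maxcauses.learning` consume.  Per-patch computations are independent
(the E-step is pure), and all enumeration orders are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .models import ModelParams, PatchSet, log_joint

__all__ = [
    "TruncationParams",
    "CandidateSet",
    "ScheduleState",
    "selection_scores",
    "build_candidates",
    "truncated_posterior",
    "truncated_expectations",
    "truncated_free_energy",
    "select_well_explained",
    "anneal_schedule",
    "EStats",
    "e_step",
    "candidate_count",
]

_CHUNK = 256  # patches per vectorized block; bounds peak memory


@dataclass(frozen=True)
class TruncationParams:
    """ET approximation constants: H' preselected units, gamma of them
    simultaneously active at most."""

    H_prime: int
    gamma: int

    def __post_init__(self) -> None:
        if not (1 <= self.gamma <= self.H_prime):
            raise ValueError("need 1 <= gamma <= H_prime")

    def validate(self, H: int) -> None:
        if self.H_prime > H:
            raise ValueError("H_prime may not exceed H")


@dataclass
class CandidateSet:
    """Per-patch truncation structure: selected units I_n, enumerated
    candidate states K_n, and cached log-joints."""

    unit_indices: np.ndarray  # (H',) sorted selected unit indices
    states: np.ndarray  # (K, H) binary
    log_joints: np.ndarray  # (K,)


@dataclass(frozen=True)
class ScheduleState:
    """Annealing state for one EM iteration: the retained-data fraction
    (1 = full dataset) and a deterministic-annealing temperature."""

    fraction: float
    temperature: float


def candidate_count(H: int, H_prime: int, gamma: int) -> int:
    """Closed-form |K_n|: subsets of I_n with <= gamma active plus the
    out-of-set singletons."""
    from math import comb

    return sum(comb(H_prime, g) for g in range(gamma + 1)) + (H - H_prime)


def state_templates(H_prime: int, gamma: int) -> np.ndarray:
    """All binary vectors of length H' with at most gamma ones, in
    size-major lexicographic order (zero state first)."""
    rows = []
    for g in range(gamma + 1):
        for idx in combinations(range(H_prime), g):
            z = np.zeros(H_prime, dtype=np.int8)
            z[list(idx)] = 1
            rows.append(z)
    return np.array(rows, dtype=np.int8)


def selection_scores(y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Normalized cross-correlation score per hidden unit.

    score_h = (W_h . y) / ||W_h|| ranks the evidence that unit h
    contributed to the patch; it is invariant to positive rescaling of the
    column.  Zero-norm columns score 0 (with a warning).
    """
    y = np.asarray(y, dtype=float)
    norms = np.linalg.norm(params.W, axis=0)
    if np.any(norms == 0):
        warnings.warn("zero-norm basis column(s); selection score set to 0")
    safe = np.where(norms > 0, norms, 1.0)
    return np.where(norms > 0, (params.W.T @ y) / safe, 0.0)


def _batch_scores(Y: np.ndarray, params: ModelParams) -> np.ndarray:
    norms = np.linalg.norm(params.W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return np.where(norms > 0, (Y @ params.W) / safe, 0.0)


def _top_units(scores: np.ndarray, H_prime: int) -> np.ndarray:
    """Indices of the H' largest scores per row, ties to the lower index;
    returned sorted ascending."""
    # stable sort on (-score, index): lexsort by index then -score
    order = np.argsort(-scores, axis=-1, kind="stable")
    return np.sort(order[..., :H_prime], axis=-1)


def build_candidates(
    y: np.ndarray, params: ModelParams, trunc: TruncationParams
) -> CandidateSet:
    """Assemble K_n for one patch: all subsets of the preselected units
    with <= gamma active, the all-zero state, and every singleton."""
    trunc.validate(params.H)
    scores = selection_scores(y, params)
    I_n = _top_units(scores, trunc.H_prime)
    Z = state_templates(trunc.H_prime, trunc.gamma)
    states = np.zeros((len(Z), params.H), dtype=np.int8)
    states[:, I_n] = Z
    outside = np.setdiff1d(np.arange(params.H), I_n)
    singles = np.zeros((len(outside), params.H), dtype=np.int8)
    singles[np.arange(len(outside)), outside] = 1
    states = np.concatenate([states, singles], axis=0)
    lj = np.array([log_joint(y, s, params) for s in states])
    return CandidateSet(unit_indices=I_n, states=states, log_joints=lj)


def truncated_posterior(cands: CandidateSet, temperature: float = 1.0) -> np.ndarray:
    """Posterior masses over K_n, normalized in log space."""
    lj = cands.log_joints / temperature
    m = np.max(lj)
    if not np.isfinite(m):
        warnings.warn("degenerate patch: all candidate log-joints -inf; "
                      "falling back to a uniform posterior")
        return np.full(len(lj), 1.0 / len(lj))
    w = np.exp(lj - m)
    return w / w.sum()


def truncated_expectations(cands: CandidateSet, g) -> np.ndarray:
    """<g(s)> under the truncated posterior:
    sum_{s in K_n} p(s, y) g(s) / sum_{s in K_n} p(s, y)."""
    w = truncated_posterior(cands)
    vals = np.array([np.asarray(g(s), dtype=float) for s in cands.states])
    return np.tensordot(w, vals, axes=(0, 0))


def _log_prior_terms(params: ModelParams) -> tuple[np.ndarray, float]:
    """log Bernoulli prior as a function of |s|, and the Gaussian constant."""
    H = params.H
    k = np.arange(H + 1)
    lp = k * np.log(params.pi) + (H - k) * np.log1p(-params.pi)
    const = -0.5 * params.D * np.log(2.0 * np.pi * params.sigma**2)
    return lp, const


@dataclass
class EStats:
    """Batched E-step output: per-patch truncated posteriors and the
    quantities the M-steps need.

    ``Pt`` holds posterior mass over the template states (subsets of the
    per-patch selected units ``I``), ``Pout`` over out-of-set singletons
    (zero elsewhere); ``r2t``/``R1`` cache the corresponding squared
    residuals under the current parameters.
    """

    I: np.ndarray  # (N, H') selected units, ascending
    Z: np.ndarray  # (K1, H') state templates
    Pt: np.ndarray  # (N, K1)
    Pout: np.ndarray  # (N, H)
    r2t: np.ndarray  # (N, K1)
    R1: np.ndarray  # (N, H) singleton residuals
    log_evidence: np.ndarray  # (N,) log sum_{K_n} p(s, y | Theta)

    @property
    def N(self) -> int:
        return self.Pt.shape[0]

    def expected_s(self) -> np.ndarray:
        """<s> per patch, shape (N, H)."""
        H = self.Pout.shape[1]
        out = self.Pout.copy()
        contrib = self.Pt @ self.Z.astype(float)  # (N, H')
        np.add.at(out, (np.arange(self.N)[:, None], self.I), contrib)
        return out

    def expected_abs_s(self) -> np.ndarray:
        """<|s|> per patch."""
        sizes = self.Z.sum(axis=1).astype(float)
        return self.Pt @ sizes + self.Pout.sum(axis=1)

    def expected_residual(self) -> np.ndarray:
        """<||y - W_bar(s)||^2> per patch under the truncated posterior."""
        return (self.Pt * self.r2t).sum(axis=1) + (self.Pout * self.R1).sum(axis=1)


def _template_means(
    Wg: np.ndarray, Zf: np.ndarray, model_kind: str
) -> np.ndarray:
    """Noiseless patches for every template state; Wg is (n, D, H')."""
    if model_kind == "BSC":
        return np.einsum("kh,ndh->nkd", Zf, Wg)
    # MCA: per pixel, signed value of the active column with max magnitude
    mag = np.abs(Wg)  # (n, D, H')
    masked = mag[:, None, :, :] * Zf[None, :, None, :]  # (n, K, D, H')
    win = np.argmax(masked, axis=-1)  # first max -> lowest index
    vals = np.take_along_axis(
        np.broadcast_to(Wg[:, None], masked.shape), win[..., None], axis=-1
    )[..., 0]
    hit = np.take_along_axis(masked, win[..., None], axis=-1)[..., 0] > 0
    return np.where(hit, vals, 0.0)


def e_step(
    Y: np.ndarray,
    params: ModelParams,
    trunc: TruncationParams,
    temperature: float = 1.0,
) -> EStats:
    """Vectorized truncated E-step over all patches.

    Computes, per patch, the selected units, the posterior over the
    candidate states and the truncated log-evidence
    ``log sum_{s in K_n} p(s, y | Theta)``.  Patch computations are
    independent; chunking only bounds memory.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    trunc.validate(params.H)
    N, D = Y.shape
    H, Hp = params.H, trunc.H_prime
    W = params.W
    Z = state_templates(Hp, trunc.gamma)
    Zf = Z.astype(float)
    sizes = Z.sum(axis=1)
    lp_k, const = _log_prior_terms(params)
    inv2s2 = 0.5 / params.sigma**2

    scores = _batch_scores(Y, params)
    I = _top_units(scores, Hp)

    # singleton residuals for every unit: ||y||^2 - 2 y.W_h + ||W_h||^2
    ynorm = np.einsum("nd,nd->n", Y, Y)
    R1 = ynorm[:, None] - 2.0 * (Y @ W) + np.einsum("dh,dh->h", W, W)[None, :]
    np.maximum(R1, 0.0, out=R1)
    lj1 = (lp_k[1] + const) - R1 * inv2s2

    Pt = np.empty((N, len(Z)))
    Pout = np.zeros((N, H))
    r2t = np.empty((N, len(Z)))
    logev = np.empty(N)
    out_mask = np.ones((N, H), dtype=bool)
    np.put_along_axis(out_mask, I, False, axis=1)

    for lo in range(0, N, _CHUNK):
        hi = min(lo + _CHUNK, N)
        Ic = I[lo:hi]
        Yc = Y[lo:hi]
        Wg = W[:, Ic].transpose(1, 0, 2)  # (n, D, H')
        means = _template_means(Wg, Zf, params.model_kind)  # (n, K, D)
        diff = Yc[:, None, :] - means
        r2 = np.einsum("nkd,nkd->nk", diff, diff)
        lj_t = (lp_k[sizes] + const)[None, :] - r2 * inv2s2

        ljo = np.where(out_mask[lo:hi], lj1[lo:hi], -np.inf)
        all_lj = np.concatenate([lj_t, ljo], axis=1) / temperature
        m = np.max(all_lj, axis=1, keepdims=True)
        wts = np.exp(all_lj - m)
        tot = wts.sum(axis=1, keepdims=True)
        wts /= tot
        # log-evidence on the untempered scale
        logev[lo:hi] = logsumexp(np.concatenate([lj_t, ljo], axis=1), axis=1)
        Pt[lo:hi] = wts[:, : len(Z)]
        Pout[lo:hi] = np.where(out_mask[lo:hi], wts[:, len(Z):], 0.0)
        r2t[lo:hi] = r2

    return EStats(I=I, Z=Z, Pt=Pt, Pout=Pout, r2t=r2t, R1=R1, log_evidence=logev)


def truncated_free_energy(
    dataset: PatchSet | np.ndarray,
    params: ModelParams,
    trunc: TruncationParams,
    M: np.ndarray | None = None,
) -> float:
    """Truncated free energy
    F = sum_{n in M} log sum_{K_n} p(s, y_n | Theta) - |M| log B(pi),
    with B(pi) = P(|s| <= gamma) under the Bernoulli prior.

    Reduces exactly to the log-likelihood when H' = H, gamma = H and M is
    the full dataset (B = 1, K_n the full state space).
    """
    from .learning import sparsity_terms

    Y = dataset.Y if isinstance(dataset, PatchSet) else np.atleast_2d(dataset)
    stats = e_step(Y, params, trunc)
    if M is None:
        M = np.arange(Y.shape[0])
    M = np.asarray(M, dtype=int)
    if M.size == 0:
        raise ValueError("M must be non-empty")
    terms = sparsity_terms(params.pi, params.H, trunc.gamma)
    return float(stats.log_evidence[M].sum() - M.size * np.log(terms.B_pi))


def select_well_explained(
    dataset: PatchSet | np.ndarray,
    params: ModelParams,
    trunc: TruncationParams,
    fraction: float = 1.0,
    stats: EStats | None = None,
) -> np.ndarray:
    """Indices of the |M| = round(N * f) patches with the largest truncated
    evidence, where f interpolates between 1 (full data) and B(pi), the
    expected fraction of patches with at most gamma active causes.

    ``fraction`` is the annealing retained-data fraction in [B(pi), 1]
    produced by :func:`anneal_schedule`; ties break to the lower patch
    index.
    """
    from .learning import sparsity_terms

    Y = dataset.Y if isinstance(dataset, PatchSet) else np.atleast_2d(dataset)
    if stats is None:
        stats = e_step(Y, params, trunc)
    N = Y.shape[0]
    B = sparsity_terms(params.pi, params.H, trunc.gamma).B_pi
    # fraction interpolates toward the ET cut: 0 keeps all, 1 keeps round(N*B)
    target = (1.0 - _clip01(fraction)) + _clip01(fraction) * B
    size = max(1, int(round(N * target)))
    order = np.argsort(-stats.log_evidence, kind="stable")
    return np.sort(order[:size])


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, float(x)))


def anneal_schedule(
    iteration: int,
    total_iters: int,
    start_temperature: float = 1.0,
) -> ScheduleState:
    """Thirds-based data-cut schedule.

    The first third of EM iterations runs on the full dataset; over the
    middle third the retained fraction is linearly decreased toward the ET
    value N*B(pi) (expressed here as an interpolation weight: ``fraction``
    0 keeps everything, 1 applies the full cut); the final third holds the
    ET cut.  An optional deterministic-annealing temperature decays
    linearly from ``start_temperature`` to 1 over the first two thirds
    (default 1 = off).
    """
    if not (1 <= iteration <= total_iters):
        raise ValueError("iteration out of range")
    t1 = total_iters // 3
    t2 = (2 * total_iters) // 3
    if iteration <= t1:
        alpha = 0.0
    elif iteration <= t2:
        alpha = (iteration - t1) / float(t2 - t1)
    else:
        alpha = 1.0
    if start_temperature <= 1.0:
        T = 1.0
    else:
        beta = min(1.0, (iteration - 1) / max(1.0, float(t2 - 1)))
        T = start_temperature + beta * (1.0 - start_temperature)
    return ScheduleState(fraction=alpha, temperature=T)
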
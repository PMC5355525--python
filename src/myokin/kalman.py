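"""Information-form discrete Kalman filtering of the latent coefficients.

The latent dimension D (state) is much smaller than the 152-dimensional
augmented feature measurement, so the update is run in information form:

    C(t|t)   = ( C^-1(t|t-1) + H^T C_v^-1 H )^-1
    xhat(t|t) = C(t|t) ( C^-1(t|t-1) xhat(t|t-1) + H^T C_v^-1 gbar(t) )

with H = Y_g (first order) or [0  Y_g] (second order).  This inverts only
state-sized matrices per frame once H^T C_v^-1 H and C_v^-1 H are cached,
and is algebraically identical to the textbook gain-form update.

The filter runs entirely in normalised measurement space; decoding through
the measurement model un-normalises to marker positions in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .measurement import MeasurementModel, N_AUG, augment
from .statespace import StateSpaceModel

# relative diagonal jitter for symmetric solves; small enough that the
# information form stays within 1e-8 of the exact gain-form algebra even
# for moderately ill-conditioned priors, large enough to keep long filter
# runs positive definite
_JITTER = 1e-12


@dataclass
class KalmanState:
    """Filter state: mean, covariance and frame index."""

    x_hat: np.ndarray
    C: np.ndarray
    t: int = 0


def _sym(C: np.ndarray) -> np.ndarray:
    return (C + C.T) / 2.0


def _solve_spd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric positive (semi-)definite A with jitter."""
    A = _sym(A)
    jit = _JITTER * abs(float(np.mean(np.diag(A))))
    A = A + jit * np.eye(A.shape[0])
    try:
        c, low = linalg.cho_factor(A, check_finite=False)
        return linalg.cho_solve((c, low), B, check_finite=False)
    except np.linalg.LinAlgError:
        return np.linalg.solve(A, B)


def predict(state: KalmanState, model: StateSpaceModel) -> KalmanState:
    """Time update: xhat(t|t-1) = F xhat, C(t|t-1) = F C F^T + C_w."""
    F = model.F
    if F.shape[0] != state.x_hat.shape[0]:
        raise ValueError(
            f"state dimension {state.x_hat.shape[0]} does not match F ({F.shape[0]})"
        )
    x = F @ state.x_hat
    C = _sym(F @ state.C @ F.T + model.C_w)
    return KalmanState(x_hat=x, C=C, t=state.t + 1)


def update(
    state_pred: KalmanState,
    g_norm: np.ndarray,
    H: np.ndarray,
    C_v: np.ndarray,
    *,
    HtCinvH: np.ndarray | None = None,
    CinvH: np.ndarray | None = None,
) -> KalmanState:
    """Information-form measurement update.

    ``HtCinvH`` and ``CinvH`` (= C_v^-1 H) may be supplied precomputed when
    filtering a long trajectory with a constant measurement model.
    """
    if CinvH is None:
        CinvH = _solve_spd(C_v, H)
    if HtCinvH is None:
        HtCinvH = _sym(H.T @ CinvH)
    n = state_pred.x_hat.shape[0]
    prior_info = _solve_spd(state_pred.C, np.eye(n))
    post_info = _sym(prior_info + HtCinvH)
    C_post = _sym(_solve_spd(post_info, np.eye(n)))
    rhs = prior_info @ state_pred.x_hat + CinvH.T @ g_norm
    x_post = C_post @ rhs
    return KalmanState(x_hat=x_post, C=C_post, t=state_pred.t)


def _initial_state(mm: MeasurementModel, ssm: StateSpaceModel) -> KalmanState:
    """Stationary prior: zero mean, training latent covariance C_b.

    For the second-order model the D-dimensional C_b is duplicated
    block-diagonally over [b(t-1); b(t)].
    """
    Cb = np.diag(mm.C_b)
    if ssm.order == 2:
        C0 = linalg.block_diag(Cb, Cb)
    else:
        C0 = Cb
    if ssm.order == "static":
        # diffuse prior consistent with near-infinite process noise
        from .statespace import STATIC_NOISE_STD_FACTOR

        C0 = C0 * STATIC_NOISE_STD_FACTOR**2
    return KalmanState(x_hat=np.zeros(C0.shape[0]), C=C0, t=0)


def _measurement_matrix(mm: MeasurementModel, ssm: StateSpaceModel) -> np.ndarray:
    Yg = mm.Y_g
    if ssm.order == 2:
        return np.concatenate([np.zeros_like(Yg), Yg], axis=1)
    return Yg


def filter_trajectory(
    mm: MeasurementModel,
    ssm: StateSpaceModel,
    features: np.ndarray,
    boundaries=None,
):
    """Filter a feature series and decode 3D marker positions.

    Parameters
    ----------
    mm, ssm
        Fitted measurement and state-space models (dimensions must agree).
    features : ndarray (n, 16) or (n, 152)
        Raw or already-augmented feature vectors; normalisation with the
        training statistics is applied internally.
    boundaries : sequence of int, optional
        Frame indices starting new concatenated segments; the filter state
        is re-initialised at each.

    Returns
    -------
    B_hat : ndarray (n, D)
        Filtered latent coefficients (lower block for order 2).
    X_hat : ndarray (n, 30)
        Decoded marker positions in mm.
    """
    G = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(G)):
        frame = int(np.flatnonzero(~np.isfinite(G).all(axis=1))[0])
        raise ValueError(f"non-finite feature value at frame {frame}")
    if G.shape[1] != N_AUG:
        G = augment(G)
    if G.shape[1] != N_AUG:
        raise ValueError(f"features must have 16 or {N_AUG} columns")
    if mm.D != ssm.D:
        raise ValueError(f"model dimensions differ: PCA D={mm.D}, dynamics D={ssm.D}")
    Gn = mm.normalize_features(G)

    H = _measurement_matrix(mm, ssm)
    CinvH = _solve_spd(mm.C_v, H)
    HtCinvH = _sym(H.T @ CinvH)
    info_obs = Gn @ CinvH  # per-frame H^T C_v^-1 g, one row per frame

    n = G.shape[0]
    D = mm.D
    bounds = set(boundaries or [])
    B_hat = np.empty((n, D))
    state = _initial_state(mm, ssm)
    for t in range(n):
        if t == 0 or t in bounds:
            state = _initial_state(mm, ssm)
        else:
            state = predict(state, ssm)
        state = _update_fast(state, info_obs[t], HtCinvH)
        B_hat[t] = state.x_hat[-D:]
    X_hat = mm.decode_positions(B_hat)
    return B_hat, X_hat


def _update_fast(
    state_pred: KalmanState, info_vec: np.ndarray, HtCinvH: np.ndarray
) -> KalmanState:
    """Information update with the measurement products precomputed."""
    n = state_pred.x_hat.shape[0]
    prior_info = _solve_spd(state_pred.C, np.eye(n))
    post_info = _sym(prior_info + HtCinvH)
    C_post = _sym(_solve_spd(post_info, np.eye(n)))
    x_post = C_post @ (prior_info @ state_pred.x_hat + info_vec)
    return KalmanState(x_hat=x_post, C=C_post, t=state_pred.t)


def static_estimate(mm: MeasurementModel, g_norm: np.ndarray) -> np.ndarray:
    """Measurement-only generalized-least-squares estimate of b.

    bhat = (Y_g^T C_v^-1 Y_g)^-1 Y_g^T C_v^-1 g_norm, for a single
    normalised augmented feature vector or a stack of them.
    """
    Yg = mm.Y_g
    CinvH = _solve_spd(mm.C_v, Yg)
    A = _sym(Yg.T @ CinvH)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular normal matrix in static estimate; increase c_v"
        )
    g_norm = np.asarray(g_norm, dtype=float)
    rhs = g_norm @ CinvH
    return np.linalg.solve(A, rhs.T).T
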
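"""Latent coefficient dynamics: first-order and decoupled AR(2) models.

First order:  b(t+1) = F b(t) + w(t), with F estimated by the lag-1
least-squares moment estimator and C_w from the residuals.  Second order:
the state is x(t) = [b(t-1); b(t)] with block transition

    F = [ 0        I      ]
        [ diag(beta) diag(alpha) ]

i.e. D decoupled AR(2) models b_n(t+1) = alpha_n b_n(t) + beta_n b_n(t-1)
+ w_n(t); process noise enters only the lower block (covariance C_22).

Each AR(2) model corresponds to a continuous-time second-order system with
natural frequency f_n = sqrt(1 - alpha - beta) / (2 pi T) and relative
damping zeta_n = (-alpha - 2) / (2 sqrt(1 - alpha - beta)).  (Note the sign
convention: zeta comes out negative for typical stable poles; the exact
algebraic inverse keeps the round trip consistent, and the c_d correction
scales whatever sign results.)  Tuning corrections: c_v regularises the
measurement-noise covariance (see measurement.regularize_cv), c_w shrinks
C_22 toward a smoothed diagonal, and c_f, c_d scale the natural frequencies
and dampings before converting back to AR coefficients.

A "static" model is obtained by inflating the process-noise standard
deviation by 1e6, which makes the Kalman filter rely on measurements only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

STATIC_NOISE_STD_FACTOR = 1e6


@dataclass(frozen=True)
class DesignParams:
    """Tunable design parameters of the estimator.

    D is the PCA dimension; c_v and c_w in [0, 1] regularise the measurement
    and process noise covariances; c_f and c_d (> 0, second order only)
    scale natural frequencies and dampings.  Defaults are the average optima
    of the reference study (D=20, c_v=0.1, c_w=0.2, c_f=3.4, c_d=0.7).
    """

    D: int = 20
    c_v: float = 0.1
    c_w: float = 0.2
    c_f: float = 3.4
    c_d: float = 0.7

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if not 0.0 <= self.c_v <= 1.0:
            raise ValueError("c_v must lie in [0, 1]")
        if not 0.0 <= self.c_w <= 1.0:
            raise ValueError("c_w must lie in [0, 1]")
        if self.c_f <= 0 or self.c_d <= 0:
            raise ValueError("c_f and c_d must be positive")


@dataclass
class StateSpaceModel:
    """Fitted latent dynamics.

    ``order`` is "static", 1 or 2.  For order 1 (and static) ``F`` is D x D
    and ``C_w`` D x D.  For order 2 ``alpha`` and ``beta`` hold the AR
    coefficients and ``C_22`` the (diagonal) process-noise covariance of the
    driven block; ``F`` and ``C_w`` expand them to the 2D x 2D block forms.
    """

    order: str | int
    D: int
    T: float = 0.01
    F1: np.ndarray | None = None  # order 1 / static: D x D transition
    Cw1: np.ndarray | None = None  # order 1 / static: D x D process noise
    alpha: np.ndarray | None = None  # order 2: D AR lag-1 coefficients
    beta: np.ndarray | None = None  # order 2: D AR lag-2 coefficients
    C_22: np.ndarray | None = None  # order 2: D x D process noise (lower block)
    design: DesignParams | None = None

    def __post_init__(self) -> None:
        if self.order not in ("static", 1, 2):
            raise ValueError(f"order must be 'static', 1 or 2, got {self.order!r}")
        if self.T <= 0:
            raise ValueError("sampling period must be positive")

    @property
    def state_dim(self) -> int:
        return 2 * self.D if self.order == 2 else self.D

    @property
    def F(self) -> np.ndarray:
        """Full transition matrix (block form for order 2)."""
        if self.order == 2:
            D = self.D
            F = np.zeros((2 * D, 2 * D))
            F[:D, D:] = np.eye(D)
            F[D:, :D] = np.diag(self.beta)
            F[D:, D:] = np.diag(self.alpha)
            return F
        return self.F1

    @property
    def C_w(self) -> np.ndarray:
        """Full process-noise covariance (zero upper block for order 2)."""
        if self.order == 2:
            D = self.D
            Cw = np.zeros((2 * D, 2 * D))
            Cw[D:, D:] = self.C_22
            return Cw
        return self.Cw1

    def to_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {
            "order": np.asarray(0 if self.order == "static" else self.order),
            "D": np.asarray(self.D),
            "T": np.asarray(self.T),
        }
        if self.order == 2:
            arrays.update(alpha=self.alpha, beta=self.beta, C_22=self.C_22)
        else:
            arrays.update(F1=self.F1, Cw1=self.Cw1)
        if self.design is not None:
            d = self.design
            arrays["design"] = np.asarray([d.D, d.c_v, d.c_w, d.c_f, d.c_d])
        return arrays

    @classmethod
    def from_arrays(cls, arrays) -> "StateSpaceModel":
        order_code = int(arrays["order"])
        order: str | int = "static" if order_code == 0 else order_code
        design = None
        if "design" in arrays:
            d = np.asarray(arrays["design"])
            design = DesignParams(int(d[0]), float(d[1]), float(d[2]), float(d[3]), float(d[4]))
        kwargs = dict(
            order=order, D=int(arrays["D"]), T=float(arrays["T"]), design=design
        )
        if order == 2:
            kwargs.update(
                alpha=arrays["alpha"], beta=arrays["beta"], C_22=arrays["C_22"]
            )
        else:
            kwargs.update(F1=arrays["F1"], Cw1=arrays["Cw1"])
        return cls(**kwargs)


def _transition_pairs(n: int, boundaries) -> np.ndarray:
    """Indices t such that (t, t+1) lies within one segment."""
    bounds = set(boundaries or [])
    t = np.arange(n - 1)
    # a boundary index marks the start of a new segment: pair (b-1, b) is invalid
    mask = np.array([tt + 1 not in bounds for tt in t])
    return t[mask]


def fit_first_order(
    B: np.ndarray,
    boundaries=None,
    T: float = 0.01,
    diagonalize: bool = True,
) -> StateSpaceModel:
    """Least-squares fit of b(t+1) = F b(t) + w(t).

    F_hat = mean[b(t+1) b(t)^T] (mean[b(t) b(t)^T])^-1 over all transition
    pairs not spanning a segment boundary; C_w is the sample covariance of
    the residuals.  With ``diagonalize`` both are reduced to their diagonals
    (empirically F and C_w are diagonal because the PCA decorrelates b).
    """
    B = np.asarray(B, dtype=float)
    n, D = B.shape
    t = _transition_pairs(n, boundaries)
    if t.size < D + 2:
        raise ValueError(
            f"need at least D+2={D + 2} transition pairs, got {t.size}"
        )
    B0, B1 = B[t], B[t + 1]
    M1 = B1.T @ B0 / t.size
    M0 = B0.T @ B0 / t.size
    cond = np.linalg.cond(M0)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "singular latent Gram matrix; reduce the PCA dimension D"
        )
    F = M1 @ np.linalg.inv(M0)
    W = B1 - B0 @ F.T
    Cw = np.cov(W, rowvar=False, bias=False)
    Cw = np.atleast_2d(Cw)
    if diagonalize:
        F = np.diag(np.diag(F))
        Cw = np.diag(np.diag(Cw))
    return StateSpaceModel(order=1, D=D, T=T, F1=F, Cw1=(Cw + Cw.T) / 2)


def fit_second_order(
    B: np.ndarray, boundaries=None, T: float = 0.01
) -> StateSpaceModel:
    """Per-coefficient least-squares AR(2) fit.

    For each latent coefficient n, regress b_n(t+1) on [b_n(t), b_n(t-1)]
    over triples lying within one segment; C_22 is the diagonal matrix of
    residual variances.
    """
    B = np.asarray(B, dtype=float)
    n, D = B.shape
    bounds = set(boundaries or [])
    t = np.array(
        [tt for tt in range(1, n - 1) if tt not in bounds and tt + 1 not in bounds]
    )
    if t.size < 3:
        raise ValueError("need at least 3 in-segment AR(2) triples")
    alpha = np.empty(D)
    beta = np.empty(D)
    resid_var = np.empty(D)
    for nn in range(D):
        A = np.column_stack([B[t, nn], B[t - 1, nn]])
        y = B[t + 1, nn]
        gram = A.T @ A
        if np.linalg.cond(gram) > 1e12:
            raise np.linalg.LinAlgError(
                f"degenerate AR(2) regressors for coefficient {nn}"
            )
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        alpha[nn], beta[nn] = coef
        r = y - A @ coef
        resid_var[nn] = r.var(ddof=2) if t.size > 2 else r.var()
    return StateSpaceModel(
        order=2, D=D, T=T, alpha=alpha, beta=beta, C_22=np.diag(resid_var)
    )


def ar_to_physical(alpha, beta, T: float):
    """Natural frequency (Hz) and relative damping of an AR(2) model.

    f = sqrt(1 - alpha - beta) / (2 pi T);
    zeta = (-alpha - 2) / (2 sqrt(1 - alpha - beta)).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    s = 1.0 - alpha - beta
    if np.any(s < 0):
        raise ValueError(
            "1 - alpha - beta < 0: complex natural frequency (unstable AR pair)"
        )
    root = np.sqrt(s)
    f = root / (2.0 * np.pi * T)
    with np.errstate(divide="ignore", invalid="ignore"):
        zeta = np.where(root > 0, (-alpha - 2.0) / (2.0 * root), 0.0)
    if alpha.ndim == 0:
        return float(f), float(zeta)
    return f, zeta


def physical_to_ar(f, zeta, T: float):
    """Exact algebraic inverse of :func:`ar_to_physical`.

    s = (2 pi T f)^2; alpha = -2 - 2 zeta sqrt(s); beta = 1 - alpha - s.
    """
    f = np.asarray(f, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    if np.any(f < 0):
        raise ValueError("natural frequency must be non-negative")
    s = (2.0 * np.pi * T * f) ** 2
    alpha = -2.0 - 2.0 * zeta * np.sqrt(s)
    beta = 1.0 - alpha - s
    if f.ndim == 0:
        return float(alpha), float(beta)
    return alpha, beta


def smoothed_diagonal(C: np.ndarray, width: int = 3) -> np.ndarray:
    """Centred moving average of the diagonal over component index.

    Edges average the available neighbours only; width 1 is the identity.
    """
    d = np.diag(np.asarray(C, dtype=float))
    if width <= 1 or d.size == 1:
        return d.copy()
    half = width // 2
    out = np.empty_like(d)
    for k in range(d.size):
        lo, hi = max(0, k - half), min(d.size, k + half + 1)
        out[k] = d[lo:hi].mean()
    return out


def apply_corrections(
    model: StateSpaceModel, design: DesignParams, smooth_width: int = 3
) -> StateSpaceModel:
    """Apply the c_w (and, for order 2, c_f/c_d) tuning corrections.

    Order 2: each (alpha_n, beta_n) is converted to (f_n, zeta_n), scaled to
    (c_f f_n, c_d zeta_n) and converted back; C_22 is replaced by
    (1 - c_w) C_22 + c_w diag(smoothed diagonal).  Order 1 / static: only the
    process-noise shrinkage applies, with the same convex form.
    """
    if model.order == 2:
        f, zeta = ar_to_physical(model.alpha, model.beta, model.T)
        alpha, beta = physical_to_ar(design.c_f * f, design.c_d * zeta, model.T)
        if np.any(1.0 - alpha - beta < 0):
            bad = np.where(1.0 - alpha - beta < 0)[0].tolist()
            raise ValueError(f"corrected frequency invalid for components {bad}")
        sm = np.diag(smoothed_diagonal(model.C_22, smooth_width))
        C22 = (1.0 - design.c_w) * model.C_22 + design.c_w * sm
        return replace(model, alpha=alpha, beta=beta, C_22=C22, design=design)
    sm = np.diag(smoothed_diagonal(model.Cw1, smooth_width))
    Cw = (1.0 - design.c_w) * model.Cw1 + design.c_w * sm
    return replace(model, Cw1=Cw, design=design)


def make_static(model: StateSpaceModel) -> StateSpaceModel:
    """Inflate the process-noise standard deviation by 1e6.

    Downstream Kalman filtering then depends on the measurements only (the
    prediction carries essentially no information), which implements
    measurement-only "static" estimation within the same filter.  The
    returned model has order "static" and a D-dimensional state regardless
    of the input order; the filter also uses a correspondingly diffuse
    initial prior.
    """
    factor = STATIC_NOISE_STD_FACTOR**2
    if model.order == 2:
        return StateSpaceModel(
            order="static",
            D=model.D,
            T=model.T,
            F1=np.eye(model.D),
            Cw1=model.C_22 * factor,
            design=model.design,
        )
    return replace(model, order="static", Cw1=model.Cw1 * factor)
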
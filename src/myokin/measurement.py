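"""Pseudo-linear PCA measurement model.

The mapping from sEMG features to lip-marker positions is nonlinear.  A
second-order truncated Taylor expansion linearises it: each 16-vector of
windowed features g is augmented with all 136 quadratic and cross terms
g_i*g_j (i <= j), giving a 152-vector gbar.  Marker positions X (30) and
augmented features (152) are concatenated into z (182), normalised
elementwise (training mean/std), and a PCA yields orthonormal loadings
Y (182 x D).  Coefficients b = Y^T z_norm then obey the pseudo-linear
measurement model

    gbar_norm = Y_g b + v,

where Y_g holds the last 152 rows of Y and v is residual measurement noise
with covariance C_v, estimated from the training residuals.  Decoding the
first 30 rows (Y_x) and un-normalising recovers marker positions in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import N_COORDS

N_FEAT = 16
N_QUAD = N_FEAT * (N_FEAT + 1) // 2  # 136
N_AUG = N_FEAT + N_QUAD  # 152
N_Z = N_COORDS + N_AUG  # 182

# fixed lexicographic (i <= j) ordering of the quadratic monomials
_QUAD_I, _QUAD_J = np.triu_indices(N_FEAT)


def augment(g: np.ndarray) -> np.ndarray:
    """Append all second-order monomials g_i*g_j (i <= j) in fixed order.

    Accepts a single feature vector or an (n, p) matrix; an n-channel input
    yields n + n(n+1)/2 terms (152 for the 16-channel case).
    """
    g = np.asarray(g, dtype=float)
    single = g.ndim == 1
    G = np.atleast_2d(g)
    p = G.shape[1]
    ii, jj = np.triu_indices(p)
    out = np.concatenate([G, G[:, ii] * G[:, jj]], axis=1)
    return out[0] if single else out


@dataclass
class Normalizer:
    """Elementwise standardisation with training-set statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, Z: np.ndarray, std_floor: float = 1e-12) -> "Normalizer":
        mean = Z.mean(axis=0)
        std = Z.std(axis=0)
        n_floored = int(np.sum(std < std_floor))
        if n_floored:
            import logging

            logging.getLogger(__name__).info(
                "normalizer: %d zero-variance element(s) floored at %g",
                n_floored,
                std_floor,
            )
        std = np.maximum(std, std_floor)
        return cls(mean=mean, std=std)

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return (Z - self.mean) / self.std

    def inverse(self, Zn: np.ndarray) -> np.ndarray:
        return Zn * self.std + self.mean


@dataclass
class MeasurementModel:
    """Fitted joint-PCA measurement model.

    Attributes
    ----------
    Y : ndarray (182, D)
        Orthonormal principal loadings of the normalised z vectors.
    C_b : ndarray (D,)
        Training variances of the coefficients b (descending).
    C_v : ndarray (152, 152)
        Covariance of the feature-block reconstruction residuals, after
        any ``c_v`` regularisation.
    normalizer : Normalizer
        Elementwise mean/std of z on the training set.
    """

    Y: np.ndarray
    C_b: np.ndarray
    C_v: np.ndarray
    normalizer: Normalizer
    c_v: float = 0.0

    def __post_init__(self) -> None:
        if self.Y.shape[0] != N_Z:
            raise ValueError(f"Y must have {N_Z} rows, got {self.Y.shape[0]}")
        if self.C_v.shape != (N_AUG, N_AUG):
            raise ValueError(f"C_v must be {N_AUG}x{N_AUG}")

    @property
    def D(self) -> int:
        return self.Y.shape[1]

    @property
    def Y_x(self) -> np.ndarray:
        """Rows of Y corresponding to the 30 marker coordinates."""
        return self.Y[:N_COORDS]

    @property
    def Y_g(self) -> np.ndarray:
        """Rows of Y corresponding to the 152 augmented features."""
        return self.Y[N_COORDS:]

    # -- encode / decode ---------------------------------------------------

    def encode(self, z: np.ndarray) -> np.ndarray:
        """b = Y^T z_norm for one z vector or a stack of them."""
        z = np.asarray(z, dtype=float)
        if z.shape[-1] != N_Z:
            raise ValueError(f"z must have {N_Z} elements, got {z.shape[-1]}")
        return self.normalizer.transform(z) @ self.Y

    def decode(self, b: np.ndarray) -> np.ndarray:
        """Un-normalised reconstruction zhat = denorm(Y b)."""
        b = np.asarray(b, dtype=float)
        if b.shape[-1] != self.D:
            raise ValueError(f"b must have {self.D} elements, got {b.shape[-1]}")
        return self.normalizer.inverse(b @ self.Y.T)

    def decode_positions(self, b: np.ndarray) -> np.ndarray:
        """Marker positions (mm) decoded from coefficients."""
        b = np.asarray(b, dtype=float)
        if b.shape[-1] != self.D:
            raise ValueError(f"b must have {self.D} elements, got {b.shape[-1]}")
        zx = b @ self.Y_x.T
        return (
            zx * self.normalizer.std[:N_COORDS] + self.normalizer.mean[:N_COORDS]
        )

    def normalize_features(self, G_aug: np.ndarray) -> np.ndarray:
        """Normalise augmented features with the training feature statistics."""
        return (G_aug - self.normalizer.mean[N_COORDS:]) / self.normalizer.std[
            N_COORDS:
        ]

    def to_arrays(self) -> dict[str, np.ndarray]:
        return {
            "Y": self.Y,
            "C_b": self.C_b,
            "C_v": self.C_v,
            "norm_mean": self.normalizer.mean,
            "norm_std": self.normalizer.std,
            "c_v": np.asarray(self.c_v),
        }

    @classmethod
    def from_arrays(cls, arrays) -> "MeasurementModel":
        return cls(
            Y=arrays["Y"],
            C_b=arrays["C_b"],
            C_v=arrays["C_v"],
            normalizer=Normalizer(mean=arrays["norm_mean"], std=arrays["norm_std"]),
            c_v=float(arrays["c_v"]),
        )


def fit_pca(X_train: np.ndarray, G_train: np.ndarray, D: int) -> MeasurementModel:
    """Fit the joint-PCA measurement model.

    Parameters
    ----------
    X_train : ndarray (J, 30)
        Marker positions in mm.
    G_train : ndarray (J, 152)
        Augmented feature vectors (use :func:`augment` on 16-channel
        features first).
    D : int
        Number of principal components retained.

    Notes
    -----
    The PCA is computed by SVD of the centred, scaled data matrix;
    component signs are fixed so each column's largest-magnitude loading
    is positive, making the fit deterministic across platforms.  C_v is
    the sample covariance of the feature-block residuals
    v = gbar_norm - Y_g Y^T z_norm over the training set.
    """
    X_train = np.asarray(X_train, dtype=float)
    G_train = np.asarray(G_train, dtype=float)
    if X_train.shape[1] != N_COORDS or G_train.shape[1] != N_AUG:
        raise ValueError(
            f"expected ({N_COORDS}, {N_AUG}) columns, got "
            f"({X_train.shape[1]}, {G_train.shape[1]})"
        )
    J = X_train.shape[0]
    if not 1 <= D <= N_Z:
        raise ValueError(f"D must be in [1, {N_Z}]")
    if J <= D:
        raise ValueError(f"need more than D={D} training samples, got {J}")

    Z = np.concatenate([X_train, G_train], axis=1)
    norm = Normalizer.fit(Z)
    Zn = norm.transform(Z)

    # principal directions of the normalised data
    _, s, Vt = np.linalg.svd(Zn - Zn.mean(axis=0), full_matrices=False)
    Y = Vt[:D].T
    # deterministic sign convention
    flip = np.sign(Y[np.argmax(np.abs(Y), axis=0), np.arange(D)])
    flip[flip == 0] = 1.0
    Y = Y * flip

    B = Zn @ Y
    C_b = B.var(axis=0)

    resid = Zn[:, N_COORDS:] - B @ Y[N_COORDS:].T
    C_v = np.cov(resid, rowvar=False, bias=False)
    C_v = (C_v + C_v.T) / 2.0

    return MeasurementModel(Y=Y, C_b=C_b, C_v=C_v, normalizer=norm)


def regularize_cv(C_v: np.ndarray, c_v: float) -> np.ndarray:
    """Shrink C_v towards a scaled identity: (1-c_v) C_v + c_v mean(diag) I.

    A convex combination that preserves the trace; ``c_v = 0`` leaves C_v
    unchanged and ``c_v = 1`` replaces it by the average-variance identity.
    """
    if not 0.0 <= c_v <= 1.0:
        raise ValueError(f"c_v must lie in [0, 1], got {c_v}")
    C_v = np.asarray(C_v, dtype=float)
    mean_diag = float(np.mean(np.diag(C_v)))
    return (1.0 - c_v) * C_v + c_v * mean_diag * np.eye(C_v.shape[0])
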
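"""Training/testing protocol: pooling, cross-validation, tuning, comparison.

Trials are pooled by concatenation (instructions 1..19 within each
repetition, repetitions ascending) with segment boundaries recorded so that
dynamics fits never learn the artificial jumps at concatenation seams.
Evaluation rotates the repetitions: each fold trains the measurement and
state-space models on all repetitions but one and filters the held-out one.
The criterion is the RMS of the error over all 30 marker coordinates and
all test frames, averaged over folds.

Design parameters (D, c_v, c_w and, for second order, c_f, c_d) are tuned
by cyclic coordinate descent with successive parabolic interpolation on the
cross-validated RMS.  Static and dynamic variants are compared with the
exact one-sided paired Wilcoxon signed-rank test (the static model is a
special case of the dynamic one, so a one-sided alternative is justified).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .datatypes import FeatureTrialSet
from .kalman import filter_trajectory
from .measurement import N_AUG, augment, fit_pca, regularize_cv
from .statespace import (
    DesignParams,
    apply_corrections,
    fit_first_order,
    fit_second_order,
    make_static,
)


@dataclass
class CvResult:
    """Cross-validation outcome: per-fold and aggregate RMS errors in mm."""

    per_fold_rms: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def mean_rms(self) -> float:
        return float(np.mean(self.per_fold_rms))

    @property
    def sd_rms(self) -> float:
        return float(np.std(self.per_fold_rms, ddof=1)) if len(self.per_fold_rms) > 1 else 0.0


def pool_trials(fts: FeatureTrialSet, repetitions):
    """Concatenate trials of the given repetitions.

    Returns ``(G, X, boundaries)`` where ``boundaries`` lists the start
    indices of every segment after the first (strictly increasing).
    Instructions are ordered ascending within each repetition, repetitions
    ascending.
    """
    repetitions = sorted(repetitions)
    instructions = fts.instructions
    G_parts, X_parts, boundaries = [], [], []
    offset = 0
    for r in repetitions:
        for i in instructions:
            if (i, r) not in fts.features:
                raise KeyError(f"trial (instruction={i}, repetition={r}) missing")
            g = fts.features[(i, r)]
            if offset > 0:
                boundaries.append(offset)
            G_parts.append(g)
            X_parts.append(fts.markers[(i, r)])
            offset += g.shape[0]
    return np.concatenate(G_parts), np.concatenate(X_parts), boundaries


def rms_error(X_hat: np.ndarray, X_true: np.ndarray, distance: bool = False) -> float:
    """RMS of the estimation error in mm.

    By default the RMS runs over all frames and all 30 coordinates.  With
    ``distance=True`` it is instead the RMS of the per-marker Euclidean
    distances (10 per frame).
    """
    X_hat = np.asarray(X_hat, dtype=float)
    X_true = np.asarray(X_true, dtype=float)
    if X_hat.shape != X_true.shape:
        raise ValueError(f"shape mismatch: {X_hat.shape} vs {X_true.shape}")
    err = X_hat - X_true
    if distance:
        d2 = err.reshape(err.shape[0], -1, 3) ** 2
        return float(np.sqrt(np.mean(d2.sum(axis=2))))
    return float(np.sqrt(np.mean(err**2)))


def fit_pipeline(
    G: np.ndarray,
    X: np.ndarray,
    boundaries,
    order,
    design: DesignParams,
    T: float = 0.01,
    diagonalize: bool = True,
    smooth_width: int = 3,
):
    """Fit measurement model + latent dynamics on pooled training data.

    ``G`` may hold 16-channel features (augmented internally) or
    already-augmented 152-column vectors.  Returns the fitted
    ``(MeasurementModel, StateSpaceModel)`` with all design corrections
    applied; ``order`` is "static", 1 or 2.
    """
    G = np.asarray(G, dtype=float)
    if G.shape[1] != N_AUG:
        G = augment(G)
    mm = fit_pca(X, G, design.D)
    mm = replace(mm, C_v=regularize_cv(mm.C_v, design.c_v), c_v=design.c_v)
    Z = np.concatenate([X, G], axis=1)
    B = mm.encode(Z)
    if order == 2:
        ssm = fit_second_order(B, boundaries, T=T)
    else:
        ssm = fit_first_order(B, boundaries, T=T, diagonalize=diagonalize)
    ssm = apply_corrections(ssm, design, smooth_width=smooth_width)
    if order == "static":
        ssm = make_static(ssm)
    return mm, ssm


def cross_validate(
    fts: FeatureTrialSet,
    order,
    design: DesignParams,
    T: float = 0.01,
    distance: bool = False,
) -> CvResult:
    """Repetition-rotation cross-validation of the full pipeline.

    For each repetition r: train on the pooled remaining repetitions, filter
    the pooled held-out repetition (filter state re-initialised at each
    concatenation seam) and score the decoded trajectories against the
    held-out markers.
    """
    reps = fts.repetitions
    if len(reps) < 2:
        raise ValueError("cross-validation requires at least 2 repetitions")
    per_fold = []
    for held_out in reps:
        train_reps = [r for r in reps if r != held_out]
        G_tr, X_tr, b_tr = pool_trials(fts, train_reps)
        mm, ssm = fit_pipeline(G_tr, X_tr, b_tr, order, design, T=T)
        G_te, X_te, b_te = pool_trials(fts, [held_out])
        _, X_hat = filter_trajectory(mm, ssm, G_te, boundaries=b_te)
        per_fold.append(rms_error(X_hat, X_te, distance=distance))
    return CvResult(
        per_fold_rms=np.asarray(per_fold),
        config={"order": order, "design": design},
    )


# -- design-parameter optimisation ----------------------------------------

#: Default search bounds: the ranges explored in the reference study.
DEFAULT_BOUNDS = {
    "D": (2, 60),
    "c_v": (0.0, 1.0),
    "c_w": (0.0, 1.0),
    "c_f": (0.5, 5.0),
    "c_d": (0.1, 2.0),
}


def _parabolic_minimize(fun, x0, lo, hi, integer=False, max_evals=8, rel_tol=1e-3):
    """1-D successive parabolic interpolation within [lo, hi].

    ``fun`` is memoised by the caller.  Starts from three points (x0 and the
    ends of the bracket), repeatedly evaluates the vertex of the parabola
    through the three best points, and falls back to bisecting the largest
    gap around the incumbent when the parabolic step is degenerate or
    duplicates an existing point.  Returns (x_best, f_best).
    """

    def snap(x):
        x = min(max(x, lo), hi)
        return int(round(x)) if integer else x

    evals: dict[float, float] = {}

    def f(x):
        x = snap(x)
        if x not in evals:
            evals[x] = fun(x)
        return evals[x]

    for x in {snap(x0), snap(lo), snap(hi), snap((lo + hi) / 2)}:
        f(x)
    for _ in range(max_evals):
        pts = sorted(evals.items(), key=lambda kv: kv[1])[:3]
        if len(pts) < 3:
            break
        (x1, f1), (x2, f2), (x3, f3) = pts
        denom = (x1 - x2) * (f1 - f3) - (x1 - x3) * (f1 - f2)
        cand = None
        if abs(denom) > 1e-300:
            num = (x1 - x2) ** 2 * (f1 - f3) - (x1 - x3) ** 2 * (f1 - f2)
            cand = snap(x1 - 0.5 * num / denom)
        if cand is None or cand in evals:
            # bisect the largest gap adjacent to the incumbent
            xs = sorted(evals)
            k = xs.index(min(evals, key=evals.get))
            gaps = []
            if k > 0:
                gaps.append((xs[k] - xs[k - 1], (xs[k] + xs[k - 1]) / 2))
            if k < len(xs) - 1:
                gaps.append((xs[k + 1] - xs[k], (xs[k] + xs[k + 1]) / 2))
            gap, mid = max(gaps)
            min_gap = 1 if integer else rel_tol * max(hi - lo, 1e-12)
            if gap <= min_gap:
                break
            cand = snap(mid)
            if cand in evals:
                break
        f_prev = min(evals.values())
        f_new = f(cand)
        if f_prev - f_new < rel_tol * max(abs(f_prev), 1e-12) and len(evals) > 4:
            break
    x_best = min(evals, key=evals.get)
    return x_best, evals[x_best]


def optimize_design(
    fts: FeatureTrialSet,
    order,
    initial: DesignParams | None = None,
    bounds: dict | None = None,
    seed: int = 0,
    max_cycles: int = 3,
    rel_tol: float = 1e-3,
    objective=None,
    T: float = 0.01,
):
    """Tune the design parameters by cyclic parabolic coordinate descent.

    Parameters are visited in the order D, c_v, c_w (plus c_f, c_d for the
    second-order system); each is minimised by successive parabolic
    interpolation on the cross-validated mean RMS while the others are held
    fixed.  Stops when a full cycle improves the criterion by less than
    ``rel_tol`` (relative) or after ``max_cycles`` cycles.  Deterministic:
    the evaluation sequence depends only on the data, bounds and initial
    point (``seed`` is accepted for interface uniformity and forwarded to
    objectives that use randomness).

    ``objective(design) -> float`` may replace the cross-validation
    criterion (used in tests with analytic surrogates).

    Returns ``(best DesignParams, CvResult at the best parameters)``.
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    if order == 2:
        params = ["D", "c_v", "c_w", "c_f", "c_d"]
    elif order == 1:
        params = ["D", "c_v", "c_w"]
    else:  # static: the process noise is inflated away, only D and c_v act
        params = ["D", "c_v"]
    design = initial or DesignParams(
        D=min(max(20, bounds["D"][0]), bounds["D"][1])
    )

    cache: dict[tuple, float] = {}

    def score(d: DesignParams) -> float:
        key = (d.D, round(d.c_v, 12), round(d.c_w, 12), round(d.c_f, 12), round(d.c_d, 12))
        if key not in cache:
            if objective is not None:
                cache[key] = float(objective(d))
            else:
                cache[key] = cross_validate(fts, order, d, T=T).mean_rms
        return cache[key]

    best = score(design)
    if not np.isfinite(best):
        raise ValueError("objective is non-finite at the initial design point")
    for _ in range(max_cycles):
        cycle_start = best
        for name in params:
            lo, hi = bounds[name]

            def fun(x, _name=name):
                return score(replace(design, **{_name: x}))

            x_best, f_best = _parabolic_minimize(
                fun,
                getattr(design, name),
                lo,
                hi,
                integer=(name == "D"),
                rel_tol=rel_tol,
            )
            if f_best <= best:
                design = replace(design, **{name: x_best})
                best = f_best
        if cycle_start - best < rel_tol * max(abs(cycle_start), 1e-12):
            break
    if objective is not None:
        result = CvResult(per_fold_rms=np.asarray([best]), config={"order": order, "design": design})
    else:
        result = cross_validate(fts, order, design, T=T)
    return design, result


def compare_models(errors_a, errors_b) -> float:
    """Exact one-sided paired Wilcoxon signed-rank test.

    Tests whether model B's per-subject errors are smaller than model A's
    (alternative: b < a).  Zero differences are dropped.  Returns the exact
    one-sided p-value (no large-sample approximation).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    diffs = a - b
    nonzero = diffs != 0
    if not np.any(nonzero):
        raise ValueError("all paired differences are zero; test undefined")
    res = stats.wilcoxon(
        a[nonzero],
        b[nonzero],
        alternative="greater",
        method="exact",
        zero_method="wilcox",
    )
    return float(res.pvalue)
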
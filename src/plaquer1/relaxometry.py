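"""Pixel-wise saturation-recovery T1 mapping and contrast-agent ΔR1 maps.

The signal model for a saturation-recovery readout at delay ``t`` with
repetition time ``TR`` is

    S(t) = S0 * [ 1 - (1 - B) e^{-t/T1} - B e^{-t/TR} / (1 - B C e^{-t/TR}) ]

where ``S0`` is the net equilibrium magnetization, ``B`` the cosine of the
effective saturation flip angle (B = 0 is perfect saturation, in which case
the model reduces to the textbook S0 (1 - e^{-t/T1})), and ``C`` the cosine
of the excitation pulse, fixed to 1 to limit the degrees of freedom.

Per-voxel parameters are estimated by bounded nonlinear least squares.  The
B1 field varies slowly in space, so mapping proceeds in several passes: the
first pass fits (S0, T1, B) freely, each later pass replaces B with a local
neighbourhood mean of the previous B map and refits only (S0, T1).

Longitudinal rates follow as R1 [s^-1] = 1000 / T1 [ms], and the
contrast-agent effect as ΔR1 = R1_post - R1_pre, proportional to the local
agent concentration through its relaxivity r1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .containers import ImageSeries
from .grid import Grid

__all__ = [
    "SRSignalParams",
    "FitResult",
    "RelaxationMap",
    "DeltaR1Map",
    "model_signal",
    "sr_signal",
    "fit_voxel",
    "fit_voxels",
    "fit_map",
    "r1_from_t1",
    "delta_r1",
    "roi_mean_delta_r1",
    "SaturationRecoveryT1Mapper",
]

logger = logging.getLogger(__name__)

T1_BOUNDS = (1.0, 10000.0)
B_MAX = 0.99


@dataclass(frozen=True)
class SRSignalParams:
    """Per-voxel parameters of the saturation-recovery signal model."""

    s0: float
    t1: float
    b: float = 0.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if not 0.0 <= self.b < 1.0:
            raise ValueError("b must lie in [0, 1)")


@dataclass(frozen=True)
class FitResult:
    params: SRSignalParams
    residual_norm: float
    n_iter: int
    converged: bool


@dataclass
class RelaxationMap:
    """Fitted T1/R1/B/S0 volumes with a validity mask and grid metadata."""

    t1_map: np.ndarray
    r1_map: np.ndarray
    b_map: np.ndarray
    s0_map: np.ndarray
    mask: np.ndarray
    grid: Grid
    converged_map: np.ndarray | None = None

    def diagnostics_frame(self):
        """Per-voxel fit diagnostics as a DataFrame (CSV-ready)."""
        import pandas as pd

        idx = np.argwhere(self.mask)
        return pd.DataFrame(
            {
                "i": idx[:, 0],
                "j": idx[:, 1],
                "k": idx[:, 2],
                "s0": self.s0_map[self.mask],
                "t1_ms": self.t1_map[self.mask],
                "b": self.b_map[self.mask],
                "r1_s-1": self.r1_map[self.mask],
                "converged": (
                    self.converged_map[self.mask]
                    if self.converged_map is not None
                    else np.ones(idx.shape[0], dtype=bool)
                ),
            }
        )


@dataclass
class DeltaR1Map:
    delta_r1: np.ndarray
    mask: np.ndarray
    grid: Grid


# ---------------------------------------------------------------------------
# signal model
# ---------------------------------------------------------------------------


def sr_signal(s0, t1, b, t, tr, c=1.0):
    """Vectorised saturation-recovery signal; arguments broadcast."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("delay t must be positive")
    if np.any(np.asarray(tr) <= 0):
        raise ValueError("tr must be positive")
    e1 = np.exp(-t / np.asarray(t1, dtype=float))
    e2 = np.exp(-t / tr)
    denom = 1.0 - np.asarray(b) * c * e2
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("singular saturation-recovery denominator (B*C*exp(-t/TR) == 1)")
    return np.asarray(s0) * (1.0 - (1.0 - np.asarray(b)) * e1 - np.asarray(b) * e2 / denom)


def model_signal(params: SRSignalParams, t, tr):
    """Signal of one parameter set at delay(s) ``t`` (ms) and ``tr`` (ms)."""
    return sr_signal(params.s0, params.t1, params.b, t, tr, c=params.c)


def _model_and_jac(s0, t1, b, delays, tr, c):
    """Model values and partial derivatives, batched over voxels.

    ``s0, t1, b`` are (n,) vectors, ``delays`` a (d,) vector; returns the
    (n, d) model and the (n, d) partials wrt S0 (per-unit model), T1 and B.
    """
    e1 = np.exp(-delays[None, :] / t1[:, None])
    e2 = np.exp(-delays / tr)[None, :]
    denom = 1.0 - b[:, None] * c * e2
    model1 = 1.0 - (1.0 - b[:, None]) * e1 - b[:, None] * e2 / denom
    model = s0[:, None] * model1
    d_t1 = -s0[:, None] * (1.0 - b[:, None]) * (delays[None, :] / t1[:, None] ** 2) * e1
    d_b = s0[:, None] * (e1 - e2 / denom**2)
    return model, model1, d_t1, d_b


_LOWER = np.array([0.0, T1_BOUNDS[0], 0.0])
_UPPER = np.array([np.inf, T1_BOUNDS[1], B_MAX])


def _lm_fit(signals, delays, tr, p0, b_free: bool, c, max_iter, tol) -> dict:
    """One Levenberg–Marquardt run over all voxels from a common start.

    The damped normal equations of every voxel are assembled and solved in
    parallel (batched 3x3 / 2x2 linear solves) with an individual damping
    parameter per voxel; steps are projected onto the parameter bounds
    (S0 >= 0, T1 in [1, 10000] ms, B in [0, 0.99]).
    """
    n, d = signals.shape
    p = p0.copy()
    free = [0, 1, 2] if b_free else [0, 1]
    p = np.clip(p, _LOWER, _UPPER)
    k = len(free)

    # Internally T1 is optimised on a log scale: steps are multiplicative, so
    # the parameter cannot tunnel through the flat exp(-t/T1) plateau at tiny
    # T1 in one jump, and the gradient scaling is uniform across the decade
    # range of physiological T1.  S0 and B keep linear scaled steps.
    s0_scale = np.maximum(p[:, 0], 1e-3)
    scales = {0: s0_scale, 1: np.ones(n), 2: np.full(n, 0.1)}

    def apply_step(pa, step, idx):
        trial = pa.copy()
        for i, f in enumerate(free):
            if f == 1:
                trial[:, 1] = trial[:, 1] * np.exp(step[:, i])
            else:
                trial[:, f] = trial[:, f] + step[:, i] * scales[f][idx]
        return np.clip(trial, _LOWER, _UPPER)

    def cost_of(params, y):
        model, _, _, _ = _model_and_jac(
            params[:, 0], params[:, 1], params[:, 2], delays, tr, c
        )
        return 0.5 * np.sum((model - y) ** 2, axis=1)

    lam = np.full(n, 1e-3)
    cost = cost_of(p, signals)
    active = np.ones(n, dtype=bool)
    converged = np.zeros(n, dtype=bool)
    n_iter = np.zeros(n, dtype=int)
    eye = np.eye(k)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        pa = p[idx]
        model_a, model1, d_t1, d_b = _model_and_jac(
            pa[:, 0], pa[:, 1], pa[:, 2], delays, tr, c
        )
        cols = {
            0: model1 * s0_scale[idx, None],
            1: d_t1 * pa[:, 1, None],  # d/d(log T1)
            2: d_b * 0.1,
        }
        jac = np.stack([cols[f] for f in free], axis=2)
        resid = model_a - signals[idx]
        g = np.einsum("ndk,nd->nk", jac, resid)
        h = np.einsum("ndk,ndl->nkl", jac, jac)
        diag_h = np.einsum("nkk->nk", h)
        a = h + lam[idx, None, None] * (diag_h[:, :, None] * eye[None] + 1e-12 * eye[None])
        try:
            step = -np.linalg.solve(a, g[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge below prevents this
            a = a + 1e-8 * eye[None]
            step = -np.linalg.solve(a, g[..., None])[..., 0]
        # cap the scaled step (one scale unit per parameter per iteration) to
        # guard against wild early Gauss-Newton jumps into the bounds
        step = np.clip(step, -1.0, 1.0)
        trial = apply_step(pa, step, idx)
        trial_cost = cost_of(trial, signals[idx])

        better = trial_cost <= cost[idx]
        gained = cost[idx] - trial_cost
        small = gained <= tol * np.maximum(cost[idx], 1e-300)
        tiny_step = np.max(np.abs(step), axis=1) <= tol

        p[idx[better]] = trial[better]
        cost[idx[better]] = trial_cost[better]
        lam[idx[better]] = np.maximum(lam[idx[better]] * 0.3, 1e-12)
        lam[idx[~better]] = np.minimum(lam[idx[~better]] * 10.0, 1e12)
        n_iter[idx] += 1

        done = better & (small | tiny_step)
        stuck = ~better & (lam[idx] >= 1e11)  # no descent direction left
        converged[idx[done]] = True
        active[idx[done | stuck]] = False

    resid_norm = np.sqrt(2.0 * cost)
    return {
        "s0": p[:, 0],
        "t1": p[:, 1],
        "b": p[:, 2],
        "residual_norm": resid_norm,
        "n_iter": n_iter,
        "converged": converged,
    }


def fit_voxels(
    signals: np.ndarray,
    delays,
    tr: float,
    init: np.ndarray | None = None,
    b_fixed: np.ndarray | None = None,
    c: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> dict:
    """Levenberg–Marquardt fit of many voxels at once.

    When B is free, the (S0, T1, B) landscape has a curved T1–B trade-off
    valley that can pin B against its lower bound from an unlucky start, so
    the solver is restarted from a small fixed set of initial points and the
    per-voxel minimum-cost solution is kept.  With ``b_fixed`` only
    (S0, T1) are free and a single start suffices.

    Parameters
    ----------
    signals : (n, d) array
        One recovery curve per voxel.
    init : (n, 3) array, optional
        Starting (S0, T1, B); defaults to (max signal, 1000 ms, 0.1).
    b_fixed : (n,) array, optional
        Hold B fixed per voxel and fit only (S0, T1).

    Returns
    -------
    dict with (n,) arrays ``s0, t1, b, residual_norm, n_iter, converged``.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    delays = np.asarray(delays, dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValueError("signal contains non-finite values")
    n, d = signals.shape
    n_free = 2 if b_fixed is not None else 3
    if d < n_free:
        raise ValueError(f"need at least {n_free} delay points for {n_free} free parameters")

    s0_init = np.maximum(signals.max(axis=1), 1e-6)
    if init is None:
        p0 = np.column_stack([s0_init, np.full(n, 1000.0), np.full(n, 0.1)])
    else:
        p0 = np.array(init, dtype=float).copy()

    if b_fixed is not None:
        p0[:, 2] = np.clip(np.asarray(b_fixed, dtype=float), 0.0, B_MAX)
        return _lm_fit(signals, delays, tr, p0, False, c, max_iter, tol)

    starts = [p0]
    # alternates cover short-T1, high-B and boundary (B = 0) optima
    for t1_alt, b_alt in ((400.0, 0.05), (1500.0, 0.35), (1000.0, 0.0)):
        alt = np.column_stack([s0_init, np.full(n, t1_alt), np.full(n, b_alt)])
        starts.append(alt)
    best: dict | None = None
    for start in starts:
        res = _lm_fit(signals, delays, tr, start, True, c, max_iter, tol)
        if best is None:
            best = res
        else:
            win = res["residual_norm"] < best["residual_norm"]
            for key in best:
                best[key] = np.where(win, res[key], best[key])

    # active-set polish: a solution grazing a B bound zigzags in the
    # projected step; pin B at that bound and refit (S0, T1) cleanly
    for bound in (0.0, B_MAX):
        at_bound = np.abs(best["b"] - bound) < 1e-3
        if at_bound.any():
            sub = np.flatnonzero(at_bound)
            p0 = np.column_stack(
                [best["s0"][sub], best["t1"][sub], np.full(sub.size, bound)]
            )
            res = _lm_fit(signals[sub], delays, tr, p0, False, c, max_iter, tol)
            win = res["residual_norm"] < best["residual_norm"][sub]
            for key in best:
                best[key][sub] = np.where(win, res[key], best[key][sub])
    return best


def fit_voxel(
    signal,
    delays,
    tr: float,
    init: SRSignalParams | None = None,
    b_fixed: float | None = None,
    c: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> FitResult:
    """Bounded Levenberg–Marquardt fit of one voxel's recovery curve.

    With ``b_fixed`` given, only (S0, T1) are free; otherwise (S0, T1, B).
    Non-convergence is reported through ``FitResult.converged``, not raised.
    """
    signal = np.asarray(signal, dtype=float)
    init_arr = None
    if init is not None:
        init_arr = np.array([[init.s0, init.t1, init.b]])
    res = fit_voxels(
        signal[None, :],
        delays,
        tr,
        init=init_arr,
        b_fixed=None if b_fixed is None else np.array([b_fixed]),
        c=c,
        max_iter=max_iter,
        tol=tol,
    )
    params = SRSignalParams(
        s0=float(res["s0"][0]), t1=float(res["t1"][0]), b=float(res["b"][0]), c=c
    )
    return FitResult(
        params=params,
        residual_norm=float(res["residual_norm"][0]),
        n_iter=int(res["n_iter"][0]),
        converged=bool(res["converged"][0]),
    )


# ---------------------------------------------------------------------------
# map fitting
# ---------------------------------------------------------------------------


class SaturationRecoveryT1Mapper(BaseEstimator):
    """Multi-pass pixel-wise T1 mapper with B1 (B-parameter) smoothing.

    Parameters
    ----------
    passes : int, default 3
        Number of fitting passes.  Pass 1 fits (S0, T1, B) per voxel; each
        later pass smooths the B map over the local neighbourhood and refits
        (S0, T1) with B held fixed, exploiting the slow spatial variation of
        the B1 field.
    smooth_radius : int, default 1
        Half-width of the mean filter (radius 1 = 3x3x3 neighbourhood).
    smooth_in_plane : bool, default False
        Restrict the B smoothing to the slice plane (3x3x1 kernel).
    c : float, default 1.0
        Cosine of the excitation pulse, fixed during fitting.

    Attributes (after :meth:`fit`)
    ------------------------------
    t1_map_, r1_map_, b_map_, s0_map_ : ndarray
        Parameter volumes, NaN outside the fitted mask.
    mask_ : ndarray of bool
        Voxels that were fitted.
    converged_map_ : ndarray of bool
    grid_ : Grid
    """

    def __init__(
        self,
        passes: int = 3,
        smooth_radius: int = 1,
        smooth_in_plane: bool = False,
        c: float = 1.0,
        init_t1: float = 1000.0,
        init_b: float = 0.1,
        max_iter: int = 200,
        tol: float = 1e-8,
    ):
        self.passes = passes
        self.smooth_radius = smooth_radius
        self.smooth_in_plane = smooth_in_plane
        self.c = c
        self.init_t1 = init_t1
        self.init_b = init_b
        self.max_iter = max_iter
        self.tol = tol

    # -- helpers -----------------------------------------------------------

    def _smooth_b(self, b_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Mask-aware neighbourhood mean of the B map."""
        r = int(self.smooth_radius)
        size = (2 * r + 1, 2 * r + 1, 1 if self.smooth_in_plane else 2 * r + 1)
        m = mask.astype(float)
        num = ndimage.uniform_filter(np.where(mask, b_map, 0.0), size=size, mode="constant")
        den = ndimage.uniform_filter(m, size=size, mode="constant")
        out = np.zeros_like(b_map)
        valid = den > 0
        out[valid] = num[valid] / den[valid]
        return out

    # -- estimator API -----------------------------------------------------

    def fit(self, X: ImageSeries, y=None, mask: np.ndarray | None = None):
        """Fit parameter maps to a saturation-recovery :class:`ImageSeries`."""
        if int(self.passes) < 1:
            raise ValueError("passes must be >= 1")
        if X.n_delays < 3:
            raise ValueError("need at least 3 saturation delays to fit (S0, T1, B)")
        shape = X.grid.shape
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError("mask shape does not match series grid")

        data = X.as_4d()
        delays = X.delays_ms
        tr = X.tr_ms

        t1 = np.full(shape, np.nan)
        s0 = np.full(shape, np.nan)
        b = np.full(shape, np.nan)
        conv = np.zeros(shape, dtype=bool)

        signals = data[mask]  # (n_voxels, n_delays)
        if signals.shape[0] == 0:
            self.t1_map_, self.s0_map_, self.b_map_ = t1, s0, b
            self.mask_, self.converged_map_ = mask, conv
            self.r1_map_ = np.full(shape, np.nan)
            self.grid_ = X.grid
            return self

        init = np.column_stack(
            [
                np.maximum(signals.max(axis=1), 1e-6),
                np.full(signals.shape[0], float(self.init_t1)),
                np.full(signals.shape[0], float(self.init_b)),
            ]
        )
        res = fit_voxels(signals, delays, tr, init=init, c=self.c,
                         max_iter=self.max_iter, tol=self.tol)
        t1[mask], s0[mask], b[mask], conv[mask] = (
            res["t1"], res["s0"], res["b"], res["converged"]
        )

        for _ in range(int(self.passes) - 1):
            b_smooth = self._smooth_b(np.where(mask, b, 0.0), mask)
            init = np.column_stack([s0[mask], t1[mask], b_smooth[mask]])
            res = fit_voxels(signals, delays, tr, init=init,
                             b_fixed=b_smooth[mask], c=self.c,
                             max_iter=self.max_iter, tol=self.tol)
            t1[mask], s0[mask], b[mask], conv[mask] = (
                res["t1"], res["s0"], res["b"], res["converged"]
            )

        self.t1_map_ = t1
        self.s0_map_ = s0
        self.b_map_ = b
        self.mask_ = mask
        self.converged_map_ = conv
        self.r1_map_ = r1_from_t1(t1, mask=mask)
        self.grid_ = X.grid
        return self

    def to_relaxation_map(self) -> RelaxationMap:
        return RelaxationMap(
            t1_map=self.t1_map_,
            r1_map=self.r1_map_,
            b_map=self.b_map_,
            s0_map=self.s0_map_,
            mask=self.mask_,
            grid=self.grid_,
            converged_map=self.converged_map_,
        )

    def fit_map(self, X: ImageSeries, mask: np.ndarray | None = None) -> RelaxationMap:
        return self.fit(X, mask=mask).to_relaxation_map()


def fit_map(
    series: ImageSeries,
    passes: int = 3,
    smooth_radius: int = 1,
    mask: np.ndarray | None = None,
    **kwargs,
) -> RelaxationMap:
    """Functional wrapper over :class:`SaturationRecoveryT1Mapper`."""
    mapper = SaturationRecoveryT1Mapper(passes=passes, smooth_radius=smooth_radius, **kwargs)
    return mapper.fit_map(series, mask=mask)


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------


def r1_from_t1(t1_map: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Longitudinal rate R1 [s^-1] = 1000 / T1 [ms], elementwise.

    Non-positive T1 inside the mask is masked out (NaN) with a logged count.
    """
    t1 = np.asarray(t1_map, dtype=float)
    if mask is None:
        mask = np.isfinite(t1)
    bad = mask & ~(t1 > 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("r1_from_t1: %d voxels with non-positive T1 masked out", n_bad)
    r1 = np.full(t1.shape, np.nan)
    ok = mask & (t1 > 0)
    r1[ok] = 1000.0 / t1[ok]
    return r1


def delta_r1(pre: RelaxationMap, post: RelaxationMap) -> DeltaR1Map:
    """ΔR1 = R1_post - R1_pre on the intersection of the two fit masks."""
    if not pre.grid.same_geometry(post.grid):
        raise ValueError("pre/post grids differ; resample to a common grid first")
    mask = pre.mask & post.mask & np.isfinite(pre.r1_map) & np.isfinite(post.r1_map)
    delta = np.full(pre.r1_map.shape, np.nan)
    delta[mask] = post.r1_map[mask] - pre.r1_map[mask]
    return DeltaR1Map(delta_r1=delta, mask=mask, grid=pre.grid)


def roi_mean_delta_r1(dmap: DeltaR1Map, rois) -> float:
    """Mean ΔR1 over the plaque-ROI voxels of one animal.

    ``rois`` is a volumetry ``ROISet`` (or anything with ``mask``/``grid``)
    on the same grid as the ΔR1 map.
    """
    if not dmap.grid.same_geometry(rois.grid):
        raise ValueError("ROIs are not on the ΔR1 map grid; transfer them first")
    sel = rois.mask & dmap.mask
    if not sel.any():
        raise ValueError("empty ROI: no fitted voxels under the plaque ROI")
    return float(np.mean(dmap.delta_r1[sel]))
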
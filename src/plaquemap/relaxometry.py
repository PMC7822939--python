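"""Voxel-wise relaxometry: linearized VFA T1 fit and log-linear T2* fit.

Both estimators reduce to an ordinary least-squares line per voxel and are
fully vectorized. Voxels that violate the model (slope out of range, signal
at/below the floor, degenerate regressor) are marked invalid: NaN in the
maps plus a boolean validity mask — never an exception mid-volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plaquemap.errors import ProtocolError
from plaquemap.synthetic import SignalStack


@dataclass
class T1FitResult:
    """T1/M0 maps (ms, a.u.), the raw slope E = exp(-TR/T1), and validity."""

    t1_map: np.ndarray
    m0_map: np.ndarray
    valid_mask: np.ndarray
    slope_map: np.ndarray


@dataclass
class T2StarFitResult:
    """T2*/S0 maps (ms, a.u.) and validity."""

    t2s_map: np.ndarray
    s0_map: np.ndarray
    valid_mask: np.ndarray


@dataclass
class RelaxationMaps:
    """Registered pair of fitted maps for one specimen position."""

    t1: T1FitResult
    t2s: T2StarFitResult
    registered: bool = True

    def __post_init__(self) -> None:
        if self.registered and self.t1.t1_map.shape != self.t2s.t2s_map.shape:
            raise ProtocolError("registered maps must share one grid shape")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.t1.t1_map.shape


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel OLS of y on x along axis 0. Returns slope, intercept, ok."""
    n = x.shape[0]
    sx = x.sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    sxy = (x * y).sum(axis=0)
    denom = n * sxx - sx * sx
    # x-variance must be meaningfully non-zero relative to the x magnitude
    ok = np.isfinite(denom) & (denom > np.finfo(float).tiny + 1e-12 * n * np.abs(sxx))
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(ok, (n * sxy - sx * sy) / denom, np.nan)
        intercept = np.where(ok, (sy - slope * sx) / n, np.nan)
    return slope, intercept, ok


def fit_t1_vfa(stack: SignalStack, signal_floor: float = 0.0) -> T1FitResult:
    """Estimate T1 and M0 from a VFA stack by the linearized regression.

    Per voxel, regress Y_i = S_i/sin(a_i) on X_i = S_i/tan(a_i); the slope is
    E = exp(-TR/T1), so T1 = -TR/ln(E) and M0 = intercept/(1 - E). Voxels
    with any signal below ``signal_floor``, slope outside (0, 1) or a
    degenerate regressor are invalid (NaN).
    """
    proto = stack.protocol
    if proto.mode != "vfa":
        raise ProtocolError(f"fit_t1_vfa requires a vfa stack, got {proto.mode!r}")
    if len(set(proto.flip_angles)) < 2:
        raise ProtocolError("need >= 2 distinct flip angles")

    s = np.asarray(stack.frames, dtype=float)
    a = np.deg2rad(np.asarray(proto.flip_angles, dtype=float)).reshape(
        (-1,) + (1,) * (s.ndim - 1)
    )
    x = s / np.tan(a)
    y = s / np.sin(a)
    slope, intercept, ok = _ols_line(x, y)

    valid = ok & (slope > 0) & (slope < 1) & np.all(s >= signal_floor, axis=0)
    if signal_floor > 0:
        valid &= np.all(s > 0, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(valid, -proto.tr / np.log(slope), np.nan)
        m0 = np.where(valid, intercept / (1.0 - slope), np.nan)
    slope = np.where(valid, slope, np.nan)
    return T1FitResult(t1_map=t1, m0_map=m0, valid_mask=valid, slope_map=slope)


def fit_t2star(
    stack: SignalStack, signal_floor: float = 0.0, t2s_cap: float = 200.0
) -> T2StarFitResult:
    """Estimate T2* and S0 from a multi-echo stack by log-linear regression.

    Per voxel, OLS of ln(S) on TE gives slope = -1/T2* and intercept =
    ln(S0). Voxels with any signal <= ``signal_floor``, non-negative slope
    (non-decaying) or fitted T2* above ``t2s_cap`` are invalid (NaN).
    """
    proto = stack.protocol
    if proto.mode != "multiecho":
        raise ProtocolError(f"fit_t2star requires a multiecho stack, got {proto.mode!r}")
    if len(set(proto.echo_times)) < 2:
        raise ProtocolError("need >= 2 distinct echo times")

    s = np.asarray(stack.frames, dtype=float)
    te = np.asarray(proto.echo_times, dtype=float).reshape((-1,) + (1,) * (s.ndim - 1))
    positive = np.all(s > max(signal_floor, 0.0), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(s > 0, np.log(np.where(s > 0, s, 1.0)), np.nan)
    slope, intercept, ok = _ols_line(np.broadcast_to(te, s.shape), logs)

    with np.errstate(divide="ignore", invalid="ignore"):
        t2s = -1.0 / slope
        s0 = np.exp(intercept)
    valid = positive & ok & np.isfinite(slope) & (slope < 0) & (t2s <= t2s_cap)
    t2s = np.where(valid, t2s, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return T2StarFitResult(t2s_map=t2s, s0_map=s0, valid_mask=valid)
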
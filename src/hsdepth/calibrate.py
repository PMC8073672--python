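"""Calibration of the depth parameter against true inclusion depth.

Shallow inclusions produce a depth parameter that varies linearly with
cover depth; beyond a breakpoint the iso-point degrades and the
parameter decays exponentially toward the background value.
:class:`DepthCalibration` fits that piecewise model (ordinary least
squares below the breakpoint, a three-parameter exponential above,
breakpoint chosen by an SSE-minimizing grid search over the sample
depths) and its results object inverts the mapping to predict depth
from the parameter — with the caveat that the mapping is surjective
like ``y = x²``: a parameter value can be reachable from both branches,
and the linear branch is preferred where both apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import EmptyProfileError, FitFailureError, OutOfRangeError
from .isopoint import DepthParameterMap
from .phantom import DEPTH_SENTINEL, GroundTruth

__all__ = [
    "Profile",
    "LinearFit",
    "ExponentialFit",
    "CalibrationResult",
    "DepthCalibration",
    "DepthCalibrationResults",
    "extract_profile",
    "inner_fraction",
    "fit_linear",
    "fit_exponential",
    "segment_regimes",
    "invert_depth",
]


@dataclass
class Profile:
    """Ordered samples of the depth-parameter map along a line.

    ``position_mm`` is the arc-length coordinate along the sampled
    line (strictly increasing); ``true_depth_mm`` is NaN where the line
    leaves the inclusion mask.
    """

    position_mm: np.ndarray
    depth_param: np.ndarray
    true_depth_mm: np.ndarray

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.depth_param = np.asarray(self.depth_param, dtype=float)
        self.true_depth_mm = np.asarray(self.true_depth_mm, dtype=float)
        n = len(self.position_mm)
        if self.depth_param.shape != (n,) or self.true_depth_mm.shape != (n,):
            raise ValueError("profile columns must have equal length")
        if n == 0:
            raise EmptyProfileError("profile contains no samples")
        if n > 1 and not np.all(np.diff(self.position_mm) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.position_mm)

    def labelled(self) -> "Profile":
        """Sub-profile restricted to samples with known true depth."""
        keep = np.isfinite(self.true_depth_mm)
        if not np.any(keep):
            raise EmptyProfileError("no samples with ground-truth depth")
        return Profile(self.position_mm[keep], self.depth_param[keep], self.true_depth_mm[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_mm": self.position_mm,
                "depth_param": self.depth_param,
                "true_depth_mm": self.true_depth_mm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "Profile":
        df = pd.read_csv(path)
        return Profile(
            df["position_mm"].to_numpy(),
            df["depth_param"].to_numpy(),
            df["true_depth_mm"].to_numpy(),
        )


def extract_profile(
    dmap: DepthParameterMap,
    truth: GroundTruth,
    axis: str = "along",
    offset_mm: float = 0.0,
    bin_lines: Optional[int] = None,
) -> Profile:
    """Sample the map along or across the inclusion.

    ``axis="along"`` follows the inclusion axis: for every scan line
    crossing the mask, the depth parameter is averaged over the full
    mask width (the cover depth is constant across the width, so this
    uses the inclusion's whole support to suppress noise), optionally
    displaced laterally by ``offset_mm``.  Consecutive lines are then
    binned in groups of ``bin_lines``; the default bins so that the
    along-axis sample spacing matches the across-axis pixel pitch
    (isotropic sampling — the 43 µm line pitch oversamples the
    millimetre-scale depth ramp more than twentyfold).  The position
    coordinate is the arc length along the scan (y) axis.

    ``axis="across"`` samples the full x extent at the single scan
    line nearest to ``offset_mm`` along y; true depth is NaN outside
    the mask there.
    """
    px = dmap.pitch_x_um / 1000.0
    py = dmap.pitch_y_um / 1000.0
    n_x, n_y = dmap.values.shape
    if axis == "along":
        positions, params, depths = [], [], []
        off_px = int(round(offset_mm / px))
        for y in range(n_y):
            xs = np.nonzero(truth.inclusion_mask[:, y])[0]
            if len(xs) == 0:
                continue
            sel = xs + off_px
            sel = sel[(sel >= 0) & (sel < n_x)]
            sel = sel[dmap.valid[sel, y]]
            if len(sel) == 0:
                continue
            d = truth.depth_map[xs[len(xs) // 2], y]
            positions.append((y + 0.5) * py)
            params.append(float(dmap.values[sel, y].mean()))
            depths.append(np.nan if d == DEPTH_SENTINEL else d)
        if not positions:
            raise EmptyProfileError("along-axis line does not intersect the inclusion mask")
        pos, par, dep = (np.asarray(v) for v in (positions, params, depths))
        if bin_lines is None:
            bin_lines = max(int(round(px / py)), 1)
        if bin_lines > 1 and len(pos) >= 2 * bin_lines:
            n = len(pos) // bin_lines * bin_lines
            pos = pos[:n].reshape(-1, bin_lines).mean(axis=1)
            par = par[:n].reshape(-1, bin_lines).mean(axis=1)
            dep = dep[:n].reshape(-1, bin_lines).mean(axis=1)
        return Profile(pos, par, dep)
    if axis == "across":
        y = int(round(offset_mm / py - 0.5))
        if not (0 <= y < n_y):
            raise EmptyProfileError(f"offset {offset_mm} mm outside the scene")
        if not truth.inclusion_mask[:, y].any():
            raise EmptyProfileError("across-axis line does not intersect the inclusion mask")
        xs = np.arange(n_x)
        depth = truth.depth_map[:, y].astype(float)
        depth[~truth.inclusion_mask[:, y]] = np.nan
        return Profile((xs + 0.5) * px, dmap.values[:, y], depth)
    raise ValueError(f"axis must be 'along' or 'across', got {axis!r}")


def inner_fraction(profile: Profile, fraction: float = 0.6) -> Profile:
    """Central ``fraction`` of the profile along its extent.

    Trims ``floor(n (1-fraction) / 2)`` samples from each end, so the
    restriction is symmetric; ``fraction=1`` is the identity.  This
    discards the inclusion's ends, where boundary effects break the
    depth model.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = len(profile)
    trim = int(np.floor(n * (1.0 - fraction) / 2.0))
    if trim == 0:
        return profile
    sl = slice(trim, n - trim)
    return Profile(profile.position_mm[sl], profile.depth_param[sl], profile.true_depth_mm[sl])


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r2: float
    stderr: float

    def __call__(self, depth):
        return self.slope * np.asarray(depth, dtype=float) + self.intercept


class ExponentialFit(NamedTuple):
    amplitude: float
    rate: float
    offset: float
    r2: float
    degenerate: bool = False

    def __call__(self, depth):
        return self.amplitude * np.exp(-self.rate * np.asarray(depth, dtype=float)) + self.offset


def _r2(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return (1.0 - sse / sst if sst > 0 else 0.0), sse


def _xy(profile) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profile, Profile):
        p = profile.labelled()
        return p.true_depth_mm, p.depth_param
    d, y = profile
    return np.asarray(d, dtype=float), np.asarray(y, dtype=float)


def fit_linear(profile) -> LinearFit:
    """OLS of the depth parameter on true depth: ``d_i = slope·d + b``.

    Accepts a :class:`Profile` or a ``(depth, depth_param)`` pair.
    """
    d, y = _xy(profile)
    if len(d) < 3:
        raise ValueError("need at least 3 samples for a linear fit")
    if np.ptp(d) == 0:
        raise ValueError("true depth is constant; linear fit is degenerate")
    dc = d - d.mean()
    sxx = float(dc @ dc)
    slope = float(dc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * d.mean())
    yhat = slope * d + intercept
    r2, sse = _r2(y, yhat)
    dof = max(len(d) - 2, 1)
    stderr = float(np.sqrt(sse / dof / sxx))
    return LinearFit(slope, intercept, r2, stderr)


def fit_exponential(profile, rate_guess: float = 0.5) -> ExponentialFit:
    """Least-squares ``d_i = A exp(-rate·d) + c`` with ``rate >= 0``.

    Deterministic initialization: the offset starts at the decay-end
    value of the data with a small margin, amplitude and rate from a
    log-linear regression of ``|d_i - offset|`` on depth; no random
    restarts.  Constant data is reported as ``degenerate`` (only
    ``amplitude + offset`` is identifiable).  Non-convergence raises
    :class:`~hsdepth.errors.FitFailureError` with diagnostics.
    """
    d, y = _xy(profile)
    if len(d) < 4:
        raise ValueError("need at least 4 samples for an exponential fit")
    span = float(np.ptp(y))
    if span == 0.0 or np.ptp(d) == 0.0:
        return ExponentialFit(0.0, 0.0, float(y.mean()), 0.0, degenerate=True)

    # direction of decay: compare the shallow and deep thirds
    order = np.argsort(d)
    third = max(len(d) // 3, 1)
    shallow = float(np.mean(y[order[:third]]))
    deep = float(np.mean(y[order[-third:]]))
    sign = 1.0 if shallow >= deep else -1.0
    offset0 = (np.min(y) - 0.05 * span) if sign > 0 else (np.max(y) + 0.05 * span)
    resid0 = sign * (y - offset0)
    with np.errstate(divide="ignore"):
        logr = np.log(np.maximum(resid0, 1e-300))
    keep = np.isfinite(logr)
    if keep.sum() >= 2 and np.ptp(d[keep]) > 0:
        lin = np.polyfit(d[keep], logr[keep], 1)
        rate0 = max(-float(lin[0]), 1e-6)
        amp0 = sign * float(np.exp(min(lin[1], 300.0)))
    else:
        rate0, amp0 = rate_guess, sign * span
    # guard against wild starting points on nearly-linear segments
    if not np.isfinite(amp0) or abs(amp0) > 1e6 * span:
        rate0, amp0 = rate_guess, sign * span

    def model(x, a, r, c):
        return a * np.exp(-r * x) + c

    try:
        with np.errstate(all="ignore"):
            popt, _ = curve_fit(
                model,
                d,
                y,
                p0=(amp0, rate0, offset0),
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:
        raise FitFailureError(
            "exponential fit did not converge",
            diagnostics={"p0": (amp0, rate0, offset0), "n": len(d), "error": str(exc)},
        ) from exc
    amp, rate, offset = (float(v) for v in popt)
    r2, _ = _r2(y, model(d, *popt))
    degenerate = rate < 1e-8
    return ExponentialFit(amp, rate, offset, r2, degenerate=degenerate)


@dataclass
class CalibrationResult:
    """Piecewise linear/exponential calibration of ``d_i`` vs depth."""

    breakpoint_depth: float
    linear: Optional[LinearFit]
    exponential: Optional[ExponentialFit]
    r2_linear: float
    r2_exponential: float
    mask_fraction: float
    total_sse: float
    depth_range: tuple[float, float]

    def to_keyvalue(self) -> dict:
        kv = {
            "breakpoint_depth_mm": f"{self.breakpoint_depth:.4f}",
            "r2_linear": f"{self.r2_linear:.6f}",
            "r2_exponential": f"{self.r2_exponential:.6f}",
            "mask_fraction": f"{self.mask_fraction:.2f}",
            "total_sse": f"{self.total_sse:.6e}",
            "depth_min_mm": f"{self.depth_range[0]:.4f}",
            "depth_max_mm": f"{self.depth_range[1]:.4f}",
        }
        if self.linear is not None:
            kv["linear_slope_per_mm"] = f"{self.linear.slope:.6e}"
            kv["linear_intercept"] = f"{self.linear.intercept:.6e}"
        if self.exponential is not None:
            kv["exp_amplitude"] = f"{self.exponential.amplitude:.6e}"
            kv["exp_rate_per_mm"] = f"{self.exponential.rate:.6e}"
            kv["exp_offset"] = f"{self.exponential.offset:.6e}"
        return kv


def segment_regimes(profile, min_linear: int = 3, min_exponential: int = 4) -> CalibrationResult:
    """Grid-search the regime breakpoint over the sample depths.

    Every distinct sample depth is a candidate breakpoint; the linear
    branch is fit at or below it, the exponential branch above, and the
    candidate with the lowest total SSE wins (ties favour the smaller
    breakpoint).  The degenerate candidates — all-linear (breakpoint at
    the deepest sample) and all-exponential — compete on the same
    footing, so the piecewise SSE never exceeds either single-model fit.
    """
    d, y = _xy(profile)
    if len(d) < min_linear:
        raise ValueError("profile too short to calibrate")
    depths = np.unique(d)
    best: Optional[CalibrationResult] = None

    def consider(candidate: CalibrationResult) -> None:
        nonlocal best
        if best is None:
            best = candidate
            return
        a, b = candidate.total_sse, best.total_sse
        tie = abs(a - b) <= 1e-9 * max(a, b)
        if (a < b and not tie) or (tie and candidate.breakpoint_depth < best.breakpoint_depth):
            best = candidate

    rng = (float(depths[0]), float(depths[-1]))

    # pure-linear candidate: breakpoint at the deepest sample
    if len(d) >= min_linear and np.ptp(d) > 0:
        lin = fit_linear((d, y))
        _, sse = _r2(y, lin(d))
        consider(
            CalibrationResult(rng[1], lin, None, lin.r2, float("nan"), 1.0, sse, rng)
        )
    # pure-exponential candidate
    if len(d) >= min_exponential and np.ptp(d) > 0:
        try:
            ex = fit_exponential((d, y))
            _, sse = _r2(y, ex(d))
            consider(CalibrationResult(rng[0], None, ex, float("nan"), ex.r2, 1.0, sse, rng))
        except FitFailureError:
            pass

    for b in depths:
        lo = d <= b
        hi = ~lo
        if lo.sum() < min_linear or hi.sum() < min_exponential:
            continue
        if np.ptp(d[lo]) == 0 or np.ptp(d[hi]) == 0:
            continue
        lin = fit_linear((d[lo], y[lo]))
        try:
            ex = fit_exponential((d[hi], y[hi]))
        except FitFailureError:
            continue
        _, sse_lo = _r2(y[lo], lin(d[lo]))
        _, sse_hi = _r2(y[hi], ex(d[hi]))
        consider(
            CalibrationResult(
                float(b), lin, ex, lin.r2, ex.r2, 1.0, sse_lo + sse_hi, rng
            )
        )
    if best is None:
        raise ValueError(
            "no feasible breakpoint: too few samples in one regime for every candidate"
        )
    return best


def _invert_scalar(di: float, cal: CalibrationResult, tol: float) -> float:
    d_lo, d_hi = cal.depth_range
    if cal.linear is not None and cal.linear.slope != 0:
        d = (di - cal.linear.intercept) / cal.linear.slope
        if d_lo - tol <= d <= cal.breakpoint_depth + tol:
            return float(np.clip(d, d_lo, d_hi))
    ex = cal.exponential
    if ex is not None and not ex.degenerate and ex.amplitude != 0:
        arg = (di - ex.offset) / ex.amplitude
        if arg > 0:
            d = -np.log(arg) / ex.rate
            if cal.breakpoint_depth - tol <= d <= d_hi + tol:
                return float(np.clip(d, d_lo, d_hi))
    raise OutOfRangeError(
        f"depth parameter {di:.4g} unreachable by either calibrated branch"
    )


def invert_depth(di, calibration: CalibrationResult, tol: float = 1e-6):
    """Predict depth (mm) from the depth parameter via the calibration.

    The linear branch is inverted in closed form and preferred; values
    only reachable through the exponential branch use its logarithmic
    inverse.  The mapping is surjective (both branches can produce the
    same parameter value, as with ``y = x²``), so predictions beyond
    the breakpoint are inherently branch-dependent.  Scalars raise
    :class:`~hsdepth.errors.OutOfRangeError` when unreachable; arrays
    return a masked array flagging unreachable entries.
    """
    if np.isscalar(di):
        return _invert_scalar(float(di), calibration, tol)
    di = np.asarray(di, dtype=float)
    out = np.empty(di.shape)
    mask = np.zeros(di.shape, dtype=bool)
    for idx in np.ndindex(di.shape):
        try:
            out[idx] = _invert_scalar(float(di[idx]), calibration, tol)
        except OutOfRangeError:
            out[idx] = np.nan
            mask[idx] = True
    return np.ma.masked_array(out, mask=mask)


class DepthCalibration:
    """Model object: depth-parameter profile → piecewise calibration.

    Built from a :class:`Profile` (or explicit depth / parameter
    arrays); :meth:`fit` performs the breakpoint search and returns a
    :class:`DepthCalibrationResults`.
    """

    def __init__(self, profile: Profile):
        self.profile = profile

    @classmethod
    def from_arrays(cls, true_depth_mm, depth_param, position_mm=None) -> "DepthCalibration":
        d = np.asarray(true_depth_mm, dtype=float)
        y = np.asarray(depth_param, dtype=float)
        pos = np.arange(len(d), dtype=float) if position_mm is None else np.asarray(position_mm)
        order = np.argsort(pos)
        return cls(Profile(pos[order], y[order], d[order]))

    def fit(self, inner: Optional[float] = None) -> "DepthCalibrationResults":
        """Fit the piecewise model, optionally on the central ``inner`` fraction."""
        profile = self.profile if inner is None else inner_fraction(self.profile, inner)
        result = segment_regimes(profile)
        result.mask_fraction = 1.0 if inner is None else inner
        return DepthCalibrationResults(self, result, profile)


class DepthCalibrationResults:
    """Fitted piecewise calibration with prediction and reporting."""

    def __init__(self, model: DepthCalibration, result: CalibrationResult, profile: Profile):
        self.model = model
        self.result = result
        self.profile = profile

    @property
    def breakpoint_depth(self) -> float:
        return self.result.breakpoint_depth

    @property
    def r2_linear(self) -> float:
        return self.result.r2_linear

    @property
    def r2_exponential(self) -> float:
        return self.result.r2_exponential

    def predict_parameter(self, depth_mm):
        """Forward model: expected ``d_i`` at the given true depth."""
        depth = np.asarray(depth_mm, dtype=float)
        r = self.result
        if r.linear is None:
            return r.exponential(depth)
        if r.exponential is None:
            return r.linear(depth)
        return np.where(depth <= r.breakpoint_depth, r.linear(depth), r.exponential(depth))

    def predict_depth(self, di):
        """Inverse model: depth (mm) from the depth parameter."""
        return invert_depth(di, self.result)

    def linear_window(self) -> tuple[float, float]:
        """Depth interval (mm) over which the mapping is treated as linear.

        Up to the breakpoint when both branches exist; the whole range
        for a purely linear calibration; the shallowest third of the
        range when the SSE search preferred a single exponential (ideal
        noise-free profiles are globally near-exponential, so no
        distinct linear regime is identified — its shallow limit is
        then a nominal window).
        """
        r = self.result
        lo, hi = r.depth_range
        if r.linear is not None and r.exponential is not None:
            return (lo, r.breakpoint_depth)
        if r.linear is not None:
            return (lo, hi)
        return (lo, lo + (hi - lo) / 3.0)

    def summary(self) -> str:
        r = self.result
        lines = [
            "Depth-parameter calibration",
            "=" * 44,
            f"samples                 : {len(self.profile)}",
            f"inner fraction used     : {r.mask_fraction:.0%}",
            f"depth range             : {r.depth_range[0]:.2f} – {r.depth_range[1]:.2f} mm",
            f"regime breakpoint       : {r.breakpoint_depth:.2f} mm",
        ]
        if r.linear is not None:
            lines += [
                "linear regime (d <= breakpoint):",
                f"  slope                 : {r.linear.slope:+.4e} /mm (SE {r.linear.stderr:.1e})",
                f"  intercept             : {r.linear.intercept:+.4e}",
                f"  explained variance r2 : {r.r2_linear:.4f}",
            ]
        if r.exponential is not None:
            lines += [
                "exponential regime (d > breakpoint):",
                f"  amplitude             : {r.exponential.amplitude:+.4e}",
                f"  rate                  : {r.exponential.rate:.4e} /mm",
                f"  offset                : {r.exponential.offset:+.4e}",
                f"  explained variance r2 : {r.r2_exponential:.4f}",
            ]
            if r.exponential.degenerate:
                lines.append("  (degenerate: rate ~ 0, amplitude+offset only jointly identified)")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.profile.labelled()
        ax.plot(p.true_depth_mm, p.depth_param, ".", ms=4, alpha=0.6, label="samples")
        grid = np.linspace(*self.result.depth_range, 200)
        ax.plot(grid, self.predict_parameter(grid), "r-", lw=1.5, label="piecewise fit")
        ax.axvline(self.result.breakpoint_depth, color="0.5", ls=":", label="breakpoint")
        ax.set_xlabel("true cover depth (mm)")
        ax.set_ylabel("depth parameter $d_i$")
        ax.legend(frameon=False)
        return ax
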
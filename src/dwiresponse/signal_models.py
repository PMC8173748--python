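"""Forward diffusion signal models and voxel-wise nonlinear least squares.

Three decay models of the DW signal S(b) are implemented, all with
diffusion coefficients expressed in 1e-3 mm^2/s and b in s/mm^2:

* mono-exponential:       S(b) = S0 * exp(-b * ADC)
* bi-exponential (IVIM):  S(b) = S0 * [f * exp(-b * D*) + (1 - f) * exp(-b * D)]
* stretched-exponential:  S(b) = S0 * exp(-(b * DDC)^alpha)

The IVIM perfusion fraction ``f`` is carried on the x100 scale
(e.g. 9.27 means 9.27% pseudodiffusing volume); the model maths use
f/100 internally. The mono-exponential fit is a log-linear least
squares (exactly determined on two-point subsets, where it reduces to
the closed-form two-point ADC); the IVIM and stretched fits are bounded
nonlinear least squares with segmented initialisation and deterministic
multi-starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .bvalues import BValueScheme, SignalDecay
from .exceptions import (
    GridError,
    InsufficientDataError,
    InvalidSignalError,
    SchemeError,
)

# Bounds bracket every value plausibly seen in breast tissue with wide
# margin (diffusion coefficients in 1e-3 mm^2/s, f on the x100 scale).
D_BOUNDS = (0.05, 4.0)
D_STAR_BOUNDS = (1.0, 80.0)
F_BOUNDS = (0.0, 60.0)
DDC_BOUNDS = (0.05, 4.0)
ALPHA_BOUNDS = (0.01, 1.0)

_NLLS_TOL = 1e-12
_NLLS_MAX_ITER = 500

MAP_NAMES = (
    "adc_0_1000",
    "adc_200_1000",
    "adc_all",
    "d_star",
    "f",
    "ddc",
    "alpha",
)


# ---------------------------------------------------------------------------
# forward models


def mono_signal(b, s0: float, adc: float) -> np.ndarray:
    """Mono-exponential decay; ``adc`` in 1e-3 mm^2/s."""
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-b * adc * 1e-3)


def ivim_signal(b, s0: float, f: float, d: float, d_star: float) -> np.ndarray:
    """Bi-exponential IVIM decay; ``f`` on the x100 scale."""
    b = np.asarray(b, dtype=float)
    fr = f / 100.0
    return s0 * (fr * np.exp(-b * d_star * 1e-3) + (1.0 - fr) * np.exp(-b * d * 1e-3))


def stretched_signal(b, s0: float, ddc: float, alpha: float) -> np.ndarray:
    """Stretched-exponential decay with heterogeneity index ``alpha``."""
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-np.power(b * ddc * 1e-3, alpha))


FORWARD_MODELS = {
    "mono": mono_signal,
    "ivim": ivim_signal,
    "stretched": stretched_signal,
}


# ---------------------------------------------------------------------------
# fit results


@dataclass(frozen=True)
class MonoExpFit:
    adc: float  # 1e-3 mm^2/s
    s0: float
    rss: float
    converged: bool
    subset: str = "ALL"


@dataclass(frozen=True)
class BiExpFit:
    d: float  # tissue diffusion, 1e-3 mm^2/s
    d_star: float  # pseudodiffusion, 1e-3 mm^2/s (NaN when unidentifiable)
    f: float  # perfusion fraction, x100 scale
    s0: float
    rss: float
    converged: bool
    d_star_identifiable: bool = True


@dataclass(frozen=True)
class StretchedExpFit:
    ddc: float  # 1e-3 mm^2/s
    alpha: float  # (0, 1]
    s0: float
    rss: float
    converged: bool


# ---------------------------------------------------------------------------
# helpers


def clamp_signal(signal: np.ndarray, floor: float | None = None) -> tuple[np.ndarray, int]:
    """Clamp non-positive intensities to a floor before log transforms.

    Default floor is half the smallest positive value in the decay.
    Returns the clamped signal and the number of clamped samples.
    """
    sig = np.asarray(signal, dtype=float).copy()
    bad = sig <= 0
    n_bad = int(bad.sum())
    if n_bad:
        if floor is None:
            positive = sig[sig > 0]
            if positive.size == 0:
                raise InvalidSignalError("all signal samples are non-positive")
            floor = 0.5 * positive.min()
        sig[bad] = floor
    return sig, n_bad


def adc_two_point(s1: float, s2: float, b1: float, b2: float) -> float:
    """Two-point ADC, ln(s1/s2)/(b2-b1), returned in 1e-3 mm^2/s."""
    if s1 <= 0 or s2 <= 0:
        raise InvalidSignalError("two-point ADC requires positive signals")
    if b2 <= b1:
        raise SchemeError("adc_two_point requires b2 > b1")
    return float(np.log(s1 / s2) / (b2 - b1) * 1e3)


# ---------------------------------------------------------------------------
# mono fit


def fit_mono(
    decay: SignalDecay,
    subset: str = "ALL",
    method: str = "loglinear",
    clamp_floor: float | None = None,
) -> MonoExpFit:
    """Fit S(b) = S0 exp(-b ADC) over a named subset.

    ``method='loglinear'`` (default) is an unweighted linear least
    squares of log-signal on b; ``method='nlls'`` refines it by
    nonlinear least squares on the raw signal. Two-point subsets are
    exactly determined and reproduce :func:`adc_two_point` bit-for-bit.
    """
    b, s = decay.subset(subset)
    if len(b) < 2:
        raise InsufficientDataError("mono fit needs at least two b-values")
    s, _ = clamp_signal(s, clamp_floor)
    if len(b) == 2:
        adc = adc_two_point(s[0], s[1], b[0], b[1])
        s0 = float(s[0] * np.exp(b[0] * adc * 1e-3))
        return MonoExpFit(adc=adc, s0=s0, rss=0.0, converged=True, subset=str(subset))
    logs = np.log(s)
    design = np.column_stack([np.ones_like(b), -b])
    coef, *_ = np.linalg.lstsq(design, logs, rcond=None)
    s0 = float(np.exp(coef[0]))
    adc = float(coef[1] * 1e3)
    if method == "nlls":
        def resid(theta):
            return mono_signal(b, theta[0], theta[1]) - s

        res = least_squares(
            resid,
            x0=[s0, adc],
            bounds=([1e-12, -10.0], [np.inf, 50.0]),
            xtol=_NLLS_TOL, ftol=_NLLS_TOL, gtol=_NLLS_TOL,
            max_nfev=_NLLS_MAX_ITER,
        )
        s0, adc = float(res.x[0]), float(res.x[1])
        rss = float(res.cost * 2)
        return MonoExpFit(adc=adc, s0=s0, rss=rss, converged=bool(res.success),
                          subset=str(subset))
    rss = float(np.sum((mono_signal(b, s0, adc) - s) ** 2))
    return MonoExpFit(adc=adc, s0=s0, rss=rss, converged=True, subset=str(subset))


# ---------------------------------------------------------------------------
# IVIM fit


def _ivim_segmented_init(b: np.ndarray, s: np.ndarray) -> tuple[float, float, float, float]:
    """Segmented initialisation: D and the extrapolated intercept from the
    flow-suppressed b >= 200 points, f from the intercept gap at b = 0."""
    hi = b >= 200
    logs = np.log(s[hi])
    design = np.column_stack([np.ones(hi.sum()), -b[hi]])
    coef, *_ = np.linalg.lstsq(design, logs, rcond=None)
    d0 = float(np.clip(coef[1] * 1e3, *D_BOUNDS))
    s0_tissue = float(np.exp(coef[0]))
    s_b0 = float(s[np.argmin(b)])
    s0_0 = max(s_b0, 1e-9)
    f0 = float(np.clip((1.0 - s0_tissue / s0_0) * 100.0, *F_BOUNDS))
    return s0_0, f0, d0, 15.0


def fit_ivim(decay: SignalDecay, n_starts: int = 5) -> BiExpFit:
    """Bounded NLLS fit of the IVIM model over the LOW b-value subset.

    Segmented initialisation followed by joint bounded least squares
    from ``n_starts`` deterministic perturbations of the starting point;
    the lowest-RSS candidate wins. The pseudodiffusion coefficient is
    parameterised as D* = D + gap (gap >= 0) so D* >= D holds by
    construction. When the fitted f is essentially zero, D* is
    unidentifiable and reported as NaN with a flag.
    """
    b, s = decay.subset("LOW")
    s, _ = clamp_signal(s)
    s0_init, f_init, d_init, dstar_init = _ivim_segmented_init(b, s)

    lo = [1e-9, F_BOUNDS[0], D_BOUNDS[0], 0.0]
    hi = [10.0 * s.max(), F_BOUNDS[1], D_BOUNDS[1],
          D_STAR_BOUNDS[1] - D_BOUNDS[1]]

    def resid(theta):
        s0, f, d, gap = theta
        return ivim_signal(b, s0, f, d, d + gap) - s

    # deterministic multi-start grid around the segmented initialisation
    perturb = [
        (1.0, 1.0, 1.0, 1.0),
        (1.0, 0.5, 1.0, 0.4),
        (1.0, 1.5, 0.8, 2.5),
        (1.05, 1.0, 1.2, 0.15),
        (0.95, 2.0, 1.0, 4.0),
    ]
    best = None
    converged = False
    for ps0, pf, pd, pds in perturb[: max(1, n_starts)]:
        x0 = [
            np.clip(s0_init * ps0, lo[0], hi[0]),
            np.clip(max(f_init, 2.0) * pf, lo[1], hi[1]),
            np.clip(d_init * pd, lo[2], hi[2]),
        ]
        gap0 = np.clip(dstar_init * pds - x0[2], 0.0, hi[3])
        x0.append(gap0)
        try:
            res = least_squares(
                resid, x0=x0, bounds=(lo, hi),
                xtol=_NLLS_TOL, ftol=_NLLS_TOL, gtol=_NLLS_TOL,
                max_nfev=_NLLS_MAX_ITER,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
            converged = bool(res.success)
    if best is None:
        raise InsufficientDataError("IVIM fit failed from every start")
    s0, f, d, gap = (float(v) for v in best.x)
    d_star = d + gap
    rss = float(best.cost * 2)
    identifiable = f > 0.5  # below half a percent the fast compartment is absent
    if not identifiable:
        d_star = float("nan")
    return BiExpFit(d=d, d_star=d_star, f=f, s0=s0, rss=rss,
                    converged=converged, d_star_identifiable=identifiable)


# ---------------------------------------------------------------------------
# stretched fit


def fit_stretched(decay: SignalDecay, n_starts: int = 3) -> StretchedExpFit:
    """Bounded NLLS fit of the stretched-exponential model over HIGH b."""
    b, s = decay.subset("HIGH")
    s, _ = clamp_signal(s)
    # log-linear slope over the subset as the DDC starting value
    logs = np.log(s)
    design = np.column_stack([np.ones_like(b), -b])
    coef, *_ = np.linalg.lstsq(design, logs, rcond=None)
    ddc_init = float(np.clip(coef[1] * 1e3, *DDC_BOUNDS))
    s0_init = float(s[np.argmin(b)])

    lo = [1e-9, DDC_BOUNDS[0], ALPHA_BOUNDS[0] + 1e-3]
    hi = [10.0 * s.max(), DDC_BOUNDS[1], ALPHA_BOUNDS[1]]

    def resid(theta):
        return stretched_signal(b, *theta) - s

    starts = [(1.0, 0.9), (1.3, 0.7), (0.8, 1.0)]
    best = None
    converged = False
    for pddc, alpha0 in starts[: max(1, n_starts)]:
        x0 = [s0_init, np.clip(ddc_init * pddc, lo[1], hi[1]), alpha0]
        try:
            res = least_squares(
                resid, x0=x0, bounds=(lo, hi),
                xtol=_NLLS_TOL, ftol=_NLLS_TOL, gtol=_NLLS_TOL,
                max_nfev=_NLLS_MAX_ITER,
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or res.cost < best.cost:
            best = res
            converged = bool(res.success)
    if best is None:
        raise InsufficientDataError("stretched fit failed from every start")
    s0, ddc, alpha = (float(v) for v in best.x)
    return StretchedExpFit(ddc=ddc, alpha=alpha, s0=s0,
                           rss=float(best.cost * 2), converged=converged)


# ---------------------------------------------------------------------------
# voxel-wise maps


@dataclass
class ParametricMaps:
    """The seven fitted parameter maps on the source voxel grid.

    Voxels outside the fitted mask hold NaN; ``converged`` marks voxels
    where every component fit converged.
    """

    maps: Mapping[str, np.ndarray]
    converged: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        shapes.add(self.converged.shape)
        shapes.add(self.mask.shape)
        if len(shapes) != 1:
            raise GridError("parametric maps must share one grid shape")
        missing = set(MAP_NAMES) - set(self.maps)
        if missing:
            raise GridError(f"missing maps: {sorted(missing)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def fit_single_decay(decay: SignalDecay, mono_method: str = "loglinear") -> dict[str, float]:
    """All seven parameters for one decay (helper for voxel loops)."""
    out: dict[str, float] = {}
    out["adc_0_1000"] = fit_mono(decay, "PAIR_0_1000", method=mono_method).adc
    out["adc_200_1000"] = fit_mono(decay, "PAIR_200_1000", method=mono_method).adc
    out["adc_all"] = fit_mono(decay, "ALL", method=mono_method).adc
    ivim = fit_ivim(decay)
    out["d_star"] = ivim.d_star
    out["f"] = ivim.f
    stretched = fit_stretched(decay)
    out["ddc"] = stretched.ddc
    out["alpha"] = stretched.alpha
    out["_converged"] = float(ivim.converged and stretched.converged)
    return out


def fit_voxelwise(
    volume: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray,
    mono_method: str = "loglinear",
) -> ParametricMaps:
    """Fit all three models voxel-by-voxel inside a mask.

    ``volume`` is a 4D array (x, y, z, b); out-of-mask voxels are NaN in
    every output map.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise GridError("volume must be 4D (x, y, z, b)")
    if volume.shape[-1] != len(scheme):
        raise GridError(
            f"volume has {volume.shape[-1]} b-frames but scheme has {len(scheme)}"
        )
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape[:3]:
        raise GridError("mask shape does not match the volume spatial grid")

    maps = {name: np.full(mask.shape, np.nan) for name in MAP_NAMES}
    converged = np.zeros(mask.shape, dtype=bool)
    n_clamped = 0
    for idx in zip(*np.nonzero(mask)):
        raw = volume[idx]
        clamped, n_bad = clamp_signal(raw)
        n_clamped += n_bad
        decay = SignalDecay(scheme=scheme, signal=clamped)
        fitted = fit_single_decay(decay, mono_method=mono_method)
        for name in MAP_NAMES:
            maps[name][idx] = fitted[name]
        converged[idx] = bool(fitted["_converged"])
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} non-positive voxel samples before "
                      "log transforms", stacklevel=2)
    return ParametricMaps(maps=maps, converged=converged, mask=mask,
                          n_clamped=n_clamped)
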
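"""Synthetic DWI phantoms and simulated patient cohorts.

Two generators make the whole pipeline testable without patient data:

* :func:`simulate_decay` / :func:`simulate_phantom` produce voxel-wise
  DW decays under the mono-, bi- or stretched-exponential forward model,
  corrupted by Rician noise (the magnitude-image noise model:
  ``sqrt((S + e1)^2 + e2^2)`` with Gaussian ``e1, e2``), together with
  ground-truth parameter maps.

* :func:`simulate_cohort` draws a three-timepoint neoadjuvant-therapy
  cohort whose group-conditional feature distributions (pre-treatment
  values and mid-/post-treatment changes, by pathologic-complete-response
  status) and biomarker positivity rates emulate the published study
  population this package's defaults are calibrated to: 144 patients,
  pCR prevalence 37.5% (54:90), mid-treatment imaging available for
  101 (37 pCR : 64 non-pCR) and post-treatment for 98 (33:65).

Features are drawn independently given response group from normal
distributions (truncated below at 0 for non-negative quantities);
changes (deltas) are untruncated since they span negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm

from .bvalues import BValueScheme, SignalDecay, default_scheme
from .exceptions import ConfigurationError
from .features import LesionFeatures, PatientRecord
from .signal_models import (
    FORWARD_MODELS,
    MAP_NAMES,
    ParametricMaps,
    adc_two_point,
    fit_mono,
)

DWI_FEATURES = ("adc_0_1000", "adc_200_1000", "adc_all", "d_star", "f", "ddc", "alpha")
CE_FEATURES = ("size", "rer")
ALL_FEATURES = DWI_FEATURES + CE_FEATURES


@dataclass(frozen=True)
class GroupStat:
    """Group-conditional normal parameters for one feature/timepoint."""

    mean_pcr: float
    sd_pcr: float
    mean_non: float
    sd_non: float
    lower: float | None = None
    upper: float | None = None


# Pre-treatment distributions are absolute values; mid/post entries are
# changes from baseline (follow-up minus pre-treatment), in native units
# (diffusion coefficients 1e-3 mm^2/s; f and alpha unitless, f x100;
# size mm; RER %).
PRE_STATS: dict[str, GroupStat] = {
    "adc_0_1000": GroupStat(0.86, 0.16, 0.85, 0.21, lower=0.0),
    "adc_200_1000": GroupStat(0.79, 0.15, 0.77, 0.20, lower=0.0),
    "adc_all": GroupStat(0.67, 0.10, 0.67, 0.16, lower=0.0),
    "d_star": GroupStat(15.62, 4.18, 15.44, 3.70, lower=0.0),
    "f": GroupStat(9.27, 3.66, 9.27, 2.98, lower=0.0),
    "ddc": GroupStat(1.00, 0.83, 0.98, 0.80, lower=0.0),
    "alpha": GroupStat(0.68, 0.08, 0.67, 0.08, lower=0.01, upper=1.0),
    "size": GroupStat(39.8, 21.2, 44.3, 18.8, lower=0.0),
    "rer": GroupStat(164.1, 66.5, 152.6, 57.0, lower=0.0),
}

MID_DELTA_STATS: dict[str, GroupStat] = {
    "adc_0_1000": GroupStat(0.46, 0.26, 0.15, 0.23),
    "adc_200_1000": GroupStat(0.50, 0.26, 0.19, 0.22),
    "adc_all": GroupStat(0.28, 0.20, 0.09, 0.17),
    "d_star": GroupStat(-3.06, 6.36, -1.97, 6.35),
    "f": GroupStat(1.78, 4.33, 0.82, 3.86),
    "ddc": GroupStat(0.78, 0.68, 0.25, 0.35),
    "alpha": GroupStat(-0.02, 0.12, -0.003, 0.09),
    "size": GroupStat(-27.4, 16.6, -17.1, 14.2),
    "rer": GroupStat(-101.2, 81.1, -36.8, 81.1),
}

POST_DELTA_STATS: dict[str, GroupStat] = {
    "adc_0_1000": GroupStat(0.60, 0.34, 0.30, 0.32),
    "adc_200_1000": GroupStat(0.60, 0.32, 0.31, 0.32),
    "adc_all": GroupStat(0.35, 0.26, 0.18, 0.22),
    "d_star": GroupStat(-1.84, 7.71, -1.47, 5.90),
    "f": GroupStat(2.90, 5.33, 1.69, 3.73),
    "ddc": GroupStat(0.96, 0.63, 0.51, 0.60),
    "alpha": GroupStat(-0.05, 0.12, -0.05, 0.10),
    "size": GroupStat(-34.0, 18.9, -24.6, 18.5),
    "rer": GroupStat(-135.1, 81.4, -60.5, 79.8),
}

# Biomarker positivity by response group (probability positive given
# pCR, probability positive given non-pCR).
BIOMARKER_RATES: dict[str, tuple[float, float]] = {
    "er": (19 / 54, 72 / 90),
    "pr": (30 / 54, 70 / 90),
    "her2": (33 / 54, 30 / 90),
    "ki67_high": (52 / 54, 66 / 90),
}

# Per-timepoint imaging availability: (n pCR, n non-pCR).
AVAILABILITY = {"pre": (54, 90), "mid": (37, 64), "post": (33, 65)}


# ---------------------------------------------------------------------------
# decay-level simulation


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician corruption of a noiseless magnitude signal."""
    signal = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise ConfigurationError("noise sigma must be non-negative")
    if sigma == 0:
        return signal.copy()
    e1 = rng.normal(0.0, sigma, size=signal.shape)
    e2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def simulate_decay(
    model: str,
    params: Mapping[str, float],
    scheme: BValueScheme | None = None,
    sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> SignalDecay:
    """Simulate one DW decay under a named forward model.

    ``params`` are the forward-model keyword arguments (e.g.
    ``{"s0": 600, "adc": 0.86}`` for ``model="mono"``). ``seed`` may be
    an integer or a ``numpy.random.Generator``; runs with the same seed
    are bit-reproducible.
    """
    if scheme is None:
        scheme = default_scheme()
    if model not in FORWARD_MODELS:
        raise ConfigurationError(f"unknown model id {model!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    clean = FORWARD_MODELS[model](scheme.b, **params)
    noisy = rician(clean, sigma, rng)
    return SignalDecay(scheme=scheme, signal=noisy)


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class Region:
    """One phantom region: a geometric shape with a generating model."""

    name: str
    shape: str  # "ellipsoid" | "box"
    center: tuple[float, float, float]  # voxel coordinates
    radii: tuple[float, float, float]  # semi-axes / half-sizes, voxels
    model: str
    params: Mapping[str, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a digital DWI phantom.

    Default in-plane resolution 2.6 x 2.6 mm with 3 mm sections mirrors
    a typical breast DW acquisition. Overlapping regions resolve by
    list order (earlier regions win).
    """

    shape: tuple[int, int, int] = (24, 24, 6)
    spacing: tuple[float, float, float] = (2.6, 2.6, 3.0)
    regions: tuple[Region, ...] = ()
    background_s0: float = 50.0
    background_adc: float = 2.0  # fluid-like background decay
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be non-negative")
        for reg in self.regions:
            c, r = np.asarray(reg.center), np.asarray(reg.radii)
            if np.any(c - r < -0.5) or np.any(c + r > np.asarray(self.shape) - 0.5):
                raise ConfigurationError(f"region {reg.name!r} exceeds the grid")


def default_tumor_phantom(sigma: float = 12.0, seed: int = 0) -> PhantomSpec:
    """Two-region tumor phantom with parameters near pre-treatment tumor
    means (an IVIM-behaving rim and a stretched-exponential core)."""
    return PhantomSpec(
        regions=(
            # core listed first: earlier regions take precedence on overlap
            Region(
                name="core", shape="ellipsoid", center=(11.5, 11.5, 2.5),
                radii=(3.5, 3.5, 1.2), model="stretched",
                params={"s0": 600.0, "ddc": 1.0, "alpha": 0.68},
            ),
            Region(
                name="rim", shape="ellipsoid", center=(11.5, 11.5, 2.5),
                radii=(8.0, 8.0, 2.2), model="ivim",
                params={"s0": 600.0, "f": 9.27, "d": 0.79, "d_star": 15.5},
            ),
        ),
        sigma=sigma,
        seed=seed,
    )


def _region_mask(reg: Region, shape: tuple[int, int, int]) -> np.ndarray:
    grid = np.indices(shape, dtype=float)
    c = np.asarray(reg.center, dtype=float).reshape(3, 1, 1, 1)
    r = np.asarray(reg.radii, dtype=float).reshape(3, 1, 1, 1)
    if reg.shape == "ellipsoid":
        return (np.sum(((grid - c) / r) ** 2, axis=0) <= 1.0)
    if reg.shape == "box":
        return np.all(np.abs(grid - c) <= r, axis=0)
    raise ConfigurationError(f"unknown region shape {reg.shape!r}")


def _truth_params(reg: Region, scheme: BValueScheme) -> dict[str, float]:
    """Seven-map ground truth implied by a region's generating model.

    The two-point ADC truths are computed in closed form from the
    noiseless forward signal; ADC_all truth is the log-linear fit of the
    noiseless decay (the estimand of that estimator). Parameters that a
    model does not define are NaN.
    """
    clean = FORWARD_MODELS[reg.model](scheme.b, **reg.params)
    decay = SignalDecay(scheme=scheme, signal=clean)
    b1, s1 = decay.subset("PAIR_0_1000")
    b2, s2 = decay.subset("PAIR_200_1000")
    truth = {name: float("nan") for name in MAP_NAMES}
    truth["adc_0_1000"] = adc_two_point(s1[0], s1[1], b1[0], b1[1])
    truth["adc_200_1000"] = adc_two_point(s2[0], s2[1], b2[0], b2[1])
    truth["adc_all"] = fit_mono(decay, "ALL").adc
    if reg.model == "mono":
        truth["f"] = 0.0
        truth["ddc"] = float(reg.params["adc"])
        truth["alpha"] = 1.0
    elif reg.model == "ivim":
        truth["d_star"] = float(reg.params["d_star"])
        truth["f"] = float(reg.params["f"])
    elif reg.model == "stretched":
        truth["ddc"] = float(reg.params["ddc"])
        truth["alpha"] = float(reg.params["alpha"])
    return truth


def simulate_phantom(
    spec: PhantomSpec, scheme: BValueScheme | None = None
) -> tuple[np.ndarray, ParametricMaps, dict[str, np.ndarray]]:
    """Build a 4D phantom volume, its truth maps, and per-region masks."""
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nb = len(scheme)

    clean = np.empty(shape + (nb,), dtype=float)
    clean[:] = FORWARD_MODELS["mono"](
        scheme.b, s0=spec.background_s0, adc=spec.background_adc
    )

    truth_maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(shape, dtype=bool)
    for reg in spec.regions:
        mask = _region_mask(reg, shape) & ~claimed
        claimed |= mask
        masks[reg.name] = mask
        clean[mask] = FORWARD_MODELS[reg.model](scheme.b, **reg.params)
        truth = _truth_params(reg, scheme)
        for name in MAP_NAMES:
            truth_maps[name][mask] = truth[name]

    volume = rician(clean, spec.sigma, rng)
    truth = ParametricMaps(
        maps=truth_maps, converged=claimed.copy(), mask=claimed.copy()
    )
    return volume, truth, masks


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated three-timepoint cohort.

    Defaults reproduce the study population the package's feature
    distributions are calibrated to. ``fixed_counts=True`` makes the
    response-group sizes, per-timepoint availability and biomarker
    counts exact (rounded from the configured rates); otherwise each is
    drawn as Bernoulli/binomial.
    """

    n_total: int = 144
    prevalence: float = 0.375
    fixed_counts: bool = True
    availability: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(AVAILABILITY)
    )
    pre_stats: Mapping[str, GroupStat] = field(default_factory=lambda: dict(PRE_STATS))
    mid_delta_stats: Mapping[str, GroupStat] = field(
        default_factory=lambda: dict(MID_DELTA_STATS)
    )
    post_delta_stats: Mapping[str, GroupStat] = field(
        default_factory=lambda: dict(POST_DELTA_STATS)
    )
    biomarker_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BIOMARKER_RATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        for table in (self.pre_stats, self.mid_delta_stats, self.post_delta_stats):
            for name, st in table.items():
                if st.sd_pcr <= 0 or st.sd_non <= 0:
                    raise ConfigurationError(f"SDs must be positive ({name})")
                if (
                    st.lower is not None
                    and st.upper is not None
                    and st.lower >= st.upper
                ):
                    raise ConfigurationError(
                        f"infeasible truncation bounds for {name}"
                    )


def scaled_counts(spec: CohortSpec) -> dict[str, tuple[int, int]]:
    """Per-timepoint (pCR, non-pCR) counts scaled to ``n_total``."""
    n_pcr = int(round(spec.n_total * spec.prevalence))
    n_non = spec.n_total - n_pcr
    ref_pcr, ref_non = spec.availability["pre"]
    out = {}
    for tp, (a_pcr, a_non) in spec.availability.items():
        out[tp] = (
            int(round(n_pcr * a_pcr / ref_pcr)),
            int(round(n_non * a_non / ref_non)),
        )
    out["pre"] = (n_pcr, n_non)
    return out


def _draw(stat: GroupStat, pcr: bool, n: int, rng: np.random.Generator) -> np.ndarray:
    mean = stat.mean_pcr if pcr else stat.mean_non
    sd = stat.sd_pcr if pcr else stat.sd_non
    if stat.lower is None and stat.upper is None:
        return rng.normal(mean, sd, size=n)
    a = -np.inf if stat.lower is None else (stat.lower - mean) / sd
    b = np.inf if stat.upper is None else (stat.upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> list[PatientRecord]:
    """Simulate a cohort of :class:`~dwiresponse.features.PatientRecord`.

    Pre-treatment features are drawn from group-conditional (truncated)
    normals; mid/post features are pre + a group-conditional change drawn
    from the corresponding delta distribution. Timepoint availability is
    missing-completely-at-random within response group.
    """
    if spec is None:
        spec = CohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)

    counts = scaled_counts(spec)
    n_pcr, n_non = counts["pre"]
    n = n_pcr + n_non
    if spec.fixed_counts:
        labels = np.zeros(n, dtype=bool)
        labels[:n_pcr] = True
        labels = labels[rng.permutation(n)]
    else:
        labels = rng.random(n) < spec.prevalence

    records: list[PatientRecord] = []
    for pcr in (True, False):
        idx = np.nonzero(labels == pcr)[0]
        m = idx.size
        # biomarkers
        markers: dict[str, np.ndarray] = {}
        for name, (p_pcr, p_non) in spec.biomarker_rates.items():
            p = p_pcr if pcr else p_non
            if spec.fixed_counts:
                k = int(round(p * m))
                flags = np.zeros(m, dtype=bool)
                flags[:k] = True
                flags = flags[rng.permutation(m)]
            else:
                flags = rng.random(m) < p
            markers[name] = flags
        # availability, independent across follow-up timepoints
        avail: dict[str, np.ndarray] = {"pre": np.ones(m, dtype=bool)}
        for tp in ("mid", "post"):
            want = counts[tp][0 if pcr else 1]
            want = min(want, m)
            if spec.fixed_counts:
                flags = np.zeros(m, dtype=bool)
                flags[rng.permutation(m)[:want]] = True
            else:
                flags = rng.random(m) < (want / m if m else 0.0)
            avail[tp] = flags
        # features
        pre = {f: _draw(spec.pre_stats[f], pcr, m, rng) for f in ALL_FEATURES}
        mid_d = {f: _draw(spec.mid_delta_stats[f], pcr, m, rng) for f in ALL_FEATURES}
        post_d = {f: _draw(spec.post_delta_stats[f], pcr, m, rng) for f in ALL_FEATURES}

        for j, i in enumerate(idx):
            feats: dict[str, LesionFeatures] = {
                "pre": _lesion({f: pre[f][j] for f in ALL_FEATURES})
            }
            for tp, deltas in (("mid", mid_d), ("post", post_d)):
                if avail[tp][j]:
                    feats[tp] = _lesion(
                        {f: pre[f][j] + deltas[f][j] for f in ALL_FEATURES}
                    )
            records.append(
                PatientRecord(
                    id=f"P{i + 1:03d}",
                    features=feats,
                    er=bool(markers["er"][j]),
                    pr=bool(markers["pr"][j]),
                    her2=bool(markers["her2"][j]),
                    ki67_high=bool(markers["ki67_high"][j]),
                    pcr=bool(pcr),
                )
            )
    records.sort(key=lambda r: r.id)
    return records


def _lesion(values: Mapping[str, float]) -> LesionFeatures:
    dwi = {k: float(values[k]) for k in DWI_FEATURES}
    return LesionFeatures(dwi=dwi, size=float(values["size"]), rer=float(values["rer"]))
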
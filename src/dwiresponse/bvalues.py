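"""Diffusion-weighting (b-value) schemes and per-voxel signal decays.

A scheme is an ordered list of b-values (s/mm^2) together with named
subsets used by the different decay models: the full 13-point list for
the mono-exponential ADC_all fit, a low-b subset (perfusion-sensitive)
for the bi-exponential IVIM fit, a high-b subset for the
stretched-exponential fit, and the two two-point pairs used for the
standard ADC (b = 0, 1000) and the flow-insensitive ADC (b = 200, 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InvalidSignalError, SchemeError

ALL = (0, 10, 30, 50, 100, 150, 200, 500, 800, 1000, 1500, 2000, 2500)
LOW = (0, 10, 30, 50, 100, 150, 200, 500, 800)
HIGH = (0, 500, 800, 1000, 1500, 2000, 2500)
PAIR_0_1000 = (0, 1000)
PAIR_200_1000 = (200, 1000)

DEFAULT_SUBSETS: dict[str, tuple[float, ...]] = {
    "ALL": ALL,
    "LOW": LOW,
    "HIGH": HIGH,
    "PAIR_0_1000": PAIR_0_1000,
    "PAIR_200_1000": PAIR_200_1000,
}


@dataclass(frozen=True)
class BValueScheme:
    """Ordered b-values (s/mm^2) with named index subsets.

    Parameters
    ----------
    values
        Strictly increasing, non-negative b-values.
    subsets
        Mapping of subset name to a tuple of b-values; every subset
        member must appear in ``values``.
    """

    values: tuple[float, ...]
    subsets: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise SchemeError("a b-value scheme needs at least two values")
        if any(v < 0 for v in vals):
            raise SchemeError("b-values must be non-negative")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise SchemeError("b-values must be strictly increasing")
        subs = {k: tuple(float(v) for v in s) for k, s in self.subsets.items()}
        object.__setattr__(self, "subsets", subs)
        known = set(vals)
        for name, sub in subs.items():
            missing = set(sub) - known
            if missing:
                raise SchemeError(
                    f"subset {name!r} contains b-values {sorted(missing)} "
                    "absent from the scheme"
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def indices(self, subset: str | Sequence[float]) -> np.ndarray:
        """Indices into ``values`` for a named or explicit subset."""
        if isinstance(subset, str):
            if subset not in self.subsets:
                raise SchemeError(f"unknown subset {subset!r}")
            members = self.subsets[subset]
        else:
            members = tuple(float(v) for v in subset)
        lookup = {v: i for i, v in enumerate(self.values)}
        try:
            return np.asarray([lookup[v] for v in members], dtype=int)
        except KeyError as exc:
            raise SchemeError(f"b-value {exc.args[0]} not in scheme") from exc

    def has_subset(self, name: str) -> bool:
        return name in self.subsets


def default_scheme() -> BValueScheme:
    """The 13-point acquisition scheme with its standard named subsets."""
    return BValueScheme(values=ALL, subsets=dict(DEFAULT_SUBSETS))


def scheme_from_bvals(bvals: Sequence[float]) -> BValueScheme:
    """Build a scheme from a raw b-value list, attaching every standard
    named subset that the listed values can support."""
    vals = tuple(float(v) for v in bvals)
    available = set(vals)
    subsets = {
        name: sub
        for name, sub in DEFAULT_SUBSETS.items()
        if set(sub) <= available
    }
    return BValueScheme(values=vals, subsets=subsets)


@dataclass(frozen=True)
class SignalDecay:
    """One voxel's (or ROI's) DW signal across a b-value scheme."""

    scheme: BValueScheme
    signal: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        if sig.shape != (len(self.scheme),):
            raise SchemeError(
                f"signal length {sig.shape} does not match scheme length "
                f"{len(self.scheme)}"
            )
        if not np.all(np.isfinite(sig)):
            raise InvalidSignalError("signal contains non-finite values")
        if np.any(sig < 0):
            raise InvalidSignalError("signal contains negative values")

    def subset(self, name: str | Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(b, signal)`` arrays restricted to a subset."""
        idx = self.scheme.indices(name)
        return self.scheme.b[idx], self.signal[idx]
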
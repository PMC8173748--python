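"""File I/O, pipeline configuration, and run manifests.

Volumes, masks and parametric maps travel as NIfTI (via nibabel, source
affine preserved, float32 maps); b-value tables as single-line
space-separated text (FSL ``.bval`` dialect); feature and results
tables as CSV with explicit unit columns; configuration as YAML/JSON.
Every pipeline run emits one JSON manifest recording the configuration
hash, input digests, seed, per-stage timings and warnings, and a digest
over all output files (timings are excluded from the digest so repeated
seeded runs agree).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import yaml

from .bvalues import BValueScheme, scheme_from_bvals
from .exceptions import ConfigurationError, SchemeError
from .signal_models import MAP_NAMES, ParametricMaps

#: file suffix per parametric map
MAP_SUFFIXES = {
    "adc_0_1000": "_adc01000",
    "adc_200_1000": "_adc2001000",
    "adc_all": "_adcall",
    "d_star": "_dstar",
    "f": "_f",
    "ddc": "_ddc",
    "alpha": "_alpha",
}


# ---------------------------------------------------------------------------
# NIfTI / bval


def read_bvals(path: str | Path) -> BValueScheme:
    """Read a single-line FSL-style .bval file into a scheme."""
    text = Path(path).read_text().split()
    if not text:
        raise SchemeError(f"empty bval file {path}")
    return scheme_from_bvals([float(v) for v in text])


def write_bvals(scheme: BValueScheme, path: str | Path) -> None:
    Path(path).write_text(" ".join(f"{v:g}" for v in scheme.values) + "\n")


def read_dwi(
    path_volume: str | Path, path_bvals: str | Path
) -> tuple[np.ndarray, np.ndarray, BValueScheme]:
    """Load a 4D DWI volume and its b-value table.

    Returns ``(data, affine, scheme)``; the volume's 4th axis must match
    the b-value count.
    """
    img = nib.load(str(path_volume))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise SchemeError(f"expected a 4D volume, got shape {data.shape}")
    scheme = read_bvals(path_bvals)
    if data.shape[-1] != len(scheme):
        raise SchemeError(
            f"volume has {data.shape[-1]} frames but bval file lists "
            f"{len(scheme)} values"
        )
    return data, np.asarray(img.affine), scheme


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path,
                dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5, np.asarray(img.affine)


def write_parametric_maps(
    maps: ParametricMaps,
    affine: np.ndarray,
    out_dir: str | Path,
    stem: str = "maps",
) -> list[Path]:
    """Write the seven maps as float32 NIfTI files with standard suffixes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in MAP_NAMES:
        path = out_dir / f"{stem}{MAP_SUFFIXES[name]}.nii"
        write_nifti(maps[name], affine, path)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    seed: int = 0
    # phantom stage
    phantom_sigma: float = 12.0  # Rician sigma; tumor S0 600 -> SNR 50
    # cohort stage
    n_total: int = 144
    prevalence: float = 0.375
    fixed_counts: bool = True
    # fitting
    mono_method: str = "loglinear"
    ivim_starts: int = 5
    # features
    diameter_mode: str = "inplane"
    # statistics
    alpha: float = 0.05
    bonferroni_dwi: int = 21
    bonferroni_ce: int = 6
    # response model
    stepwise_alpha: float = 0.05
    loocv_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if self.phantom_sigma < 0:
            raise ConfigurationError("phantom sigma must be non-negative")
        if self.mono_method not in ("loglinear", "nlls"):
            raise ConfigurationError(f"unknown mono_method {self.mono_method!r}")
        if self.diameter_mode not in ("inplane", "3d"):
            raise ConfigurationError(f"unknown diameter_mode {self.diameter_mode!r}")
        if not 0.0 < self.loocv_cutoff < 1.0:
            raise ConfigurationError("loocv_cutoff must be in (0, 1)")
        if self.bonferroni_dwi < 1 or self.bonferroni_ce < 1:
            raise ConfigurationError("Bonferroni family sizes must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# manifest


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int
    package_version: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: list[dict[str, Any]] = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, warnings_seen: list[str]) -> None:
        self.stages.append(
            {"name": name, "seconds": seconds, "warnings": warnings_seen}
        )

    def add_output(self, path: str | Path) -> None:
        self.outputs[Path(path).name] = file_digest(path)

    @property
    def outputs_digest(self) -> str:
        """Digest over all output file digests (timings excluded), so a
        repeated seeded run must reproduce it exactly."""
        payload = json.dumps(dict(sorted(self.outputs.items()))).encode()
        return hashlib.sha256(payload).hexdigest()

    def write(self, path: str | Path) -> None:
        doc = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "package_version": self.package_version,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "outputs_digest": self.outputs_digest,
            "stages": self.stages,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_table(df, path: str | Path) -> None:
    """Deterministic CSV serialization (fixed float format)."""
    df.to_csv(path, index=False, float_format="%.10g")
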
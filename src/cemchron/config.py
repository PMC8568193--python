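"""Run configuration and physical-unit helpers.

All tunable parameters of the counting pipeline live in :class:`RunConfig`;
the defaults are the study conditions of the underlying cementochronology
protocol (1000 random 10-pixel transects per slice, five sections per
transect, cut-offs at half a standard deviation, a 3-pixel minimum event
separation, 30 slices per specimen at 0.66 um voxels).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

#: Default physical pixel edge length, in micrometres.
DEFAULT_VOXEL_SIZE_UM = 0.66

ROUNDING_MODES = ("integer", "quarter")


def px_to_um(px: float, voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> float:
    """Convert a pixel distance to micrometres (3 px at 0.66 um -> 1.98 um)."""
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be positive")
    return px * voxel_size_um


def um_to_px(um: float, voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM) -> float:
    """Convert a micrometre distance to pixels."""
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be positive")
    return um / voxel_size_um


@dataclasses.dataclass
class RunConfig:
    """Parameters of the increment-counting pipeline.

    Attributes
    ----------
    n_transects:
        Number of random transects sampled per slice.
    transect_thickness_px:
        Width of the column band averaged into one radial profile.
    n_sections:
        Number of equal-length sections each transect is split into.
    cutoff_factor:
        Peak/trough cut-offs sit at section mean +/- cutoff_factor * SD.
    min_separation_px:
        Counted events closer than this along the transect are merged.
    n_slices_per_specimen:
        Slices aggregated into one specimen estimate.
    rounding_mode:
        "integer" (nearest integer) or "quarter" (nearest 0.25).
    rng_seed:
        Seed for the single pipeline generator.
    voxel_size_um:
        Physical pixel edge length in micrometres.
    smooth_cutoff_factor:
        Half-gain frequency of the denoising spline, as a multiple of the
        transect's dominant luminance frequency.
    baseline_cutoff_factor:
        Half-gain frequency of the stiff baseline spline (subtracted before
        section statistics), as a multiple of the dominant frequency.
    smooth_lambda:
        Explicit spline penalty overriding the spectral selection, or None.
    """

    n_transects: int = 1000
    transect_thickness_px: int = 10
    n_sections: int = 5
    cutoff_factor: float = 0.5
    min_separation_px: int = 3
    n_slices_per_specimen: int = 30
    rounding_mode: str = "integer"
    rng_seed: int = 0
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    smooth_cutoff_factor: float = 1.25
    baseline_cutoff_factor: float = 0.75
    smooth_lambda: float | None = None

    def __post_init__(self) -> None:
        for name in ("n_transects", "transect_thickness_px", "n_sections",
                     "min_separation_px", "n_slices_per_specimen"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
            setattr(self, name, int(getattr(self, name)))
        if not 0 < self.cutoff_factor <= 1:
            raise ValueError("cutoff_factor must be in (0, 1]")
        if self.rounding_mode not in ROUNDING_MODES:
            raise ValueError(f"rounding_mode must be one of {ROUNDING_MODES}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.smooth_cutoff_factor <= self.baseline_cutoff_factor:
            raise ValueError("smooth_cutoff_factor must exceed baseline_cutoff_factor")

    @property
    def min_separation_um(self) -> float:
        """The minimum event separation expressed in micrometres."""
        return px_to_um(self.min_separation_px, self.voxel_size_um)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
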
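"""Synthetic validation suite: noisy sine patterns and 2D banded phantoms.

The sine suite emulates a radial luminance profile with a known number of
increments: ``true_count`` full sine periods over ``length_px`` samples plus
additive Gaussian noise. The noise level is set by ``snr``, interpreted by
default as the signal's share of the total variance (snr = var_signal /
(var_signal + var_noise), so noise_sd = (amplitude/sqrt(2)) *
sqrt(1/snr - 1)); the simpler amplitude ratio (noise_sd = amplitude/snr)
is available as ``noise_model="amplitude_ratio"``. The robustness sweep
counts 30 replicates per (true count 5..30) x (snr 0.9..0.1) cell and flags
each cell as accurate (|mean - truth| <= 0.5) and robust (SD < 1).

The 2D phantom emulates a straightened cementum band: horizontal light/dark
band pairs with a sinusoidal radial profile, an optional monotone density
gradient rising towards the cemento-dentine side, optional band splitting
(accessory increments) over given column ranges, and additive noise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .counting import RadialProfile, count_transect
from .straighten import StraightenedImage

log = logging.getLogger("cemchron")

NOISE_MODELS = ("variance_fraction", "amplitude_ratio")
DEFAULT_COUNTS = tuple(range(5, 31))
DEFAULT_SNRS = tuple(round(0.9 - 0.1 * i, 1) for i in range(9))  # 0.9 .. 0.1


def noise_sd_for_snr(amplitude: float, snr: float,
                     noise_model: str = "variance_fraction") -> float:
    """Noise SD corresponding to a target snr level."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    if noise_model == "variance_fraction":
        if snr > 1:
            raise ValueError("variance-fraction snr must be in (0, 1]")
        return float(amplitude / np.sqrt(2.0) * np.sqrt(1.0 / snr - 1.0))
    if noise_model == "amplitude_ratio":
        return float(amplitude / snr)
    raise ValueError(f"noise_model must be one of {NOISE_MODELS}")


@dataclasses.dataclass
class SinePattern:
    true_count: int
    length_px: int
    amplitude: float
    snr: float
    noise_sd: float
    values: np.ndarray
    seed: int


@dataclasses.dataclass
class PhantomImage:
    n_pairs: int
    width_px: int
    height_px: int
    gradient: bool
    split_events: list[tuple[int, tuple[int, int]]]
    noise_sd: float
    seed: int
    pixels: np.ndarray
    band_rows: np.ndarray  # centre row of each light band


@dataclasses.dataclass
class RobustnessReport:
    grid: pd.DataFrame  # columns: true_count, snr, mean, sd, accuracy, robustness
    counts: tuple[int, ...]
    snrs: tuple[float, ...]
    replicates: int
    seed: int
    noise_model: str


def make_sine(true_count: int, length_px: int = 1000, amplitude: float = 100.0,
              snr: float = 0.5, seed: int = 0,
              noise_model: str = "variance_fraction") -> SinePattern:
    """Noisy sine luminance pattern with ``true_count`` full periods."""
    if true_count < 1:
        raise ValueError("true_count must be >= 1")
    if length_px < 4 * true_count:
        raise ValueError(
            f"length_px {length_px} too short for {true_count} increments "
            "(need >= 4 samples per period)")
    sd = noise_sd_for_snr(amplitude, snr, noise_model)
    rng = np.random.default_rng(seed)
    t = np.arange(length_px)
    clean = amplitude * np.sin(2.0 * np.pi * true_count * t / length_px)
    raw = clean + (rng.normal(0.0, sd, length_px) if sd > 0 else 0.0)
    values = raw - raw.min() + 1.0  # offset keeps every value positive
    return SinePattern(true_count=true_count, length_px=length_px,
                       amplitude=amplitude, snr=snr, noise_sd=sd,
                       values=values, seed=seed)


def make_phantom(n_pairs: int, width_px: int = 200, height_px: int = 400,
                 gradient: bool = False,
                 split_events: list[tuple[int, tuple[int, int]]] | None = None,
                 noise_sd: float = 0.0, seed: int = 0,
                 amplitude: float = 1000.0) -> PhantomImage:
    """Banded 2D phantom emulating a straightened cementum image.

    Rows are radial depth (row 0 = outer surface, last row = CDJ side);
    ``n_pairs`` light/dark band pairs fill rows 1..height-2 with a
    sinusoidal radial profile starting and ending at a trough, so every
    column shows exactly ``n_pairs`` interior maxima when clean. A one-pixel
    zero margin on the outer and inner edges delimits the tissue extent.
    ``split_events`` lists (light-band index, (col_start, col_stop)) ranges
    over which that band is split in two (an accessory increment),
    adding one local maximum inside the range.
    """
    split_events = list(split_events or [])
    tissue_h = height_px - 2
    if tissue_h < 4 * n_pairs:
        raise ValueError(
            f"height_px {height_px} too small for {n_pairs} band pairs")
    rows = np.arange(tissue_h, dtype=float)
    phase = 2.0 * np.pi * n_pairs * (rows + 0.5) / tissue_h
    # starts and ends at mid-grey so all n_pairs maxima and minima lie in
    # the tissue interior
    radial = amplitude * (1.0 + np.sin(phase)) / 2.0
    base = 2.0 * amplitude
    profile = base + radial
    if gradient:
        profile = profile + 2.0 * amplitude * rows / tissue_h  # rises to CDJ
    img = np.tile(profile[:, None], (1, width_px))
    band_rows = np.array([1 + int(round((j + 0.25) * tissue_h / n_pairs - 0.5))
                          for j in range(n_pairs)])
    period = tissue_h / n_pairs
    for band, (c0, c1) in split_events:
        if not 0 <= band < n_pairs:
            raise ValueError(f"split band index {band} out of range")
        if not 0 <= c0 < c1 <= width_px:
            raise ValueError(f"split column range ({c0}, {c1}) out of range")
        centre = band_rows[band] - 1  # back to tissue coordinates
        width = max(period / 6.0, 1.0)
        dip = 1.5 * amplitude * np.exp(-0.5 * ((rows - centre) / width) ** 2)
        img[:, c0:c1] -= dip[:, None]
    img = np.clip(img, amplitude * 0.05, None)  # keep tissue strictly positive
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    out = np.zeros((height_px, width_px))
    out[1:height_px - 1, :] = img
    return PhantomImage(n_pairs=n_pairs, width_px=width_px,
                        height_px=height_px, gradient=gradient,
                        split_events=split_events, noise_sd=noise_sd,
                        seed=seed, pixels=out, band_rows=band_rows)


def phantom_to_image(phantom: PhantomImage,
                     voxel_size_um: float = 0.66) -> StraightenedImage:
    """Wrap a phantom as a StraightenedImage for the counting pipeline."""
    half = (phantom.height_px - 1) // 2
    pixels = phantom.pixels
    if pixels.shape[0] != 2 * half + 1:  # pad to odd height
        pixels = np.vstack([pixels, np.zeros((1, phantom.width_px))])
        half = (pixels.shape[0] - 1) // 2
    return StraightenedImage(pixels=pixels, half_width_px=half,
                             voxel_size_um=voxel_size_um)


def _cell_seed(master: int, count: int, snr: float, rep: int) -> int:
    ss = np.random.SeedSequence([master, count, int(round(snr * 10)), rep])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def robustness_sweep(cfg: RunConfig | None = None,
                     counts=DEFAULT_COUNTS, snrs=DEFAULT_SNRS,
                     replicates: int = 30, seed: int = 0,
                     length_px: int = 1000, amplitude: float = 100.0,
                     noise_model: str = "variance_fraction"
                     ) -> RobustnessReport:
    """Count sine replicates over the (true count) x (snr) grid.

    Every replicate runs the full transect pipeline (sections, cut-offs,
    rejection rules) via :func:`count_transect`; per-cell seeds derive from
    the master seed so cells are independently reproducible. Per-cell
    errors are recorded as NaN without aborting the sweep.
    """
    cfg = cfg or RunConfig()
    rows = []
    for c in counts:
        for s in snrs:
            estimates = []
            for rep in range(replicates):
                try:
                    pat = make_sine(c, length_px, amplitude, s,
                                    seed=_cell_seed(seed, c, s, rep),
                                    noise_model=noise_model)
                    prof = RadialProfile(values=pat.values)
                    estimates.append(count_transect(prof, cfg))
                except Exception as exc:  # keep sweeping
                    log.warning("cell (count=%d, snr=%.1f, rep=%d) failed: %s",
                                c, s, rep, exc)
                    estimates.append(np.nan)
            est = np.asarray(estimates, float)
            ok = est[np.isfinite(est)]
            mean = float(np.mean(ok)) if ok.size else np.nan
            sd = float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan
            rows.append({"true_count": c, "snr": s, "mean": mean, "sd": sd,
                         "n": int(ok.size),
                         "accuracy": bool(np.isfinite(mean) and abs(mean - c) <= 0.5),
                         "robustness": bool(np.isfinite(sd) and sd < 1.0)})
            log.info("sweep cell count=%d snr=%.1f: mean %.2f sd %.2f",
                     c, s, mean, sd)
    grid = pd.DataFrame(rows)
    return RobustnessReport(grid=grid, counts=tuple(counts),
                            snrs=tuple(snrs), replicates=replicates,
                            seed=seed, noise_model=noise_model)


def assess(report: RobustnessReport) -> dict:
    """Per-snr accuracy and robustness pass rates as a JSON-able summary."""
    grid = report.grid
    if grid.empty:
        raise ValueError("empty robustness grid")
    expected = len(report.counts) * len(report.snrs)
    if len(grid) != expected:
        raise ValueError(
            f"incomplete grid: {len(grid)} cells, expected {expected}")
    per_snr = {}
    for s, grp in grid.groupby("snr"):
        per_snr[f"{s:.1f}"] = {
            "accuracy_rate": float(grp["accuracy"].mean()),
            "robustness_rate": float(grp["robustness"].mean()),
            "max_abs_mean_error": float((grp["mean"] - grp["true_count"]).abs().max()),
            "max_sd": float(grp["sd"].max()),
        }
    return {
        "counts": list(report.counts),
        "replicates": report.replicates,
        "noise_model": report.noise_model,
        "per_snr": dict(sorted(per_snr.items(), reverse=True)),
    }


def save_report(report: RobustnessReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.grid.to_csv(out / "robustness_grid.csv", index=False)
    with open(out / "robustness_summary.json", "w") as fh:
        json.dump(assess(report), fh, indent=2)
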
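"""The semi-automated increment-pair counting algorithm.

A cementum increment pair (one translucent plus one opaque annual layer)
appears along a radial luminance profile as one peak-trough system. The
algorithm estimates the pair count of a straightened slice as follows:

1.  ``sample_transects`` draws random 10-pixel-wide vertical bands and
    averages them into 1D radial profiles (outer surface -> cemento-dentine
    junction). ``screen_lengths`` redraws transects whose tissue extent
    falls below mean - SD of the originally sampled lengths.
2.  Each profile's tissue extent is denoised with a cubic smoothing spline
    (uniform-grid second-difference penalty, solved in the DCT domain) and
    a much stiffer baseline spline is subtracted to remove the overarching
    radial density gradient. The spline penalty is chosen per transect from
    the dominant luminance frequency of its periodogram so that genuine
    increments pass the filter while finer-scale noise does not; an explicit
    penalty can be configured instead.
3.  The profile is split into ``n_sections`` equal sections. Per section,
    the mean and SD of the smoothed values define an upper and lower
    cut-off at mean +/- cutoff_factor * SD. Each above-mean excursion
    contributes at most one candidate peak (its largest maximum - secondary
    "piggy-back" maxima on the same excursion are rejected), counted only
    if it exceeds the upper cut-off; below-mean excursions contribute
    troughs symmetrically.
4.  Counted events closer than ``min_separation_px`` (3 px = 1.98 um at
    0.66 um voxels) are merged, keeping the larger excess. The transect
    pair count is min(#peaks, #troughs) over the ordered event list, plus
    one pair per section boundary where ``boundary_pass`` recovers an
    excursion whose apex/nadir was truncated by the sectioning.
5.  ``count_slice`` averages the pair counts of all transects of a slice;
    ``count_specimen`` averages slice means and rounds.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.fft import dct, idct, rfft, rfftfreq
from scipy.interpolate import make_smoothing_spline

from .config import RunConfig

log = logging.getLogger("cemchron")

PEAK = "peak"
TROUGH = "trough"


# ---------------------------------------------------------------------------
# data containers

@dataclasses.dataclass
class RadialProfile:
    """Mean luminance of one transect band, outer surface first."""

    values: np.ndarray
    origin_column: int = 0
    voxel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and >= 0")

    @property
    def tissue_bounds(self) -> tuple[int, int]:
        """(start, stop) of the non-zero tissue extent."""
        nz = np.flatnonzero(self.values > 0)
        if nz.size == 0:
            return (0, 0)
        return int(nz[0]), int(nz[-1]) + 1

    @property
    def length_px(self) -> int:
        start, stop = self.tissue_bounds
        return stop - start

    @property
    def tissue(self) -> np.ndarray:
        start, stop = self.tissue_bounds
        return self.values[start:stop]


@dataclasses.dataclass
class SectionStats:
    """Smoothed luminance and cut-off statistics of one transect section."""

    start: int
    stop: int
    smoothed: np.ndarray
    mean_g: float = dataclasses.field(init=False)
    sd: float = dataclasses.field(init=False)
    upper_cutoff: float = dataclasses.field(init=False)
    lower_cutoff: float = dataclasses.field(init=False)
    cutoff_factor: dataclasses.InitVar[float] = 0.5

    def __post_init__(self, cutoff_factor: float) -> None:
        self.smoothed = np.asarray(self.smoothed, float)
        self.mean_g = float(np.mean(self.smoothed))
        self.sd = float(np.std(self.smoothed, ddof=1)) if len(self.smoothed) > 1 else 0.0
        self.upper_cutoff = self.mean_g + cutoff_factor * self.sd
        self.lower_cutoff = self.mean_g - cutoff_factor * self.sd


@dataclasses.dataclass(frozen=True)
class ExtremumEvent:
    kind: str  # PEAK or TROUGH
    position_px: int  # index along the tissue profile
    value: float  # smoothed luminance at the extremum
    excess: float  # |value - section mean|


@dataclasses.dataclass
class IncrementEstimate:
    """Pair-count estimate at transect, slice or specimen level."""

    label: str = ""
    per_transect_pairs: list[int] | None = None
    slice_mean: float | None = None
    slice_sd: float | None = None
    slice_means: list[float] | None = None
    specimen_mean: float | None = None
    specimen_count: float | None = None
    rounding_mode: str = "integer"

    @property
    def n(self) -> int:
        if self.per_transect_pairs is not None:
            return len(self.per_transect_pairs)
        if self.slice_means is not None:
            return len(self.slice_means)
        return 0


# ---------------------------------------------------------------------------
# smoothing-spline machinery

def penalized_smooth(values: np.ndarray, lam: float) -> np.ndarray:
    """Cubic smoothing spline on a uniform grid via its DCT diagonalisation.

    Minimises ||s - y||^2 + lam * ||D2 s||^2 (second differences, reflecting
    boundaries); equivalent filter gain 1/(1 + lam * (2 - 2 cos w)^2).
    """
    y = np.asarray(values, float)
    n = len(y)
    if n < 2:
        return y.copy()
    k = np.arange(n)
    gain = 1.0 / (1.0 + lam * (2.0 - 2.0 * np.cos(np.pi * k / n)) ** 2)
    return idct(dct(y, norm="ortho") * gain, norm="ortho")


def lambda_for_cutoff(freq: float) -> float:
    """Penalty whose equivalent filter has half gain at ``freq`` (cycles/px)."""
    if freq <= 0:
        raise ValueError("cutoff frequency must be positive")
    return 1.0 / (2.0 - 2.0 * np.cos(np.pi * min(2.0 * freq, 1.0))) ** 2


def dominant_frequency(values: np.ndarray, max_freq: float = 1.0 / 6.0) -> float:
    """Dominant periodicity of a profile, in cycles/pixel.

    The linearly detrended periodogram is searched in (0, max_freq]; the
    default ceiling 1/6 cycles/px mirrors the 3-px minimum event separation
    (a genuine peak-trough system spans at least 6 px). Falls back to one
    cycle per profile length for structureless input.
    """
    y = np.asarray(values, float)
    n = len(y)
    if n < 4:
        return 1.0 / max(n, 1)
    x = np.arange(n)
    y = y - np.polyval(np.polyfit(x, y, 1), x)
    power = np.abs(rfft(y)) ** 2
    freqs = rfftfreq(n)
    band = (freqs > 0) & (freqs <= max_freq)
    if not np.any(band) or np.all(power[band] == 0):
        return 1.0 / n
    return float(max(freqs[band][np.argmax(power[band])], 1.0 / n))


def smooth_section(values: np.ndarray, lam: float | None = None
                   ) -> tuple[np.ndarray, SectionStats]:
    """Smooth one section and compute its statistics.

    With ``lam`` given, the uniform-grid penalized spline is used; with
    ``lam=None`` the smoothing parameter is chosen by generalized
    cross-validation (scipy's smoothing-spline fit).
    """
    y = np.asarray(values, float)
    if len(y) < 4:
        raise ValueError("section too short to smooth (< 4 samples)")
    if np.ptp(y) == 0:
        smoothed = y.copy()
    elif lam is None:
        x = np.arange(len(y), dtype=float)
        smoothed = make_smoothing_spline(x, y)(x)
    else:
        smoothed = penalized_smooth(y, lam)
    return smoothed, SectionStats(0, len(y), smoothed)


# ---------------------------------------------------------------------------
# transect sampling and screening

def sample_transects(image, n: int, thickness_px: int,
                     rng: np.random.Generator) -> list[RadialProfile]:
    """Draw ``n`` random vertical bands (with replacement) and average each
    into a radial profile."""
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels, float)
    voxel = getattr(image, "voxel_size_um", None)
    width = pixels.shape[1]
    if width < thickness_px:
        raise ValueError(
            f"image width {width} narrower than transect thickness {thickness_px}")
    cols = rng.integers(0, width - thickness_px + 1, size=n)
    return [RadialProfile(values=pixels[:, c:c + thickness_px].mean(axis=1),
                          origin_column=int(c), voxel_size_um=voxel)
            for c in cols]


def screen_lengths(profiles: list[RadialProfile], image, cfg: RunConfig,
                   rng: np.random.Generator) -> list[RadialProfile]:
    """Redraw transects whose tissue extent is an outlier on the short side.

    The threshold T = mean - SD of the *original* sample's lengths is
    computed once; short transects are resampled until all lengths >= T,
    capped at 100 * n redraws.
    """
    if len(profiles) < 2:
        raise ValueError("screening needs >= 2 profiles")
    lengths = np.array([p.length_px for p in profiles], float)
    if np.all(lengths == 0):
        raise ValueError("no pixel above zero in any transect")
    threshold = float(np.mean(lengths) - np.std(lengths, ddof=1))
    n = len(profiles)
    out = list(profiles)
    rejected = [i for i in range(n) if lengths[i] < threshold]
    draws = 0
    best = float(np.max(lengths))
    for i in rejected:
        while True:
            if draws >= 100 * n:
                raise RuntimeError(
                    f"length screening exhausted {100 * n} redraws "
                    f"(threshold {threshold:.2f} px, best length {best:.0f} px)")
            cand = sample_transects(image, 1, cfg.transect_thickness_px, rng)[0]
            draws += 1
            best = max(best, cand.length_px)
            if cand.length_px >= threshold:
                out[i] = cand
                break
    log.info("length screening: %d/%d transects redrawn (threshold %.1f px)",
             len(rejected), n, threshold)
    return out


def split_sections(profile: RadialProfile | np.ndarray, k: int
                   ) -> list[tuple[int, int]]:
    """(start, stop) bounds of ``k`` near-equal sections of the tissue extent.

    Section lengths differ by at most one pixel; the remainder goes to the
    innermost (cemento-dentine junction side) sections, where the oldest
    and thinnest increments sit.
    """
    if isinstance(profile, RadialProfile):
        start, stop = profile.tissue_bounds
    else:
        start, stop = 0, len(profile)
    length = stop - start
    if length < k:
        raise ValueError(f"tissue extent {length} px shorter than {k} sections")
    base, rem = divmod(length, k)
    sizes = [base] * (k - rem) + [base + 1] * rem
    bounds = []
    pos = start
    for s in sizes:
        bounds.append((pos, pos + s))
        pos += s
    return bounds


# ---------------------------------------------------------------------------
# event detection

def _excursion_events(smoothed: np.ndarray, stats: SectionStats,
                      offset: int = 0) -> list[ExtremumEvent]:
    """One candidate event per above-/below-mean excursion of a section.

    The candidate is the excursion's largest maximum (smallest minimum),
    with plateau centres as the extremum index; it is counted only when it
    passes the section's cut-off. Excursions truncated by the section edge
    whose extremum falls on the edge sample are left to the boundary pass.
    """
    s = np.asarray(smoothed, float)
    n = len(s)
    above = s > stats.mean_g
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    events: list[ExtremumEvent] = []
    for a, b in zip(starts, ends):
        seg = s[a:b]
        if above[a]:
            ext = np.flatnonzero(seg == seg.max())
            i = a + int(ext[len(ext) // 2])
            if s[i] > stats.upper_cutoff and i != 0 and i != n - 1:
                events.append(ExtremumEvent(PEAK, i + offset, float(s[i]),
                                            float(s[i] - stats.mean_g)))
        else:
            ext = np.flatnonzero(seg == seg.min())
            i = a + int(ext[len(ext) // 2])
            if s[i] < stats.lower_cutoff and i != 0 and i != n - 1:
                events.append(ExtremumEvent(TROUGH, i + offset, float(s[i]),
                                            float(stats.mean_g - s[i])))
    return events


def _merge_min_separation(events: list[ExtremumEvent],
                          sep: int) -> list[ExtremumEvent]:
    """Merge counted events closer than ``sep`` px, keeping the larger excess
    (ties: the earlier event)."""
    out: list[ExtremumEvent] = []
    for ev in sorted(events, key=lambda e: e.position_px):
        if out and ev.position_px - out[-1].position_px < sep:
            if ev.excess > out[-1].excess:
                out[-1] = ev
        else:
            out.append(ev)
    return out


def detect_pairs(stats: SectionStats, min_separation_px: int = 3
                 ) -> tuple[list[ExtremumEvent], int]:
    """Counted events and pair count of a single section.

    The pair count is min(#peaks, #troughs): only one peak is counted for
    every trough.
    """
    events = _excursion_events(stats.smoothed, stats, offset=stats.start)
    events = _merge_min_separation(events, min_separation_px)
    n_peaks = sum(1 for e in events if e.kind == PEAK)
    return events, min(n_peaks, len(events) - n_peaks)


def boundary_pass(left: SectionStats, right: SectionStats,
                  events: list[ExtremumEvent]) -> int:
    """Recover one pair for an excursion split across a section boundary.

    The terminal limb of the left section (beyond its last counted event)
    and the initial limb of the right section are concatenated; if they
    form an interior excursion whose apex crosses the upper cut-off of one
    flanking section while the limb base crosses the lower cut-off of the
    other (or the mirrored nadir case), and that apex/nadir was counted in
    neither section, one pair is added. At most one pair per boundary.
    """
    lev = [e for e in events if left.start <= e.position_px < left.stop]
    rev = [e for e in events if right.start <= e.position_px < right.stop]
    tail = (lev[-1].position_px - left.start + 1) if lev else 0
    head = (rev[0].position_px - right.start) if rev else (right.stop - right.start)
    seg = np.concatenate([left.smoothed[tail:], right.smoothed[:head]])
    if len(seg) < 3:
        return 0
    ai = int(np.argmax(seg))
    ni = int(np.argmin(seg))
    smax, smin = float(seg[ai]), float(seg[ni])
    crest = (0 < ai < len(seg) - 1
             and ((smax > left.upper_cutoff and smin < right.lower_cutoff)
                  or (smax > right.upper_cutoff and smin < left.lower_cutoff))
             and seg[0] < left.mean_g and seg[-1] < right.mean_g)
    if crest:
        return 1
    nadir = (0 < ni < len(seg) - 1
             and ((smin < left.lower_cutoff and smax > right.upper_cutoff)
                  or (smin < right.lower_cutoff and smax > left.upper_cutoff))
             and seg[0] > left.mean_g and seg[-1] > right.mean_g)
    return 1 if nadir else 0


# ---------------------------------------------------------------------------
# transect / slice / specimen counting

def transect_sections(profile: RadialProfile, cfg: RunConfig
                      ) -> tuple[list[SectionStats], np.ndarray]:
    """Smooth a transect's tissue extent and build its section statistics.

    One spline fit covers the whole tissue extent (per-section fits would
    flatten extrema near section edges at noise-scale smoothing); a stiff
    baseline spline is subtracted to remove the radial density gradient.
    Section bounds are relative to the tissue extent.
    """
    tissue = profile.tissue
    k = cfg.n_sections
    if len(tissue) < 4 * k:
        raise ValueError(
            f"tissue extent {len(tissue)} px too short for {k} sections "
            "of >= 4 px")
    if cfg.smooth_lambda is not None:
        smoothed = penalized_smooth(tissue, cfg.smooth_lambda)
    else:
        f0 = dominant_frequency(tissue,
                                max_freq=1.0 / (2 * cfg.min_separation_px))
        smoothed = penalized_smooth(
            tissue, lambda_for_cutoff(cfg.smooth_cutoff_factor * f0))
        # the baseline spline uses natural boundary conditions (free edge
        # slope): the DCT smoother's implicit reflection would bias the
        # baseline wherever the tissue edge sits away from the local mean
        fb = cfg.baseline_cutoff_factor * f0
        x = np.arange(len(tissue), dtype=float)
        baseline = make_smoothing_spline(
            x, tissue, lam=1.0 / (2.0 * np.pi * fb) ** 4)(x)
        smoothed = smoothed - baseline + float(np.mean(tissue))
    bounds = split_sections(tissue, k)
    sections = [SectionStats(a, b, smoothed[a:b],
                             cutoff_factor=cfg.cutoff_factor)
                for a, b in bounds]
    return sections, smoothed


def count_transect(profile: RadialProfile, cfg: RunConfig) -> int:
    """Increment-pair count of one screened transect."""
    sections, _ = transect_sections(profile, cfg)
    events: list[ExtremumEvent] = []
    for sec in sections:
        events.extend(_excursion_events(sec.smoothed, sec, offset=sec.start))
    events = _merge_min_separation(events, cfg.min_separation_px)
    n_peaks = sum(1 for e in events if e.kind == PEAK)
    pairs = min(n_peaks, len(events) - n_peaks)
    for left, right in zip(sections[:-1], sections[1:]):
        pairs += boundary_pass(left, right, events)
    return pairs


def count_slice(image, cfg: RunConfig,
                rng: np.random.Generator | None = None,
                label: str = "") -> IncrementEstimate:
    """Estimate a slice's pair count from ``cfg.n_transects`` random
    transects (mean and SD over all accepted transects)."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    profiles = sample_transects(image, cfg.n_transects,
                                cfg.transect_thickness_px, rng)
    if len(profiles) >= 2:
        profiles = screen_lengths(profiles, image, cfg, rng)
    counts = [count_transect(p, cfg) for p in profiles]
    sd = float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0
    return IncrementEstimate(label=label, per_transect_pairs=counts,
                             slice_mean=float(np.mean(counts)), slice_sd=sd,
                             rounding_mode=cfg.rounding_mode)


def _round_half_away(x: float) -> float:
    return np.floor(x + 0.5) if x >= 0 else -np.floor(-x + 0.5)


def count_specimen(slice_estimates: list[IncrementEstimate],
                   rounding_mode: str = "integer",
                   label: str = "") -> IncrementEstimate:
    """Aggregate slice estimates into a specimen count.

    The specimen mean is the mean of the slice means, rounded to the
    nearest integer (default) or nearest 0.25 ("quarter" mode); half-way
    ties round away from zero.
    """
    if not slice_estimates:
        raise ValueError("no slice estimates")
    means = [float(e.slice_mean) for e in slice_estimates]
    mean = float(np.mean(means))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    if rounding_mode == "integer":
        count = float(_round_half_away(mean))
    elif rounding_mode == "quarter":
        count = float(_round_half_away(mean * 4.0) / 4.0)
    else:
        raise ValueError(f"unknown rounding mode {rounding_mode!r}")
    return IncrementEstimate(label=label, slice_means=means,
                             slice_sd=sd, specimen_mean=mean,
                             specimen_count=count, rounding_mode=rounding_mode)
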
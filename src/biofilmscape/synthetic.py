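"""Synthetic biofilm landscapes, CE-SSCP profiles and disturbance series.

The generators emulate the statistical structure the analysis pipeline
assumes, so the whole pipeline runs and is testable without any external
data:

* **Landscape images** — a smooth biomass field (base film + a number of
  bump-like structures growing with a complexity parameter ``c`` + smoothed
  noise) rendered as an 8-bit transmitted-light image (dense biomass dark)
  and an oblique-illumination image (dense biomass bright).
* **Fingerprint profiles** — a fixed species pool rendered as Gaussian peaks
  on a scan-position axis with a per-run migration shift and mild
  nonlinearity, plus a synthetic internal size-standard ladder channel, so
  alignment against the ladder is a real operation.
* **Disturbance series** — biocide pulses shift the abundance distribution of
  the fixed pool toward single-species dominance (the dominant member jumps
  to relative abundance ``rho``); between pulses the community relaxes
  exponentially (time constant ``tau``) back toward its undisturbed
  abundance vector.  Composition (the presence set) never changes under the
  default settings: disturbance acts on abundances only.  Morphological
  complexity follows the same relaxation clock, which makes a
  morphology-community correlation plantable.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .dynamics import DisturbanceSchedule
from .fingerprints import RawProfile, SizeStandard
from .texture import GrayImage

__all__ = [
    "LandscapeParams",
    "CommunityParams",
    "SimSeriesParams",
    "SimulatedSample",
    "LADDER_SIZES",
    "derive_seed",
    "geometric_abundances",
    "geometric_simpson_lambda",
    "generate_landscape_image",
    "generate_profile",
    "make_standard",
    "weekly_schedule",
    "daily_schedule",
    "latent_state",
    "simulate_disturbance_series",
]

#: Fragment sizes of the synthetic internal-standard ladder (arbitrary size units).
LADDER_SIZES = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0, 400.0, 450.0, 500.0)


def derive_seed(master: int, *tokens) -> int:
    """Stable per-stage/per-sample seed below 2^31 derived from a master seed."""
    h = zlib.crc32("|".join(str(t) for t in tokens).encode())
    return (int(master) ^ h) % (2 ** 31)


# ---------------------------------------------------------------------------
# landscape images


@dataclass
class LandscapeParams:
    """Controls of the synthetic biofilm landscape renderer.

    ``complexity`` in [0, 1] sets the number of protruding structures
    (``round(c * n_structures_max)``); 0 renders a bare base film.
    """

    complexity: float = 0.5
    dims: tuple[int, int] = (512, 512)  # rows, cols
    base_biomass: float = 0.15
    n_structures_max: int = 40
    amp_range: tuple[float, float] = (0.25, 0.7)
    width_range_px: tuple[float, float] = (8.0, 40.0)
    noise_sd: float = 0.02
    pixel_size_um: float = 2.92
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.complexity <= 1.0:
            raise ValueError("complexity must lie in [0, 1]")
        if self.dims[0] < 64 or self.dims[1] < 64:
            raise ValueError("image dims must be at least 64x64")


def generate_landscape_image(p: LandscapeParams, sample_id: str = "",
                             location_index: int = 0) -> dict[str, GrayImage]:
    """Render one transmitted/oblique image pair of a synthetic landscape.

    The biomass field is ``base + structures + smoothed noise``; transmitted
    intensity is ``255 (1 - biomass)`` (light absorbed where biomass is
    dense), oblique intensity is a differently gained ``biomass`` rendering
    (inclined light refracted toward the camera).  All structure parameters
    for ``n_structures_max`` bumps are drawn before selecting the first
    ``round(c * n_max)``, so at a fixed seed a higher complexity only adds
    biomass — the transmitted mean gray decreases monotonically with ``c``.
    """
    rng = np.random.default_rng(p.seed)
    nr, nc = p.dims
    n_max = p.n_structures_max
    rows = rng.uniform(0, nr, size=n_max)
    cols = rng.uniform(0, nc, size=n_max)
    amps = rng.uniform(*p.amp_range, size=n_max)
    widths = rng.uniform(*p.width_range_px, size=n_max)
    noise = rng.normal(0.0, 1.0, size=(nr, nc))

    n_struct = int(round(p.complexity * n_max))
    rr = np.arange(nr)[:, None]
    cc = np.arange(nc)[None, :]
    biomass = np.full((nr, nc), p.base_biomass)
    for k in range(n_struct):
        d2 = (rr - rows[k]) ** 2 + (cc - cols[k]) ** 2
        biomass += amps[k] * np.exp(-d2 / (2.0 * widths[k] ** 2))
    if p.noise_sd > 0:
        biomass += p.noise_sd * gaussian_filter(noise, sigma=2.0)
    biomass = np.clip(biomass, 0.0, 1.0)

    trans = np.clip(np.rint(255.0 * (1.0 - biomass)), 0, 255).astype(np.uint8)
    obli = np.clip(np.rint(255.0 * 0.85 * biomass), 0, 255).astype(np.uint8)
    return {
        "transmitted": GrayImage(trans, "transmitted", p.pixel_size_um,
                                 sample_id, location_index),
        "oblique": GrayImage(obli, "oblique", p.pixel_size_um,
                             sample_id, location_index),
    }


# ---------------------------------------------------------------------------
# fingerprint profiles


@dataclass
class CommunityParams:
    """Fixed species pool rendered as CE-SSCP peaks.

    ``dominance_k`` is the ratio of the geometric abundance series: small k
    means strong single-species dominance, k near 1 an even community.
    """

    pool_size: int = 20
    peak_positions: np.ndarray | None = None  # size-coordinate units
    dominance_k: float = 0.85
    dominant_index: int = 0
    peak_width: float = 3.0  # size units
    baseline_level: float = 0.02
    noise_sd: float = 0.004
    n_scan: int = 3000
    scan_per_size: float = 5.0
    migration_jitter: float = 20.0  # scan units, per-sample shift sd
    curvature: float = 2e-5  # mild nonlinearity of the size->scan map
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if not 0.0 < self.dominance_k < 1.0:
            raise ValueError("dominance_k must lie in (0, 1)")
        if self.peak_positions is None:
            self.peak_positions = np.linspace(110.0, 470.0, self.pool_size)
        else:
            self.peak_positions = np.asarray(self.peak_positions, dtype=float)
            if self.peak_positions.size != self.pool_size:
                raise ValueError("peak_positions must have pool_size entries")


def geometric_abundances(pool_size: int, k: float,
                         dominant_index: int = 0) -> np.ndarray:
    """Normalized geometric abundance series, the dominant species first.

    ``a_i = (1-k) k^(i-1) / (1-k^S)``; the largest share is moved to
    ``dominant_index``.
    """
    i = np.arange(pool_size)
    a = (1.0 - k) * k ** i / (1.0 - k ** pool_size)
    a = np.roll(a, dominant_index)
    return a / a.sum()


def geometric_simpson_lambda(pool_size: int, k: float) -> float:
    """Closed-form Simpson concentration of the geometric series."""
    num = (1.0 - k) ** 2 * (1.0 - k ** (2 * pool_size))
    den = (1.0 - k ** 2) * (1.0 - k ** pool_size) ** 2
    return num / den


def _scan_of_size(cp: CommunityParams, size: np.ndarray,
                  shift: float) -> np.ndarray:
    s = np.asarray(size, dtype=float)
    return cp.scan_per_size * s + cp.curvature * cp.scan_per_size * s ** 2 + shift


def make_standard(cp: CommunityParams, shift: float = 0.0) -> SizeStandard:
    """Ground-truth ladder mapping for one run (known sizes -> scan positions)."""
    sizes = np.asarray(LADDER_SIZES)
    return SizeStandard(known_sizes=sizes,
                        detected_positions=_scan_of_size(cp, sizes, shift))


def generate_profile(cp: CommunityParams, abundances: Sequence[float],
                     sample_id: str = "", day: float = 0.0, reactor: str = "",
                     seed: int | None = None) -> tuple[RawProfile, SizeStandard]:
    """Render one raw electropherogram plus its internal-standard channel.

    ``abundances`` (unit sum, one entry per pool member) set the Gaussian
    peak masses; a per-sample migration shift displaces the whole trace, the
    ladder channel carries synthetic standard spikes at the shifted
    positions, and mild baseline plus white noise are added.
    """
    a = np.asarray(abundances, dtype=float)
    if a.size != cp.pool_size:
        raise ValueError("abundances length must equal pool_size")
    if abs(a.sum() - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    rng = np.random.default_rng(cp.seed if seed is None else seed)
    shift = rng.normal(0.0, cp.migration_jitter)
    scan = np.arange(cp.n_scan, dtype=float)
    width_scan = cp.peak_width * cp.scan_per_size
    centers = _scan_of_size(cp, cp.peak_positions, shift)
    intensity = np.zeros(cp.n_scan)
    for ai, c in zip(a, centers):
        intensity += ai * np.exp(-0.5 * ((scan - c) / width_scan) ** 2)
    intensity /= width_scan * np.sqrt(2.0 * np.pi)  # unit-mass peaks in scan units
    peak_scale = intensity.max() if intensity.max() > 0 else 1.0
    baseline = cp.baseline_level * peak_scale * (
        1.0 + 0.2 * np.sin(2.0 * np.pi * scan / cp.n_scan))
    noisy = intensity + baseline + rng.normal(0.0, cp.noise_sd * peak_scale,
                                              size=cp.n_scan)
    std_sizes = np.asarray(LADDER_SIZES)
    std_centers = _scan_of_size(cp, std_sizes, shift)
    std_channel = np.zeros(cp.n_scan)
    for c in std_centers:
        std_channel += np.exp(-0.5 * ((scan - c) / 3.0) ** 2)
    raw = RawProfile(intensity=noisy, standard_intensity=std_channel,
                     sample_id=sample_id, day=day, reactor=reactor)
    std = SizeStandard(known_sizes=std_sizes, detected_positions=std_centers)
    return raw, std


def detect_standard(raw: RawProfile, known_sizes: Sequence[float]) -> SizeStandard:
    """Recover ladder scan positions from the standard channel by peak calling."""
    from scipy.signal import find_peaks

    known = np.asarray(known_sizes, dtype=float)
    smoothed = gaussian_filter1d(raw.standard_intensity, 1.0)
    idx, props = find_peaks(smoothed, height=0.2 * smoothed.max(), distance=10)
    if idx.size < known.size:
        raise ValueError("fewer standard peaks detected than ladder sizes")
    order = np.argsort(props["peak_heights"])[::-1][:known.size]
    pos = np.sort(idx[order]).astype(float)
    return SizeStandard(known_sizes=known, detected_positions=pos)


# ---------------------------------------------------------------------------
# disturbance / recovery series


def weekly_schedule(start: float, n_pulses: int,
                    window_pad: float = 7.0) -> DisturbanceSchedule:
    pulses = start + 7.0 * np.arange(n_pulses)
    return DisturbanceSchedule(pulse_days=pulses,
                               window=(start, pulses[-1] + window_pad),
                               frequency="weekly")


def daily_schedule(start: float, n_pulses: int,
                   window_pad: float = 1.0) -> DisturbanceSchedule:
    pulses = start + 1.0 * np.arange(n_pulses)
    return DisturbanceSchedule(pulse_days=pulses,
                               window=(start, pulses[-1] + window_pad),
                               frequency="daily")


@dataclass
class SimSeriesParams:
    """Latent disturbance/recovery dynamics shared by community and morphology.

    At each biocide pulse the dominant pool member's relative abundance jumps
    to ``rho`` and morphological complexity drops by the factor
    ``complexity_drop``; both relax exponentially with time constant ``tau``
    (days) toward their undisturbed levels between pulses.
    """

    schedule: DisturbanceSchedule = field(
        default_factory=lambda: weekly_schedule(21.0, 5))
    rho: float = 0.6
    tau: float = 2.0
    sampling_days: np.ndarray | None = None
    complexity_drop: float = 0.7  # fraction of complexity removed by a pulse
    baseline_complexity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must lie in (0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sampling_days is None:
            end = self.schedule.window[1]
            self.sampling_days = np.arange(0.0, end + 1.0)
        else:
            self.sampling_days = np.asarray(self.sampling_days, dtype=float)


@dataclass
class SimulatedSample:
    """One rendered sampling day with its ground-truth latent state."""

    day: float
    raw_profile: RawProfile
    standard: SizeStandard
    images: dict[str, GrayImage] | None
    true_abundances: np.ndarray
    true_complexity: float
    true_dominant_fraction: float


def latent_state(sp: SimSeriesParams, cp: CommunityParams,
                 day: float) -> tuple[np.ndarray, float]:
    """Undisturbed-or-relaxing latent abundances and complexity at one day.

    Between pulses the state is ``a0 + (a_pulse - a0) exp(-dt/tau)`` where
    ``a_pulse`` moves the dominant member to ``rho`` and rescales the rest;
    the presence set is unchanged (disturbance shifts abundances only).
    """
    a0 = geometric_abundances(cp.pool_size, cp.dominance_k, cp.dominant_index)
    c0 = sp.baseline_complexity
    past = sp.schedule.pulse_days[sp.schedule.pulse_days <= day]
    if past.size == 0:
        return a0, c0
    dt = day - past[-1]
    decay = np.exp(-dt / sp.tau)
    dom = cp.dominant_index
    a_pulse = a0 * (1.0 - sp.rho) / (1.0 - a0[dom])
    a_pulse[dom] = sp.rho
    a = a0 + (a_pulse - a0) * decay
    a = a / a.sum()
    c_pulse = c0 * (1.0 - sp.complexity_drop)
    c = c0 + (c_pulse - c0) * decay
    return a, float(np.clip(c, 0.0, 1.0))


def simulate_disturbance_series(sp: SimSeriesParams, cp: CommunityParams,
                                lp: LandscapeParams | None = None,
                                render_images: bool = False,
                                n_locations: int = 2,
                                reactor: str = "R1") -> list[SimulatedSample]:
    """Render profiles (and optionally image pairs) along a sampling schedule.

    Each sampling day draws its own derived seed from ``sp.seed``, so series
    are bit-reproducible while days stay independent.  Sampling days must lie
    inside [0, window end].
    """
    # sampling may extend past the treatment window (post-treatment recovery
    # phase) but never precede the experiment start
    if np.any(sp.sampling_days < 0.0):
        raise ValueError("sampling days precede the schedule window")
    out = []
    for day in sp.sampling_days:
        a, c = latent_state(sp, cp, day)
        sid = f"{reactor}_d{day:g}"
        raw, std = generate_profile(cp, a, sample_id=sid, day=float(day),
                                    reactor=reactor,
                                    seed=derive_seed(sp.seed, "profile", reactor, day))
        images = None
        if render_images:
            base = lp if lp is not None else LandscapeParams()
            images = {}
            for loc in range(n_locations):
                ip = replace(base, complexity=c,
                             seed=derive_seed(sp.seed, "image", reactor, day, loc))
                images[loc] = generate_landscape_image(ip, sample_id=sid,
                                                       location_index=loc)
        out.append(SimulatedSample(day=float(day), raw_profile=raw, standard=std,
                                   images=images, true_abundances=a,
                                   true_complexity=c,
                                   true_dominant_fraction=float(a[cp.dominant_index])))
    return out
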
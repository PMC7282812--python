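"""Synthetic inputs for every stage of the pipeline.

Three classes of study input are emulated so the whole analysis chain is
testable without any measured data:

* two-channel confocal z-stacks of striated myofibers, built from a
  periodic sarcomere density model (Z-line spike, I-band band,
  terminal-cisternae doublet, scattered clusters), blurred with a Gaussian
  PSF surrogate, mixed between channels with known bleed-through, and
  corrupted with Poisson + Gaussian read noise — with full ground truth;
* gel / blot scan pairs with known per-lane protein amounts and loading
  factors, for densitometry;
* patient cohorts with the group effects and correlation structure of the
  study population (Gaussian copula over log-normal contents), plus
  nested replicate tables for variance-component analysis.

All generators take an explicit integer seed; one seed fans out
deterministically to per-component streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .restoration import ZStack

__all__ = [
    "MotifComponent",
    "zline_spike",
    "iband_band",
    "tc_doublet",
    "cluster_patches",
    "NoiseModel",
    "FiberImageParams",
    "GroundTruth",
    "simulate_fiber_stack",
    "GelBlotParams",
    "GelBlotFixture",
    "simulate_gel_blot",
    "CohortParams",
    "simulate_cohort",
    "effective_correlation_targets",
    "TABLE1_EFFECTS",
    "CORRELATION_TARGETS",
    "COHORT_VARIABLES",
    "ReplicateParams",
    "simulate_replicate_table",
]


# ---------------------------------------------------------------------------
# fiber stacks


@dataclass(frozen=True)
class MotifComponent:
    """One structural element of the periodic sarcomere motif.

    ``center_um`` is the position within one period, measured from the
    Z line (period boundaries at integer multiples of the sarcomere
    length).  Kinds:

    - ``"band"``: Gaussian band of given FWHM along x, uniform in y, z;
    - ``"doublet"``: two Gaussian lines at center ± separation/2 (the
      terminal-cisternae pair of a triad);
    - ``"clusters"``: randomly scattered 3-D Gaussian spots of given
      density, not periodic.
    """

    kind: str  # band | doublet | clusters
    amplitude: float  # photons/voxel at peak
    center_um: float = 0.0
    fwhm_um: float = 0.4
    separation_nm: float = 200.0
    line_fwhm_nm: float = 80.0
    density_per_um3: float = 0.05
    spot_sigma_nm: float = 80.0

    def __post_init__(self) -> None:
        if self.kind not in ("band", "doublet", "clusters"):
            raise ValueError(f"unknown motif kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def zline_spike(amplitude: float, fwhm_um: float = 0.12) -> MotifComponent:
    """Narrow band at the Z line."""
    return MotifComponent("band", amplitude, center_um=0.0, fwhm_um=fwhm_um)


def iband_band(amplitude: float, fwhm_um: float, center_um: float = 0.0) -> MotifComponent:
    """Band occupying the interior of the I band (straddling the Z line)."""
    return MotifComponent("band", amplitude, center_um=center_um, fwhm_um=fwhm_um)


def tc_doublet(
    amplitude: float,
    separation_nm: float = 200.0,
    center_um: float = 0.0,
    line_fwhm_nm: float = 80.0,
) -> MotifComponent:
    """Terminal-cisternae doublet: two lines flanking the Z line."""
    return MotifComponent(
        "doublet",
        amplitude,
        center_um=center_um,
        separation_nm=separation_nm,
        line_fwhm_nm=line_fwhm_nm,
    )


def cluster_patches(
    amplitude: float, density_per_um3: float = 0.05, spot_sigma_nm: float = 80.0
) -> MotifComponent:
    """Scattered punctate component (e.g. extra-triadic protein patches)."""
    return MotifComponent(
        "clusters",
        amplitude,
        density_per_um3=density_per_um3,
        spot_sigma_nm=spot_sigma_nm,
    )


@dataclass(frozen=True)
class NoiseModel:
    poisson: bool = True
    read_sigma: float = 2.0  # counts

    def __post_init__(self) -> None:
        if self.read_sigma < 0:
            raise ValueError("read noise sigma must be >= 0")


@dataclass
class FiberImageParams:
    """Forward-model parameters of a two-channel striated-fiber stack.

    Defaults follow the high-resolution acquisition geometry: 20 planes at
    120 nm z separation, 36 nm x-y pixels, ~100 nm lateral resolution.
    """

    sarcomere_length: float = 2.0  # µm
    structure_templates: list[list[MotifComponent]] = field(
        default_factory=lambda: [
            [iband_band(80.0, fwhm_um=1.26)],          # all-forms enzyme band
            [tc_doublet(100.0, separation_nm=200.0)],  # phospho form at the TC
        ]
    )
    background: float = 10.0  # photons/voxel
    psf_sigma: tuple[float, float, float] = (42.0, 42.0, 150.0)  # (sx, sy, sz) nm
    bleedthrough: tuple[float, float] = (0.0, 0.0)  # (b12, b21)
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    voxel_size: tuple[float, float] = (36.0, 120.0)  # (dxy, dz) nm
    grid_shape: tuple[int, int, int] = (20, 64, 256)  # (nz, ny, nx)

    def __post_init__(self) -> None:
        if self.sarcomere_length <= 0:
            raise ValueError("sarcomere length must be positive")
        b12, b21 = self.bleedthrough
        if not (0 <= b12 < 1 and 0 <= b21 < 1 and b12 * b21 < 1):
            raise ValueError("bleed-through coefficients must be in [0,1) with b12*b21 < 1")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        nz, ny, nx = self.grid_shape
        dxy, _ = self.voxel_size
        if nx * dxy * 1e-3 < self.sarcomere_length:
            raise ValueError(
                "grid too small to cover one sarcomere period along x: "
                f"{nx * dxy * 1e-3:.2f} µm < {self.sarcomere_length:.2f} µm"
            )


@dataclass
class GroundTruth:
    """Noiseless provenance of a simulated stack.

    ``density`` is the per-channel marker density before blurring;
    ``blurred`` the same after PSF convolution (no mixing, background or
    noise); ``object_centers`` lists (z, y, x) nm for every discrete
    structure rendered (doublet lines, cluster spots).
    """

    density: np.ndarray  # (channel, z, y, x)
    blurred: np.ndarray  # (channel, z, y, x)
    object_centers: list[list[tuple[float, float, float]]]
    params: FiberImageParams


_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _periodic_gaussian_sum(d: np.ndarray, period: float, sigma: float) -> np.ndarray:
    prof = np.exp(-0.5 * (d / sigma) ** 2)
    # neighbouring repeats contribute when fwhm ~ period
    for k in (-1.0, 1.0):
        prof += np.exp(-0.5 * ((d + k * period) / sigma) ** 2)
    return prof


def _measured_fwhm_of_periodic(period: float, sigma: float) -> float:
    """FWHM of one repeat of the periodic profile, above its inter-peak floor."""
    x = np.linspace(-period / 2, period / 2, 4001)
    prof = _periodic_gaussian_sum(x, period, sigma)
    lo, hi = prof.min(), prof.max()
    half = lo + 0.5 * (hi - lo)
    above = prof >= half
    return float(x[above][-1] - x[above][0])


def _calibrated_band_sigma(fwhm_um: float, period: float) -> float:
    """Gaussian width whose periodic repeat measures the requested FWHM.

    Overlap of neighbouring repeats raises the inter-peak floor and narrows
    the measured width; solve for sigma by bisection.  Widths approaching
    half the period are not realizable by this motif and are rejected.
    """
    naive = fwhm_um / _FWHM_FACTOR
    if _measured_fwhm_of_periodic(period, naive) >= fwhm_um - 1e-6:
        return naive  # negligible overlap
    lo, hi = naive, period
    if _measured_fwhm_of_periodic(period, hi) < fwhm_um:
        raise ValueError(
            f"band FWHM {fwhm_um} µm not realizable within a {period} µm period"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _measured_fwhm_of_periodic(period, mid) < fwhm_um:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _periodic_band_profile(
    x_um: np.ndarray, period: float, center: float, fwhm_um: float
) -> np.ndarray:
    """Periodic band profile whose measured FWHM equals ``fwhm_um``, peak 1."""
    sigma = _calibrated_band_sigma(fwhm_um, period)
    # wrap offsets into [-period/2, period/2) for the nearest repeat
    d = np.remainder(x_um - center + period / 2.0, period) - period / 2.0
    prof = _periodic_gaussian_sum(d, period, sigma)
    return prof / prof.max()


def _render_channel(
    components: list[MotifComponent],
    params: FiberImageParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    nz, ny, nx = params.grid_shape
    dxy, dz = params.voxel_size
    x_um = np.arange(nx) * dxy * 1e-3
    density = np.zeros(params.grid_shape, dtype=float)
    centers: list[tuple[float, float, float]] = []
    period = params.sarcomere_length
    for comp in components:
        if comp.kind == "band":
            prof = comp.amplitude * _periodic_band_profile(
                x_um, period, comp.center_um, comp.fwhm_um
            )
            density += prof[None, None, :]
        elif comp.kind == "doublet":
            half = comp.separation_nm * 1e-3 / 2.0
            prof = np.zeros(nx)
            for sgn in (-1.0, 1.0):
                prof += _periodic_band_profile(
                    x_um, period, comp.center_um + sgn * half, comp.line_fwhm_nm * 1e-3
                )
            density += comp.amplitude * prof[None, None, :] / prof.max()
            # record line centers for every visible repeat
            n_rep = int(np.floor(x_um[-1] / period)) + 1
            for rep in range(n_rep):
                for sgn in (-1.0, 1.0):
                    cx = (comp.center_um + rep * period + sgn * half) * 1e3
                    if 0 <= cx <= x_um[-1] * 1e3:
                        centers.append((nz / 2 * dz, ny / 2 * dxy, cx))
        else:  # clusters
            vol_um3 = nz * dz * ny * dxy * nx * dxy * 1e-9
            n_spots = rng.poisson(comp.density_per_um3 * vol_um3)
            zz, yy, xx = np.meshgrid(
                np.arange(nz) * dz, np.arange(ny) * dxy, np.arange(nx) * dxy,
                indexing="ij",
            )
            for _ in range(n_spots):
                cz = rng.uniform(0, (nz - 1) * dz)
                cy = rng.uniform(0, (ny - 1) * dxy)
                cx = rng.uniform(0, (nx - 1) * dxy)
                s = comp.spot_sigma_nm
                density += comp.amplitude * np.exp(
                    -0.5 * (((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) / s**2)
                )
                centers.append((cz, cy, cx))
    return density, centers


def simulate_fiber_stack(
    params: FiberImageParams, seed: int = 0
) -> tuple[ZStack, GroundTruth]:
    """Render, blur, mix and corrupt a two-channel fiber stack.

    Forward model: per-channel densities are convolved with the Gaussian
    PSF, mixed between channels (F1 = A1 + b21·A2, F2 = A2 + b12·A1),
    offset by the background and degraded with Poisson + read noise.
    """
    rng = np.random.default_rng(seed)
    streams = rng.spawn(len(params.structure_templates) + 1)
    dxy, dz = params.voxel_size
    densities, all_centers = [], []
    for comps, st in zip(params.structure_templates, streams):
        d, c = _render_channel(comps, params, st)
        densities.append(d)
        all_centers.append(c)
    density = np.stack(densities)

    sig_vox = (params.psf_sigma[2] / dz, params.psf_sigma[1] / dxy, params.psf_sigma[0] / dxy)
    if all(s == 0 for s in params.psf_sigma):
        blurred = density.copy()
    else:
        blurred = np.stack([gaussian_filter(d, sigma=sig_vox, mode="reflect") for d in density])

    b12, b21 = params.bleedthrough
    if density.shape[0] == 2:
        f1 = blurred[0] + b21 * blurred[1]
        f2 = blurred[1] + b12 * blurred[0]
        mixed = np.stack([f1, f2])
    else:
        mixed = blurred.copy()
    signal = mixed + params.background

    if params.noise is not None:
        noise_rng = streams[-1]
        if params.noise.poisson:
            signal = noise_rng.poisson(signal).astype(float)
        if params.noise.read_sigma > 0:
            signal = signal + noise_rng.normal(0.0, params.noise.read_sigma, signal.shape)

    stack = ZStack(signal, voxel_size=params.voxel_size)
    return stack, GroundTruth(density, blurred, all_centers, params)


# ---------------------------------------------------------------------------
# gel / blot scans


@dataclass
class GelBlotParams:
    """Forward model of a scanned gel and its derived blot.

    Bands are separable: Gaussian along the molecular-weight (y) axis and a
    flat-top lane profile along x, normalized so the integrated (background-
    free, blur-free) band signal equals amplitude × loading factor.  The gel
    carries a many-band total-protein pattern; the blot a single target band
    per lane.
    """

    n_lanes: int = 4
    band_amplitudes: tuple[float, ...] | None = None  # target band per lane
    loading_factors: tuple[float, ...] | None = None
    target_band_y: int = 120
    gel_band_rows: tuple[int, ...] = (40, 70, 120, 160, 210, 250)
    gel_band_weights: tuple[float, ...] = (0.6, 1.0, 2.0, 0.8, 1.2, 0.5)
    gel_band_scale: float = 3.0e4
    band_sigma_y: float = 6.0  # px
    lane_width: int = 28  # px
    lane_pitch: int = 48  # px
    shape: tuple[int, int] = (300, 220)  # (ny, nx)
    background: float = 20.0
    background_gradient: tuple[float, float] = (0.0, 0.0)  # counts/px along (y, x)
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_lanes < 1:
            raise ValueError("need at least one lane")
        if self.band_amplitudes is None:
            self.band_amplitudes = tuple(5.0e4 for _ in range(self.n_lanes))
        if self.loading_factors is None:
            self.loading_factors = tuple(1.0 for _ in range(self.n_lanes))
        if len(self.band_amplitudes) != self.n_lanes or len(self.loading_factors) != self.n_lanes:
            raise ValueError("per-lane parameter lengths must equal n_lanes")
        if any(lf <= 0 for lf in self.loading_factors):
            raise ValueError("loading factors must be positive")
        if any(a < 0 for a in self.band_amplitudes):
            raise ValueError("band amplitudes must be >= 0")
        ny, _ = self.shape
        rows = set(self.gel_band_rows) | {self.target_band_y}
        if any(not 0 <= r < ny for r in rows):
            raise ValueError("band positions must lie within the image")
        if self.blur_sigma > 0:
            rows_sorted = sorted(rows)
            gaps = np.diff(rows_sorted)
            if np.any(gaps < 3 * self.blur_sigma):
                warnings.warn(
                    "bands closer than 3×blur_sigma: quantification may be ambiguous",
                    stacklevel=2,
                )

    def lane_x0(self, lane: int) -> int:
        return 10 + lane * self.lane_pitch


@dataclass
class GelBlotFixture:
    """A simulated gel/blot pair with per-lane truth and ready-made ROIs."""

    gel: np.ndarray
    blot: np.ndarray
    truth_amounts: tuple[float, ...]  # amplitude × loading per lane (blot band mass)
    params: GelBlotParams

    def _band_height(self) -> int:
        # ±6 sigma captures all but ~2e-9 of the band mass
        p = self.params
        return int(12 * p.band_sigma_y + 6 * p.blur_sigma)

    def band_roi(self, lane: int) -> tuple[int, int, int, int]:
        """(x0, y0, w, h) enclosing the target band in the blot."""
        p = self.params
        h = self._band_height()
        return (p.lane_x0(lane) - 4, p.target_band_y - h // 2, p.lane_width + 8, h)

    def band_background_roi(self, lane: int) -> tuple[int, int, int, int]:
        p = self.params
        h = self._band_height()
        end = p.target_band_y - h // 2 - 4  # leave a gap above the band ROI
        y0 = max(end - h, 0)
        return (p.lane_x0(lane) - 4, y0, p.lane_width + 8, end - y0)

    def lane_roi(self, lane: int) -> tuple[int, int, int, int]:
        p = self.params
        return (p.lane_x0(lane), 10, p.lane_width, p.shape[0] - 20)

    def lane_background_roi(self, lane: int) -> tuple[int, int, int, int]:
        p = self.params
        x0 = p.lane_x0(lane) + p.lane_width + 2
        w = max(p.lane_pitch - p.lane_width - 6, 4)
        return (x0, 10, w, p.shape[0] - 20)


def _render_band(
    img: np.ndarray, x0: int, width: int, y_center: int, sigma_y: float, mass: float
) -> None:
    ny = img.shape[0]
    y = np.arange(ny, dtype=float)
    g = np.exp(-0.5 * ((y - y_center) / sigma_y) ** 2)
    g /= g.sum() * width  # integrates to 1 over the lane footprint
    img[:, x0 : x0 + width] += mass * g[:, None]


def simulate_gel_blot(
    params: GelBlotParams, seed: int = 0
) -> GelBlotFixture:
    """Simulate a total-protein gel and the single-target blot derived from it."""
    rng = np.random.default_rng(seed)
    ny, nx = params.shape
    gel = np.zeros((ny, nx), dtype=float)
    blot = np.zeros((ny, nx), dtype=float)
    truth = []
    for lane in range(params.n_lanes):
        x0 = params.lane_x0(lane)
        lf = params.loading_factors[lane]
        for row, w in zip(params.gel_band_rows, params.gel_band_weights):
            _render_band(gel, x0, params.lane_width, row, params.band_sigma_y,
                         w * params.gel_band_scale * lf)
        mass = params.band_amplitudes[lane] * lf
        _render_band(blot, x0, params.lane_width, params.target_band_y,
                     params.band_sigma_y, mass)
        truth.append(mass)
    if params.blur_sigma > 0:
        gel = gaussian_filter(gel, params.blur_sigma, mode="reflect")
        blot = gaussian_filter(blot, params.blur_sigma, mode="reflect")
    yy, xx = np.mgrid[0:ny, 0:nx]
    bg = params.background + params.background_gradient[0] * yy + params.background_gradient[1] * xx
    gel = gel + bg
    blot = blot + bg
    if params.noise_sigma > 0:
        gel = gel + rng.normal(0, params.noise_sigma, gel.shape)
        blot = blot + rng.normal(0, params.noise_sigma, blot.shape)
    return GelBlotFixture(gel, blot, tuple(truth), params)


# ---------------------------------------------------------------------------
# cohorts

COHORT_VARIABLES = [
    "GP_mc", "GP_wm", "GPa_mc", "GPa_wm", "PhK_mc", "PhK_wm",
    "GSaGS_mc", "GDE_mc", "GLUT4_mc", "glycogen_mc", "SERCA1_mc",
]

# per variable: (MHN median, MHS median, coefficient of variation)
# medians are the study's group statistics; CVs derived from the group
# SEMs at n = 13 / 12
TABLE1_EFFECTS: dict[str, tuple[float, float, float]] = {
    "GP_mc": (5.28, 11.6, 0.42),
    "GP_wm": (3.33, 4.28, 0.19),
    "GPa_mc": (3.09, 4.76, 0.57),
    "GPa_wm": (1.26, 2.08, 0.28),
    "PhK_mc": (0.82, 1.41, 0.35),
    "PhK_wm": (0.82, 0.81, 0.50),
    "GSaGS_mc": (0.76, 1.37, 0.46),
    "GDE_mc": (3.44, 5.81, 0.42),
    "GLUT4_mc": (1.23, 0.54, 0.58),
    "glycogen_mc": (1.15, 0.75, 0.33),
    "SERCA1_mc": (18.9, 19.2, 0.31),
}

# signed pairwise correlation targets between contents, pooled over patients
# (upper triangle; order = COHORT_VARIABLES)
_R = np.array([
    #  GPmc GPwm GPamc GPawm PhKmc PhKwm GSaGS GDE  GLUT4 glyc  SERCA
    [1.00, 0.41, 0.72, 0.64, 0.83, 0.52, 0.53, 0.94, -0.46, -0.47, -0.24],
    [0.41, 1.00, 0.38, 0.52, 0.49, 0.69, 0.36, 0.34, -0.25, -0.66, -0.30],
    [0.72, 0.38, 1.00, 0.64, 0.75, 0.55, 0.52, 0.48, -0.51, -0.36, 0.10],
    [0.64, 0.52, 0.64, 1.00, 0.66, 0.58, 0.38, 0.43, -0.46, -0.48, -0.09],
    [0.83, 0.49, 0.75, 0.66, 1.00, 0.57, 0.48, 0.42, -0.23, -0.47, -0.14],
    [0.52, 0.69, 0.55, 0.58, 0.57, 1.00, 0.37, 0.49, -0.06, -0.21, -0.27],
    [0.53, 0.36, 0.52, 0.38, 0.48, 0.37, 1.00, 0.37, -0.41, -0.14, -0.19],
    [0.94, 0.34, 0.48, 0.43, 0.42, 0.49, 0.37, 1.00, -0.09, -0.09, -0.26],
    [-0.46, -0.25, -0.51, -0.46, -0.23, -0.06, -0.41, -0.09, 1.00, 0.39, 0.23],
    [-0.47, -0.66, -0.36, -0.48, -0.47, -0.21, -0.14, -0.09, 0.39, 1.00, 0.15],
    [-0.24, -0.30, 0.10, -0.09, -0.14, -0.27, -0.19, -0.26, 0.23, 0.15, 1.00],
])
CORRELATION_TARGETS = pd.DataFrame(_R, index=COHORT_VARIABLES, columns=COHORT_VARIABLES)


def _nearest_psd_correlation(r: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped correlation matrix (symmetric, unit diagonal, PSD)."""
    r = (r + r.T) / 2.0
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, min_eig, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _sigma_from_cv(cv: float) -> float:
    """Log-normal shape parameter producing a given coefficient of variation."""
    return float(np.sqrt(np.log(1.0 + cv**2)))


def _latent_correlation(r_target: float, s1: float, s2: float) -> float:
    """Latent-normal correlation giving Pearson r_target between two log-normals.

    Inverts corr(e^{s1 Z1}, e^{s2 Z2}) = (e^{rho s1 s2} - 1) /
    sqrt((e^{s1^2}-1)(e^{s2^2}-1)) for rho.
    """
    a = r_target * np.sqrt(np.expm1(s1**2) * np.expm1(s2**2))
    if a <= -1.0:
        return -0.999
    rho = np.log1p(a) / (s1 * s2)
    return float(np.clip(rho, -0.999, 0.999))


@dataclass
class CohortParams:
    """Study-cohort generator settings.

    Contents are log-normal (strictly positive, right-skewed) with
    group-specific medians; correlations are imposed through a Gaussian
    copula.  Fasting blood sugar follows a linear model in the whole-muscle
    phosphorylation ratio GPa/GP, with slope 2.5 mM per unit ratio.
    """

    n_mhn: int = 13
    n_mhs: int = 12
    group_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(TABLE1_EFFECTS)
    )
    correlation_targets: pd.DataFrame | None = None  # default: study matrix
    fbs_intercept: float = 4.2  # mM
    fbs_slope: float = 2.5  # mM per unit GPa/GP (wm)
    fbs_noise_sd: float = 0.7  # mM
    psd_repair_tolerance: float = 0.5  # max allowed Frobenius change in repair

    def __post_init__(self) -> None:
        if self.n_mhn < 0 or self.n_mhs < 0:
            raise ValueError("group sizes must be >= 0")
        for var, (_, _, cv) in self.group_effects.items():
            if cv <= 0:
                raise ValueError(f"dispersion for {var} must be positive")
        if self.correlation_targets is None:
            vars_ = list(self.group_effects)
            base = CORRELATION_TARGETS.reindex(index=vars_, columns=vars_)
            if base.isna().any().any():
                # user-supplied variables without study targets: uncorrelated
                base = base.fillna(0.0)
                np.fill_diagonal(base.values, 1.0)
            self.correlation_targets = base
        r = self.correlation_targets.to_numpy()
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation targets must be symmetric with unit diagonal")


def _latent_matrix(params: CohortParams) -> tuple[list[str], dict[str, float], np.ndarray]:
    """Repaired latent-normal correlation matrix realizing the targets."""
    vars_ = list(params.group_effects)
    sigmas = {v: _sigma_from_cv(params.group_effects[v][2]) for v in vars_}
    r_target = params.correlation_targets.reindex(index=vars_, columns=vars_).to_numpy()
    latent = np.ones_like(r_target)
    for i, vi in enumerate(vars_):
        for j, vj in enumerate(vars_):
            if i != j:
                latent[i, j] = _latent_correlation(r_target[i, j], sigmas[vi], sigmas[vj])
    repaired = _nearest_psd_correlation(latent)
    if np.linalg.norm(repaired - latent) > params.psd_repair_tolerance:
        raise ValueError("correlation targets too far from positive semi-definite")
    return vars_, sigmas, repaired


def _pearson_of_lognormals(rho: float, s1: float, s2: float) -> float:
    return float(np.expm1(rho * s1 * s2) / np.sqrt(np.expm1(s1**2) * np.expm1(s2**2)))


def effective_correlation_targets(params: CohortParams) -> pd.DataFrame:
    """The correlation matrix the generator can actually realize.

    A user- or study-supplied target matrix need not be positive
    semi-definite (a valid joint distribution may not exist for it); the
    generator clips its latent counterpart's eigenvalues.  This returns the
    repaired targets mapped back to the observed (log-normal) scale — the
    matrix empirical correlations converge to.
    """
    vars_, sigmas, repaired = _latent_matrix(params)
    eff = np.ones_like(repaired)
    for i, vi in enumerate(vars_):
        for j, vj in enumerate(vars_):
            if i != j:
                eff[i, j] = _pearson_of_lognormals(repaired[i, j], sigmas[vi], sigmas[vj])
    return pd.DataFrame(eff, index=vars_, columns=vars_)


def simulate_cohort(params: CohortParams, seed: int = 0) -> pd.DataFrame:
    """Draw a synthetic patient cohort.

    Returns a table with one row per patient: id, dx (MHN/MHS), all content
    variables, derived phosphorylation ratios (GPaGP_mc, GPaGP_wm when the
    numerator/denominator pairs are present), FBS, age and BMI.
    """
    rng = np.random.default_rng(seed)
    vars_, sigmas, repaired = _latent_matrix(params)
    n = params.n_mhn + params.n_mhs
    k = len(vars_)
    chol = np.linalg.cholesky(repaired + 1e-10 * np.eye(k))
    z = rng.standard_normal((n, k))
    if n > k + 1:
        # impose the latent correlation exactly on the sample (whiten, then
        # color), so the generated structure is reproducible at finite n
        z = (z - z.mean(axis=0)) / z.std(axis=0)
        sample_chol = np.linalg.cholesky(np.cov(z.T) + 1e-12 * np.eye(k))
        z = z @ np.linalg.inv(sample_chol).T
    z = z @ chol.T

    dx = np.array(["MHN"] * params.n_mhn + ["MHS"] * params.n_mhs)
    data: dict[str, np.ndarray] = {}
    for j, v in enumerate(vars_):
        mhn_med, mhs_med, _ = params.group_effects[v]
        mu = np.where(dx == "MHN", np.log(mhn_med), np.log(mhs_med))
        data[v] = np.exp(mu + sigmas[v] * z[:, j])

    df = pd.DataFrame(data)
    df.insert(0, "dx", dx)
    df.insert(0, "id", [f"P{i + 1:03d}" for i in range(n)])
    for frac in ("mc", "wm"):
        num, den = f"GPa_{frac}", f"GP_{frac}"
        if num in df and den in df:
            df[f"GPaGP_{frac}"] = df[num] / df[den]
    if "GPaGP_wm" in df:
        df["FBS"] = (
            params.fbs_intercept
            + params.fbs_slope * df["GPaGP_wm"]
            + rng.normal(0.0, params.fbs_noise_sd, n)
        )
    df["age"] = np.clip(rng.normal(40.0, 12.0, n), 18, 80)
    df["BMI"] = np.clip(rng.normal(27.0, 4.0, n), 16, 45)
    return df


# ---------------------------------------------------------------------------
# replicate tables


@dataclass
class ReplicateParams:
    """Nested replicate design: lanes within patients, repeated evaluations
    within lanes.  ``lane_cv`` is the fractional SD of true lane-to-lane
    variation; ``tech_cv`` that of repeated evaluation of the same lane."""

    n_patients: int = 4
    lanes_per_patient: int = 3
    tech_reps_per_lane: int = 5
    patient_means: tuple[float, ...] | None = None
    lane_cv: float = 0.165
    tech_cv: float = 0.051

    def __post_init__(self) -> None:
        if min(self.n_patients, self.lanes_per_patient, self.tech_reps_per_lane) < 1:
            raise ValueError("all counts must be >= 1")
        if self.lane_cv < 0 or self.tech_cv < 0:
            raise ValueError("CVs must be >= 0")
        if self.patient_means is None:
            self.patient_means = tuple(
                float(m) for m in np.linspace(1.0, 2.0, self.n_patients)
            )
        if len(self.patient_means) != self.n_patients:
            raise ValueError("one mean per patient required")


def simulate_replicate_table(params: ReplicateParams, seed: int = 0) -> pd.DataFrame:
    """Long-format table (patient, lane, tech_rep, value) with nested noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(params.n_patients):
        m = params.patient_means[p]
        for lane in range(params.lanes_per_patient):
            lane_value = m * (1.0 + params.lane_cv * rng.standard_normal())
            for rep in range(params.tech_reps_per_lane):
                v = lane_value * (1.0 + params.tech_cv * rng.standard_normal())
                rows.append((f"P{p + 1}", lane + 1, rep + 1, v))
    return pd.DataFrame(rows, columns=["patient", "lane", "tech_rep", "value"])
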
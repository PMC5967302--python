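"""Synthetic fixtures with known ground truth for every analysis stage.

The microscopy, optical-trap and cytometry data this package analyzes are
not publicly deposited, so each analysis has a generator here that emits
the same primitives (label masks, fluorescence channels, nuclei tables,
bead/stage tracks, ratio traces, intensity populations) from an explicit
parameterization, together with the ground-truth summary computed by
direct counting from that parameterization.

Physics of the trap simulators: an overdamped bead in a harmonic trap
follows the Ornstein–Uhlenbeck process with relaxation time ``tau = γ/k``
and stationary variance ``k_B·T/k``.  The update used is the *exact*
discretization

    x[n+1] = x[n]·exp(-dt/τ) + N(0, (k_B·T/k)·(1 - exp(-2·dt/τ)))

which is free of Euler step-size bias at any dt.  Tether pulls use a
series-spring stand-in (trap spring k against tether spring k_t):
``Δx = k_t/(k + k_t) · stage`` — a deliberate idealization; real tether
force-extension shapes are only assumed to have a first linear part.

All randomness flows from the single integer ``seed`` inside each spec;
no global state.  Every generator is deterministic given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError, InvalidParameterError
from .morphometry import FieldSummary, MorphometryConfig
from .signal_traces import Trace
from .trap_mechanics import BOLTZMANN_PN_UM, BeadTrack, StageTrack

#: Dynamic viscosity of water at 23 °C, Pa·s.
WATER_VISCOSITY_23C = 9.33e-4

#: Diameter of the streptavidin-coated polystyrene beads, μm.
BEAD_DIAMETER_UM = 1.76

#: Calibrated trap stiffness used as the default simulation condition, pN/μm.
DEFAULT_TRAP_STIFFNESS = 7.29


def stokes_drag(
    radius_um: float = BEAD_DIAMETER_UM / 2,
    viscosity_pa_s: float = WATER_VISCOSITY_23C,
) -> float:
    """Stokes drag coefficient 6πηr in pN·s/μm.

    With η in Pa·s and r in μm the SI result converts so that
    γ[pN·s/μm] = 6π · η · r numerically.
    """
    if radius_um <= 0 or viscosity_pa_s <= 0:
        raise InvalidParameterError("radius and viscosity must be positive")
    return 6.0 * math.pi * viscosity_pa_s * radius_um


# ---------------------------------------------------------------------------
# Trap simulators
# ---------------------------------------------------------------------------

@dataclass
class TrapSimParams:
    """Equilibrium trapped-bead simulation parameters.

    Defaults mirror the experimental recording: stiffness 7.29 pN/μm,
    1000 frames/s for 10 s (10^4 frames), drag from Stokes' law for the
    1.76-μm bead in water at room temperature.
    """

    stiffness: float = DEFAULT_TRAP_STIFFNESS  # pN/μm
    temperature: float = 296.15  # K
    drag: float = dataclass_field(default_factory=stokes_drag)  # pN·s/μm
    dt: float = 1e-3  # s
    n_frames: int = 10_000
    x0: float = 0.0  # μm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise InvalidParameterError("stiffness must be positive")
        if self.temperature < 0:
            raise InvalidParameterError("temperature must be >= 0")
        if self.drag <= 0:
            raise InvalidParameterError("drag must be positive")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")


def simulate_trapped_bead(params: TrapSimParams) -> BeadTrack:
    """Exact-discretization OU trajectory of a bead in a harmonic trap.

    The generating process has stationary variance k_B·T/k and
    autocorrelation exp(-k·Δt/γ); at T = 0 the trajectory decays
    deterministically toward the trap centre.
    """
    tau = params.drag / params.stiffness
    a = math.exp(-params.dt / tau)
    stat_var = BOLTZMANN_PN_UM * params.temperature / params.stiffness
    step_sd = math.sqrt(stat_var * (1.0 - a * a))
    rng = np.random.default_rng(params.seed)
    x = np.empty(params.n_frames)
    x[0] = params.x0
    noise = rng.standard_normal(params.n_frames - 1) * step_sd
    for i in range(1, params.n_frames):
        x[i] = x[i - 1] * a + noise[i - 1]
    times = np.arange(params.n_frames) * params.dt
    return BeadTrack(
        times=times,
        x=x,
        frame_rate=1.0 / params.dt,
        meta={"stiffness_true": params.stiffness, "temperature": params.temperature},
    )


@dataclass
class TetherSimParams:
    """Series-spring tether-pull simulation parameters.

    The stage ramps at ``speed`` μm/s (1 μm/s in the experiments) and the
    bead displacement balances the trap spring against the tether spring:
    k·Δx = k_t·(stage − Δx).  ``noise_sd`` is Gaussian position noise on
    the bead, μm.
    """

    stiffness: float = DEFAULT_TRAP_STIFFNESS  # trap spring k, pN/μm
    tether_stiffness: float = 20.0  # tether spring k_t, pN/μm
    speed: float = 1.0  # μm/s
    duration: float = 5.0  # s
    dt: float = 0.01  # s (images every 10 ms during pulls)
    noise_sd: float = 0.0  # μm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise InvalidParameterError("trap stiffness must be positive")
        if self.tether_stiffness < 0:
            raise InvalidParameterError("tether stiffness must be >= 0")
        if self.speed < 0:
            raise InvalidParameterError("pull speed must be >= 0")
        if self.duration <= 0 or self.dt <= 0:
            raise InvalidParameterError("duration and dt must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def simulate_tether_pull(params: TetherSimParams) -> tuple[BeadTrack, StageTrack]:
    """Noisy bead track and exact stage ramp for a tether pull.

    With k_t = 0 (no tether) the bead never moves.  Noiseless curves have
    force-vs-stage slope k·k_t/(k+k_t) and force-vs-tether-extension
    slope k_t exactly.
    """
    times = np.arange(0.0, params.duration + params.dt / 2, params.dt)
    stage = params.speed * times
    gain = params.tether_stiffness / (params.stiffness + params.tether_stiffness)
    displacement = gain * stage
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        displacement = displacement + rng.normal(0.0, params.noise_sd, times.size)
    bead = BeadTrack(
        times=times,
        x=displacement,
        frame_rate=1.0 / params.dt,
        meta={
            "tether_stiffness_true": params.tether_stiffness,
            "series_stiffness_true": params.stiffness * gain,
            "stiffness_true": params.stiffness,
        },
    )
    return bead, StageTrack(times=times, position=stage)


# ---------------------------------------------------------------------------
# Syncytium fields
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """One elliptical cell: centre/semi-axes in μm, orientation in rad."""

    center: tuple[float, float]  # (row, col), μm
    semi_axes: tuple[float, float]  # (a, b), μm
    orientation: float = 0.0
    nucleus_count: int = 1
    is_differentiated: bool = True

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise InvalidParameterError("semi_axes must be positive")
        if self.nucleus_count < 1:
            raise InvalidParameterError("nucleus_count must be >= 1")

    @property
    def aspect_ratio(self) -> float:
        return max(self.semi_axes) / min(self.semi_axes)

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass
class FieldSpec:
    """A microscopic field of elliptical cells for the MyHC/DAPI pipeline."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 1.0  # μm/pixel
    cells: list[CellSpec] = dataclass_field(default_factory=list)
    background_level: float = 10.0
    cell_level: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class SyntheticField:
    """Generated field plus ground truth from direct counting."""

    label_mask: np.ndarray  # uint16 labels, 0 = background
    nuclei: pd.DataFrame  # columns x_px, y_px, label (ground truth)
    myhc: np.ndarray  # float32 MyHC channel
    truth: FieldSummary
    cell_table: pd.DataFrame  # per-cell analytic ground truth


def _rasterize_ellipse(
    shape: tuple[int, int], cell: CellSpec, pixel_size: float
) -> np.ndarray:
    """Boolean mask of a filled, rotated ellipse (pixel-centre test)."""
    r0, c0 = (v / pixel_size for v in cell.center)
    a, b = (v / pixel_size for v in cell.semi_axes)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - r0, cc - c0
    cos_t, sin_t = math.cos(cell.orientation), math.sin(cell.orientation)
    # rotate into the ellipse frame: axis a along the orientation direction
    u = dr * cos_t + dc * sin_t
    v = -dr * sin_t + dc * cos_t
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_nuclei(
    cell_mask: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample nucleus centroids inside the eroded cell mask.

    Erosion keeps centroids away from the boundary so nearest-pixel
    containment is unambiguous; sub-pixel jitter (±0.3 px) keeps them
    rounding back to the sampled pixel.
    """
    eroded = ndimage.binary_erosion(cell_mask)
    if not eroded.any():
        eroded = cell_mask
    rows, cols = np.nonzero(eroded)
    rmin, rmax, cmin, cmax = rows.min(), rows.max(), cols.min(), cols.max()
    out = np.empty((count, 2))
    placed = 0
    for _ in range(1000 * count):
        r = rng.integers(rmin, rmax + 1)
        c = rng.integers(cmin, cmax + 1)
        if eroded[r, c]:
            jitter = rng.uniform(-0.3, 0.3, size=2)
            out[placed] = (r + jitter[0], c + jitter[1])
            placed += 1
            if placed == count:
                return out
    raise GenerationError("could not place nuclei inside the eroded mask")


def _truth_summary(cells: list[CellSpec], config: MorphometryConfig) -> FieldSummary:
    """Field indices by direct counting over the analytic cell specs."""
    diff = [c for c in cells if c.is_differentiated]
    diff_nuclei = sum(c.nucleus_count for c in diff)
    total_nuclei = sum(c.nucleus_count for c in cells)
    fused = sum(
        c.nucleus_count
        for c in diff
        if c.nucleus_count >= config.fusion_nuclei_threshold
    )
    diff_area = sum(c.area for c in diff)
    elong_area = sum(
        c.area for c in diff if c.aspect_ratio >= config.elongation_ar_threshold
    )
    return FieldSummary(
        fusion_index=100.0 * fused / diff_nuclei if diff_nuclei else float("nan"),
        elongation_index=100.0 * elong_area / diff_area if diff_area else float("nan"),
        differentiation_index=(
            100.0 * diff_nuclei / total_nuclei if total_nuclei else float("nan")
        ),
        n_syncytia=len(cells),
        n_nuclei_total=total_nuclei,
    )


def generate_syncytium_field(
    spec: FieldSpec, config: MorphometryConfig | None = None
) -> SyntheticField:
    """Rasterize a field of elliptical cells with nuclei and a MyHC channel.

    Each cell becomes one integer label; overlapping cells raise a
    generation error (use :func:`sample_field_spec` to draw non-overlapping
    layouts).  Differentiated cells get ``cell_level`` intensity in the
    MyHC channel, others stay at background.  The returned ground truth is
    computed by direct counting from the spec, not from the raster.
    """
    if not spec.cells:
        raise InvalidParameterError("field spec contains no cells")
    config = config or MorphometryConfig(pixel_size=spec.pixel_size)
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    label_mask = np.zeros(shape, dtype=np.uint16)
    myhc = np.full(shape, spec.background_level, dtype=np.float64)
    nuclei_rows = []
    for i, cell in enumerate(spec.cells, start=1):
        ell = _rasterize_ellipse(shape, cell, spec.pixel_size)
        if not ell.any():
            raise GenerationError(f"cell {i} rasterizes to zero pixels")
        if (label_mask[ell] != 0).any():
            raise GenerationError(f"cell {i} overlaps an earlier cell")
        edge = (
            ell[0, :].any() or ell[-1, :].any() or ell[:, 0].any() or ell[:, -1].any()
        )
        if edge:
            raise GenerationError(f"cell {i} touches the image border")
        label_mask[ell] = i
        if cell.is_differentiated:
            myhc[ell] = spec.cell_level
        for r, c in _place_nuclei(ell, cell.nucleus_count, rng):
            nuclei_rows.append({"x_px": c, "y_px": r, "label": i})
    if spec.noise_sd > 0:
        myhc = myhc + rng.normal(0.0, spec.noise_sd, shape)
    nuclei = pd.DataFrame(nuclei_rows, columns=["x_px", "y_px", "label"])
    cell_table = pd.DataFrame(
        {
            "label": np.arange(1, len(spec.cells) + 1),
            "nucleus_count": [c.nucleus_count for c in spec.cells],
            "area_um2": [c.area for c in spec.cells],
            "aspect_ratio": [c.aspect_ratio for c in spec.cells],
            "is_differentiated": [c.is_differentiated for c in spec.cells],
        }
    )
    return SyntheticField(
        label_mask=label_mask,
        nuclei=nuclei,
        myhc=myhc.astype(np.float32),
        truth=_truth_summary(spec.cells, config),
        cell_table=cell_table,
    )


def sample_field_spec(
    seed: int,
    n_cells: int = 5,
    image_shape: tuple[int, int] = (320, 320),
    pixel_size: float = 0.5,
    max_tries: int = 400,
) -> FieldSpec:
    """Draw a random non-overlapping field layout with known ground truth.

    Aspect ratios are sampled away from the elongation threshold of 3
    (uniform on [1.2, 2.5] or [3.5, 4.5]) so the elongated/round
    classification is unambiguous; nucleus counts mix mononuclear cells
    and syncytia on both sides of the default fusion threshold of 16.
    At least one differentiated multinucleate cell is guaranteed.
    Placement is by bounded rejection against an occupancy mask with a
    2-pixel clearance; persistent failure raises a generation error.
    """
    rng = np.random.default_rng(seed)
    occupancy = np.zeros(image_shape, dtype=bool)
    cells: list[CellSpec] = []
    for i in range(n_cells):
        for attempt in range(max_tries):
            # minor semi-axis >= 12 px keeps moment-ellipse aspect ratios
            # within ~2% of the analytic value at any orientation
            minor = rng.uniform(6.0, 12.0)
            if rng.random() < 0.5:
                ar = rng.uniform(1.2, 2.5)
            else:
                ar = rng.uniform(3.5, 4.5)
            major = minor * ar
            orientation = rng.uniform(0.0, math.pi)
            margin = major / pixel_size + 3
            if 2 * margin >= min(image_shape):
                continue
            center = (
                rng.uniform(margin, image_shape[0] - margin) * pixel_size,
                rng.uniform(margin, image_shape[1] - margin) * pixel_size,
            )
            multinucleate = i == 0 or rng.random() < 0.6
            if multinucleate:
                nucleus_count = int(rng.integers(2, 31))
                differentiated = True
            else:
                nucleus_count = 1
                differentiated = bool(rng.random() < 0.5)
            cell = CellSpec(
                center=center,
                semi_axes=(major, minor),
                orientation=orientation,
                nucleus_count=nucleus_count,
                is_differentiated=differentiated,
            )
            ell = _rasterize_ellipse(image_shape, cell, pixel_size)
            grown = ndimage.binary_dilation(ell, iterations=2)
            if ell.any() and not (occupancy & grown).any():
                occupancy |= grown
                cells.append(cell)
                break
        else:
            raise GenerationError(
                f"could not place cell {i + 1}/{n_cells} after {max_tries} tries"
            )
    return FieldSpec(
        image_shape=image_shape,
        pixel_size=pixel_size,
        cells=cells,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Cortical-ring images
# ---------------------------------------------------------------------------

@dataclass
class CorticalSpec:
    """One elliptical cell with a bright cortical band of given depth."""

    image_shape: tuple[int, int] = (160, 160)
    pixel_size: float = 0.5  # μm/pixel
    center: tuple[float, float] = (40.0, 40.0)  # μm
    semi_axes: tuple[float, float] = (30.0, 20.0)  # μm
    orientation: float = 0.0
    cortex_depth: float = 1.5  # μm
    cortex_level: float = 100.0
    interior_level: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.cortex_depth <= 0:
            raise InvalidParameterError("cortex_depth must be positive")
        if self.cortex_level < 0 or self.interior_level < 0:
            raise InvalidParameterError("intensity levels must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.cortex_depth >= min(self.semi_axes):
            raise InvalidParameterError(
                "cortex_depth must be smaller than the minor semi-axis"
            )


def generate_cortical_image(spec: CorticalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Mask and fluorescence channel with a cortical band at the edge.

    Pixels within ``cortex_depth`` (by Euclidean distance transform) of
    the mask edge get ``cortex_level``; deeper pixels ``interior_level``;
    outside the mask is zero.  Gaussian noise is added when requested.
    """
    cell = CellSpec(center=spec.center, semi_axes=spec.semi_axes,
                    orientation=spec.orientation)
    mask = _rasterize_ellipse(spec.image_shape, cell, spec.pixel_size)
    if not mask.any():
        raise GenerationError("cortical cell rasterizes to zero pixels")
    depth_um = ndimage.distance_transform_edt(mask) * spec.pixel_size
    image = np.zeros(spec.image_shape, dtype=np.float64)
    image[mask] = np.where(
        depth_um[mask] <= spec.cortex_depth, spec.cortex_level, spec.interior_level
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, spec.image_shape)
    return mask, image.astype(np.float32)


# ---------------------------------------------------------------------------
# Fura2 traces and intensity populations
# ---------------------------------------------------------------------------

@dataclass
class TraceSpec:
    """Agonist-response ratio trace: baseline, then a saturating rise
    (optionally decaying) after the onset.

    Defaults mirror the imaging protocol: samples every 10 s over 600 s
    with the agonist arriving after a 120-s baseline perfusion.  An
    infinite ``decay_tau`` gives a sustained plateau at
    baseline + amplitude.
    """

    baseline: float = 1.0
    amplitude: float = 0.8
    onset_time: float = 120.0  # s
    rise_tau: float = 20.0  # s
    decay_tau: float = math.inf  # s
    sampling_interval: float = 10.0  # s
    duration: float = 600.0  # s
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise InvalidParameterError("sampling_interval must be positive")
        if self.duration < self.sampling_interval:
            raise InvalidParameterError("duration must cover >= 1 interval")
        if self.onset_time > self.duration:
            raise InvalidParameterError("onset_time lies beyond the trace duration")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise InvalidParameterError("time constants must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def generate_fura2_trace(spec: TraceSpec) -> Trace:
    """Sampled ratio trace; the programmed amplitude rides in ``meta``."""
    times = np.arange(
        0.0, spec.duration + spec.sampling_interval / 2, spec.sampling_interval
    )
    values = np.full(times.shape, spec.baseline, dtype=float)
    after = times >= spec.onset_time
    dt = times[after] - spec.onset_time
    response = spec.amplitude * (1.0 - np.exp(-dt / spec.rise_tau))
    if math.isfinite(spec.decay_tau):
        response = response * np.exp(-dt / spec.decay_tau)
    values[after] += response
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, times.size)
    return Trace(
        times=times,
        values=values,
        meta={"amplitude_true": spec.amplitude, "baseline_true": spec.baseline},
    )


@dataclass
class PopulationSpec:
    """Two-component log-normal intensity mixture for gating fixtures.

    Defaults emulate an annexin V readout: 2×10^4 cells with a 20%
    positive component well separated (about a decade) from the negative
    one on the log-intensity axis.
    """

    n_cells: int = 20_000
    positive_fraction: float = 0.2
    log_mean_negative: float = math.log(100.0)
    log_sd_negative: float = 0.5
    log_mean_positive: float = math.log(2000.0)
    log_sd_positive: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise InvalidParameterError("positive_fraction must lie in [0, 1]")
        if self.log_sd_negative <= 0 or self.log_sd_positive <= 0:
            raise InvalidParameterError("log-sds must be positive")


@dataclass
class IntensityPopulation:
    """Drawn intensities plus the ground-truth component labels."""

    intensities: np.ndarray
    is_positive: np.ndarray  # boolean ground truth per cell


def generate_intensity_population(spec: PopulationSpec) -> IntensityPopulation:
    """Sample the two-component log-normal mixture."""
    rng = np.random.default_rng(spec.seed)
    positive = rng.random(spec.n_cells) < spec.positive_fraction
    log_mu = np.where(positive, spec.log_mean_positive, spec.log_mean_negative)
    log_sd = np.where(positive, spec.log_sd_positive, spec.log_sd_negative)
    intensities = np.exp(rng.normal(log_mu, log_sd))
    return IntensityPopulation(intensities=intensities, is_positive=positive)
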
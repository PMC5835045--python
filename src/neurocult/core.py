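"""Shared domain types for micrograph-based assay quantification.

The pipeline operates on single-channel fluorescence micrographs carrying a
physical pixel size, and on a small set of value objects shared by the
viability, neurite and calcium-analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel labels a micrograph may carry.
CHANNELS = ("nuclei", "dead", "live", "neurite", "calcium")

#: Conversion: micrometres per centimetre.
UM_PER_CM = 1.0e4


@dataclass(frozen=True)
class Micrograph:
    """A single-field, single-channel intensity image with physical scale.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities (any float/integer dtype).
    pixel_size
        Physical size of one pixel edge in micrometres per pixel.
    channel
        One of :data:`CHANNELS`; purely descriptive metadata.
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str = "nuclei"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("Micrograph requires a non-empty 2D pixel array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (µm/px)")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_area_cm2(self) -> float:
        """Imaged area in cm², from the pixel grid and pixel size."""
        h, w = self.pixels.shape
        return (h * self.pixel_size / UM_PER_CM) * (w * self.pixel_size / UM_PER_CM)


@dataclass(frozen=True)
class ThresholdSpec:
    """How to resolve an absolute intensity threshold for binarization.

    ``mode="absolute"`` uses ``value`` directly.  ``mode="relative"``
    multiplies ``value`` by a robust background scale,
    ``median + k_mad * MAD`` of the image, so a single user-chosen
    multiplier adapts across images of one condition while remaining
    consistent — the semi-automatic thresholding model used throughout.

    ``min_object_area``/``max_object_area`` (in pixels) bound the size of
    connected components accepted as objects; components above the maximum
    are split by distance-transform declumping rather than discarded.
    """

    mode: str = "relative"
    value: float = 1.0
    k_mad: float = 6.0
    min_object_area: int = 5
    max_object_area: int = 75

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise ValueError("mode must be 'absolute' or 'relative'")
        if self.value <= 0:
            raise ValueError("threshold value must be positive")
        if not (0 < self.min_object_area <= self.max_object_area):
            raise ValueError("require 0 < min_object_area <= max_object_area")


@dataclass(frozen=True)
class FieldCounts:
    """Per-field object counts from the nuclei and dead-stain channels."""

    n_total: int
    n_dead: int
    field_area: float  # cm²

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_dead < 0:
            raise ValueError("counts must be non-negative")
        if self.field_area <= 0:
            raise ValueError("field_area must be positive")


@dataclass(frozen=True)
class WellSummary:
    """Well-level aggregation of live/dead counts.

    ``viability`` is live/total (NaN when no cells were counted) and
    ``live_density`` is live cells per cm² of summed imaged area.
    """

    total: int
    dead: int
    live: int
    viability: float
    live_density: float


@dataclass(frozen=True)
class ExperimentDesign:
    """Condition × density × replicate layout of a co-culture experiment.

    Defaults mirror the study design this package emulates: six seeding
    densities spanning 1,000–50,000 cells/cm², a co-culture and a
    mono-culture control arm, 2 biological × 5 technical replicates,
    three imaged fields per well for viability/neurites, and 2-minute
    calcium recordings at 32 Hz from 3 positions per well.
    """

    densities: tuple[float, ...] = (1000.0, 2500.0, 5000.0, 10000.0, 20000.0, 50000.0)
    conditions: tuple[str, ...] = ("co-culture", "control")
    n_biological: int = 2
    n_technical: int = 5
    fields_per_well_viability: int = 3
    positions_per_well_activity: int = 3
    movie_duration: float = 120.0
    frame_rate: float = 32.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.densities):
            raise ValueError("densities must be positive")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ValueError("need at least one replicate of each kind")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.movie_duration <= 0:
            raise ValueError("movie_duration must be positive")

    @property
    def n_wells(self) -> int:
        return (
            len(self.densities)
            * len(self.conditions)
            * self.n_biological
            * self.n_technical
        )

    def iter_wells(self):
        """Yield (condition, density, biological, technical) tuples."""
        for cond in self.conditions:
            for dens in self.densities:
                for b in range(1, self.n_biological + 1):
                    for t in range(1, self.n_technical + 1):
                        yield cond, dens, b, t


@dataclass(frozen=True)
class CalciumMovie:
    """T × H × W fluorescence stack with acquisition timing."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames)
        if fr.ndim != 3:
            raise ValueError("frames must be a T×H×W array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class CellROI:
    """A segmented cell: integer label plus its pixel footprint.

    ``footprint`` is stored as an (N, 2) array of (row, col) indices.
    """

    label: int
    footprint: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=int)
        if fp.ndim != 2 or fp.shape[1] != 2 or fp.shape[0] == 0:
            raise ValueError("footprint must be a non-empty (N, 2) index array")
        object.__setattr__(self, "footprint", fp)

    @property
    def area(self) -> int:
        return int(self.footprint.shape[0])


@dataclass(frozen=True)
class FluorescenceTrace:
    """Mean-intensity time series of one ROI with its ΔF/F normalization."""

    samples: np.ndarray
    dff: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        d = np.asarray(self.dff, dtype=float)
        if s.ndim != 1 or s.size == 0 or d.shape != s.shape:
            raise ValueError("samples and dff must be equal-length 1D arrays")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "dff", d)


@dataclass(frozen=True)
class SpikeTrain:
    """Detected calcium events of one cell, as frame indices and seconds."""

    event_frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        ef = np.asarray(self.event_frames, dtype=int)
        if ef.ndim != 1:
            raise ValueError("event_frames must be 1D")
        if ef.size > 1 and not np.all(np.diff(ef) > 0):
            raise ValueError("event_frames must be strictly increasing")
        object.__setattr__(self, "event_frames", ef)

    @property
    def event_times(self) -> np.ndarray:
        return self.event_frames / self.frame_rate

    @property
    def n_events(self) -> int:
        return int(self.event_frames.size)


@dataclass(frozen=True)
class ActivitySummary:
    """Well-level spiking summary: pooled events over pooled cells."""

    total_spike_frequency: float  # Hz, summed events / duration
    n_cells: int
    mean_frequency_per_cell: float  # Hz


@dataclass
class GroundTruthField:
    """True nucleus geometry of one synthetic field."""

    nuclei_centers: np.ndarray  # (N, 2) float, (row, col)
    dead_flags: np.ndarray  # (N,) bool
    field_area: float  # cm²

    def __post_init__(self) -> None:
        c = np.asarray(self.nuclei_centers, dtype=float).reshape(-1, 2)
        f = np.asarray(self.dead_flags, dtype=bool).reshape(-1)
        if c.shape[0] != f.shape[0]:
            raise ValueError("one dead flag per nucleus required")
        if self.field_area <= 0:
            raise ValueError("field_area must be positive")
        self.nuclei_centers = c
        self.dead_flags = f

    @property
    def n_total(self) -> int:
        return int(self.nuclei_centers.shape[0])

    @property
    def n_dead(self) -> int:
        return int(self.dead_flags.sum())


@dataclass
class GroundTruthNeurites:
    """True neurite geometry: polylines and their analytic total length."""

    polylines: list  # list of (M, 2) float arrays, (row, col) in px
    true_total_length: float  # µm

    def recompute_length(self, pixel_size: float) -> float:
        """Sum of Euclidean segment lengths over all polylines, in µm."""
        total = 0.0
        for poly in self.polylines:
            p = np.asarray(poly, dtype=float)
            if p.shape[0] >= 2:
                total += float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
        return total * pixel_size


@dataclass
class GroundTruthActivity:
    """True cell footprints and spike times of one synthetic movie."""

    cell_footprints: list  # list of (N, 2) int index arrays
    spike_times: list  # list of sorted 1D float arrays (s)
    duration: float  # s

    def __post_init__(self) -> None:
        if len(self.cell_footprints) != len(self.spike_times):
            raise ValueError("one spike-time list per footprint required")
        for st in self.spike_times:
            st = np.asarray(st)
            if st.size and (st.min() < 0 or st.max() > self.duration):
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_footprints)

    @property
    def total_spikes(self) -> int:
        return int(sum(len(st) for st in self.spike_times))
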
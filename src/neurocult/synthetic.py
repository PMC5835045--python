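"""Ground-truth synthetic microscopy for co-culture assay benchmarking.

The study this package quantifies deposited no raw microscopy, so every
analysis stage is validated against synthetic data with exactly known truth:

* live/dead viability fields — Gaussian-spot nuclei on a noisy background,
  rendered into nuclei / dead-stain / live-stain channels with a known dead
  fraction;
* neurite fields — random-walk arbors rooted at somata, whose total polyline
  length is recorded analytically from the vertex geometry before
  rasterization;
* calcium movies — per-cell homogeneous Poisson spike trains convolved with
  a difference-of-exponentials indicator kernel plus Gaussian noise;
* full multi-well experiments — the condition × density × replicate layout
  of the emulated study, written to disk as TIFFs plus design/truth CSVs.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import (
    CalciumMovie,
    ExperimentDesign,
    GroundTruthActivity,
    GroundTruthField,
    GroundTruthNeurites,
    Micrograph,
    UM_PER_CM,
)

# ---------------------------------------------------------------------------
# Defaults: the imaging geometry and dose-response curves the generator
# emulates.  Field of view is 512×512 px at 1.3 µm/px (≈0.00443 cm²), which
# puts 4–220 cells in a field over the 1,000–50,000 cells/cm² density range.
# ---------------------------------------------------------------------------

DEFAULT_IMAGE_SHAPE = (512, 512)
DEFAULT_PIXEL_SIZE = 1.3  # µm/px
DEFAULT_SPOT_SIGMA = 3.0  # px
DEFAULT_CONTRAST = 10.0  # spot peak height, in units of the noise SD
DEFAULT_NOISE_SD = 2.0  # intensity counts
DEFAULT_BASELINE = 100.0  # background intensity counts
DEFAULT_MIN_SPACING = 12.0  # px, ≈4 spot sigmas

#: Condition → density → viability fraction.  Co-culture plateaus around
#: 0.91 from 10,000 cells/cm² and holds 0.70 at 1,000; the control stays
#: lower and rises mildly with density (0.69 at 10,000).
DEFAULT_VIABILITY_CURVE = {
    "co-culture": {
        1000.0: 0.70, 2500.0: 0.80, 5000.0: 0.86,
        10000.0: 0.91, 20000.0: 0.91, 50000.0: 0.92,
    },
    "control": {
        1000.0: 0.55, 2500.0: 0.60, 5000.0: 0.65,
        10000.0: 0.69, 20000.0: 0.73, 50000.0: 0.78,
    },
}

#: Condition → density → per-cell spontaneous event rate (Hz).
DEFAULT_ACTIVITY_CURVE = {
    "co-culture": {
        1000.0: 0.08, 2500.0: 0.09, 5000.0: 0.10,
        10000.0: 0.11, 20000.0: 0.12, 50000.0: 0.13,
    },
    "control": {
        1000.0: 0.03, 2500.0: 0.04, 5000.0: 0.05,
        10000.0: 0.06, 20000.0: 0.08, 50000.0: 0.10,
    },
}

#: Condition → mean neurite length per cell (µm) at 5 DIV.
DEFAULT_NEURITE_LENGTH = {"co-culture": 180.0, "control": 150.0}

# Calcium indicator kernel defaults: a slow-indicator transient.
DEFAULT_TAU_RISE = 0.18  # s
DEFAULT_TAU_DECAY = 0.55  # s
DEFAULT_AMPLITUDE = 0.2  # ΔF/F per event
DEFAULT_DFF_NOISE = 0.04  # ΔF/F noise SD


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested minimum spacing."""


# ---------------------------------------------------------------------------
# Nuclei / viability fields
# ---------------------------------------------------------------------------

def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_spacing: float,
    margin: float,
    max_attempts_per_cell: int = 200,
) -> np.ndarray:
    """Dart-throwing placement with a minimum center-to-center distance."""
    if n == 0:
        return np.empty((0, 2))
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("field too small for the requested margin")
    centers: list[np.ndarray] = []
    placed = np.empty((n, 2))
    for i in range(n):
        for _ in range(max_attempts_per_cell):
            cand = rng.uniform([margin, margin], [h - margin, w - margin])
            if i == 0:
                break
            d2 = np.sum((placed[:i] - cand) ** 2, axis=1)
            if d2.min() >= min_spacing**2:
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} at spacing {min_spacing} px"
            )
        placed[i] = cand
        centers.append(cand)
    return placed


def _render_spots(
    canvas: np.ndarray,
    centers: np.ndarray,
    sigma: float,
    amplitude: float,
) -> None:
    """Add isotropic Gaussian spots onto ``canvas`` in place."""
    if centers.size == 0:
        return
    h, w = canvas.shape
    half = int(np.ceil(4 * sigma))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    for r, c in centers:
        ri, ci = int(round(r)), int(round(c))
        dr, dc = r - ri, c - ci
        patch = amplitude * np.exp(
            -((yy - dr) ** 2 + (xx - dc) ** 2) / (2 * sigma**2)
        )
        r0, r1 = max(ri - half, 0), min(ri + half + 1, h)
        c0, c1 = max(ci - half, 0), min(ci + half + 1, w)
        canvas[r0:r1, c0:c1] += patch[
            r0 - (ri - half) : r1 - (ri - half),
            c0 - (ci - half) : c1 - (ci - half),
        ]


def generate_nuclei_field(
    n_cells: int,
    dead_fraction: float,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    spot_sigma: float = DEFAULT_SPOT_SIGMA,
    contrast: float = DEFAULT_CONTRAST,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline: float = DEFAULT_BASELINE,
    min_spacing: float = DEFAULT_MIN_SPACING,
    overlap_pair_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[Micrograph, Micrograph, Micrograph, GroundTruthField]:
    """Render one live/dead viability field with known truth.

    Every nucleus appears as a Gaussian spot of height ``contrast × noise_sd``
    (or ``contrast`` intensity counts when noise-free) above the background
    in the nuclei channel; dead cells additionally appear in the dead-stain
    channel and live cells in the live-stain channel.  Exactly
    ``round(n_cells × dead_fraction)`` cells are flagged dead.

    ``overlap_pair_fraction`` places that fraction of the cells as touching
    companions of already-placed cells (center distance 1.2–2.0 effective
    nucleus radii), to exercise declumping; the remainder respect
    ``min_spacing``.

    Returns ``(nuclei, dead, live, truth)``.
    """
    if not 0 <= dead_fraction <= 1:
        raise ValueError("dead_fraction must lie in [0, 1]")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    n_overlap = int(round(n_cells * overlap_pair_fraction))
    n_spaced = n_cells - n_overlap
    margin = max(2 * spot_sigma, 4.0)
    centers = _place_centers(rng, n_spaced, image_shape, min_spacing, margin)
    if n_overlap:
        if n_spaced == 0:
            raise PlacementError("overlapping companions require host cells")
        hosts = centers[rng.integers(0, n_spaced, size=n_overlap)]
        # Touching-nuclei geometry: a rendered nucleus has an effective
        # radius ≈ 1.5 spot sigmas, and adjacent nuclei overlap between
        # contact (2 r) and strong overlap (1.2 r) of center distance.
        r_eff = 1.5 * spot_sigma
        dist = rng.uniform(1.2 * r_eff, 2.0 * r_eff, size=n_overlap)
        ang = rng.uniform(0, 2 * np.pi, size=n_overlap)
        companions = hosts + np.stack(
            [dist * np.sin(ang), dist * np.cos(ang)], axis=1
        )
        companions[:, 0] = np.clip(companions[:, 0], margin, image_shape[0] - margin)
        companions[:, 1] = np.clip(companions[:, 1], margin, image_shape[1] - margin)
        centers = np.vstack([centers, companions])

    n_dead = int(round(n_cells * dead_fraction))
    dead_flags = np.zeros(n_cells, dtype=bool)
    if n_dead:
        dead_flags[rng.choice(n_cells, size=n_dead, replace=False)] = True

    amplitude = contrast * noise_sd if noise_sd > 0 else contrast

    def channel(mask: np.ndarray, label: str) -> Micrograph:
        img = np.full(image_shape, baseline, dtype=float)
        _render_spots(img, centers[mask], spot_sigma, amplitude)
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=image_shape)
        np.clip(img, 0, None, out=img)
        return Micrograph(img, pixel_size, label)

    all_mask = np.ones(n_cells, dtype=bool)
    nuclei = channel(all_mask, "nuclei")
    dead = channel(dead_flags, "dead")
    live = channel(~dead_flags, "live")

    area = (
        image_shape[0] * pixel_size / UM_PER_CM
    ) * (image_shape[1] * pixel_size / UM_PER_CM)
    truth = GroundTruthField(centers, dead_flags, area)
    return nuclei, dead, live, truth


# ---------------------------------------------------------------------------
# Neurite fields
# ---------------------------------------------------------------------------

def _grow_arbor(
    rng: np.random.Generator,
    soma: np.ndarray,
    target_length_px: float,
    shape: tuple[int, int],
    step: float = 4.0,
    turn_sd: float = 0.25,
    n_branches: int | None = None,
) -> list[np.ndarray]:
    """Random-walk branches rooted at a soma; integer-valued vertices.

    Vertices are rounded to the pixel grid as they are generated so the
    analytic truth length describes exactly the polyline that is drawn.
    Walks reflect off the field borders.
    """
    if target_length_px <= 0:
        return []
    if n_branches is None:
        n_branches = int(rng.integers(2, 5))
    h, w = shape
    per_branch = target_length_px / n_branches
    polylines = []
    for _ in range(n_branches):
        theta = rng.uniform(0, 2 * np.pi)
        pos = soma.astype(float).copy()
        verts = [np.round(pos).astype(int)]
        grown = 0.0
        while grown < per_branch:
            theta += rng.normal(0.0, turn_sd)
            nxt = pos + step * np.array([np.sin(theta), np.cos(theta)])
            if not (1 <= nxt[0] < h - 1):
                theta = -theta
                nxt = pos + step * np.array([np.sin(theta), np.cos(theta)])
            if not (1 <= nxt[1] < w - 1):
                theta = np.pi - theta
                nxt = pos + step * np.array([np.sin(theta), np.cos(theta)])
            nxt[0] = np.clip(nxt[0], 1, h - 2)
            nxt[1] = np.clip(nxt[1], 1, w - 2)
            v = np.round(nxt).astype(int)
            if np.any(v != verts[-1]):
                grown += float(np.linalg.norm(v - verts[-1]))
                verts.append(v)
            pos = nxt
        if len(verts) >= 2:
            polylines.append(np.array(verts, dtype=float))
    return polylines


def _raster_polylines(
    canvas: np.ndarray, polylines: list[np.ndarray], amplitude: float
) -> None:
    """Draw anti-aliased polylines onto ``canvas`` (max-composited)."""
    from skimage.draw import line_aa

    for poly in polylines:
        p = np.asarray(poly, dtype=int)
        for (r0, c0), (r1, c1) in zip(p[:-1], p[1:]):
            rr, cc, val = line_aa(int(r0), int(c0), int(r1), int(c1))
            np.maximum.at(canvas, (rr, cc), val * amplitude)


def polyline_total_length(polylines: list[np.ndarray], pixel_size: float) -> float:
    """Analytic total length (µm) of a set of pixel-coordinate polylines."""
    total = 0.0
    for poly in polylines:
        p = np.asarray(poly, dtype=float)
        if p.shape[0] >= 2:
            total += float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
    return total * pixel_size


def generate_neurite_field(
    n_cells: int,
    mean_length_per_cell: float,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    spot_sigma: float = DEFAULT_SPOT_SIGMA,
    contrast: float = DEFAULT_CONTRAST,
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline: float = DEFAULT_BASELINE,
    min_spacing: float = DEFAULT_MIN_SPACING,
    seed: int | np.random.Generator = 0,
) -> tuple[Micrograph, Micrograph, GroundTruthNeurites]:
    """Render a neurite-stain field plus its nuclei channel.

    Each cell grows 2–4 random-walk branches with per-cell total length drawn
    from a Gamma distribution with mean ``mean_length_per_cell`` (µm).  The
    true total length is the exact vertex-geometry sum recorded before
    rasterization.  Somata appear only in the nuclei channel, so the neurite
    channel contains neurites alone.
    """
    if mean_length_per_cell < 0:
        raise ValueError("mean_length_per_cell must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    margin = max(2 * spot_sigma, 4.0)
    centers = _place_centers(rng, n_cells, image_shape, min_spacing, margin)

    amplitude = contrast * noise_sd if noise_sd > 0 else contrast
    all_polylines: list[np.ndarray] = []
    for i in range(n_cells):
        if mean_length_per_cell > 0:
            # Gamma with shape 4: CV 0.5, strictly positive lengths.
            length_um = rng.gamma(4.0, mean_length_per_cell / 4.0)
            all_polylines.extend(
                _grow_arbor(rng, centers[i], length_um / pixel_size, image_shape)
            )

    # Strokes are max-composited among themselves, then sit on the baseline.
    strokes = np.zeros(image_shape, dtype=float)
    _raster_polylines(strokes, all_polylines, amplitude)
    neurite_img = np.full(image_shape, baseline, dtype=float) + strokes
    if noise_sd > 0:
        neurite_img += rng.normal(0.0, noise_sd, size=image_shape)
    np.clip(neurite_img, 0, None, out=neurite_img)

    nuclei_img = np.full(image_shape, baseline, dtype=float)
    _render_spots(nuclei_img, centers, spot_sigma, amplitude)
    if noise_sd > 0:
        nuclei_img += rng.normal(0.0, noise_sd, size=image_shape)
    np.clip(nuclei_img, 0, None, out=nuclei_img)

    truth = GroundTruthNeurites(
        all_polylines, polyline_total_length(all_polylines, pixel_size)
    )
    return (
        Micrograph(neurite_img, pixel_size, "neurite"),
        Micrograph(nuclei_img, pixel_size, "nuclei"),
        truth,
    )


# ---------------------------------------------------------------------------
# Calcium movies
# ---------------------------------------------------------------------------

def transient_kernel(
    frame_rate: float,
    tau_rise: float = DEFAULT_TAU_RISE,
    tau_decay: float = DEFAULT_TAU_DECAY,
) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient, sampled."""
    if not tau_decay > tau_rise > 0:
        raise ValueError("require tau_decay > tau_rise > 0")
    t = np.arange(0, 8 * tau_decay, 1.0 / frame_rate)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def simulate_dff_traces(
    n_cells: int,
    firing_rate: float,
    duration: float,
    frame_rate: float,
    tau_rise: float = DEFAULT_TAU_RISE,
    tau_decay: float = DEFAULT_TAU_DECAY,
    amplitude: float = DEFAULT_AMPLITUDE,
    noise_sd: float = DEFAULT_DFF_NOISE,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Simulate per-cell ΔF/F traces from Poisson spike trains.

    Returns ``(traces, spike_times)`` where ``traces`` is (n_cells, T) and
    ``spike_times[i]`` holds cell i's true event times in seconds.  Spike
    times are continuous; each contributes a difference-of-exponentials
    transient of peak height ``amplitude`` starting at its (fractional)
    frame position.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if firing_rate < 0:
        raise ValueError("firing_rate must be non-negative")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_frames = int(round(duration * frame_rate))
    kernel = amplitude * transient_kernel(frame_rate, tau_rise, tau_decay)
    klen = kernel.size
    # Oversampled kernel for sub-frame spike-time placement.
    oversample = 8
    t_fine = np.arange(0, 8 * tau_decay, 1.0 / (frame_rate * oversample))
    k_fine = np.exp(-t_fine / tau_decay) - np.exp(-t_fine / tau_rise)
    k_fine = amplitude * k_fine / k_fine.max()

    traces = np.zeros((n_cells, n_frames))
    spike_times: list[np.ndarray] = []
    for i in range(n_cells):
        n_spk = rng.poisson(firing_rate * duration) if firing_rate > 0 else 0
        times = np.sort(rng.uniform(0, duration, size=n_spk))
        spike_times.append(times)
        for ts in times:
            f0 = ts * frame_rate
            start = int(np.ceil(f0))
            if start >= n_frames:
                continue
            # Sample the oversampled kernel at the frame offsets after onset.
            offs = np.arange(start, min(start + klen, n_frames)) - f0
            idx = np.clip((offs * oversample).astype(int), 0, k_fine.size - 1)
            traces[i, start : start + idx.size] += k_fine[idx]
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=traces.shape)
    return traces, spike_times


def _disk_footprint(center: tuple[int, int], radius: int, shape) -> np.ndarray:
    from skimage.draw import disk

    rr, cc = disk(center, radius, shape=shape)
    return np.stack([rr, cc], axis=1)


def generate_calcium_movie(
    n_cells: int,
    firing_rate: float,
    duration: float = 120.0,
    frame_rate: float = 32.0,
    movie_shape: tuple[int, int] = (96, 96),
    cell_radius: int = 4,
    tau_rise: float = DEFAULT_TAU_RISE,
    tau_decay: float = DEFAULT_TAU_DECAY,
    amplitude: float = DEFAULT_AMPLITUDE,
    noise_sd: float = DEFAULT_DFF_NOISE,
    baseline: float = 100.0,
    background: float = 30.0,
    bleach_rate: float = 0.0,
    bleach_model: str = "none",
    seed: int | np.random.Generator = 0,
) -> tuple[CalciumMovie, GroundTruthActivity]:
    """Simulate a GCaMP-like movie with known footprints and spike times.

    Cells are disks of ``cell_radius`` px placed with spacing ≥ 3 radii;
    each cell's pixels follow ``baseline × (1 + ΔF/F)`` plus per-pixel
    Gaussian noise of ``baseline × noise_sd`` counts; the background sits at
    ``background`` counts with the same noise.  Optional photobleaching
    multiplies all intensities by a linear or exponential decay
    (``bleach_model`` in {"none", "linear", "exponential"} at ``bleach_rate``
    per second); off by default.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    traces, spike_times = simulate_dff_traces(
        n_cells, firing_rate, duration, frame_rate,
        tau_rise, tau_decay, amplitude, 0.0, rng,
    )
    n_frames = traces.shape[1] if n_cells else int(round(duration * frame_rate))

    centers = _place_centers(
        rng, n_cells, movie_shape, min_spacing=3.0 * cell_radius,
        margin=cell_radius + 1,
    )
    footprints = [
        _disk_footprint((int(round(r)), int(round(c))), cell_radius, movie_shape)
        for r, c in centers
    ]

    movie = np.full((n_frames,) + tuple(movie_shape), background, dtype=np.float32)
    for fp, tr in zip(footprints, traces):
        movie[:, fp[:, 0], fp[:, 1]] = baseline * (1.0 + tr)[:, None]
    if noise_sd > 0:
        movie += rng.normal(0.0, baseline * noise_sd, size=movie.shape).astype(
            np.float32
        )
    if bleach_model != "none" and bleach_rate > 0:
        t = np.arange(n_frames) / frame_rate
        if bleach_model == "linear":
            decay = np.clip(1.0 - bleach_rate * t, 0.0, None)
        elif bleach_model == "exponential":
            decay = np.exp(-bleach_rate * t)
        else:
            raise ValueError(f"unknown bleach_model {bleach_model!r}")
        movie *= decay[:, None, None].astype(np.float32)
    np.clip(movie, 0, None, out=movie)

    truth = GroundTruthActivity(footprints, spike_times, duration)
    return CalciumMovie(movie, frame_rate), truth


# ---------------------------------------------------------------------------
# Full experiments on disk
# ---------------------------------------------------------------------------

def well_id(condition: str, density: float, biological: int, technical: int) -> str:
    cond = "co" if condition == "co-culture" else "ctrl"
    return f"{cond}_d{int(density)}_b{biological}_t{technical}"


def generate_experiment(
    out_dir: str | Path,
    design: ExperimentDesign = ExperimentDesign(),
    viability_curve: dict | None = None,
    activity_curve: dict | None = None,
    neurite_length: dict | None = None,
    image_shape: tuple[int, int] = DEFAULT_IMAGE_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    movie_shape: tuple[int, int] = (96, 96),
    stages: tuple[str, ...] = ("viability", "neurite"),
    seed: int = 0,
    force: bool = False,
    write_images: bool = True,
) -> pd.DataFrame:
    """Emit a full synthetic experiment dataset tree and return its truth table.

    Layout::

        out_dir/
          manifest.json          seed, parameters, file list
          design.csv             one row per well
          truth.csv              per-well ground truth
          wells/<well_id>/field<i>_{nuclei,dead,live}.tif
                          field<i>_neurite.tif           (stage "neurite")
                          pos<i>_calcium.tif             (stage "activity")

    Per-field cell numbers are Poisson-distributed around seeding density ×
    field area; the truth table records the realized counts, so end-to-end
    recovery is judged against what was actually drawn.  The activity stage
    is off by default because calcium stacks dominate disk and runtime; add
    ``"activity"`` to ``stages`` to emit movies.

    Refuses to overwrite an existing dataset unless ``force`` is set.
    """
    viability_curve = viability_curve or DEFAULT_VIABILITY_CURVE
    activity_curve = activity_curve or DEFAULT_ACTIVITY_CURVE
    neurite_length = neurite_length or DEFAULT_NEURITE_LENGTH
    for cond in design.conditions:
        for d in design.densities:
            if d not in viability_curve[cond]:
                raise ValueError(f"viability_curve missing {cond}@{d}")
            if "activity" in stages and d not in activity_curve[cond]:
                raise ValueError(f"activity_curve missing {cond}@{d}")

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is non-empty; pass force=True")
    (out / "wells").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    field_area = (
        image_shape[0] * pixel_size / UM_PER_CM
    ) * (image_shape[1] * pixel_size / UM_PER_CM)

    design_rows, truth_rows, files = [], [], []
    for cond, dens, b, t in design.iter_wells():
        wid = well_id(cond, dens, b, t)
        wdir = out / "wells" / wid
        if write_images:
            wdir.mkdir(exist_ok=True)
        viability = viability_curve[cond][dens]
        dead_fraction = 1.0 - viability
        tot = dead = 0
        neurite_true = 0.0
        for i in range(design.fields_per_well_viability):
            n = int(rng.poisson(dens * field_area))
            nuc, dd, lv, truth = generate_nuclei_field(
                n, dead_fraction, image_shape, pixel_size, seed=rng
            )
            tot += truth.n_total
            dead += truth.n_dead
            if write_images:
                _write_tiff(wdir / f"field{i}_nuclei.tif", nuc.pixels, files)
                _write_tiff(wdir / f"field{i}_dead.tif", dd.pixels, files)
                _write_tiff(wdir / f"field{i}_live.tif", lv.pixels, files)
            if "neurite" in stages:
                n_live = truth.n_total - truth.n_dead
                neu, nuc2, ntruth = generate_neurite_field(
                    n_live, neurite_length[cond], image_shape, pixel_size,
                    seed=rng,
                )
                neurite_true += ntruth.true_total_length
                if write_images:
                    _write_tiff(wdir / f"field{i}_neurite.tif", neu.pixels, files)
                    _write_tiff(
                        wdir / f"field{i}_neurite_nuclei.tif", nuc2.pixels, files
                    )
        n_spikes_true = 0
        n_cells_movies = 0
        if "activity" in stages:
            rate = activity_curve[cond][dens]
            movie_area = (
                movie_shape[0] * pixel_size / UM_PER_CM
            ) * (movie_shape[1] * pixel_size / UM_PER_CM)
            for p in range(design.positions_per_well_activity):
                n_mov = max(1, int(rng.poisson(dens * movie_area * viability)))
                movie, mtruth = generate_calcium_movie(
                    n_mov, rate, design.movie_duration, design.frame_rate,
                    movie_shape, seed=rng,
                )
                n_spikes_true += mtruth.total_spikes
                n_cells_movies += mtruth.n_cells
                if write_images:
                    _write_tiff_stack(
                        wdir / f"pos{p}_calcium.tif", movie.frames, files
                    )
        design_rows.append(
            dict(
                well_id=wid, condition=cond, density=dens, biological=b,
                technical=t, n_fields=design.fields_per_well_viability,
                n_positions=design.positions_per_well_activity,
                frame_rate=design.frame_rate, duration=design.movie_duration,
                pixel_size=pixel_size,
            )
        )
        truth_rows.append(
            dict(
                well_id=wid, condition=cond, density=dens, biological=b,
                technical=t,
                true_total=tot, true_dead=dead, true_live=tot - dead,
                true_viability=(tot - dead) / tot if tot else np.nan,
                true_live_density=(tot - dead)
                / (design.fields_per_well_viability * field_area),
                curve_viability=viability,
                true_neurite_length_um=neurite_true,
                true_n_spikes=n_spikes_true,
                true_n_cells_movies=n_cells_movies,
                true_rate_per_cell=(
                    activity_curve[cond][dens] if "activity" in stages else np.nan
                ),
            )
        )

    design_df = pd.DataFrame(design_rows)
    truth_df = pd.DataFrame(truth_rows)
    design_df.to_csv(out / "design.csv", index=False)
    truth_df.to_csv(out / "truth.csv", index=False)
    manifest = dict(
        seed=seed,
        stages=list(stages),
        image_shape=list(image_shape),
        movie_shape=list(movie_shape),
        pixel_size=pixel_size,
        field_area_cm2=field_area,
        n_wells=design.n_wells,
        files=sorted(files),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return truth_df


def _write_tiff(path: Path, pixels: np.ndarray, files: list) -> None:
    tifffile.imwrite(path, np.clip(pixels, 0, 65535).astype(np.uint16))
    files.append(str(path.relative_to(path.parents[2])))


def _write_tiff_stack(path: Path, frames: np.ndarray, files: list) -> None:
    tifffile.imwrite(path, np.clip(frames, 0, 65535).astype(np.uint16))
    files.append(str(path.relative_to(path.parents[2])))
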
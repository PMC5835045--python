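"""Live/dead viability quantification from nuclei and dead-stain channels.

Counting is semi-automatic: a single user-chosen threshold multiplier is
resolved per image against robust background statistics, the image is
binarized, connected components are filtered by area, and oversized clumps
are split by distance-transform declumping.  Per-well viability is
``(total − dead) / total`` with the dead count summed over the well's fields
and clamped to the total; live-cell density is live cells per summed imaged
area, directly comparable to the seeding density.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.stats import median_abs_deviation
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .core import ExperimentDesign, FieldCounts, Micrograph, ThresholdSpec, WellSummary

log = logging.getLogger(__name__)


def select_threshold(image: Micrograph, spec: ThresholdSpec) -> float:
    """Resolve an absolute intensity threshold for one image.

    Absolute mode returns ``spec.value`` unchanged.  Relative mode returns
    ``spec.value × (median + k_mad × MAD)`` of the image — a robust
    background scale, since objects occupy a small pixel fraction.  A
    degenerate all-zero image in relative mode raises rather than silently
    returning a zero threshold.
    """
    if spec.mode == "absolute":
        return float(spec.value)
    px = image.pixels.astype(float, copy=False)
    scale = float(np.median(px)) + spec.k_mad * float(
        median_abs_deviation(px, axis=None)
    )
    if scale <= 0:
        raise ValueError(
            "relative threshold undefined: image background scale is zero"
        )
    return float(spec.value) * scale


def _declump(
    mask: np.ndarray,
    intensity: np.ndarray | None = None,
    min_distance: int = 2,
) -> np.ndarray:
    """Split one oversized component by seeded watershed.

    Markers are the local maxima of the lightly smoothed intensity inside
    the component (round stains give one intensity peak per cell even when
    their footprints merge); without an intensity image the maxima of the
    distance transform are used instead.  A component with a single
    interior maximum stays whole.
    """
    if intensity is not None:
        relief = ndi.gaussian_filter(intensity.astype(float), sigma=0.6)
    else:
        relief = ndi.gaussian_filter(
            ndi.distance_transform_edt(mask), sigma=0.6
        )
    peaks = peak_local_max(
        relief, min_distance=min_distance, labels=mask, exclude_border=False
    )
    if len(peaks) <= 1:
        return mask.astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-relief, markers, mask=mask)


def count_objects(
    image: Micrograph, spec: ThresholdSpec
) -> tuple[int, np.ndarray]:
    """Count stained objects and return their centroids.

    Pipeline: binarize at :func:`select_threshold`; label 8-connected
    components; discard components smaller than ``min_object_area``;
    components larger than ``max_object_area`` are declumped by
    distance-transform local maxima + watershed, and the resulting pieces
    are re-filtered by ``min_object_area``.  Returns ``(count, centroids)``
    with centroids as an (N, 2) array of (row, col).
    """
    thr = select_threshold(image, spec)
    mask = image.pixels > thr
    if not mask.any():
        return 0, np.empty((0, 2))
    labels = cc_label(mask, connectivity=2)
    centroids: list[tuple[float, float]] = []
    for prop in regionprops(labels):
        if prop.area < spec.min_object_area:
            continue
        if prop.area <= spec.max_object_area:
            centroids.append(prop.centroid)
            continue
        sub = _declump(
            labels[prop.slice] == prop.label, image.pixels[prop.slice]
        )
        r0, c0 = prop.slice[0].start, prop.slice[1].start
        for piece in regionprops(sub):
            if piece.area >= spec.min_object_area:
                pr, pc = piece.centroid
                centroids.append((pr + r0, pc + c0))
    if not centroids:
        return 0, np.empty((0, 2))
    return len(centroids), np.asarray(centroids)


def segment_objects(image: Micrograph, spec: ThresholdSpec) -> np.ndarray:
    """Label image of accepted objects (same contract as count_objects)."""
    thr = select_threshold(image, spec)
    mask = image.pixels > thr
    out = np.zeros(image.pixels.shape, dtype=np.int32)
    if not mask.any():
        return out
    labels = cc_label(mask, connectivity=2)
    nxt = 1
    for prop in regionprops(labels):
        if prop.area < spec.min_object_area:
            continue
        if prop.area <= spec.max_object_area:
            out[prop.slice][labels[prop.slice] == prop.label] = nxt
            nxt += 1
            continue
        sub = _declump(
            labels[prop.slice] == prop.label, image.pixels[prop.slice]
        )
        for piece in regionprops(sub):
            if piece.area >= spec.min_object_area:
                out[prop.slice][sub == piece.label] = nxt
                nxt += 1
    return out


def count_field(
    nuclei: Micrograph,
    dead: Micrograph,
    nuclei_spec: ThresholdSpec,
    dead_spec: ThresholdSpec | None = None,
) -> FieldCounts:
    """Counts for one field: total from nuclei channel, dead from dead stain."""
    dead_spec = dead_spec or nuclei_spec
    n_total, _ = count_objects(nuclei, nuclei_spec)
    n_dead, _ = count_objects(dead, dead_spec)
    return FieldCounts(n_total, n_dead, nuclei.field_area_cm2)


def summarize_well(fields: list[FieldCounts]) -> WellSummary:
    """Aggregate a well's fields into viability and live-cell density.

    Counts are summed across fields before the ratio is taken.  The summed
    dead count is clamped to the summed total — the two come from different
    channels and can disagree on pathological input — so live = total − dead
    is never negative.  Viability is NaN for a well with zero counted cells.
    """
    if not fields:
        raise ValueError("summarize_well requires at least one field")
    total = sum(f.n_total for f in fields)
    dead = min(sum(f.n_dead for f in fields), total)
    live = total - dead
    viability = live / total if total > 0 else float("nan")
    area = sum(f.field_area for f in fields)
    return WellSummary(total, dead, live, viability, live / area)


def run_viability_analysis(
    dataset_dir: str | Path,
    nuclei_spec: ThresholdSpec = ThresholdSpec(),
    dead_spec: ThresholdSpec | None = None,
    design: ExperimentDesign | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Run viability counting over a dataset tree and return a per-well table.

    Expects the layout emitted by :func:`neurocult.synthetic.generate_experiment`
    (``design.csv`` plus ``wells/<well_id>/field<i>_{nuclei,dead}.tif``).  The
    relative threshold multiplier is fixed once and applied uniformly — the
    per-image absolute threshold adapts only through the robust background
    scale.  Wells with missing field images are flagged in the ``status``
    column rather than dropped.

    Columns: well_id, condition, density, biological, technical, total, dead,
    live, viability, live_density, status.
    """
    root = Path(dataset_dir)
    design_df = pd.read_csv(root / "design.csv")
    dead_spec = dead_spec or nuclei_spec
    rows = []
    for rec in design_df.itertuples():
        wdir = root / "wells" / rec.well_id
        fields: list[FieldCounts] = []
        status = "ok"
        for i in range(int(rec.n_fields)):
            npath = wdir / f"field{i}_nuclei.tif"
            dpath = wdir / f"field{i}_dead.tif"
            if not npath.exists() or not dpath.exists():
                status = "missing-fields"
                log.warning("well %s: missing field %d images", rec.well_id, i)
                continue
            nuc = Micrograph(
                tifffile.imread(npath).astype(float), rec.pixel_size, "nuclei"
            )
            dd = Micrograph(
                tifffile.imread(dpath).astype(float), rec.pixel_size, "dead"
            )
            fields.append(count_field(nuc, dd, nuclei_spec, dead_spec))
        if fields:
            s = summarize_well(fields)
            rows.append(
                dict(
                    well_id=rec.well_id, condition=rec.condition,
                    density=rec.density, biological=rec.biological,
                    technical=rec.technical, total=s.total, dead=s.dead,
                    live=s.live, viability=s.viability,
                    live_density=s.live_density, status=status,
                )
            )
        else:
            rows.append(
                dict(
                    well_id=rec.well_id, condition=rec.condition,
                    density=rec.density, biological=rec.biological,
                    technical=rec.technical, total=0, dead=0, live=0,
                    viability=float("nan"), live_density=float("nan"),
                    status="missing-fields",
                )
            )
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
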
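"""Neurite length measurement via thresholding and skeletonization.

The neurite stain is binarized with the condition-wide threshold, thinned to
1-px-wide centerlines, and the skeleton is measured with a diagonal-weighted
step metric (1 px for 4-neighbour steps, √2 px for diagonal steps), which
bounds the rotation bias of a straight segment below 9%.  Cell counts come
from the paired nuclei channel.  Condition-level comparability follows the
reference-image rule: the threshold is resolved once on a designated
reference image and reused verbatim across its condition.  Fold changes are
computed within each biological replicate against the mean of its control
samples.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from dataclasses import dataclass
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .core import Micrograph, ThresholdSpec
from .viability import count_objects, select_threshold

log = logging.getLogger(__name__)

SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class NeuriteMeasurement:
    """Per-image result: total neurite length (µm), cell count, threshold."""

    total_length: float
    n_cells: int
    threshold_used: float


def skeleton_length(skeleton: np.ndarray, pixel_size: float) -> float:
    """Physical length of a 1-px skeleton via the diagonal step metric.

    Each 4-adjacent pixel pair contributes ``pixel_size`` and each
    8-diagonal pair ``√2 × pixel_size``.  Diagonal pairs whose step is
    shortcut by an orthogonal neighbour (both legs of the right angle
    present) are skipped, so an L-corner is not double counted.
    """
    s = skeleton.astype(bool)
    if not s.any():
        return 0.0
    horiz = s[:, :-1] & s[:, 1:]
    vert = s[:-1, :] & s[1:, :]
    # Diagonal ↘ from (r, c) to (r+1, c+1); redundant if (r, c+1) or (r+1, c)
    # is also set (the path goes around the corner in two unit steps).
    d1 = s[:-1, :-1] & s[1:, 1:]
    d1 &= ~(s[:-1, 1:] | s[1:, :-1])
    # Diagonal ↙ from (r, c+1) to (r+1, c).
    d2 = s[:-1, 1:] & s[1:, :-1]
    d2 &= ~(s[:-1, :-1] | s[1:, 1:])
    n_unit = int(horiz.sum()) + int(vert.sum())
    n_diag = int(d1.sum()) + int(d2.sum())
    return (n_unit + SQRT2 * n_diag) * pixel_size


def measure_neurites(
    neurite_img: Micrograph,
    nuclei_img: Micrograph,
    neurite_spec: ThresholdSpec,
    nuclei_spec: ThresholdSpec,
    soma_exclusion_radius: float = 0.0,
) -> NeuriteMeasurement:
    """Measure total neurite length and cell count for one field.

    Binarizes the neurite channel, skeletonizes, and sums the diagonal-step
    metric over the skeleton; the cell count uses
    :func:`neurocult.viability.count_objects` on the nuclei channel.  When
    ``soma_exclusion_radius`` (px) is positive, skeleton pixels within that
    radius of a detected nucleus are removed before length summation.
    """
    if neurite_img.pixels.shape != nuclei_img.pixels.shape:
        raise ValueError("neurite and nuclei images must share a shape")
    if neurite_img.pixel_size != nuclei_img.pixel_size:
        raise ValueError("neurite and nuclei images must share a pixel size")
    thr = select_threshold(neurite_img, neurite_spec)
    mask = neurite_img.pixels > thr
    skel = skeletonize(mask)
    n_cells, centers = count_objects(nuclei_img, nuclei_spec)
    if soma_exclusion_radius > 0 and len(centers):
        soma = np.zeros(mask.shape, dtype=bool)
        idx = np.round(centers).astype(int)
        idx[:, 0] = np.clip(idx[:, 0], 0, mask.shape[0] - 1)
        idx[:, 1] = np.clip(idx[:, 1], 0, mask.shape[1] - 1)
        soma[idx[:, 0], idx[:, 1]] = True
        dist = ndi.distance_transform_edt(~soma)
        skel = skel & (dist > soma_exclusion_radius)
    length = skeleton_length(skel, neurite_img.pixel_size)
    return NeuriteMeasurement(length, n_cells, thr)


def propagate_threshold(
    images_in_condition: list[Micrograph],
    reference_index: int,
    spec: ThresholdSpec,
) -> list[float]:
    """Resolve the threshold on one reference image, reuse it verbatim.

    Mirrors the manual protocol: the threshold is determined on a single
    image and applied to all images of the same condition.  Returns one
    absolute threshold per image (all equal to the reference's).
    """
    if not images_in_condition:
        raise ValueError("propagate_threshold requires at least one image")
    if not 0 <= reference_index < len(images_in_condition):
        raise IndexError("reference_index outside the image list")
    ref_thr = select_threshold(images_in_condition[reference_index], spec)
    return [ref_thr] * len(images_in_condition)


def fold_change(
    table: pd.DataFrame,
    value_col: str,
    control_label: str = "control",
    condition_col: str = "condition",
    group_cols: tuple[str, ...] = ("biological", "density"),
) -> pd.DataFrame:
    """Normalize measurements to the control mean within each group.

    For every ``group_cols`` group (by default biological replicate ×
    density), each row's ``value_col`` is divided by the mean of the group's
    control rows.  Groups whose control mean is zero or that lack control
    rows are flagged (``fold_change`` NaN, ``fold_status`` column) and a
    warning is logged; they are never silently dropped.

    The mean fold change of control rows is exactly 1 in every valid group.
    """
    if table.empty:
        raise ValueError("fold_change requires a non-empty table")
    out = table.copy()
    # Snapshot first: value_col may itself be named "fold_change".
    values = out[value_col].astype(float).copy()
    out["fold_change"] = np.nan
    out["fold_status"] = "ok"
    for key, grp in out.groupby(list(group_cols)):
        ctrl = values.loc[grp.index[grp[condition_col] == control_label]]
        if ctrl.empty or not np.isfinite(ctrl.mean()) or ctrl.mean() == 0:
            out.loc[grp.index, "fold_status"] = "no-valid-control"
            log.warning("fold_change: group %s lacks a usable control mean", key)
            continue
        out.loc[grp.index, "fold_change"] = values.loc[grp.index] / ctrl.mean()
    return out


def run_neurite_analysis(
    dataset_dir: str | Path,
    neurite_spec: ThresholdSpec = ThresholdSpec(),
    nuclei_spec: ThresholdSpec = ThresholdSpec(),
    control_label: str = "control",
    out_csv: str | Path | None = None,
    fold_out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Measure neurites over a dataset tree; per-well totals plus fold changes.

    For each condition the neurite threshold is resolved on the condition's
    first available image and propagated to every other image of that
    condition.  Per well, lengths and cell counts are summed over fields
    before fold-change computation.  Returns the per-well table with
    ``fold_change`` columns for total length and length per cell.
    """
    root = Path(dataset_dir)
    design_df = pd.read_csv(root / "design.csv")

    # Resolve one threshold per condition from its reference image.
    cond_thr: dict[str, float] = {}
    for cond, sub in design_df.groupby("condition"):
        for rec in sub.itertuples():
            path = root / "wells" / rec.well_id / "field0_neurite.tif"
            if path.exists():
                ref = Micrograph(
                    tifffile.imread(path).astype(float), rec.pixel_size, "neurite"
                )
                cond_thr[cond] = select_threshold(ref, neurite_spec)
                break
        else:
            log.warning("condition %s: no neurite images found", cond)

    rows = []
    for rec in design_df.itertuples():
        if rec.condition not in cond_thr:
            continue
        fixed = ThresholdSpec(
            mode="absolute", value=cond_thr[rec.condition],
            min_object_area=neurite_spec.min_object_area,
            max_object_area=neurite_spec.max_object_area,
        )
        wdir = root / "wells" / rec.well_id
        total_len = 0.0
        total_cells = 0
        status = "ok"
        n_found = 0
        for i in range(int(rec.n_fields)):
            npath = wdir / f"field{i}_neurite.tif"
            cpath = wdir / f"field{i}_neurite_nuclei.tif"
            if not cpath.exists():
                cpath = wdir / f"field{i}_nuclei.tif"
            if not npath.exists() or not cpath.exists():
                status = "missing-fields"
                continue
            neu = Micrograph(
                tifffile.imread(npath).astype(float), rec.pixel_size, "neurite"
            )
            nuc = Micrograph(
                tifffile.imread(cpath).astype(float), rec.pixel_size, "nuclei"
            )
            m = measure_neurites(neu, nuc, fixed, nuclei_spec)
            total_len += m.total_length
            total_cells += m.n_cells
            n_found += 1
        rows.append(
            dict(
                well_id=rec.well_id, condition=rec.condition,
                density=rec.density, biological=rec.biological,
                technical=rec.technical, total_length_um=total_len,
                n_cells=total_cells,
                length_per_cell_um=total_len / total_cells if total_cells else np.nan,
                threshold_used=cond_thr[rec.condition],
                status=status if n_found else "missing-fields",
            )
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = fold_change(
            table, "total_length_um", control_label=control_label
        ).rename(
            columns={"fold_change": "fold_change_length",
                     "fold_status": "fold_status_length"}
        )
        table = fold_change(
            table, "length_per_cell_um", control_label=control_label
        ).rename(
            columns={"fold_change": "fold_change_length_per_cell",
                     "fold_status": "fold_status_length_per_cell"}
        )
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if fold_out_csv is not None:
        cols = [
            "well_id", "condition", "density", "biological", "technical",
            "total_length_um", "fold_change_length",
            "length_per_cell_um", "fold_change_length_per_cell",
        ]
        table[cols].to_csv(fold_out_csv, index=False)
    return table
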
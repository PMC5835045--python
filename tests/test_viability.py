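"""Thresholding, counting and well-summary behaviour of the viability stage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurocult import (
    FieldCounts,
    Micrograph,
    ThresholdSpec,
    count_objects,
    generate_nuclei_field,
    run_viability_analysis,
    select_threshold,
    summarize_well,
)


def flood_fill_count(mask: np.ndarray, min_area: int) -> int:
    """Brute-force 8-connectivity component count (independent oracle)."""
    mask = mask.copy()
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0]:
                continue
            stack = [(r0, c0)]
            mask[r0, c0] = False
            area = 0
            while stack:
                r, c = stack.pop()
                area += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                            mask[rr, cc] = False
                            stack.append((rr, cc))
            if area >= min_area:
                count += 1
    return count


class TestSelectThreshold:
    def test_absolute_mode_is_identity(self):
        img = Micrograph(np.ones((8, 8)), 1.0)
        spec = ThresholdSpec(mode="absolute", value=500.0)
        assert select_threshold(img, spec) == 500.0

    def test_relative_mode_on_constant_image(self):
        """median 100, MAD 0, k irrelevant at k=0: threshold = 1.5 × 100."""
        img = Micrograph(np.full((16, 16), 100.0), 1.0)
        spec = ThresholdSpec(mode="relative", value=1.5, k_mad=0.0)
        assert select_threshold(img, spec) == pytest.approx(150.0)

    def test_zero_image_raises_in_relative_mode(self):
        img = Micrograph(np.zeros((8, 8)), 1.0)
        with pytest.raises(ValueError, match="background scale"):
            select_threshold(img, ThresholdSpec(mode="relative", value=1.0))

    def test_threshold_separates_background_from_peaks(self):
        """On a generated field the resolved threshold clears ≥99% of
        background pixels yet stays below the truth-center peaks."""
        nuc, *_, truth = generate_nuclei_field(50, 0.0, seed=10)
        thr = select_threshold(nuc, ThresholdSpec())
        centers = np.round(truth.nuclei_centers).astype(int)
        peak_vals = nuc.pixels[centers[:, 0], centers[:, 1]]
        assert (peak_vals > thr).mean() >= 0.99
        # background = pixels far from any nucleus
        mask = np.ones_like(nuc.pixels, dtype=bool)
        for r, c in centers:
            mask[max(r - 10, 0) : r + 10, max(c - 10, 0) : c + 10] = False
        assert (nuc.pixels[mask] <= thr).mean() >= 0.99


class TestCountObjects:
    def test_blank_image(self):
        img = Micrograph(np.zeros((32, 32)), 1.0)
        spec = ThresholdSpec(mode="absolute", value=10.0)
        assert count_objects(img, spec) == (0, pytest.approx(np.empty((0, 2))))

    def test_well_separated_nuclei_counted_exactly(self, default_spec):
        nuc, *_, truth = generate_nuclei_field(50, 0.2, seed=20)
        n, centers = count_objects(nuc, default_spec)
        assert n == truth.n_total == 50
        # every reported centroid lies near a true center
        d = np.linalg.norm(
            centers[:, None] - truth.nuclei_centers[None], axis=-1
        ).min(axis=1)
        assert d.max() < 3.0

    def test_overlapping_pairs_within_five_percent(self, default_spec):
        errors = []
        for s in range(20):
            nuc, *_, truth = generate_nuclei_field(
                50, 0.2, overlap_pair_fraction=0.1, seed=s
            )
            n, _ = count_objects(nuc, default_spec)
            errors.append((n - truth.n_total) / truth.n_total)
        assert abs(np.mean(errors)) <= 0.05

    def test_threshold_monotonicity(self):
        """Raising the absolute threshold never increases the count."""
        nuc, *_, _ = generate_nuclei_field(40, 0.0, seed=21)
        counts = [
            count_objects(
                nuc,
                ThresholdSpec(mode="absolute", value=v, max_object_area=10**9),
            )[0]
            for v in (105.0, 108.0, 112.0, 118.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_flood_fill_oracle_equivalence(self, default_spec):
        """On non-touching objects, counting equals a brute-force flood fill
        of the binarized image."""
        nuc, *_, _ = generate_nuclei_field(
            25, 0.0, image_shape=(256, 256), seed=22
        )
        thr = select_threshold(nuc, default_spec)
        n, _ = count_objects(nuc, default_spec)
        assert n == flood_fill_count(
            nuc.pixels > thr, default_spec.min_object_area
        )

    def test_scale_equivariance_of_relative_mode(self, default_spec):
        nuc, *_, _ = generate_nuclei_field(30, 0.0, seed=23)
        n1, _ = count_objects(nuc, default_spec)
        scaled = Micrograph(nuc.pixels * 7.3, nuc.pixel_size, "nuclei")
        n2, _ = count_objects(scaled, default_spec)
        assert n1 == n2


class TestSummarizeWell:
    def test_three_field_arithmetic(self):
        fields = [FieldCounts(10, 2, 0.001)] * 3
        s = summarize_well(fields)
        assert (s.total, s.dead, s.live) == (30, 6, 24)
        assert s.viability == pytest.approx(0.8)
        assert s.live_density == pytest.approx(24 / 0.003)

    def test_all_dead(self):
        s = summarize_well([FieldCounts(5, 5, 0.001)])
        assert s.viability == 0.0 and s.live == 0

    def test_dead_clamped_to_total(self):
        s = summarize_well([FieldCounts(4, 9, 0.001)])
        assert s.dead == 4 and s.live == 0 and s.viability == 0.0

    def test_zero_cells_gives_nan_viability(self):
        s = summarize_well([FieldCounts(0, 0, 0.001)])
        assert np.isnan(s.viability)

    def test_empty_field_list_raises(self):
        with pytest.raises(ValueError):
            summarize_well([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 500), st.integers(0, 600)),
            min_size=1,
            max_size=5,
        )
    )
    def test_conservation_and_range(self, counts):
        """live + dead = total, viability in [0, 1] whenever total > 0."""
        fields = [FieldCounts(t, d, 0.004) for t, d in counts]
        s = summarize_well(fields)
        assert s.live + s.dead == s.total
        if s.total > 0:
            assert 0.0 <= s.viability <= 1.0


class TestRunViabilityAnalysis:
    def test_forty_well_table(self, tiny_dataset):
        root, _ = tiny_dataset
        table = run_viability_analysis(root)
        assert len(table) == 40
        assert set(table.status) == {"ok"}

    def test_injected_effect_direction_recovered(self, tiny_dataset):
        root, _ = tiny_dataset
        table = run_viability_analysis(root)
        for dens in (1000.0, 50000.0):
            sub = table[table.density == dens]
            co = sub[sub.condition == "co-culture"].viability.mean()
            ctrl = sub[sub.condition == "control"].viability.mean()
            assert co > ctrl

    def test_live_density_bounded_by_seeding(self, tiny_dataset):
        """Recovered live density never exceeds seeding density beyond
        Poisson placement fluctuation."""
        root, _ = tiny_dataset
        table = run_viability_analysis(root)
        area3 = 3 * (512 * 1.3 / 1e4) ** 2
        for rec in table.itertuples():
            n_expect = rec.density * area3
            upper = rec.density * (1 + 3 / np.sqrt(n_expect))
            assert rec.live_density <= upper

    def test_missing_field_flagged_not_dropped(self, tmp_path, tiny_design):
        from neurocult import generate_experiment

        root = tmp_path / "ds"
        generate_experiment(
            root,
            tiny_design,
            stages=("viability",),
            seed=5,
        )
        victim = next((root / "wells").iterdir())
        (victim / "field0_nuclei.tif").unlink()
        table = run_viability_analysis(root)
        assert len(table) == 40
        flagged = table[table.well_id == victim.name]
        assert (flagged.status == "missing-fields").all()
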
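"""Preprocessing: resampling, windowing, slice selection, pack assembly."""

import numpy as np
import pytest

from ctprog.phantom import PatientVolumeSet
from ctprog.preprocess import (
    ABDOMEN_WINDOW,
    CHEST_WINDOW,
    WindowSpec,
    apply_window,
    assemble_pack,
    augment_flip,
    resample_axial,
    select_slices,
)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

class TestResample:
    def test_already_at_target_is_identity(self, rng):
        vol = rng.normal(size=(6, 5, 5))
        out = resample_axial(vol, (5.0, 1.0, 1.0))
        assert np.array_equal(out, vol)

    def test_linear_ramp_resampled_exactly(self):
        # values linear in z at 2.5-mm spacing: interpolation at 5 mm is exact
        nz = 9
        vol = np.tile((2.0 * np.arange(nz) + 1.0)[:, None, None], (1, 4, 4))
        out = resample_axial(vol, (2.5, 1.0, 1.0))
        # new positions at 0, 5, 10, ... mm = source index 0, 2, 4, ...
        expected_z = 2.0 * np.arange(0, nz, 2) + 1.0
        assert out.shape[0] == 5
        assert np.allclose(out[:, 0, 0], expected_z)

    def test_constant_volume_stays_constant(self):
        vol = np.full((7, 3, 3), 42.0)
        out = resample_axial(vol, (3.3, 1.0, 1.0))
        assert np.allclose(out, 42.0)

    def test_z_extent_preserved_within_one_slice(self, rng):
        vol = rng.normal(size=(11, 3, 3))
        zs = 2.0
        out = resample_axial(vol, (zs, 1.0, 1.0))
        in_extent = (vol.shape[0] - 1) * zs
        out_extent = (out.shape[0] - 1) * 5.0
        assert abs(in_extent - out_extent) <= 5.0

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            resample_axial(np.zeros((4, 3, 3)), (0.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

class TestWindow:
    def test_endpoints_map_to_0_and_1(self):
        spec = WindowSpec(width=400, level=50)
        assert apply_window(np.array(50 - 200.0), spec) == 0.0
        assert apply_window(np.array(50 + 200.0), spec) == 1.0

    def test_abdomen_example(self):
        assert apply_window(np.array(100.0), ABDOMEN_WINDOW) == pytest.approx(0.75)

    def test_chest_level_maps_to_midpoint(self):
        assert apply_window(np.array(-600.0), CHEST_WINDOW) == pytest.approx(0.5)

    def test_monotone_and_clipped(self, rng):
        hu = rng.uniform(-2000, 2000, size=100)
        out = apply_window(hu, ABDOMEN_WINDOW)
        assert (out >= 0).all() and (out <= 1).all()
        order = np.argsort(hu)
        assert (np.diff(out[order]) >= 0).all()

    def test_unit_window_is_identity_on_unit_interval(self, rng):
        img = rng.uniform(0, 1, size=(8, 8))
        assert np.allclose(apply_window(img, WindowSpec(1.0, 0.5)), img)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(width=0, level=0)


# ---------------------------------------------------------------------------
# slice selection
# ---------------------------------------------------------------------------

def _masks_from_areas(tumor_areas, organ_areas, width=12):
    """Build 3D masks whose per-slice areas equal the given counts."""
    nz = len(tumor_areas)
    tumor = np.zeros((nz, width, width), bool)
    organ = np.zeros((nz, width, width), bool)
    for z, (at, ao) in enumerate(zip(tumor_areas, organ_areas)):
        flat_o = organ[z].reshape(-1)
        flat_o[:ao] = True
        flat_t = tumor[z].reshape(-1)
        flat_t[:at] = True
    return tumor, organ | tumor  # organ covers tumor voxels


def _oracle_select(tumor_areas, organ_areas, k=3):
    """Independent greedy argmax re-implementation of the selection rule."""
    n = len(tumor_areas)
    chosen, basis = [], []
    candidates = [z for z in range(n) if tumor_areas[z] > 0]
    candidates.sort(key=lambda z: (-tumor_areas[z], z))
    for z in candidates[:k]:
        chosen.append(z)
        basis.append("tumor_area")
    rest = [z for z in range(n) if z not in chosen and organ_areas[z] > 0]
    rest.sort(key=lambda z: (-organ_areas[z], z))
    for z in rest[: k - len(chosen)]:
        chosen.append(z)
        basis.append("organ_area")
    while len(chosen) < k and chosen:
        chosen.append(chosen[-1])
        basis.append("pad")
    return chosen, basis


class TestSelectSlices:
    def test_pure_tumor_ranking(self):
        tumor, organ = _masks_from_areas([0, 5, 9, 2], [10, 10, 10, 10])
        idx, basis = select_slices(tumor, organ)
        assert idx == [2, 1, 3]
        assert basis == ["tumor_area"] * 3

    def test_organ_fallback_with_tie_broken_by_smaller_z(self):
        tumor, organ = _masks_from_areas([0, 0, 0, 0], [10, 40, 40, 5])
        idx, basis = select_slices(tumor, organ)
        assert idx == [1, 2, 0]
        assert basis == ["organ_area"] * 3

    def test_mixed_tumor_then_organ_without_reuse(self):
        tumor, organ = _masks_from_areas([0, 7, 0, 0], [9, 8, 8, 3])
        idx, basis = select_slices(tumor, organ)
        assert idx == [1, 0, 2]
        assert basis == ["tumor_area", "organ_area", "organ_area"]

    def test_empty_organ_rejected(self):
        with pytest.raises(ValueError):
            select_slices(np.zeros((4, 5, 5), bool), np.zeros((4, 5, 5), bool))

    def test_padding_when_organ_spans_fewer_slices(self):
        tumor, organ = _masks_from_areas([0, 4, 0], [0, 6, 0])
        idx, basis = select_slices(tumor, organ)
        assert idx == [1, 1, 1]
        assert basis == ["tumor_area", "pad", "pad"]

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(200):
            nz = int(rng.integers(3, 9))
            a_o = rng.integers(0, 30, size=nz)
            a_t = np.where(rng.random(nz) < 0.5, rng.integers(0, 10, size=nz), 0)
            a_t = np.minimum(a_t, a_o)  # tumor within organ
            if a_o.sum() == 0:
                a_o[0] = 1
            tumor, organ = _masks_from_areas(a_t.tolist(), a_o.tolist())
            idx, basis = select_slices(tumor, organ)
            oidx, obasis = _oracle_select(a_t.tolist(), a_o.tolist())
            assert idx == oidx and basis == obasis


# ---------------------------------------------------------------------------
# pack assembly
# ---------------------------------------------------------------------------

class TestAssemblePack:
    def test_pack_has_exactly_12_standardized_images(self, small_cohort, small_packs):
        for pack in small_packs:
            assert pack.n_images == 12
            for arr in pack.images.values():
                assert arr.shape == (3, 224, 224)
                for img in arr:
                    if img.std() > 0:
                        assert abs(float(img.mean())) < 1e-5
                        assert abs(float(img.var()) - 1.0) < 1e-4

    def test_locf_copies_baseline_chest(self, small_cohort, small_packs):
        _, vols, _, _ = small_cohort
        assert any(not v.followup_chest_present for v in vols)
        for v, pack in zip(vols, small_packs):
            if not v.followup_chest_present:
                assert pack.locf_applied
                assert np.array_equal(pack.images[("lung", "followup")],
                                      pack.images[("lung", "baseline")])
            else:
                assert not pack.locf_applied

    def test_missing_baseline_is_hard_error(self, small_cohort):
        _, vols, _, _ = small_cohort
        v = vols[0]
        crippled = PatientVolumeSet(
            patient_id=v.patient_id,
            volumes={k: a for k, a in v.volumes.items() if k != ("liver", "baseline")},
            organ_masks=v.organ_masks, tumor_masks=v.tumor_masks,
            spacing_mm=v.spacing_mm,
            followup_chest_present=v.followup_chest_present)
        with pytest.raises(ValueError):
            assemble_pack(crippled)

    def test_identical_followup_equals_locf_output(self, small_cohort):
        """A physically present follow-up chest identical to baseline yields the
        same pack as an absent one imputed by LOCF."""
        _, vols, _, _ = small_cohort
        v = next(x for x in vols if x.followup_chest_present)
        dup = PatientVolumeSet(
            patient_id=v.patient_id,
            volumes={**v.volumes, ("lung", "followup"): v.volumes[("lung", "baseline")]},
            organ_masks={**v.organ_masks,
                         ("lung", "followup"): v.organ_masks[("lung", "baseline")]},
            tumor_masks={**v.tumor_masks,
                         ("lung", "followup"): v.tumor_masks[("lung", "baseline")]},
            spacing_mm=v.spacing_mm, followup_chest_present=True)
        absent = PatientVolumeSet(
            patient_id=v.patient_id,
            volumes={k: a for k, a in v.volumes.items() if k != ("lung", "followup")},
            organ_masks={k: a for k, a in v.organ_masks.items() if k != ("lung", "followup")},
            tumor_masks={k: a for k, a in v.tumor_masks.items() if k != ("lung", "followup")},
            spacing_mm=v.spacing_mm, followup_chest_present=False)
        p_dup = assemble_pack(dup)
        p_absent = assemble_pack(absent)
        for key in p_dup.images:
            assert np.array_equal(p_dup.images[key], p_absent.images[key])

    def test_constant_region_standardizes_to_zeros(self):
        shape = (6, 20, 20)
        organ = np.zeros(shape, bool)
        organ[:, 5:15, 5:15] = True
        keys = [("liver", "baseline"), ("liver", "followup"),
                ("lung", "baseline"), ("lung", "followup")]
        v = PatientVolumeSet(
            patient_id="C",
            volumes={k: np.full(shape, 100.0, np.float32) for k in keys},
            organ_masks={k: organ for k in keys},
            tumor_masks={k: np.zeros(shape, bool) for k in keys},
            spacing_mm=(5.0, 1.0, 1.0))
        pack = assemble_pack(v)
        for arr in pack.images.values():
            assert np.allclose(arr, 0.0)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

class TestAugmentFlip:
    def test_p_zero_is_identity(self, small_packs):
        pack = small_packs[0]
        out = augment_flip(pack, p=0.0, seed=0)
        for key in pack.images:
            assert np.array_equal(out.images[key], pack.images[key])

    def test_p_one_mirrors_every_image(self, small_packs):
        pack = small_packs[0]
        out = augment_flip(pack, p=1.0, seed=0)
        for key in pack.images:
            assert np.array_equal(out.images[key], pack.images[key][:, :, ::-1])

    def test_flip_fraction_near_half(self, rng):
        from ctprog.preprocess import SlicePack

        images = {("liver", "baseline"): rng.normal(size=(1000, 8, 8)).astype(np.float32)}
        pack = SlicePack(patient_id="F", images=images)
        out = augment_flip(pack, p=0.5, seed=123)
        flipped = sum(
            not np.array_equal(out.images[("liver", "baseline")][i],
                               images[("liver", "baseline")][i])
            for i in range(1000))
        assert abs(flipped / 1000 - 0.5) < 0.05


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.floats(1e-3, 4000), st.floats(-1200, 1200),
       st.lists(st.floats(-3000, 3000), min_size=2, max_size=40))
def test_windowing_bounded_and_monotone_property(width, level, hus):
    """Any window maps HU into [0, 1] preserving order."""
    spec = WindowSpec(width=width, level=level)
    hu = np.array(hus)
    out = apply_window(hu, spec)
    assert (out >= 0).all() and (out <= 1).all()
    order = np.argsort(hu, kind="stable")
    assert (np.diff(out[order]) >= -1e-12).all()
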
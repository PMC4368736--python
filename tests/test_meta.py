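import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucmix import meta
from nucmix.meta import (
    FocusRecord,
    ReferenceCOM,
    assign_hemisphere,
    com_separation,
    coord_kernel_correlation,
    deviation_stats,
    kernel_summary,
    load_foci,
    mni_to_tal,
    roi_volume_ratio,
    tal_to_mni,
    voxel_summary,
)


def _record(structure="STN", x=5.0, y=-15.0, z=-5.0, fwhm=6.0, vol=27.0, sid="s1"):
    return FocusRecord(
        study_id=sid, task="t", structure=structure, space="MNI",
        x=x, y=y, z=z, fwhm=fwhm, voxel_volume=vol, field_strength=3.0,
    )


_SIMPLE_REFS = [
    ReferenceCOM("STN", "L", (-10.0, -14.0, -6.0)),
    ReferenceCOM("STN", "R", (10.0, -14.0, -6.0)),
    ReferenceCOM("SN", "L", (-9.0, -16.0, -12.0)),
    ReferenceCOM("SN", "R", (9.0, -16.0, -12.0)),
]


class TestLoadFoci:
    def test_fixture_has_52_studies(self, foci_records):
        assert len({r.study_id for r in foci_records}) == 52

    def test_unreported_coordinates_are_retained_without_position(self, foci_records):
        no_coord = [r for r in foci_records if not r.has_coordinate]
        assert len(no_coord) == 9
        assert all(r.x is None and r.y is None and r.z is None for r in no_coord)
        # they still carry kernel metadata for the summaries
        assert any(r.fwhm is not None for r in no_coord)

    def test_malformed_structure_label_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "study_id,structure,x_mm,y_mm,z_mm,fwhm_mm\n"
            "s1,STM,1,2,3,6\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            load_foci(bad)

    def test_non_numeric_coordinate_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "study_id,structure,x_mm,y_mm,z_mm,fwhm_mm\n"
            "s1,STN,abc,2,3,6\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            load_foci(bad)

    def test_decimal_commas_normalized(self, tmp_path):
        path = tmp_path / "commas.csv"
        path.write_text(
            "study_id,structure,x_mm,y_mm,z_mm,fwhm_mm\n"
            's1,SN,"-11,92","-19,31","-8,07",6\n'
        )
        (rec,) = load_foci(path)
        assert rec.x == pytest.approx(-11.92)


class TestTalairachTransform:
    def test_round_trip_identity(self):
        coord = np.array([12.0, -20.0, -8.0])
        assert np.allclose(mni_to_tal(tal_to_mni(coord)), coord, atol=1e-9)

    def test_origin_maps_to_translation_column(self):
        assert np.allclose(tal_to_mni((0, 0, 0)), (-1.0423, -1.3940, 3.6475))

    @given(
        lam=st.floats(min_value=-3, max_value=3),
        bx=st.floats(min_value=-20, max_value=20),
    )
    @settings(max_examples=30, derandomize=True)
    def test_transform_is_affine(self, lam, bx):
        a = np.array([3.0, -11.0, -6.0])
        b = np.array([bx, 4.0, -2.0])
        lhs = tal_to_mni(a + lam * b) - tal_to_mni(a)
        rhs = lam * (tal_to_mni(b) - tal_to_mni((0, 0, 0)))
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            tal_to_mni((np.nan, 0, 0))


class TestAssignHemisphere:
    @pytest.mark.parametrize("x,expected", [(-12.0, "L"), (0.0, "R"), (8.0, "R")])
    def test_sign_convention(self, x, expected):
        assert assign_hemisphere(x) == expected

    def test_missing_x_rejected(self):
        with pytest.raises(ValueError):
            assign_hemisphere(_record(x=None, y=None, z=None))


class TestDeviationStats:
    def test_focus_at_com_gives_zero_deviation(self):
        stats = deviation_stats([_record(x=-10.0, y=-14.0, z=-6.0, structure="STN")], _SIMPLE_REFS)
        row = stats.iloc[0]
        assert row.mean_dx == row.mean_dy == row.mean_dz == row.mean_total == 0.0

    def test_3_4_5_offset(self):
        stats = deviation_stats([_record(x=13.0, y=-14.0, z=-2.0, structure="STN")], _SIMPLE_REFS)
        row = stats.iloc[0]
        assert (row.mean_dx, row.mean_dz, row.mean_total) == (3.0, 4.0, 5.0)
        assert np.isnan(row.sd_total)  # single focus: sample SD undefined

    def test_all_sn_type_labels_compared_to_sn_com(self):
        recs = [
            _record(structure="SN", x=9.0, y=-16.0, z=-12.0, sid="a"),
            _record(structure="SN/VTA", x=9.0, y=-16.0, z=-12.0, sid="b"),
            _record(structure="SN/STN", x=9.0, y=-16.0, z=-12.0, sid="c"),
        ]
        stats = deviation_stats(recs, _SIMPLE_REFS)
        assert set(stats.structure_group) == {"SN", "SN/VTA", "SN/STN"}
        assert np.allclose(stats.mean_total, 0.0)

    def test_matches_naive_per_focus_oracle_on_fixture(self, foci_records):
        stats = deviation_stats(foci_records, _SIMPLE_REFS)
        lookup = {(r.structure, r.hemisphere): np.asarray(r.coordinate) for r in _SIMPLE_REFS}
        for _, row in stats.iterrows():
            deltas, totals = [], []
            for rec in foci_records:  # independent loop-based recount
                if not rec.has_coordinate:
                    continue
                hemi = "L" if rec.x < 0 else "R"
                if rec.structure != row.structure_group or hemi != row.hemisphere:
                    continue
                ref = lookup[(meta.STRUCTURE_TO_REFERENCE[rec.structure], hemi)]
                d = rec.coordinate - ref
                deltas.append(d)
                totals.append(float(np.linalg.norm(d)))
            deltas = np.array(deltas)
            assert row.n_coordinates == len(totals)
            assert row.mean_dx == pytest.approx(deltas[:, 0].mean(), abs=1e-12)
            assert row.mean_total == pytest.approx(np.mean(totals), abs=1e-12)

    def test_permutation_invariant(self, foci_records):
        rng = np.random.default_rng(3)
        shuffled = list(foci_records)
        rng.shuffle(shuffled)
        a = deviation_stats(foci_records, _SIMPLE_REFS)
        b = deviation_stats(shuffled, _SIMPLE_REFS)
        key = ["structure_group", "hemisphere"]
        a, b = a.sort_values(key).reset_index(drop=True), b.sort_values(key).reset_index(drop=True)
        assert a[key + ["n_coordinates", "n_studies"]].equals(b[key + ["n_coordinates", "n_studies"]])
        numeric = [c for c in a.columns if c.startswith(("mean_", "sd_"))]
        assert np.allclose(a[numeric], b[numeric], atol=1e-12, equal_nan=True)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="missing reference"):
            deviation_stats([_record()], [ReferenceCOM("SN", "L", (-9.0, -16.0, -12.0))])

    def test_fixture_group_sizes(self, foci_records):
        """Left-hemisphere groups match the published deviation table.

        (The published right-hemisphere counts do not reconcile with the
        study table itself; the right groups assert the faithful
        transcription counts.)
        """
        stats = deviation_stats(foci_records, _SIMPLE_REFS)
        sizes = stats.set_index(["hemisphere", "structure_group"])["n_coordinates"]
        assert sizes[("L", "SN")] == 12
        assert sizes[("L", "SN/VTA")] == 17
        assert sizes[("L", "STN")] == 20
        assert sizes[("R", "SN/STN")] == 1
        assert sizes[("R", "SN")] == 16
        assert sizes[("R", "SN/VTA")] == 21
        assert sizes[("R", "STN")] == 26
        studies = stats.set_index(["hemisphere", "structure_group"])["n_studies"]
        assert studies[("L", "SN")] == 9
        assert studies[("L", "STN")] == 12
        assert studies[("R", "STN")] == 14


class TestKernelSummary:
    def test_fixture_reproduces_published_kernel_statistics(self, foci_records):
        s = kernel_summary(foci_records)
        assert s["median_fwhm_mm"] == 6.0
        assert s["modal_fwhm_mm"] == 8.0
        assert s["n_studies_mode"] == 16
        assert s["n_studies_total"] == 52
        assert s["mean_fwhm_mm"] == pytest.approx(6.3, abs=0.5)

    def test_uniform_kernels(self):
        recs = [_record(fwhm=5.0, sid=f"s{i}") for i in range(4)]
        s = kernel_summary(recs)
        assert s["mean_fwhm_mm"] == s["median_fwhm_mm"] == s["modal_fwhm_mm"] == 5.0
        assert s["n_studies_mode"] == 4

    def test_within_study_kernels_averaged_once(self):
        recs = [
            _record(fwhm=4.0, sid="multi"),
            _record(fwhm=8.0, sid="multi"),
            _record(fwhm=6.0, sid="single"),
        ]
        s = kernel_summary(recs)
        assert s["mean_fwhm_mm"] == pytest.approx(6.0)  # (6 + 6) / 2
        assert s["n_studies_reporting"] == 2

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            kernel_summary([_record(fwhm=None)])


class TestVoxelSummary:
    def test_fixture_reproduces_published_voxel_statistics(self, foci_records):
        s = voxel_summary(foci_records)
        assert s["min_voxel_volume_mm3"] == pytest.approx(3.4, abs=0.05)
        assert s["max_voxel_volume_mm3"] == pytest.approx(103.8, abs=0.05)
        assert s["mean_voxel_volume_mm3"] == pytest.approx(34.0, abs=0.5)

    def test_single_study_sd_undefined(self):
        s = voxel_summary([_record(vol=27.0)])
        assert np.isnan(s["sd_voxel_volume_mm3"])


class TestCoordKernelCorrelation:
    def test_exactly_linear_pairs(self):
        recs = [_record(z=float(f), fwhm=float(f), sid=f"s{i}") for i, f in enumerate((2, 4, 6, 8))]
        r, df, p = coord_kernel_correlation(recs, ("STN",), "z")
        assert r == pytest.approx(1.0)
        assert df == 2

    def test_anti_linear_pairs(self):
        recs = [_record(z=-float(f), fwhm=float(f), sid=f"s{i}") for i, f in enumerate((2, 4, 6, 8))]
        r, _, _ = coord_kernel_correlation(recs, ("STN",), "z")
        assert r == pytest.approx(-1.0)

    def test_constant_kernel_rejected(self):
        recs = [_record(z=float(i), fwhm=6.0, sid=f"s{i}") for i in range(4)]
        with pytest.raises(ValueError):
            coord_kernel_correlation(recs, ("STN",), "z")

    def test_sn_group_z_correlation_positive_on_fixture(self, foci_records):
        r, df, _ = coord_kernel_correlation(foci_records, ("SN", "SN/VTA", "SN/STN"), "z")
        assert r > 0
        assert df >= 3


class TestComSeparation:
    def test_identical_coms_give_zero(self):
        refs = [ReferenceCOM("STN", "L", (-5.0, 0, 0)), ReferenceCOM("SN", "L", (-5.0, 0, 0))]
        assert com_separation(refs) == {"L": 0.0}

    def test_synthetic_atlas_recovers_configured_separation(self, default_cohort):
        from nucmix.anatomy import default_config

        cfg = default_config()
        refs = meta.reference_coms_from_cohort(default_cohort)
        seps = com_separation(refs)
        assert seps["L"] == pytest.approx(cfg.com_separation_left, abs=0.5)
        assert seps["R"] == pytest.approx(cfg.com_separation_right, abs=0.5)

    def test_missing_structure_rejected(self):
        with pytest.raises(ValueError):
            com_separation([ReferenceCOM("STN", "L", (-5.0, 0, 0))])


class TestRoiVolumeRatio:
    def test_equal_volumes(self):
        assert roi_volume_ratio(120.0, 120.0) == 1.0

    def test_box_vs_median_and_mean_literature_volumes(self):
        # 10 mm cube vs weighted-median and weighted-average nucleus volume
        assert roi_volume_ratio(1000.0, 131.75) == pytest.approx(7.59, abs=0.01)
        assert roi_volume_ratio(1000.0, 119.88) == pytest.approx(8.34, abs=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            roi_volume_ratio(0.0, 100.0)


class TestReferenceComYaml:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "coms.yaml"
        meta.save_reference_coms(_SIMPLE_REFS, path)
        loaded = meta.load_reference_coms(path)
        assert {(r.structure, r.hemisphere, r.coordinate) for r in loaded} == {
            (r.structure, r.hemisphere, r.coordinate) for r in _SIMPLE_REFS
        }

    def test_wrong_side_com_rejected(self):
        with pytest.raises(ValueError):
            ReferenceCOM("STN", "L", (4.0, 0, 0))
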
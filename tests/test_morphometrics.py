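import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from eggchamber import morphometrics as mm
from eggchamber import synthetic_data as sd


def circle_geometry(radius=50.0, n=1440, n_fc=40):
    """Circle split into symmetric halves by a straight diameter chord."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    contour = radius * np.stack([np.cos(th), np.sin(th)], axis=1)
    y = np.linspace(-radius, radius, 201)[1:-1]
    interface = np.stack([np.zeros_like(y), y], axis=1)
    perim = 2 * np.pi * radius
    pos = (np.arange(n_fc) + 0.5) / n_fc * perim
    return sd.EggChamberGeometry(
        outer_contour=contour,
        aspect_ratio_AP=1.0,
        germline_area=np.pi * radius**2,
        oocyte_area=np.pi * radius**2 / 2,
        nc_oocyte_interface=interface,
        triple_eta=np.pi / 2,
        fc_positions=pos,
        fc_extents=np.full(n_fc, perim / n_fc),
        fc_fate=np.array(["MBFC"] * n_fc, dtype=object),
        fc_eya=np.full(n_fc, 80.0),
        fc_total_count_3d=850,
        afc_count_3d=85,
        interface_angle_true=90.0,
        nc_section_area_fractions=np.full(7, 1 / 7),
        nc_section_interface_fractions=np.full(7, 1 / 7),
    )


class TestAssignPhase:
    @pytest.mark.parametrize(
        "area,phase", [(5000.0, 1), (6500.0, 2), (20000.0, 2), (31500.0, 3),
                       (40000.0, 3)]
    )
    def test_boundaries_left_closed(self, area, phase):
        assert mm.assign_phase(area) == phase

    @given(st.floats(1.0, 1e6), st.floats(1.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_area(self, a1, a2):
        lo, hi = sorted((a1, a2))
        assert mm.assign_phase(lo) <= mm.assign_phase(hi)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            mm.assign_phase(0.0)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            mm.PhaseThresholds(t12=5000.0, t23=4000.0)


class TestInterfaceAngle:
    def test_perpendicular_diameter_gives_ninety(self):
        geo = circle_geometry()
        assert mm.interface_angle(geo) == pytest.approx(90.0, abs=1.5)

    def test_oocyte_wetting_below_ninety(self, noise_free_config):
        g = sd.generate_chamber(15000.0, "wt", seed=2, config=noise_free_config)
        assert g.interface_angle_true < 90
        assert mm.interface_angle(g) < 90

    def test_nurse_bulge_above_ninety(self, noise_free_config):
        g = sd.generate_chamber(3000.0, "wt", seed=2, config=noise_free_config)
        assert g.interface_angle_true > 90
        assert mm.interface_angle(g) > 90

    def test_mirror_symmetry(self, noise_free_config):
        g = sd.generate_chamber(15000.0, "wt", seed=2, config=noise_free_config)
        flipped = dataclasses.replace(
            g,
            outer_contour=g.outer_contour * np.array([1.0, -1.0]),
            nc_oocyte_interface=(g.nc_oocyte_interface * np.array([1.0, -1.0]))[
                ::-1
            ],
        )
        assert mm.interface_angle(flipped) == pytest.approx(
            mm.interface_angle(g), abs=0.5
        )

    def test_detached_interface_rejected(self):
        geo = circle_geometry()
        geo.nc_oocyte_interface = geo.nc_oocyte_interface * 0.5  # floats inside
        with pytest.raises(ValueError, match="reach"):
            mm.interface_angle(geo)


class TestContactProportion:
    def test_empty_oocyte_gives_zero(self, noise_free_config):
        g = sd.generate_chamber(3000.0, "wt", seed=1, config=noise_free_config)
        g = dataclasses.replace(g, oocyte_area=0.0)
        assert mm.contact_proportion(g) == 0.0

    def test_whole_germline_oocyte_gives_one(self, noise_free_config):
        g = sd.generate_chamber(3000.0, "wt", seed=1, config=noise_free_config)
        g = dataclasses.replace(g, oocyte_area=g.germline_area)
        assert mm.contact_proportion(g) == 1.0

    def test_phase1_fraction_in_printed_band(self, noise_free_config):
        props = [
            mm.contact_proportion(
                sd.generate_chamber(a, "wt", seed=i, config=noise_free_config)
            )
            for i, a in enumerate(np.linspace(1200, 6200, 10))
        ]
        assert 0.14 <= np.mean(props) <= 0.20

    def test_contact_proportions_sum_to_one(self, noise_free_config):
        g = sd.generate_chamber(15000.0, "wt", seed=3, config=noise_free_config)
        rec = mm.measure(g)
        prop_oo = rec.values["prop_fc_on_oocyte"]
        # nurse-side proportion is the complement by construction
        u_frac = rec.values["oocyte_fc_interface_fraction"]
        nc_frac = rec.values["nc_fc_interface_length"] / rec.values[
            "germline_perimeter"
        ]
        assert u_frac + nc_frac == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= prop_oo <= 1.0


class TestNurseCellCV:
    def test_identical_cells_zero_cv(self):
        geo = circle_geometry()
        cvs = mm.nurse_cell_cv(geo)
        assert cvs["cv_area_fraction"] == pytest.approx(0.0, abs=1e-12)
        assert cvs["cv_interface_fraction"] == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_example(self):
        geo = circle_geometry()
        geo.nc_section_area_fractions = np.array([0.25, 0.75])
        geo.nc_section_interface_fractions = np.array([0.5, 0.5])
        assert mm.nurse_cell_cv(geo)["cv_area_fraction"] == pytest.approx(
            0.7071, abs=1e-4
        )

    def test_single_cell_rejected(self):
        geo = circle_geometry()
        geo.nc_section_area_fractions = np.array([1.0])
        geo.nc_section_interface_fractions = np.array([1.0])
        with pytest.raises(ValueError):
            mm.nurse_cell_cv(geo)

    def test_eya_knockdown_raises_nurse_variance(self, noise_free_config):
        wt = sd.generate_chamber(4000.0, "wt", seed=6, config=noise_free_config)
        kd = sd.generate_chamber(4000.0, "gr1_eyaRNAi", seed=6,
                                 config=noise_free_config)
        assert (
            mm.nurse_cell_cv(kd)["cv_area_fraction"]
            > mm.nurse_cell_cv(wt)["cv_area_fraction"]
        )


class TestApicalProfile:
    def test_phase1_extents_uniform(self, noise_free_config):
        g = sd.generate_chamber(3000.0, "wt", seed=1, config=noise_free_config)
        prof = mm.apical_area_profile(g)
        ext = prof["apical_extent_um"].to_numpy()
        assert np.ptp(ext) / ext.mean() < 0.01

    def test_phase2_gradient_decreases_posteriorly(self, noise_free_config):
        g = sd.generate_chamber(20000.0, "wt", seed=1, config=noise_free_config)
        prof = mm.apical_area_profile(g)
        afc = prof[prof["fate"] == "AFC"]
        rho = spearmanr(
            afc["apical_extent_um"], afc["distance_to_anterior_um"]
        ).statistic
        assert rho < 0

    def test_profile_covers_upper_half_rows(self, noise_free_config):
        g = sd.generate_chamber(3000.0, "wt", seed=1, config=noise_free_config)
        prof = mm.apical_area_profile(g)
        assert len(prof) == g.fc_positions.size // 2


class TestMeasure:
    def test_deterministic(self, noise_free_config):
        g = sd.generate_chamber(9000.0, "wt", seed=8, config=noise_free_config)
        r1 = mm.measure(g)
        r2 = mm.measure(g)
        assert r1.values == r2.values

    def test_all_24_parameters_present(self, noise_free_config):
        g = sd.generate_chamber(9000.0, "wt", seed=8, config=noise_free_config)
        rec = mm.measure(g)
        assert len(mm.PARAMETER_COLUMNS) == 24
        assert set(rec.values) == set(mm.PARAMETER_COLUMNS)

    def test_proportions_within_unit_interval(self, wt_cohort_table):
        for col in ("oocyte_fraction_of_germline", "prop_fc_on_oocyte",
                    "oocyte_fc_interface_fraction"):
            assert wt_cohort_table[col].between(0, 1).all()
        assert wt_cohort_table["interface_angle"].between(0, 180).all()

    def test_phase_consistent_with_area(self, wt_cohort_table):
        for _, row in wt_cohort_table.iterrows():
            assert row["phase"] == mm.assign_phase(row["germline_area"])
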
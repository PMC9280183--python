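"""Electrode geometry: region assignment rules and the azimuthal equidistant projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegfusion.montage import (
    REGIONS,
    ElectrodeMontage,
    MontageError,
    assign_regions,
    default_montage,
    load_montage,
    project_aep,
)


class TestDefaultMontage:
    def test_geometry_invariants(self, montage):
        assert len(montage) == 36
        assert len(set(montage.labels)) == 36
        norms = np.linalg.norm(montage.coords3d, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_every_region_has_at_least_three_electrodes(self, montage):
        for region in REGIONS:
            assert len(montage.region_members(region)) >= 3, region

    @pytest.mark.parametrize(
        "label, region",
        [
            ("F3", "frontal"),
            ("Fp1", "frontal"),
            ("Fz", "frontal"),
            ("FC3", "frontal"),
            ("O1", "occipital"),
            ("POz", "occipital"),
            ("T7", "left_temporal"),
            ("FT7", "left_temporal"),
            ("T8", "right_temporal"),
            ("TP8", "right_temporal"),
            ("C3", "parietal"),
            ("CP4", "parietal"),
            ("Pz", "parietal"),
        ],
    )
    def test_prefix_rule_assignments(self, montage, label, region):
        assert montage.region_of[label] == region

    def test_explicit_table_overrides_prefix_rule(self, montage):
        override = assign_regions(montage, {"O1": "parietal"})
        assert override.region_of["O1"] == "parietal"
        assert override.region_of["O2"] == "occipital"

    def test_depleted_region_raises_naming_it(self, montage):
        table = {lab: "unassigned" for lab in ("O1", "O2", "Oz", "POz")}
        with pytest.raises(MontageError, match="occipital"):
            assign_regions(montage, table)


class TestMontageValidation:
    def test_rejects_off_sphere_coordinates(self):
        with pytest.raises(MontageError, match="unit sphere"):
            ElectrodeMontage(("A", "B"), [[0, 0, 2.0], [0, 0, 1.0]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(MontageError, match="duplicate"):
            ElectrodeMontage(("A", "A"), [[0, 0, 1.0], [0, 1.0, 0]])

    def test_loader_normalizes_and_parses_mixed_separators(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "# comment\nCz 0 0 2.0\nXx, 0.5, 0.5, 0.0\nO1 0 -3 1\nO2 0 -3 -1\n"
        )
        mont = load_montage(path, assign=False)
        assert mont.labels == ("Cz", "Xx", "O1", "O2")
        assert np.allclose(np.linalg.norm(mont.coords3d, axis=1), 1.0)


class TestProjection:
    def test_vertex_maps_to_origin(self):
        mont = ElectrodeMontage(("Cz", "T8"), [[0, 0, 1.0], [1.0, 0, 0]])
        proj = project_aep(mont, ["Cz"])
        assert np.allclose(proj.coords2d, [[0.0, 0.0]], atol=1e-12)

    def test_equatorial_electrode_at_quarter_turn(self):
        # closed form: polar angle pi/2, azimuth 0 -> (pi/2, 0)
        mont = ElectrodeMontage(("X",), [[1.0, 0, 0]])
        proj = project_aep(mont)
        assert np.allclose(proj.coords2d, [[np.pi / 2, 0.0]], atol=1e-12)

    def test_equal_polar_angle_gives_equal_radius(self, montage):
        proj = project_aep(montage, ["F7", "F8", "Oz"])  # all on the 72-degree ring
        radii = np.linalg.norm(proj.coords2d, axis=1)
        assert np.allclose(radii, radii[0], atol=1e-9)

    def test_injective_on_default_montage(self, montage):
        uv = project_aep(montage).coords2d
        dists = np.linalg.norm(uv[:, None, :] - uv[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() > 1e-6

    def test_radius_strictly_increases_with_polar_angle(self):
        polars = np.deg2rad([10, 30, 50, 70, 110])
        coords = [[np.sin(p), 0, np.cos(p)] for p in polars]
        mont = ElectrodeMontage([f"e{i}" for i in range(len(polars))], coords)
        radii = np.linalg.norm(project_aep(mont).coords2d, axis=1)
        assert np.all(np.diff(radii) > 0)

    def test_antipodal_electrode_rejected(self):
        mont = ElectrodeMontage(("Down",), [[0, 0, -1.0]])
        with pytest.raises(MontageError, match="antipodal"):
            project_aep(mont)

    @settings(derandomize=True, max_examples=50)
    @given(
        polar=st.floats(1e-3, np.pi - 1e-3),
        azimuth=st.floats(-np.pi + 1e-9, np.pi - 1e-6),
    )
    def test_azimuth_round_trip(self, polar, azimuth):
        xyz = [
            np.sin(polar) * np.cos(azimuth),
            np.sin(polar) * np.sin(azimuth),
            np.cos(polar),
        ]
        mont = ElectrodeMontage(("e",), [np.asarray(xyz) / np.linalg.norm(xyz)])
        u, v = project_aep(mont).coords2d[0]
        recovered = np.arctan2(v, u)
        delta = np.angle(np.exp(1j * (recovered - azimuth)))
        assert abs(delta) < 1e-9
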
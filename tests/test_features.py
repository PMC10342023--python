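"""Feature definitions: accessibility, secondary structure, loops, termini."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleavability.features import (
    NormalizationBounds,
    build_feature_vectors,
    compute_raw_features,
    fit_normalization,
    loop_length_feature,
    max_asa,
    relative_accessibility,
    sasa_per_atom,
    ss8_to_ss3,
    termini_feature,
)
from cleavability.synthetic import ToySpec, generate_toy_structure

ss_strings = st.lists(st.sampled_from(["helix", "strand", "loop"]), min_size=1,
                      max_size=60)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        area = sasa_per_atom(np.zeros((1, 3)), np.array([1.70]))[0]
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.02)

    def test_distant_atoms_do_not_occlude(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        areas = sasa_per_atom(coords, np.array([1.70, 1.70]))
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert areas == pytest.approx([exact, exact], rel=0.02)

    def test_two_carbons_against_sphere_cap_closed_form(self):
        # equal expanded spheres at distance d each lose a cap of height R - d/2
        d = 2.0
        R = 1.70 + 1.4
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        areas = sasa_per_atom(coords, np.array([1.70, 1.70]))
        exact = 4 * math.pi * R**2 - 2 * math.pi * R * (R - d / 2)
        assert areas.sum() == pytest.approx(2 * exact, rel=0.03)

    def test_point_count_convergence_on_random_clusters(self, rng):
        for _ in range(3):
            coords = rng.normal(scale=2.0, size=(10, 3))
            radii = np.full(10, 1.70)
            coarse = sasa_per_atom(coords, radii, n_points=960).sum()
            dense = sasa_per_atom(coords, radii, n_points=4000).sum()
            assert abs(coarse - dense) / dense < 0.02

    def test_unknown_element_is_configuration_error(self, tmp_path):
        from conftest import make_pdb_text
        from cleavability.features import shrake_rupley_sasa
        from cleavability.structure_io import read_structure
        path = tmp_path / "zz.pdb"
        text = make_pdb_text([("A", 1, "ALA")]).replace(" N\n", "ZZ\n", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="radius"):
            shrake_rupley_sasa(read_structure(path))


class TestRelativeAccessibility:
    @pytest.mark.parametrize(
        "abs_acc, res, expected",
        [
            (129.0, "ALA", 1.0),
            (0.0, "ALA", 0.0),
            (104.0 * 1.1, "GLY", 1.0),  # clamped above the residue maximum
            (64.5, "ALA", 0.5),
        ],
    )
    def test_ratio_and_clamp(self, abs_acc, res, expected):
        assert relative_accessibility(abs_acc, res) == pytest.approx(expected)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(KeyError):
            max_asa("MSE")


class TestSs3:
    @pytest.mark.parametrize("ss8, ss3", [
        ("H", "helix"), ("G", "helix"), ("I", "helix"),
        ("E", "strand"), ("B", "strand"),
        ("T", "loop"), ("S", "loop"), ("-", "loop"),
    ])
    def test_mapping(self, ss8, ss3):
        assert ss8_to_ss3(ss8) == ss3

    def test_unknown_code(self):
        with pytest.raises(ValueError):
            ss8_to_ss3("Q")


def brute_force_loop_lengths(ss3_seq):
    """Independent run-scanner: for each residue, count its contiguous loop run."""
    out = []
    for i, state in enumerate(ss3_seq):
        if state != "loop":
            out.append(0)
            continue
        length = 1
        j = i - 1
        while j >= 0 and ss3_seq[j] == "loop":
            length += 1
            j -= 1
        j = i + 1
        while j < len(ss3_seq) and ss3_seq[j] == "loop":
            length += 1
            j += 1
        out.append(length)
    return out


class TestLoopLength:
    def test_single_run(self):
        assert list(loop_length_feature(["loop"] * 7)) == [7] * 7

    def test_mixed_pattern(self):
        seq = ["loop"] * 3 + ["helix"] * 3 + ["loop"] * 2
        assert list(loop_length_feature(seq)) == [3, 3, 3, 0, 0, 0, 2, 2]

    def test_all_helix_zero(self):
        assert list(loop_length_feature(["helix"] * 5)) == [0] * 5

    @settings(deadline=None)
    @given(ss_strings)
    def test_matches_brute_force_scanner(self, seq):
        assert list(loop_length_feature(seq)) == brute_force_loop_lengths(seq)


class TestTermini:
    def test_prefix_before_first_long_helix(self):
        seq = ["loop"] * 2 + ["helix"] * 4 + ["loop"] * 3 + ["strand"] * 4
        got = termini_feature(seq)
        assert list(got[:2]) == [1, 1]
        assert got[2:9].sum() == 0  # interior, including the mid loop

    def test_short_leading_element_skipped(self):
        seq = ["loop", "helix", "helix", "loop", "loop"] + ["helix"] * 4
        got = termini_feature(seq)
        assert list(got) == [1, 1, 1, 1, 1, 0, 0, 0, 0]

    def test_all_loop_chain_fully_flagged(self):
        assert termini_feature(["loop"] * 6).sum() == 6

    def test_short_strand_threshold_differs_from_helix(self):
        seq = ["loop"] + ["strand"] * 3 + ["loop"] * 4
        got = termini_feature(seq)  # a 3-strand qualifies
        assert list(got) == [1, 0, 0, 0, 1, 1, 1, 1]

    @settings(deadline=None)
    @given(ss_strings)
    def test_flags_form_prefix_and_suffix_blocks_only(self, seq):
        flags = termini_feature(seq)
        interior = np.flatnonzero(flags == 0)
        if interior.size:
            # zeros are contiguous: no flagged island inside them
            assert flags[interior.min():interior.max() + 1].sum() == 0


class TestNormalization:
    def test_bounds_and_application(self):
        b = fit_normalization({"x": np.array([2.0, 4.0, 10.0])})
        assert b.bounds["x"] == (2.0, 10.0)
        assert b.apply("x", np.array([4.0]))[0] == pytest.approx(0.25)
        assert b.apply("x", np.array([12.0]))[0] == 1.0  # clamped
        assert b.apply("x", np.array([0.0]))[0] == 0.0

    def test_constant_feature_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_normalization({"x": np.array([3.0, 3.0, 3.0])})

    def test_roundtrip_serialization(self):
        b = fit_normalization({"x": np.array([1.0, 5.0])})
        assert NormalizationBounds.from_dict(b.to_dict()).bounds == b.bounds


@pytest.fixture(scope="module")
def toy_features():
    spec = ToySpec(
        segments=[("loop", 5), ("helix", 8), ("loop", 4), ("strand", 5), ("loop", 3)],
        structure_id="feat_toy", seed=7,
    )
    structure, ss3 = generate_toy_structure(spec)
    raw = compute_raw_features(structure, "A", ss3=ss3)
    bounds = fit_normalization({
        "rel_acc": raw["rel_acc_raw"].to_numpy(),
        "loop_len": raw["loop_len_raw"].to_numpy(),
    })
    return structure, ss3, raw, bounds


class TestFeatureVectors:
    def test_one_hot_secondary_structure(self, toy_features):
        _, _, raw, bounds = toy_features
        vec = build_feature_vectors(raw, bounds)
        onehot = vec[["ss_helix", "ss_strand", "ss_loop"]].to_numpy()
        assert np.all(onehot.sum(axis=1) == 1.0)

    def test_helix_core_has_no_loop_or_terminus_signal(self, toy_features):
        _, ss3, raw, bounds = toy_features
        vec = build_feature_vectors(raw, bounds)
        core = vec.iloc[7]  # inside the 8-residue helix
        assert ss3[7] == "helix"
        assert core["ss_helix"] == 1.0
        assert core["loop_len_norm"] == 0.0
        assert core["terminus"] == 0.0

    def test_all_normalized_features_in_unit_interval(self, toy_features):
        _, _, raw, bounds = toy_features
        vec = build_feature_vectors(raw, bounds)
        cols = ["rel_acc", "bfactor_norm", "loop_len_norm", "terminus"]
        values = vec.loc[vec["complete"], cols].to_numpy()
        assert np.all((values >= 0.0) & (values <= 1.0))

    def test_predicted_model_gets_confidence_not_bfactor(self, tmp_path):
        from conftest import make_pdb_text
        from cleavability.structure_io import read_structure
        path = tmp_path / "af.pdb"
        path.write_text(make_pdb_text(
            [("A", i + 1, "ALA") for i in range(6)], bfactor=100.0))
        s = read_structure(path, source_kind="predicted")
        raw = compute_raw_features(s, "A", ss3=["loop"] * 6)
        bounds = NormalizationBounds({"rel_acc": (0.0, 1.0), "loop_len": (0.0, 10.0)})
        vec = build_feature_vectors(raw, bounds, source_kind="predicted")
        assert "bfactor_norm" not in vec.columns
        assert np.allclose(vec["confidence_norm"], 1.0)

    def test_loop_feature_constant_within_run(self, toy_features):
        _, ss3, raw, bounds = toy_features
        vec = build_feature_vectors(raw, bounds)
        first_loop = vec["loop_len_norm"].to_numpy()[:5]
        assert np.allclose(first_loop, first_loop[0])
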
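import numpy as np
import pandas as pd
import pytest

from turnprop.dihedrals import compute_phi_psi
from turnprop.reference_data import CLASSICAL_TYPES, get_ideal_angles
from turnprop.synthetic_data import build_backbone
from turnprop.trajectory_io import TorsionSeries, Trajectory
from turnprop.turn_analysis import (
    classify_turn_window,
    helical_residue_flags,
    population_table,
    scan_turns,
)


def brute_force_classify(phi1, psi1, phi2, psi2, d, hel1=False, hel2=False,
                         strict=False):
    """Independent straightforward matcher over all type definitions."""
    if d >= 7.0 or (hel1 and hel2):
        return None

    def circ(a, b):
        return min((a - b + 360.0 * k for k in range(-2, 3)), key=abs)

    matches = []
    for label in CLASSICAL_TYPES:
        ideal = get_ideal_angles(label)
        devs = [abs(circ(x, y)) for x, y in
                zip((phi1, psi1, phi2, psi2), ideal)]
        n30 = sum(dv > 30.0 for dv in devs)
        n45 = sum(dv > 45.0 for dv in devs)
        ok = (n30 == 0) if strict else (n45 == 0 and n30 <= 1)
        if ok:
            matches.append((sum(devs), CLASSICAL_TYPES.index(label), label))
    if not matches:
        return "IV"
    return min(matches)[2]


class TestClassifyWindow:
    def test_ideal_type_i(self):
        assert classify_turn_window(-60, -30, -90, 0, 5.5) == "I"

    def test_dft_i_prime_quadruple(self):
        assert classify_turn_window(53.3, 41.5, 98.7, -16.5, 5.0) == "I'"

    def test_dft_ii_prime_quadruple(self):
        assert classify_turn_window(57.1, -134.9, -87.8, -7.4, 5.0) == "II'"

    def test_origin_quadruple_is_miscellaneous(self):
        # brute force over all five ideal quadruples: no match even relaxed
        assert brute_force_classify(0, 0, 0, 0, 5.0) == "IV"
        assert classify_turn_window(0, 0, 0, 0, 5.0) == "IV"

    def test_distance_criterion_is_strict(self):
        assert classify_turn_window(-60, -30, -90, 0, 7.2) is None
        assert classify_turn_window(-60, -30, -90, 0, 7.0) is None
        assert classify_turn_window(-60, -30, -90, 0, 6.999) == "I"

    def test_both_central_helical_excluded(self):
        assert classify_turn_window(-60, -30, -90, 0, 5.0,
                                    helical_flags=(True, True)) is None
        assert classify_turn_window(-60, -30, -90, 0, 5.0,
                                    helical_flags=(True, False)) == "I"

    def test_undefined_angle_gives_none(self):
        assert classify_turn_window(np.nan, -30, -90, 0, 5.0) is None

    def test_single_relaxed_angle_default_vs_strict(self):
        # psi2 at 40 deg from ideal: allowed by the one-angle 45-deg
        # relaxation, rejected in strict-30 mode
        assert classify_turn_window(-60, -30, -90, 40, 5.0) == "I"
        assert classify_turn_window(-60, -30, -90, 40, 5.0, strict=True) == "IV"

    def test_wrap_invariance_plus_360(self):
        assert classify_turn_window(-60 + 360, -30, -90 - 360, 0 + 360, 5.0) == "I"

    def test_mirror_swaps_primed_types(self, rng):
        q = rng.uniform(-180, 179.9, size=(2000, 4))
        d = rng.uniform(3.0, 9.0, size=2000)
        swap = {"I": "I'", "I'": "I", "II": "II'", "II'": "II"}
        for row, dist in zip(q, d):
            a = classify_turn_window(*row, dist)
            b = classify_turn_window(*(-row), dist)
            if a in swap or b in swap:
                assert swap.get(a) == b or swap.get(b) == a

    def test_agrees_with_brute_force_oracle(self, rng):
        q = rng.uniform(-180, 179.9, size=(20000, 4))
        d = rng.uniform(3.0, 8.0, size=20000)
        for strict in (False, True):
            for row, dist in zip(q[:10000], d[:10000]):
                expected = brute_force_classify(*row, dist, strict=strict)
                got = classify_turn_window(*row, dist, strict=strict)
                assert got == expected, (row, dist, strict, got, expected)


class TestHelicalFlags:
    def _series(self, phi_psi_rows):
        arr = np.array(phi_psi_rows, dtype=float)[None, :, :]
        return TorsionSeries(
            residue_ids=list(range(1, arr.shape[1] + 1)),
            phi=arr[:, :, 0], psi=arr[:, :, 1],
        )

    def test_run_of_four_is_helical(self):
        ts = self._series([[-60, -47]] * 4 + [[60, 60]] * 2)
        flags = helical_residue_flags(ts)
        assert flags[0].tolist() == [True] * 4 + [False] * 2

    def test_short_run_is_not_helical(self):
        ts = self._series([[-60, -47]] * 3 + [[60, 60]] * 3)
        assert not helical_residue_flags(ts).any()


class TestScanAndPopulations:
    def test_programmed_pure_turn_ensemble_recovered(self):
        """Every frame of a tight ideal-I' Asn-Gly ensemble classifies I'."""
        from turnprop.synthetic_data import ConformerSpec, EnsembleSpec, simulate_ensemble

        spec = EnsembleSpec(
            sequence=("ALA", "ALA", "ASN", "GLY", "ALA", "ALA"),
            conformers=(ConformerSpec("t", 1.0, window_start=2,
                                      central_angles=get_ideal_angles("I'")),),
            kappa=1e4, n_frames=100, seed=8,
        )
        res = simulate_ensemble(spec)
        a = scan_turns(res.trajectory, res.torsions)
        asn_gly = a[a.window_start == 2]
        assert (asn_gly["type"] == "I'").all()

    def test_frame_count_mismatch_raises(self, small_ensemble):
        bad = small_ensemble.torsions.subset(range(10))
        with pytest.raises(ValueError, match="mismatch"):
            scan_turns(small_ensemble.trajectory, bad)

    def test_zero_frame_trajectory_gives_empty_assignments(self, small_ensemble):
        traj = small_ensemble.trajectory.subset([])
        ts = small_ensemble.torsions.subset([])
        assert scan_turns(traj, ts).empty

    def test_population_table_all_one_type(self):
        assignments = pd.DataFrame(
            {"frame": range(100), "window_start": 2, "type": "I"}
        )
        table = population_table(assignments, {"Asn-Gly": 2}, n_frames=100)
        assert table.loc["I", "Asn-Gly"] == 100.0
        assert table.loc["IV", "Asn-Gly"] == 0.0

    def test_population_total_row_is_column_sum(self, small_ensemble):
        a = scan_turns(small_ensemble.trajectory, small_ensemble.torsions)
        table = population_table(
            a, {"Ala-Asn": 1, "Asn-Gly": 2, "Gly-Ala": 3},
            n_frames=small_ensemble.trajectory.n_frames,
        )
        sums = table.loc[[t for t in table.index if t != "Total"]].sum()
        assert np.allclose(table.loc["Total"], sums, atol=0.01)
        assert ((table.values >= 0) & (table.values <= 100.0 + 1e-9)).all()

    def test_unknown_pair_raises(self, small_ensemble):
        a = scan_turns(small_ensemble.trajectory, small_ensemble.torsions)
        with pytest.raises(KeyError, match="no scanned window"):
            population_table(a, {"Xxx-Yyy": 9})


def test_table1_geometries_classify_as_printed_labels():
    from turnprop.reference_data import iter_dft_geometries

    for geo in iter_dft_geometries():
        tors = np.array(geo.angles).reshape(4, 2)
        traj = build_backbone(["ALA"] * 4, tors)
        ts = compute_phi_psi(traj)
        a = scan_turns(traj, ts)
        assert a[a.window_start == 1]["type"].iloc[0] == geo.turn_type
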
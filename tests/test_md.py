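"""MD interaction-distance statistics: Welch tests, summaries, tables, RMSD/RMSF."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from poselod.io import Atom, TrajectoryFrame
from poselod.md import (
    AtomSelector, DistanceSeries, InteractionSummary, block_average,
    build_interaction_table, compare_to_control, extract_distance_series,
    format_signed, kabsch_superpose, mean_difference, rmsd_series,
    rmsf_per_residue, significance_flag, summarize_series, welch_test,
)
from poselod.simulate import TrajSimParams, gen_distance_series


def series(values, drug="d", label="Asp1222:OD2", t0=40.0):
    values = np.asarray(values, dtype=float)
    times = t0 + 0.1 * np.arange(values.size)
    return DistanceSeries(drug_id=drug, target_id="t", interaction_label=label,
                          times=times, distances=values,
                          window=(float(times[0]), float(times[-1])))


def welch_oracle(a, b):
    """Textbook Welch formulas: statistic, Welch-Satterthwaite df, two-sided p,
    95% CI of the mean difference."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * math.sqrt(va + vb)
    d = a.mean() - b.mean()
    return t, df, p, (d - half, d + half)


class TestWelch:
    def test_hand_sized_case_matches_textbook_formulas(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, df, p, ci = welch_test(a, b)
        ot, odf, op, oci = welch_oracle(a, b)
        assert t == pytest.approx(ot, abs=1e-12)
        assert df == pytest.approx(odf, abs=1e-12)
        assert p == pytest.approx(op, abs=1e-12)
        assert ci == pytest.approx(oci, abs=1e-10)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_oracle_on_random_small_samples(self, trial):
        rng = np.random.default_rng(5000 + trial)
        a = rng.normal(5, 1, size=int(rng.integers(2, 12)))
        b = rng.normal(6, 2, size=int(rng.integers(2, 12)))
        got = welch_test(a, b)
        want = welch_oracle(a, b)
        for g, w in zip(got[:3], want[:3]):
            assert g == pytest.approx(w, abs=1e-10)
        assert got[3] == pytest.approx(want[3], abs=1e-10)

    def test_identical_samples_not_significant(self, rng):
        a = rng.normal(5, 0.3, size=50)
        _, _, p, _ = welch_test(a, a.copy())
        assert p >= 0.05
        assert significance_flag(p) == "NS"

    def test_well_separated_samples_highly_significant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(4.5, 0.2, size=100)
        b = rng.normal(8.1, 0.2, size=100)
        _, _, p, ci = welch_test(a, b)
        assert p < 1e-4
        assert significance_flag(p) == "***"
        assert ci[0] < -3.5 < ci[1] or ci[1] < -3.4  # CI around ~-3.6

    def test_zero_variance_equal_means_degenerate(self):
        t, _, p, ci = welch_test([5.0, 5.0], [5.0, 5.0])
        assert (t, p, ci) == (0.0, 1.0, (0.0, 0.0))

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestFlagsAndDiffs:
    @pytest.mark.parametrize("p,flag", [(5e-5, "***"), (0.2, "NS"), (0.01, "*"),
                                        (0.0, "***"), (1.0, "NS")])
    def test_flag_thresholds(self, p, flag):
        assert significance_flag(p) == flag

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            significance_flag(1.5)

    @pytest.mark.parametrize("drug,ctrl,want", [
        (4.54, 8.09, -3.55),   # vs crizotinib on c-Met Asp1222
        (16.54, 8.94, 7.60),   # vs cabozantinib on VEGFR-2 Cys1024
        (6.07, 6.07, 0.00),
    ])
    def test_mean_difference(self, drug, ctrl, want):
        assert mean_difference(drug, ctrl) == pytest.approx(want, abs=1e-12)

    def test_signed_formatting(self):
        assert format_signed(7.60) == "+7.60"
        assert format_signed(-3.55) == "-3.55"


class TestSummarize:
    def test_mean_of_two(self):
        mean, _, n = summarize_series(series([4.0, 6.0]))
        assert (mean, n) == (5.0, 2)

    def test_constant_series_zero_dispersion(self):
        _, disp, _ = summarize_series(series([5.0] * 10))
        assert disp == 0.0

    def test_sem_vs_sd(self):
        s = series([4.0, 5.0, 6.0, 7.0])
        _, sem, _ = summarize_series(s, dispersion="sem")
        _, sd, _ = summarize_series(s, dispersion="sd")
        assert sd == pytest.approx(sem * 2)  # n = 4

    def test_recovers_generator_mean_within_sampling_band(self):
        # parameters mirror a lead-drug interaction cell: mu 4.54, sigma 0.24
        p = TrajSimParams(mu=4.54, sigma=0.24, n_frames=1000, ar1_phi=0.0, seed=11)
        mean, _, n = summarize_series(gen_distance_series(p))
        assert abs(mean - 4.54) < 3 * 0.24 / math.sqrt(n)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match=">= 2 frames"):
            summarize_series(series([4.0]))


def toy_frames(n, ligand_offset, residue_atoms, interval=0.1):
    """Frames with a fixed residue and a ligand carbon at ``ligand_offset``."""
    frames = []
    for k in range(n):
        atoms = [Atom(name=nm, element=el, coords=c, residue_name=rn, residue_number=ri,
                      mass=12.0)
                 for nm, el, c, rn, ri in residue_atoms]
        atoms.append(Atom(name="C1", element="C", coords=ligand_offset,
                          residue_name="LIG", residue_number=1, mass=12.0))
        frames.append(TrajectoryFrame(time=k * interval, atoms=atoms))
    return frames


class TestExtractSeries:
    RES = [("OD2", "O", (0.0, 0.0, 0.0), "ASP", 1222)]

    def test_fixed_geometry_gives_constant_series(self):
        frames = toy_frames(30, (5.0, 0.0, 0.0), self.RES)
        s = extract_distance_series(
            frames, AtomSelector(residue_name="LIG"),
            AtomSelector(residue_number=1222, atom_name="OD2"),
            window=(0.0, 10.0))
        assert np.allclose(s.distances, 5.0)
        assert s.interaction_label == "1222:OD2"

    def test_trailing_window_retains_expected_frames(self):
        # 50 ns at 0.1 ns; final-10 ns window keeps t in [40.0, 49.9]: 100 frames
        frames = toy_frames(500, (5.0, 0.0, 0.0), self.RES)
        s = extract_distance_series(
            frames, AtomSelector(residue_name="LIG"),
            AtomSelector(residue_number=1222), window=(40.0, 50.0))
        assert s.distances.size == 100
        assert s.times[0] == pytest.approx(40.0)

    def test_minimum_over_ligand_atoms(self):
        frames = toy_frames(5, (7.0, 0.0, 0.0), self.RES)
        for fr in frames:
            fr.atoms.append(Atom(name="C2", element="C", coords=(3.0, 0.0, 0.0),
                                 residue_name="LIG", residue_number=1, mass=12.0))
        s = extract_distance_series(
            frames, AtomSelector(residue_name="LIG"),
            AtomSelector(residue_number=1222), window=(0.0, 1.0))
        assert np.allclose(s.distances, 3.0)

    def test_unmatched_selector_named_in_error(self):
        frames = toy_frames(3, (5.0, 0.0, 0.0), self.RES)
        with pytest.raises(ValueError, match="9999"):
            extract_distance_series(frames, AtomSelector(residue_name="LIG"),
                                    AtomSelector(residue_number=9999), window=(0.0, 1.0))

    def test_empty_window_rejected(self):
        frames = toy_frames(3, (5.0, 0.0, 0.0), self.RES)
        with pytest.raises(ValueError, match="window"):
            extract_distance_series(frames, AtomSelector(residue_name="LIG"),
                                    AtomSelector(residue_number=1222), window=(5.0, 5.0))


class TestInteractionTable:
    def test_formatted_cells_reproduce_printed_differences(self):
        summaries = [
            InteractionSummary("Crizotinib", "Asp1222:OD2", 8.09, 0.19, 100),
            InteractionSummary("Triamterene", "Asp1222:OD2", 4.54, 0.24, 100,
                               mean_diff_vs_control=mean_difference(4.54, 8.09),
                               p_value=1e-6, ci95=(-3.6, -3.5), flag="***"),
            InteractionSummary("Triamterene", "His1202:O1", 3.05, 0.34, 100,
                               mean_diff_vs_control=mean_difference(3.05, 8.43),
                               p_value=1e-6, ci95=(-5.5, -5.3), flag="***"),
            InteractionSummary("Crizotinib", "His1202:O1", 8.43, 0.25, 100),
        ]
        table = build_interaction_table(summaries, "Crizotinib")
        assert "(-3.55)" in table.loc["Triamterene", "Asp1222:OD2"]
        assert "(-5.38)" in table.loc["Triamterene", "His1202:O1"]
        assert "(" not in table.loc["Crizotinib", "Asp1222:OD2"]  # control row

    def test_absent_cell_renders_dash(self):
        summaries = [
            InteractionSummary("ctrl", "A:X", 8.0, 0.1, 50),
            InteractionSummary("ctrl", "B:Y", 9.0, 0.1, 50),
            InteractionSummary("drug", "A:X", 4.0, 0.1, 50,
                               mean_diff_vs_control=-4.0, p_value=1e-9, flag="***"),
        ]
        table = build_interaction_table(summaries, "ctrl")
        assert table.loc["drug", "B:Y"] == "-"
        assert table.shape == (2, 2)

    def test_missing_control_is_an_error(self):
        summaries = [
            InteractionSummary("ctrl", "A:X", 8.0, 0.1, 50),
            InteractionSummary("drug", "B:Y", 4.0, 0.1, 50, flag="***"),
        ]
        with pytest.raises(ValueError, match="B:Y"):
            build_interaction_table(summaries, "ctrl")

    def test_identical_series_give_zero_diff_ns(self):
        x = np.linspace(4, 5, 40)
        out = compare_to_control(
            {"drug": series(x, drug="drug"), "ctrl": series(x, drug="ctrl")}, "ctrl")
        drug = next(s for s in out if s.drug_id == "drug")
        assert drug.mean_diff_vs_control == 0.0
        assert drug.flag == "NS"


class TestBlockAverage:
    def test_block_means(self):
        x = np.arange(10.0)
        assert np.allclose(block_average(x, 5), [2.0, 7.0])

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_average(np.arange(5.0), 4)


def rigid_frames(coords, motions):
    """One frame per rigid motion applied to ``coords`` (n_atoms, 3)."""
    frames = []
    for k, (rot, shift) in enumerate(motions):
        moved = coords @ rot.T + shift
        atoms = [Atom(name=f"CA", element="C", coords=tuple(c), residue_name="ALA",
                      residue_number=i + 1, mass=12.0) for i, c in enumerate(moved)]
        frames.append(TrajectoryFrame(time=float(k), atoms=atoms))
    return frames


class TestRmsdRmsf:
    COORDS = np.array([[0.0, 0, 0], [1.5, 0, 0], [1.5, 1.5, 0], [0, 1.5, 1.5]])

    def test_identical_frame_zero_rmsd(self):
        frames = rigid_frames(self.COORDS, [(np.eye(3), np.zeros(3))])
        assert rmsd_series(frames, frames[0], AtomSelector())[0] == pytest.approx(0.0)

    def test_translation_pythagoras(self):
        ref, moved = rigid_frames(self.COORDS, [(np.eye(3), np.zeros(3)),
                                                (np.eye(3), np.array([3.0, 4.0, 0.0]))])
        sel = AtomSelector()
        assert rmsd_series([moved], ref, sel)[0] == pytest.approx(0.0, abs=1e-12)
        assert rmsd_series([moved], ref, sel, superpose=False)[0] == pytest.approx(5.0)

    def test_rmsd_invariant_under_rigid_motion_of_all_frames(self, rng):
        rots = [Rotation.random(rng=rng).as_matrix() for _ in range(3)]
        base = rigid_frames(self.COORDS + rng.normal(0, 0.3, self.COORDS.shape),
                            [(r, rng.uniform(-5, 5, 3)) for r in rots])
        ref = rigid_frames(self.COORDS, [(np.eye(3), np.zeros(3))])[0]
        r0 = rmsd_series(base, ref, AtomSelector())
        extra_rot = Rotation.random(rng=rng).as_matrix()
        extra_shift = rng.uniform(-10, 10, 3)
        moved = rigid_frames(
            self.COORDS, [(np.eye(3), np.zeros(3))])  # placeholder, rebuilt below
        moved = []
        for fr in base:
            coords = np.array([a.coords for a in fr.atoms]) @ extra_rot.T + extra_shift
            moved.append(rigid_frames(coords, [(np.eye(3), np.zeros(3))])[0])
        r1 = rmsd_series(moved, ref, AtomSelector())
        assert np.allclose(r0, r1, atol=1e-9)

    def test_rigid_trajectory_zero_rmsf(self, rng):
        motions = [(Rotation.random(rng=rng).as_matrix(), rng.uniform(-5, 5, 3))
                   for _ in range(5)]
        frames = rigid_frames(self.COORDS, motions)
        rmsf = rmsf_per_residue(frames, AtomSelector())
        assert np.allclose(rmsf.to_numpy(), 0.0, atol=1e-9)
        assert list(rmsf.index) == [1, 2, 3, 4]

    def test_selection_mismatch_rejected(self):
        a = rigid_frames(self.COORDS, [(np.eye(3), np.zeros(3))])[0]
        b = rigid_frames(self.COORDS[:3], [(np.eye(3), np.zeros(3))])[0]
        with pytest.raises(ValueError, match="selection"):
            rmsd_series([b], a, AtomSelector())

    def test_kabsch_recovers_exact_superposition(self, rng):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-8, 8, 3)
        moved = self.COORDS @ rot.T + shift
        fitted = kabsch_superpose(moved, self.COORDS)
        assert np.allclose(fitted, self.COORDS, atol=1e-9)
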
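"""Shape descriptors: RMSD series/matrix, Rg, EED, distance maps, stats."""

import numpy as np
import pandas as pd
import pytest

from gagconf.descriptors import (
    descriptor_correlations,
    descriptor_table,
    eed_series,
    residue_distance_map,
    rg_series,
    rmsd_matrix,
    rmsd_timeseries,
    summary_stats,
)
from gagconf.geometry import center_of_mass
from gagconf.structure import AtomSelection, Ensemble, Structure
from gagconf.synthetic import EnsembleRecipe, build_chain, generate_ensemble

from .conftest import random_rigid_motion, random_structure
from .oracles import quaternion_superposition_rmsd


def _ensemble_of(structures):
    return Ensemble.from_structures(structures)


class TestRmsdTimeseries:
    def test_rigid_copies_give_all_zeros(self, rng):
        s = random_structure(rng)
        frames = [s] + [
            s.transformed(*random_rigid_motion(rng)) for _ in range(4)
        ]
        assert rmsd_timeseries(_ensemble_of(frames)) == pytest.approx(
            np.zeros(5), abs=1e-9
        )

    def test_duplicated_reference_frame_is_zero(self, rng):
        a = random_structure(rng)
        b = a.with_positions(a.positions + rng.normal(size=a.positions.shape))
        series = rmsd_timeseries(_ensemble_of([a, b, a]))
        assert series[0] == 0.0
        assert series[2] == pytest.approx(0.0, abs=1e-9)
        assert series[1] > 0.1

    def test_matches_pairwise_oracle(self, rng):
        base = random_structure(rng, 9)
        frames = [
            base.with_positions(rng.normal(scale=4.0, size=(9, 3)))
            for _ in range(3)
        ]
        ens = _ensemble_of(frames)
        series = rmsd_timeseries(ens)
        for f in range(3):
            expected = quaternion_superposition_rmsd(
                frames[f].positions, frames[0].positions, frames[0].masses
            )
            assert series[f] == pytest.approx(expected, abs=1e-6)

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError):
            rmsd_timeseries(_ensemble_of([random_structure(rng)]))


class TestRmsdMatrix:
    def test_constant_ensemble_gives_zero_matrix(self, rng):
        s = random_structure(rng)
        m = rmsd_matrix(_ensemble_of([s] * 4))
        assert np.abs(m.values).max() < 1e-12

    def test_two_frames_reduce_to_pairwise_rmsd(self, rng):
        a = random_structure(rng)
        b = a.with_positions(rng.normal(scale=4.0, size=a.positions.shape))
        m = rmsd_matrix(_ensemble_of([a, b]))
        expected = quaternion_superposition_rmsd(
            b.positions, a.positions, a.masses
        )
        assert m.values[0, 1] == pytest.approx(expected, abs=1e-6)
        assert m.values[1, 0] == m.values[0, 1]
        assert m.values[0, 0] == m.values[1, 1] == 0.0

    def test_matches_elementwise_oracle(self, rng):
        base = random_structure(rng, 8)
        frames = [
            base.with_positions(rng.normal(scale=4.0, size=(8, 3)))
            for _ in range(5)
        ]
        m = rmsd_matrix(_ensemble_of(frames), mass_weighted=False)
        for i in range(5):
            for j in range(5):
                expected = quaternion_superposition_rmsd(
                    frames[j].positions, frames[i].positions
                )
                assert m.values[i, j] == pytest.approx(expected, abs=1e-6)

    def test_row_zero_reproduces_timeseries(self, small_ensemble):
        m = rmsd_matrix(small_ensemble, stride=3)
        series = rmsd_timeseries(small_ensemble)
        assert m.values[0] == pytest.approx(series[m.frame_indices], abs=1e-9)

    def test_overlong_stride_rejected(self, small_ensemble):
        with pytest.raises(ValueError):
            rmsd_matrix(small_ensemble, stride=10**6)

    def test_two_cluster_block_structure(self):
        """Two templates + small noise → within-block mean < between-block mean."""
        torsions_a = [(-70.0, 120.0), (60.0, 60.0), (-70.0, 120.0)]
        torsions_b = [(-90.0, -50.0), (60.0, 110.0), (-90.0, -50.0)]
        a = build_chain(4, linkage_torsions=torsions_a)
        b = build_chain(4, linkage_torsions=torsions_b)
        rng = np.random.default_rng(5)
        frames = [
            a.with_positions(a.positions + rng.normal(0, 0.05, a.positions.shape))
            for _ in range(8)
        ] + [
            b.with_positions(b.positions + rng.normal(0, 0.05, b.positions.shape))
            for _ in range(8)
        ]
        m = rmsd_matrix(_ensemble_of(frames)).values
        within = np.concatenate(
            [m[:8, :8][np.triu_indices(8, 1)], m[8:, 8:][np.triu_indices(8, 1)]]
        )
        between = m[:8, 8:].ravel()
        assert within.mean() < between.mean()


class TestSeries:
    def test_eed_trivial_cases(self, rng):
        # two single-atom residues 5 Å apart
        s = Structure(
            ["A", "B"], ["C", "C"], np.array([12.0, 16.0]),
            np.array([1, 2]), ["X", "Y"],
            np.array([[0.0, 0, 0], [5.0, 0, 0]]),
        )
        assert eed_series(_ensemble_of([s]), 1, 2)[0] == pytest.approx(5.0)

    def test_eed_matches_direct_com_computation(self, small_ensemble):
        series = eed_series(small_ensemble, 1, 6)
        f = small_ensemble.frame(3)
        ca = center_of_mass(f, AtomSelection.residues([1]))
        cb = center_of_mass(f, AtomSelection.residues([6]))
        assert series[3] == pytest.approx(float(np.linalg.norm(ca - cb)), abs=1e-10)

    def test_rg_scaling_homogeneity(self, rng):
        s = random_structure(rng)
        ens = _ensemble_of([s, s.with_positions(2.0 * s.positions)])
        rg = rg_series(ens)
        assert rg[1] == pytest.approx(2.0 * rg[0], rel=1e-12)

    def test_constant_ensemble_constant_series(self, rng):
        s = random_structure(rng)
        assert np.ptp(rg_series(_ensemble_of([s] * 5))) == 0.0


class TestResidueDistanceMap:
    def test_collinear_equally_spaced_residues(self):
        d = 3.0
        s = Structure(
            [f"A{i}" for i in range(5)],
            ["C"] * 5,
            np.ones(5),
            np.arange(1, 6),
            ["X"] * 5,
            np.array([[d * i, 0.0, 0.0] for i in range(5)]),
        )
        dmap = residue_distance_map(_ensemble_of([s]))
        for i in range(1, 6):
            for j in range(1, 6):
                assert dmap.loc[i, j] == pytest.approx(abs(i - j) * d)

    def test_constant_ensemble_equals_single_frame(self, dp12_chain):
        one = residue_distance_map(_ensemble_of([dp12_chain]))
        many = residue_distance_map(_ensemble_of([dp12_chain] * 4))
        assert np.allclose(one.to_numpy(), many.to_numpy())

    def test_matches_per_frame_average(self, small_ensemble):
        dmap = residue_distance_map(small_ensemble)
        acc = np.zeros_like(dmap.to_numpy())
        for f in range(small_ensemble.n_frames):
            frame = small_ensemble.frame(f)
            coms = np.array(
                [
                    center_of_mass(frame, AtomSelection.residues([ri]))
                    for ri in frame.residue_ids
                ]
            )
            acc += np.sqrt(
                ((coms[:, None] - coms[None, :]) ** 2).sum(-1)
            )
        assert np.allclose(dmap.to_numpy(), acc / small_ensemble.n_frames)


class TestSummaryStats:
    def test_constant_series(self):
        assert summary_stats(np.full(10, 3.5)) == (3.5, 0.0)

    def test_two_point_mean(self):
        mean, _ = summary_stats(np.array([0.0, 2.0]))
        assert mean == 1.0

    def test_matches_two_pass_oracle(self, rng):
        x = rng.normal(5, 2, 100)
        mean, sd = summary_stats(x)
        mu = sum(x) / len(x)
        var = sum((xi - mu) ** 2 for xi in x) / (len(x) - 1)
        assert mean == pytest.approx(mu, abs=1e-12)
        assert sd == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_population_convention(self, rng):
        x = rng.normal(size=50)
        _, sd = summary_stats(x, ddof=0)
        assert sd == pytest.approx(float(np.std(x)), abs=1e-12)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            summary_stats(np.array([]))


class TestCorrelations:
    def _table(self, rng, n=50):
        return pd.DataFrame(
            {
                "rmsd": rng.normal(5, 1, n),
                "rg": rng.normal(15, 0.5, n),
                "eed": rng.normal(34, 4, n),
            }
        )

    def test_unit_diagonal_and_symmetry(self, rng):
        c = descriptor_correlations(self._table(rng))
        assert np.allclose(np.diag(c.to_numpy()), 1.0)
        assert np.allclose(c.to_numpy(), c.to_numpy().T)
        assert (np.abs(c.to_numpy()) <= 1.0 + 1e-12).all()

    def test_negated_column_gives_minus_one(self, rng):
        t = self._table(rng)
        t["rg"] = -t["rmsd"]
        c = descriptor_correlations(t)
        assert c.loc["rmsd", "rg"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        t = self._table(rng)
        c = descriptor_correlations(t)
        x, y = t["rmsd"].to_numpy(), t["eed"].to_numpy()
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert c.loc["rmsd", "eed"] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_raises(self, rng):
        t = self._table(rng)
        t["rg"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            descriptor_correlations(t)


class TestDescriptorTable:
    def test_rigid_motion_of_every_frame_changes_nothing(self, rng):
        base = generate_ensemble(EnsembleRecipe(n_frames=6, seed=2, n_residues=4))
        table = descriptor_table(base)
        rot, trans = random_rigid_motion(rng)
        moved = Ensemble(
            base.topology,
            base.coordinates @ rot.T + trans,
            base.frame_spacing_ps,
        )
        table2 = descriptor_table(moved)
        for col in ("rmsd", "rg", "eed"):
            assert table2[col].to_numpy() == pytest.approx(
                table[col].to_numpy(), abs=1e-8
            )

    def test_columns_aligned_and_finite(self, small_ensemble):
        t = descriptor_table(small_ensemble)
        assert list(t.columns) == ["frame", "rmsd", "rg", "eed"]
        assert len(t) == small_ensemble.n_frames
        assert np.isfinite(t[["rmsd", "rg", "eed"]].to_numpy()).all()
        assert (t[["rmsd", "rg", "eed"]].to_numpy() >= 0).all()
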
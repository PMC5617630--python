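from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import pinpattern as pp
from pinpattern.analysis import UndefinedStatisticError


def state_with(A):
    A = np.asarray(A, dtype=float)
    n = len(A)
    return pp.SystemState(t=0.0, A=A, P_tot=np.zeros(n), X=np.zeros(n))


def brute_force_peaks(A, tissue, rel_threshold):
    """Literal re-implementation of the peak definition, cell by cell."""
    out = []
    for c in tissue.cell_ids:
        k = tissue.index_of(c)
        nbrs = tissue.neighbors(c)
        if all(A[k] > A[tissue.index_of(j)] for j in nbrs) and A[k] > rel_threshold * A.max():
            out.append(c)
    return sorted(out)


class TestDetectPeaks:
    def test_homogeneous_field_has_no_peaks(self, ring100):
        peaks = pp.detect_peaks(state_with(np.ones(100)), ring100)
        assert len(peaks) == 0

    def test_single_dominant_cell(self, ring100):
        A = np.ones(100)
        A[42] = 10.0
        peaks = pp.detect_peaks(state_with(A), ring100, rel_threshold=0.5)
        assert peaks.peak_cells == [42]
        assert peaks.peak_values == pytest.approx([10.0])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        A=arrays(float, 50, elements=st.floats(0.0, 10.0)),
        thr=st.floats(0.1, 1.0),
    )
    def test_matches_brute_force_oracle(self, A, thr):
        tissue = pp.generate_ring_tissue(50)
        if A.max() == 0.0:
            A = A + 1e-6
        peaks = pp.detect_peaks(state_with(A), tissue, rel_threshold=thr)
        assert sorted(peaks.peak_cells) == brute_force_peaks(A, tissue, thr)

    def test_no_two_peaks_adjacent(self, disc_small):
        rng = np.random.default_rng(4)
        A = rng.random(disc_small.n_cells)
        peaks = pp.detect_peaks(state_with(A), disc_small, rel_threshold=0.1)
        cells = set(peaks.peak_cells)
        for i, j in disc_small.walls:
            assert not (i in cells and j in cells)

    def test_bad_threshold(self, ring100):
        with pytest.raises(ValueError):
            pp.detect_peaks(state_with(np.ones(100)), ring100, rel_threshold=0.0)


class TestBoundaryScore:
    def _peaks(self, cells):
        return pp.PeakSet(
            peak_cells=list(cells),
            peak_values=np.ones(len(cells)),
            threshold_used=0.5,
            peak_indices=list(cells),
        )

    @pytest.mark.parametrize(
        "cells,mask_true,expected",
        [
            ([0, 1, 2, 3, 4], [0, 1, 2, 3, 4], 1.0),
            ([0, 1, 2, 3], [0, 1], 0.5),
            ([5, 6], [], 0.0),
        ],
    )
    def test_fraction(self, cells, mask_true, expected):
        mask = np.zeros(10, dtype=bool)
        mask[mask_true] = True
        assert pp.boundary_restriction_score(self._peaks(cells), mask) == expected

    def test_empty_peak_set_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pp.boundary_restriction_score(self._peaks([]), np.ones(5, dtype=bool))

    def test_invariant_under_relabeling(self, disc_small):
        rng = np.random.default_rng(7)
        A = rng.random(disc_small.n_cells)
        mask = rng.random(disc_small.n_cells) > 0.5
        peaks = pp.detect_peaks(state_with(A), disc_small, rel_threshold=0.1)
        score = pp.boundary_restriction_score(peaks, mask)
        relabeled = pp.TissueGraph(
            cell_ids=[c + 1000 for c in disc_small.cell_ids],
            volumes=disc_small.volumes,
            centroids=disc_small.centroids,
            walls=[(i + 1000, j + 1000) for i, j in disc_small.walls],
            wall_areas=disc_small.wall_areas,
            boundary_flags=disc_small.boundary_flags,
        )
        peaks2 = pp.detect_peaks(state_with(A), relabeled, rel_threshold=0.1)
        assert pp.boundary_restriction_score(peaks2, mask) == score


class TestPeakSpacing:
    def _ring_peaks_at(self, tissue, cells):
        return pp.PeakSet(
            peak_cells=cells,
            peak_values=np.ones(len(cells)),
            threshold_used=0.0,
            peak_indices=cells,
        )

    def test_four_equally_spaced(self):
        t = pp.generate_ring_tissue(100)
        peaks = self._ring_peaks_at(t, [0, 25, 50, 75])
        sp = pp.peak_spacing(peaks, t)
        assert np.allclose(sp.gaps_deg, 90.0)
        assert sp.gap_cv == pytest.approx(0.0, abs=1e-12)

    def test_two_unequal(self):
        t = pp.generate_ring_tissue(360)  # one cell per degree
        peaks = self._ring_peaks_at(t, [0, 120])
        sp = pp.peak_spacing(peaks, t)
        assert sorted(sp.gaps_deg) == pytest.approx([120.0, 240.0])
        assert sp.gaps_deg.sum() == pytest.approx(360.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(cells=st.lists(st.integers(0, 99), min_size=2, max_size=10, unique=True))
    def test_matches_brute_force_sorting(self, cells):
        t = pp.generate_ring_tissue(100)
        peaks = self._ring_peaks_at(t, sorted(cells))
        sp = pp.peak_spacing(peaks, t)
        center = t.center()
        angles = sorted(
            np.degrees(
                np.arctan2(
                    t.centroids[c, 1] - center[1], t.centroids[c, 0] - center[0]
                )
            )
            % 360.0
            for c in cells
        )
        gaps = np.diff(angles + [angles[0] + 360.0])
        assert np.allclose(np.sort(sp.gaps_deg), np.sort(gaps))
        assert sp.gaps_deg.sum() == pytest.approx(360.0)

    def test_single_peak_undefined(self):
        t = pp.generate_ring_tissue(10)
        with pytest.raises(UndefinedStatisticError):
            pp.peak_spacing(self._ring_peaks_at(t, [0]), t)


class TestConservationReport:
    def test_closed_two_cell_exchange(self):
        # constant membrane PIN (k_p = 0, frozen P_tot) makes the two-cell
        # exchange linear: A relaxes to the mean at rate 2(D + T c) with
        # c = P_tot/(f_p + 1); compare against that closed form
        tissue = pp.TissueGraph(
            cell_ids=[0, 1],
            volumes=np.array([1.0, 1.0]),
            centroids=np.array([[0.0, 0.0], [1.0, 0.0]]),
            walls=[(0, 1)],
            wall_areas=np.array([1.0]),
            boundary_flags=np.array([True, True]),
        )
        prm = replace(
            pp.ModelParams(), c_A=0.0, d_A=0.0, c_P=0.0, d_P=0.0, k_p=0.0,
            D=0.2, T=1.5, f_p=1.0,
        )
        p0 = 2.0
        init = pp.SystemState(
            t=0.0, A=np.array([1.0, 0.0]), P_tot=np.full(2, p0), X=np.zeros(2)
        )
        traj = pp.simulate(tissue, None, prm, 5.0, initial_state=init)
        rep = pp.conservation_report(traj, tissue, prm)
        assert rep.max_relative_drift < 1e-6
        c = p0 / (prm.f_p + 1.0)
        rate = 2.0 * (prm.D + prm.T * c)
        for st_ in traj.states:
            expected = 0.5 + 0.5 * np.exp(-rate * st_.t)
            assert st_.A[0] == pytest.approx(expected, abs=1e-6)
            assert st_.A[1] == pytest.approx(1.0 - expected, abs=1e-6)

    def test_zero_transport_exactly_conserves(self, ring100):
        prm = replace(pp.ModelParams(), c_A=0.0, d_A=0.0, D=0.0, T=0.0)
        init = pp.SystemState(
            t=0.0, A=np.ones(100), P_tot=np.zeros(100), X=np.zeros(100)
        )
        traj = pp.simulate(ring100, None, prm, 10.0, initial_state=init)
        rep = pp.conservation_report(traj, ring100, prm)
        assert rep.max_relative_drift < 1e-12

    def test_production_run_is_informational(self, ring100):
        prm = pp.ModelParams()
        init = pp.SystemState(
            t=0.0, A=np.ones(100), P_tot=np.zeros(100), X=np.zeros(100)
        )
        traj = pp.simulate(ring100, None, prm, 5.0, initial_state=init)
        rep = pp.conservation_report(traj, ring100, prm)
        assert rep.informational

    def test_zero_initial_mass_undefined(self, ring100):
        prm = replace(pp.ModelParams(), c_A=0.0, d_A=0.0)
        traj = pp.simulate(ring100, None, prm, 1.0)
        with pytest.raises(UndefinedStatisticError):
            pp.conservation_report(traj, ring100, prm)
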
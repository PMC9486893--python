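import numpy as np
import pytest

from allostate.errors import ConfigError, UnsupportedResidueError
from allostate.geometry import align_reference_to_x
from allostate.landscape import (
    INTERMEDIATE,
    R_LIKE,
    T_LIKE,
    DistanceDistribution,
    LoopThresholds,
    StateThresholds,
    classify_state,
    find_peaks,
    landscape,
    loop_state,
    make_distribution,
    sidechain_substates,
)
from allostate.synthetic_data import EnsembleSpec, make_ensemble, reference_ensemble


# ---------------------------------------------------------------------------
# distributions and peaks
# ---------------------------------------------------------------------------

def test_unimodal_density(rng):
    values = rng.normal(17.0, 0.5, 10_000)
    dist = make_distribution(values)
    assert dist.integral() == pytest.approx(1.0, abs=1e-6)
    assert len(dist.peaks) == 1
    assert dist.peak_locations[0] == pytest.approx(17.0, abs=0.1)


def test_balanced_mixture_two_peaks(rng):
    values = np.concatenate(
        [rng.normal(17.0, 0.5, 5_000), rng.normal(20.0, 0.5, 5_000)]
    )
    dist = make_distribution(values)
    assert len(dist.peaks) == 2
    np.testing.assert_allclose(dist.peak_locations, [17.0, 20.0], atol=0.15)


def test_constant_series_degenerate():
    dist = make_distribution(np.full(200, 15.0))
    assert dist.degenerate
    assert dist.peaks == []
    assert dist.integral() == pytest.approx(1.0, abs=1e-6)


def test_short_series_warns(rng):
    with pytest.warns(UserWarning, match="samples"):
        make_distribution(rng.normal(10, 1, 20))


def test_peak_shift_equivariance(rng):
    values = np.concatenate(
        [rng.normal(11.0, 0.4, 4_000), rng.normal(13.0, 0.4, 4_000)]
    )
    base = make_distribution(values)
    shifted = make_distribution(values + 2.5)
    np.testing.assert_allclose(
        np.array(shifted.peak_locations) - np.array(base.peak_locations),
        2.5,
        atol=1e-9,
    )


def test_shoulder_below_prominence_filtered():
    # constructed trimodal density: two tall modes plus one tiny shoulder
    grid = np.arange(5.0, 20.0, 0.05)

    def g(mu, sd):
        return np.exp(-0.5 * ((grid - mu) / sd) ** 2)

    density = g(10.0, 0.5) + 0.8 * g(14.0, 0.5) + 0.012 * g(12.0, 0.3)
    density = density / np.trapezoid(density, grid)
    dist = DistanceDistribution(grid=grid, density=density, bandwidth=0.3)
    unfiltered = find_peaks(dist, min_prominence=1e-6, min_separation=0.3)
    assert len(unfiltered) == 3  # the shoulder is a genuine local maximum
    filtered = find_peaks(dist, min_prominence=0.05, min_separation=1.0)
    assert [round(loc) for loc, _, _ in filtered] == [10, 14]


def test_unimodal_exactly_one_peak(rng):
    dist = make_distribution(rng.normal(9.6, 0.3, 2_000))
    assert len(find_peaks(dist)) == 1


# ---------------------------------------------------------------------------
# R/T-like classification
# ---------------------------------------------------------------------------

def test_classify_examples():
    assert classify_state(0.0, 14.0) == R_LIKE
    assert classify_state(12.0, 21.0) == T_LIKE
    assert classify_state(2.0, 18.0) == INTERMEDIATE


def test_classify_partitions_plane():
    t = StateThresholds()
    for theta in np.linspace(-30, 30, 31):
        for d in np.linspace(10, 26, 33):
            labels = {classify_state(theta, d, t)}
            assert len(labels) == 1
            assert labels <= {R_LIKE, T_LIKE, INTERMEDIATE}


def test_inconsistent_thresholds_rejected():
    with pytest.raises(ConfigError):
        StateThresholds(d_R=18.0, d_T=16.0)
    with pytest.raises(ConfigError):
        StateThresholds(theta_R=9.0, theta_T=8.0)


def test_pure_r_state_ensemble(ref_ensemble):
    spec = EnsembleSpec(
        seed=4, n_frames=100,
        fractions={R_LIKE: 1.0, T_LIKE: 0.0, INTERMEDIATE: 0.0},
        r_distance_modes=((15.0, 0.2, 1.0),), r_theta=(0.0, 1.0),
    )
    ens, _ = make_ensemble(spec)
    ref = align_reference_to_x(reference_ensemble(spec), "A")
    table = landscape(ens, "A", ref)
    assert set(table["label"]) == {R_LIKE}


def test_planted_t_fraction_recovered(ref_ensemble):
    spec = EnsembleSpec(seed=5, n_frames=1000, noise_sd=0.05)
    ens, _ = make_ensemble(spec)
    ref = align_reference_to_x(reference_ensemble(spec), "A")
    table = landscape(ens, "A", ref)
    frac = (table["label"] == T_LIKE).mean()
    assert frac == pytest.approx(0.30, abs=0.03)


def test_reference_frame_is_single_r_point(ref_ensemble):
    ref = align_reference_to_x(ref_ensemble, "A")
    table = landscape(ref, "A", ref)
    assert len(table) == 1
    assert table.at[0, "label"] == R_LIKE
    assert table.at[0, "theta_deg"] == pytest.approx(0.0, abs=1e-9)


def test_labels_invariant_under_frame_permutation(ensemble_and_truth, ref_ensemble, rng):
    ens, _ = ensemble_and_truth
    ref = align_reference_to_x(ref_ensemble, "A")
    table = landscape(ens, "A", ref)
    perm = rng.permutation(ens.n_frames)
    from dataclasses import replace

    shuffled = replace(ens, coords=ens.coords[perm], frame_times=None)
    shuffled.residue_maps = dict(ens.residue_maps)
    table2 = landscape(shuffled, "A", ref)
    assert list(table2["label"]) == [table.at[i, "label"] for i in perm]


# ---------------------------------------------------------------------------
# side-chain substates
# ---------------------------------------------------------------------------

def test_three_planted_modes_recovered(ensemble_and_truth):
    ens, truth = ensemble_and_truth
    result = sidechain_substates(ens, "A", seed=0)
    assert result.k == 3
    occ = sorted(result.occupancies.values(), reverse=True)
    np.testing.assert_allclose(occ, [0.5, 0.3, 0.2], atol=0.05)


def test_substate_labels_ordered_by_occupancy(ensemble_and_truth):
    ens, _ = ensemble_and_truth
    result = sidechain_substates(ens, "A", seed=0)
    occs = [result.occupancies[f"Cs{i}"] for i in range(1, result.k + 1)]
    assert occs == sorted(occs, reverse=True)
    assert sum(occs) == pytest.approx(1.0, abs=1e-12)
    assert len(result.table) == ens.n_frames


def test_single_mode_gives_k1():
    spec = EnsembleSpec(
        seed=6, n_frames=150, chi_modes=((-60.0, 170.0, 1.0),), chi_sd=10.0
    )
    ens, _ = make_ensemble(spec)
    result = sidechain_substates(ens, "A", seed=0)
    assert result.k == 1
    assert result.occupancies == {"Cs1": 1.0}


def test_wrapped_modes_merge():
    # 175 and -175 degrees are 10 degrees apart on the circle
    gap = abs((175.0 - (-175.0) + 180.0) % 360.0 - 180.0)
    assert gap == pytest.approx(10.0)
    spec = EnsembleSpec(
        seed=7, n_frames=200,
        chi_modes=((175.0, 60.0, 0.5), (-175.0, 60.0, 0.5)), chi_sd=6.0,
    )
    ens, _ = make_ensemble(spec)
    result = sidechain_substates(ens, "A", seed=0)
    assert result.k == 1


def test_proline_unsupported():
    spec = EnsembleSpec(seed=8, n_frames=20, residue250="PRO")
    ens, _ = make_ensemble(spec)
    with pytest.raises(UnsupportedResidueError, match="chi"):
        sidechain_substates(ens, "A", seed=0)


def test_planted_chi_angles_exact(ensemble_and_truth):
    ens, truth = ensemble_and_truth
    result = sidechain_substates(ens, "A", seed=0)
    np.testing.assert_allclose(
        result.table["chi1"], truth["chains"]["A"]["chi1"], atol=1e-8
    )
    np.testing.assert_allclose(
        result.table["chi2"], truth["chains"]["A"]["chi2"], atol=1e-8
    )


# ---------------------------------------------------------------------------
# mobile loop
# ---------------------------------------------------------------------------

def test_loop_exemplars():
    t = LoopThresholds()
    assert t.classify(13.1, 9.6) == "closed"
    assert t.classify(22.0, 21.0) == "open"
    assert t.classify(17.0, 13.0) == INTERMEDIATE


def test_loop_thresholds_validated():
    with pytest.raises(ConfigError):
        LoopThresholds(closed_d102=21.0)


def test_planted_loop_states_recovered():
    spec = EnsembleSpec(
        seed=9, n_frames=300,
        loop_fractions={"closed": 0.5, "open": 0.3, "intermediate": 0.2},
    )
    ens, truth = make_ensemble(spec)
    table = loop_state(ens, "A")
    planted = truth["chains"]["A"]["loop_state"]
    agree = np.mean([a == b for a, b in zip(table["state"], planted)])
    assert agree > 0.97  # narrow planted SDs keep states inside their bands
    np.testing.assert_allclose(table["d102_A"], truth["chains"]["A"]["d102"], atol=1e-9)
    np.testing.assert_allclose(table["d109_A"], truth["chains"]["A"]["d109"], atol=1e-9)
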
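"""Recombination-frequency MLEs, phase selection, and LOD scores.

The independent oracle used throughout is a dense grid search of the
scenario log-likelihood, built from hand-coded class-frequency formulas
(transcribed from the published two-locus tables, not from the package's
own model objects).
"""

import math

import numpy as np
import pytest

from clonalmap.estimation import (
    InestimableError,
    Phase,
    closed_form_s9_phase23,
    estimate_all_pairs,
    estimate_pair,
    s9_phase_estimates,
)
from clonalmap.markers import MarkerCategory
from conftest import make_joint_counts

# ---------------------------------------------------------------------------
# Hand-coded class frequencies (oracle side)
# ---------------------------------------------------------------------------

def freq_s1(rf, rm):
    rf, rm = np.asarray(rf), np.asarray(rm)
    qf, qm = 1 - rf, 1 - rm
    female = [qf] * 4 + [rf] * 8 + [qf] * 4
    male_rec = {1, 2, 5, 6, 9, 10, 13, 14}
    return np.stack(
        [0.25 * female[i] * (rm if i in male_rec else qm) for i in range(16)]
    )


def freq_s2(rm):
    rm = np.asarray(rm)
    q, p = 0.25 * (1 - rm), 0.25 * rm
    return np.stack([q, p, p, q, q, p, p, q])


def freq_s3(rf):
    rf = np.asarray(rf)
    q, p = 0.25 * (1 - rf), 0.25 * rf
    return np.stack([q, p, q, p, p, q, p, q])


def freq_s4(rf, rm):
    rf, rm = np.asarray(rf), np.asarray(rm)
    qf, qm = 1 - rf, 1 - rm
    return 0.25 * np.stack(
        [
            qf * qm,
            qf * rm + rf * qm,
            rf * rm,
            qf * rm,
            qf * qm + rf * rm,
            rf * qm,
            rf * qm,
            qf * qm + rf * rm,
            qf * rm,
            rf * rm,
            qf * rm + rf * qm,
            qf * qm,
        ]
    )


def freq_s5(rm):
    rm = np.asarray(rm)
    q, p = 0.5 * (1 - rm), 0.5 * rm
    return np.stack([q, p, p, q])


def freq_s6(rm):
    rm = np.asarray(rm)
    q, p = 0.25 * (1 - rm), 0.25 * rm
    h = np.full_like(q, 0.25)
    return np.stack([q, h, p, p, h, q])


def freq_s9(rf, rm):
    rf, rm = np.asarray(rf), np.asarray(rm)
    qf, qm = 1 - rf, 1 - rm
    hom = 0.25 * qf * qm
    het = 0.25 * (qf * rm + rf * qm)
    opp = 0.25 * rf * rm
    dbl = 0.5 * (qf * qm + rf * rm)
    return np.stack([hom, het, opp, het, dbl, het, opp, het, hom])


PHASE_SUB = {
    Phase.I: lambda r: (r, r),
    Phase.II: lambda r: (r, 1 - r),
    Phase.III: lambda r: (1 - r, r),
    Phase.IV: lambda r: (1 - r, 1 - r),
}


def oracle_freqs(sid, r, phase=Phase.I):
    """Class frequencies at combined r for any scenario, oracle side."""
    rf, rm = PHASE_SUB[phase](np.asarray(r, dtype=float))
    if sid == 1:
        return freq_s1(rf, rm)
    if sid == 2:
        return freq_s2(rm)
    if sid == 3:
        return freq_s3(rf)
    if sid == 4:
        return freq_s4(rf, rm)
    if sid == 5:
        return freq_s5(rm)
    if sid == 6:
        return freq_s6(rm)
    if sid == 7:
        return freq_s5(rf)
    if sid == 8:
        return freq_s6(rf)
    if sid == 9:
        return freq_s9(rf, rm)
    if sid == 10:
        return freq_s4(rf, 1 - rm)
    if sid == 11:
        return freq_s6(1 - rm)
    if sid == 12:
        return freq_s6(rf)
    if sid == 13:
        return freq_s9(rf, 1 - rm)
    if sid == 14:
        return freq_s9(rf, rm)
    raise ValueError(sid)


def grid_argmax(counts, probs, grid):
    """Grid-search maximizer of sum c_i log p_i(r); oracle."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(probs)
    counts = np.asarray(counts, dtype=float)
    ll = np.where(counts[:, None] > 0, counts[:, None] * logp, 0.0).sum(axis=0)
    ll = np.where(np.isnan(ll), -np.inf, ll)
    return float(grid[int(np.argmax(ll))])


GRID_HALF = np.linspace(1e-6, 0.5, 50001)       # step 1e-5 on (0, 0.5]
GRID_FULL = np.linspace(1e-6, 1 - 1e-6, 100001)  # step 1e-5 on (0, 1)


# ---------------------------------------------------------------------------
# Worked examples per scenario
# ---------------------------------------------------------------------------

class TestScenario1:
    def test_pure_parental_classes(self):
        counts = np.zeros(16)
        counts[[0, 3, 12, 15]] = 25
        est = estimate_pair(make_joint_counts(1, counts))
        assert est.r_f == 0 and est.r_m == 0 and est.r == 0
        assert est.phase is Phase.I

    def test_expected_counts_recover_parameters(self):
        counts = freq_s1(0.1, 0.3) * 1000
        est = estimate_pair(make_joint_counts(1, counts))
        assert est.r_f == pytest.approx(0.1, abs=1e-12)
        assert est.r_m == pytest.approx(0.3, abs=1e-12)
        assert est.r == pytest.approx(0.2, abs=1e-12)
        assert est.phase is Phase.I

    def test_uniform_counts_mean_no_linkage(self):
        est = estimate_pair(make_joint_counts(1, [10] * 16))
        assert est.r_f == 0.5 and est.r_m == 0.5 and est.r == 0.5
        assert est.lod == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "rf,rm,phase,r",
        [
            (0.1, 0.3, Phase.I, 0.2),
            (0.1, 0.7, Phase.II, 0.2),
            (0.7, 0.3, Phase.III, 0.3),
            (0.9, 0.7, Phase.IV, 0.2),
        ],
    )
    def test_phase_case_analysis(self, rf, rm, phase, r):
        counts = freq_s1(rf, rm) * 2000
        est = estimate_pair(make_joint_counts(1, counts))
        assert est.phase is phase
        assert est.r == pytest.approx(r, abs=1e-12)


class TestScenario2and3:
    def test_s2_expected_counts(self):
        counts = freq_s2(0.2) * 800
        est = estimate_pair(make_joint_counts(2, counts))
        assert est.r_m == pytest.approx(0.2) and est.r == pytest.approx(0.2)
        assert math.isnan(est.r_f)

    def test_s2_repulsion_reflects(self):
        counts = freq_s2(0.7) * 800
        est = estimate_pair(make_joint_counts(2, counts))
        assert est.r_m == pytest.approx(0.7) and est.r == pytest.approx(0.3)

    def test_s3_no_recombinants(self):
        counts = freq_s3(0.0) * 100
        est = estimate_pair(make_joint_counts(3, counts))
        assert est.r_f == 0 and est.r == 0 and math.isnan(est.r_m)


class TestScenario4:
    def test_phase_I_expected_counts(self):
        counts = freq_s4(0.2, 0.2) * 1200
        est = estimate_pair(make_joint_counts(4, counts))
        assert est.phase is Phase.I
        assert est.r == pytest.approx(0.2, abs=1e-6)
        oracle = grid_argmax(counts, oracle_freqs(4, GRID_HALF), GRID_HALF)
        assert est.r == pytest.approx(oracle, abs=1e-4)

    def test_no_recombinants_in_informative_classes(self):
        counts = freq_s4(0.0, 0.0) * 400  # mass only on classes 1, 5, 8, 12
        est = estimate_pair(make_joint_counts(4, counts))
        assert est.r_f == 0 and est.r_m == 0 and est.phase is Phase.I
        assert est.r == pytest.approx(0.0, abs=1e-4)

    def test_only_heterozygote_classes_falls_back_to_phase_search(self):
        counts = np.zeros(12)
        counts[[1, 4, 7, 10]] = 30
        est = estimate_pair(make_joint_counts(4, counts))
        assert 0 <= est.r <= 0.5


class TestScenario5to8:
    def test_s5_coupling(self):
        est = estimate_pair(make_joint_counts(5, [45, 5, 5, 45]))
        assert est.r_m == pytest.approx(0.1) and est.r == pytest.approx(0.1)

    def test_s5_repulsion(self):
        est = estimate_pair(make_joint_counts(5, [5, 45, 45, 5]))
        assert est.r_m == pytest.approx(0.9) and est.r == pytest.approx(0.1)

    def test_s5_no_linkage(self):
        est = estimate_pair(make_joint_counts(5, [25, 25, 25, 25]))
        assert est.r == pytest.approx(0.5)

    def test_s6_informative_classes_only(self):
        est = estimate_pair(make_joint_counts(6, [45, 50, 5, 5, 50, 45]))
        assert est.r == pytest.approx(0.1)

    def test_s6_only_heterozygotes_inestimable(self):
        with pytest.raises(InestimableError):
            estimate_pair(make_joint_counts(6, [0, 40, 0, 0, 40, 0]))

    def test_s6_expected_at_half(self):
        counts = freq_s6(0.5) * 400
        est = estimate_pair(make_joint_counts(6, counts))
        assert est.r == pytest.approx(0.5)

    def test_s7_s8_female_side(self):
        est7 = estimate_pair(make_joint_counts(7, [45, 5, 5, 45]))
        assert est7.r_f == pytest.approx(0.1) and math.isnan(est7.r_m)
        est8 = estimate_pair(make_joint_counts(8, [45, 50, 5, 5, 50, 45]))
        assert est8.r_f == pytest.approx(0.1) and math.isnan(est8.r_m)


class TestScenario9:
    def test_phase_profile_at_r02(self):
        """Matched phase estimates 0.2; II/III sit at the 0.5 boundary; IV mirrors."""
        counts = freq_s9(0.2, 0.2) * 10000
        fits = s9_phase_estimates(counts)
        assert fits[Phase.I] == pytest.approx(0.2, abs=1e-6)
        assert fits[Phase.II] == pytest.approx(0.5, abs=1e-12)
        assert fits[Phase.III] == pytest.approx(0.5, abs=1e-12)
        assert fits[Phase.IV] == pytest.approx(0.8, abs=1e-6)
        est = estimate_pair(make_joint_counts(9, counts))
        assert est.phase is Phase.I and est.r == pytest.approx(0.2, abs=1e-6)
        assert est.r_f == pytest.approx(0.2, abs=1e-6)
        assert est.r_m == pytest.approx(0.2, abs=1e-6)

    def test_perfect_coupling(self):
        est = estimate_pair(make_joint_counts(9, np.array([1, 0, 0, 0, 2, 0, 0, 0, 1]) * 50))
        assert est.phase is Phase.I and est.r == pytest.approx(0.0, abs=1e-4)

    def test_phase23_closed_form_hand_value(self):
        # corner+double-het proportion 0.32: r = (1 - sqrt(1 - 0.64))/2 = 0.2
        counts = np.zeros(9)
        counts[0] = 32
        counts[1] = 68
        assert closed_form_s9_phase23(counts) == pytest.approx(0.2)

    def test_repulsion_phase_selected(self):
        counts = freq_s9(0.2, 1 - 0.2) * 10000  # female coupling, male repulsion
        est = estimate_pair(make_joint_counts(9, counts))
        assert est.phase is Phase.II
        assert est.r == pytest.approx(0.2, abs=1e-9)
        assert est.r_f == pytest.approx(0.2, abs=1e-9)
        assert est.r_m == pytest.approx(0.8, abs=1e-9)

    def test_unlinked_phase_unassigned(self):
        counts = freq_s9(0.5, 0.5) * 1600
        est = estimate_pair(make_joint_counts(9, counts))
        assert est.phase is Phase.UNASSIGNED and est.r == 0.5

    def test_phase_recovery_rate(self):
        """The generating phase is recovered in >=95% of samples at r=0.2, n=200."""
        rng = np.random.default_rng(99)
        for true_phase in (Phase.I, Phase.II, Phase.IV):
            probs = oracle_freqs(9, 0.2, true_phase)
            hits = 0
            for _ in range(100):
                counts = rng.multinomial(200, probs)
                est = estimate_pair(make_joint_counts(9, counts))
                got = est.phase
                if true_phase is Phase.II:
                    hits += got in (Phase.II, Phase.III)
                else:
                    hits += got is true_phase
            assert hits >= 95


class TestDoubleCross:
    def test_s12_identical_to_s8(self):
        counts = [45, 50, 5, 5, 50, 45]
        est12 = estimate_pair(make_joint_counts(12, counts))
        est8 = estimate_pair(make_joint_counts(8, counts))
        assert est12.r == pytest.approx(est8.r)

    def test_s14_expected_counts(self):
        counts = freq_s9(0.2, 0.2) * 10000
        est = estimate_pair(make_joint_counts(14, counts))
        assert est.r == pytest.approx(0.2, abs=1e-6)
        assert est.r_f == pytest.approx(0.2, abs=1e-6)

    def test_s13_expected_counts(self):
        counts = oracle_freqs(13, 0.2) * 10000
        est = estimate_pair(make_joint_counts(13, counts))
        assert est.r == pytest.approx(0.2, abs=1e-9)

    def test_s10_expected_counts(self):
        counts = oracle_freqs(10, 0.2) * 10000
        est = estimate_pair(make_joint_counts(10, counts))
        assert est.r == pytest.approx(0.2, abs=1e-6)
        assert est.r_f == pytest.approx(0.2, abs=1e-9)
        assert est.r_m == pytest.approx(0.2, abs=1e-9)

    def test_s11_expected_counts(self):
        counts = oracle_freqs(11, 0.15) * 4000
        est = estimate_pair(make_joint_counts(11, counts))
        assert est.r == pytest.approx(0.15, abs=1e-9)
        assert est.r_m == pytest.approx(0.15, abs=1e-9)


class TestLod:
    def test_zero_at_half(self):
        est = estimate_pair(make_joint_counts(5, [25, 25, 25, 25]))
        assert est.lod == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_scenario5(self):
        # 90 log10(0.45/0.25) + 10 log10(0.05/0.25) = 15.9848
        est = estimate_pair(make_joint_counts(5, [45, 5, 5, 45]))
        assert est.lod == pytest.approx(15.9848, abs=1e-3)

    def test_linear_in_sample_size(self):
        lod1 = estimate_pair(make_joint_counts(5, [45, 5, 5, 45])).lod
        lod3 = estimate_pair(make_joint_counts(5, [135, 15, 15, 135])).lod
        assert lod3 == pytest.approx(3 * lod1, rel=1e-9)


# ---------------------------------------------------------------------------
# Properties: grid-search oracle, consistency, recovery
# ---------------------------------------------------------------------------

def _random_counts(rng, sid, n=200):
    r = rng.uniform(0.03, 0.47)
    if sid <= 9:
        phase = rng.choice([Phase.I, Phase.II, Phase.III, Phase.IV])
    else:
        phase = Phase.I
    probs = oracle_freqs(sid, r, phase)
    return rng.multinomial(n, probs)


@pytest.mark.parametrize("sid", list(range(1, 15)))
def test_mle_matches_grid_oracle(sid):
    """Closed forms and Newton-Raphson agree with a 1e-5 grid search."""
    rng = np.random.default_rng(1000 + sid)
    for _ in range(200):
        counts = _random_counts(rng, sid)
        try:
            est = estimate_pair(make_joint_counts(sid, counts))
        except InestimableError:
            continue
        if sid in (2, 5, 6, 11):  # male-side closed forms: raw parameter grid
            oracle = grid_argmax(counts, oracle_freqs(sid, GRID_FULL), GRID_FULL)
            assert est.r_m == pytest.approx(oracle, abs=1e-4)
        elif sid in (3, 7, 8, 12):
            oracle = grid_argmax(counts, oracle_freqs(sid, GRID_FULL), GRID_FULL)
            assert est.r_f == pytest.approx(oracle, abs=1e-4)
        elif sid == 1:
            ofs = freq_s1(GRID_FULL, np.full_like(GRID_FULL, 0.3))
            assert est.r_f == pytest.approx(grid_argmax(counts, ofs, GRID_FULL), abs=1e-4)
            oms = freq_s1(np.full_like(GRID_FULL, 0.3), GRID_FULL)
            assert est.r_m == pytest.approx(grid_argmax(counts, oms, GRID_FULL), abs=1e-4)
        elif sid == 4:
            if est.phase is Phase.UNASSIGNED:
                continue
            probs = oracle_freqs(4, GRID_HALF, est.phase)
            assert est.r == pytest.approx(grid_argmax(counts, probs, GRID_HALF), abs=1e-4)
        elif sid == 9:
            fits = s9_phase_estimates(np.asarray(counts, dtype=float))
            o1 = grid_argmax(counts, oracle_freqs(9, GRID_FULL, Phase.I), GRID_FULL)
            o4 = grid_argmax(counts, oracle_freqs(9, GRID_FULL, Phase.IV), GRID_FULL)
            o2 = grid_argmax(counts, oracle_freqs(9, GRID_HALF, Phase.II), GRID_HALF)
            assert fits[Phase.I] == pytest.approx(o1, abs=1e-4)
            assert fits[Phase.IV] == pytest.approx(o4, abs=1e-4)
            assert fits[Phase.II] == pytest.approx(o2, abs=1e-4)
        else:  # 10, 13, 14: combined-r models on (0, 0.5]
            probs = oracle_freqs(sid, GRID_HALF)
            assert est.r == pytest.approx(grid_argmax(counts, probs, GRID_HALF), abs=1e-4)
        assert est.r <= 0.5 + 1e-9
        assert est.lod >= -1e-9


@pytest.mark.parametrize("sid", list(range(1, 15)))
def test_consistency_at_expectation(sid):
    """Estimation on exact expected counts returns the true r within 1e-6."""
    phases = [Phase.I, Phase.II, Phase.III, Phase.IV] if sid in (1, 4, 9) else [Phase.I]
    for phase in phases:
        for r in np.arange(0.05, 0.5, 0.05):
            counts = oracle_freqs(sid, r, phase) * 100000
            est = estimate_pair(make_joint_counts(sid, counts))
            assert est.r == pytest.approx(r, abs=1e-6), (sid, phase, r)
            if sid in (1, 4):
                assert est.phase is phase
            elif sid == 9:
                # phases II and III are genetically equivalent and collapse
                expected = {Phase.II: {Phase.II, Phase.III}, Phase.III: {Phase.II, Phase.III}}
                assert est.phase in expected.get(phase, {phase})


@pytest.mark.parametrize("sid", list(range(1, 15)))
def test_parameter_recovery_in_sampling(sid):
    """mean(r-hat) over 500 samples of n=200 lies within 3 SE of the true r."""
    rng = np.random.default_rng(2000 + sid)
    true_r = 0.2
    probs = oracle_freqs(sid, true_r, Phase.I)
    ests = []
    for _ in range(500):
        counts = rng.multinomial(200, probs)
        try:
            ests.append(estimate_pair(make_joint_counts(sid, counts)).r)
        except InestimableError:
            pass
    ests = np.asarray(ests)
    assert len(ests) >= 490
    se = ests.std(ddof=1) / math.sqrt(len(ests))
    assert abs(ests.mean() - true_r) < 3 * se + 1e-3


class TestAllPairs:
    def test_matrices_symmetric_masked(self, demo_result):
        rm = demo_result.rm
        assert np.allclose(rm.r.to_numpy(), rm.r.to_numpy().T, equal_nan=True)
        assert (rm.mask.to_numpy() == rm.mask.to_numpy().T).all()
        assert not rm.mask.to_numpy().diagonal().any()
        valid = rm.r.to_numpy()[rm.mask.to_numpy()]
        assert (valid <= 0.5 + 1e-9).all()
        assert (rm.lod.to_numpy()[rm.mask.to_numpy()] >= -1e-9).all()

    def test_masked_cells_are_exactly_ii_iii_pairs(self, demo_result, demo_population):
        gm, _ = demo_population
        rm = demo_result.rm
        for a in gm.marker_ids:
            for b in gm.marker_ids:
                if a == b:
                    continue
                cats = {gm.categories[a], gm.categories[b]}
                expect = cats != {MarkerCategory.II, MarkerCategory.III}
                assert bool(rm.mask.loc[a, b]) == expect
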
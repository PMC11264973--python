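import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astruct.alignment_io import AllelePartition, HetSNPObservation, SNPSite, SNPWindow
from astruct.asrs import (
    GROUP_HIGH,
    GROUP_LOW,
    GROUP_MEDIUM,
    NullDistribution,
    astruct_score,
    call_site,
    classify_group,
    esdc,
    p_value,
    permutation_null,
    strucdiff,
    strucdiff_track,
)
from astruct.errors import InsufficientDataError
from astruct.reactivity import ReactivityProfile

from conftest import mk_read
from oracles import strucdiff_oracle


def _profile(scores, n=None, allele="ref"):
    scores = np.asarray(scores, dtype=float)
    n = len(scores) if n is None else n
    w = SNPWindow("chr1", 0, n, "+", 0)
    return ReactivityProfile(w, scores, allele)


class TestEsdc:
    def test_identical_profiles_zero(self):
        scores = np.linspace(0, 1, 100)
        pcc, e = esdc(_profile(scores), _profile(scores, allele="alt"))
        assert pcc == pytest.approx(1.0)
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_uncorrelated_profiles(self):
        x = np.array([0.0, 1.0, 0.0, 1.0] * 25)
        y = np.array([0.0, 0.0, 1.0, 1.0] * 25)
        pcc, e = esdc(_profile(x), _profile(y, allele="alt"))
        assert pcc == pytest.approx(0.0, abs=1e-12)
        assert e == pytest.approx(10.0)  # (1 - 0) * sqrt(100)

    def test_anticorrelated_profiles(self):
        x = np.array([0.0, 1.0, 0.5, 0.2, 0.9] * 5)
        y = 1.0 - x
        pcc, e = esdc(_profile(x), _profile(y, allele="alt"))
        assert pcc == pytest.approx(-1.0)
        assert e == pytest.approx(10.0)  # (1 - (-1)) * sqrt(25)

    def test_zero_variance_is_degenerate(self):
        pcc, e = esdc(_profile(np.full(20, 0.5)), _profile(np.linspace(0, 1, 20), allele="alt"))
        assert math.isnan(pcc) and e == 0.0

    def test_too_few_shared_bases(self):
        a = np.full(10, np.nan)
        a[:2] = [0.1, 0.9]
        with pytest.raises(InsufficientDataError):
            esdc(_profile(a), _profile(np.linspace(0, 1, 10), allele="alt"))


class TestPValue:
    def test_observed_beats_all(self):
        null = NullDistribution(np.linspace(0, 1, 1000), 1000)
        assert p_value(2.0, null) == pytest.approx(1 / 1001)

    def test_observed_zero_maximal(self):
        null = NullDistribution(np.abs(np.sin(np.arange(100))), 100)
        assert p_value(0.0, null) == 1.0

    def test_observed_at_median(self):
        null = NullDistribution(np.arange(1.0, 1001.0), 1000)
        # direct counting: 501 null values >= 500
        assert p_value(500.0, null) == pytest.approx(502 / 1001)


class TestAstructScore:
    def test_full_spanning_fraction(self):
        assert astruct_score(0.01, 2.0, 10, 10) == pytest.approx(4.0)

    def test_nonspanning_reads_inflate_factor(self):
        assert astruct_score(0.1, 3.0, 1, 10) == pytest.approx(6.0)

    def test_p_one_gives_zero_and_low(self):
        s = astruct_score(1.0, 5.0, 3, 7)
        assert s == 0.0
        assert classify_group(s) == GROUP_LOW

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            astruct_score(0.0, 1.0, 5, 10)
        with pytest.raises(ValueError):
            astruct_score(0.5, 1.0, 0, 10)
        with pytest.raises(ValueError):
            astruct_score(0.5, 1.0, 11, 10)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "score,group",
        [
            (0.0, GROUP_LOW),
            (1e-9, GROUP_MEDIUM),
            (1.0, GROUP_MEDIUM),  # the Medium interval is closed at 1
            (1.0 + 1e-9, GROUP_HIGH),
            (8.74, GROUP_HIGH),
        ],
    )
    def test_boundaries(self, score, group):
        assert classify_group(score) == group

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_group(-0.1)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    p1=st.floats(1e-6, 1.0, exclude_max=True),
    p2=st.floats(1e-6, 1.0, exclude_max=True),
    e1=st.floats(0.01, 50),
    e2=st.floats(0.01, 50),
)
def test_score_monotonicity(p1, p2, e1, e2):
    """Strictly increasing in eSDC at fixed P; strictly decreasing in P at
    fixed eSDC (spanning fraction held fixed)."""
    if e1 != e2:
        lo, hi = sorted([e1, e2])
        assert astruct_score(p1, lo, 5, 20) < astruct_score(p1, hi, 5, 20)
    if p1 != p2:
        lo, hi = sorted([p1, p2])
        assert astruct_score(lo, e1, 5, 20) > astruct_score(hi, e1, 5, 20)


class TestStrucDiff:
    def test_identical_profiles_all_zero(self):
        scores = np.linspace(0, 1, 30)
        track = strucdiff_track(scores, scores)
        inner = track[2:-2]
        assert np.all(inner == 0.0)
        assert np.isnan(track[:2]).all() and np.isnan(track[-2:]).all()

    def test_single_unit_difference_spreads_fifths(self):
        n, k = 30, 12
        a = np.zeros(n)
        b = np.zeros(n)
        b[k] = 1.0
        track = strucdiff_track(a, b)
        for i in range(2, n - 2):
            assert track[i] == pytest.approx(0.2 if k - 2 <= i <= k + 2 else 0.0)

    def test_matches_naive_double_loop(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = rng.random(n)
            b = rng.random(n)
            if n > 10:  # sprinkle missing values
                a[rng.integers(0, n)] = np.nan
                b[rng.integers(0, n)] = np.nan
            track = strucdiff_track(a, b)
            expected = strucdiff_oracle(list(a), list(b))
            for i in range(n):
                if expected[i] is None:
                    assert np.isnan(track[i])
                else:
                    assert track[i] == pytest.approx(expected[i], abs=1e-12)

    def test_short_window_all_missing(self):
        track = strucdiff_track(np.zeros(4), np.ones(4))
        assert np.isnan(track).all()

    def test_per_base_p_values_from_null_tracks(self):
        a = np.zeros(20)
        b = np.zeros(20)
        b[10] = 1.0
        nulls = np.zeros((99, 20))  # null never reaches the observed bump
        sd, pv = strucdiff(_profile(a), _profile(b, allele="alt"), nulls, 99)
        assert sd[10] == pytest.approx(0.2)
        assert pv[10] == pytest.approx(1 / 100)
        assert pv[5] == pytest.approx(1.0)  # ties: null >= 0 everywhere
        assert np.isnan(pv[0])


def _toy_partition(shift=0):
    """12 ref + 12 alt spanning reads and a few shared non-spanning reads."""
    ref = [mk_read(95 + (i % 6), 135 + (i % 6), "A") for i in range(12)]
    alt = [mk_read(95 + ((i + shift) % 6), 135 + ((i + shift) % 6), "G") for i in range(12)]
    shared = [mk_read(105 + i, 139, None) for i in range(4)]
    part = AllelePartition()
    for arm in ("treated", "control"):
        part.ref_spanning[arm] = ref
        part.alt_spanning[arm] = alt
        part.nonspanning[arm] = shared
    window = SNPWindow("chr1", 95, 141, "+", 20)
    return window, part


class TestPermutationNull:
    def test_cardinality_and_determinism(self):
        window, part = _toy_partition()
        null1, _ = permutation_null(window, part, n_perm=50, rng=7)
        null2, _ = permutation_null(window, part, n_perm=50, rng=7)
        assert null1.n_perm == 50 and len(null1.esdc_values) == 50
        assert np.array_equal(null1.esdc_values, null2.esdc_values)

    def test_different_seeds_differ(self):
        window, part = _toy_partition()
        null1, _ = permutation_null(window, part, n_perm=50, rng=7)
        null2, _ = permutation_null(window, part, n_perm=50, rng=8)
        assert not np.array_equal(null1.esdc_values, null2.esdc_values)

    def test_identical_allele_patterns_not_significant(self):
        window, part = _toy_partition(shift=0)
        site = SNPSite("chr1", 115, "rs1", "A", "G")
        obs = HetSNPObservation(site, 12, 12, 0, True)
        call = call_site(obs, window, part, n_perm=200, rng=3)
        assert call.p_value >= 0.5
        assert call.group == GROUP_LOW


class TestCallSite:
    def test_deterministic_given_seed(self):
        window, part = _toy_partition(shift=3)
        site = SNPSite("chr1", 115, "rs1", "A", "G")
        obs = HetSNPObservation(site, 12, 12, 0, True)
        c1 = call_site(obs, window, part, n_perm=100, rng=11, per_base=True)
        c2 = call_site(obs, window, part, n_perm=100, rng=11, per_base=True)
        assert c1.esdc == c2.esdc
        assert c1.p_value == c2.p_value
        assert c1.astruct_score == c2.astruct_score
        assert np.array_equal(c1.strucdiff, c2.strucdiff, equal_nan=True)
        assert np.array_equal(c1.strucdiff_p, c2.strucdiff_p, equal_nan=True)

    def test_group_consistent_with_score(self):
        window, part = _toy_partition(shift=2)
        site = SNPSite("chr1", 115, "rs1", "A", "G")
        obs = HetSNPObservation(site, 12, 12, 0, True)
        call = call_site(obs, window, part, n_perm=100, rng=5)
        assert call.group == classify_group(call.astruct_score)
        assert call.r_d == 48 and call.r_total == 56
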
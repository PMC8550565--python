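import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dvmetric.exceptions import (
    ConfigError,
    InputError,
    PairedSampleError,
    ParameterError,
)
from dvmetric.mi import (
    EnsembleConfig,
    as_sample_vector,
    estimate_cmi,
    estimate_mi,
    estimate_mi_hash_ensemble,
    estimate_mi_knn,
    estimate_mi_plugin,
)

from conftest import brute_force_mi


class TestPlugin:
    def test_constant_x_gives_zero(self):
        x = np.zeros(50, dtype=int)
        y = np.arange(50) % 3
        assert estimate_mi_plugin(x, y).value == 0.0

    def test_self_information_fair_coin_is_one_bit(self):
        x = np.array([0, 1] * 40)
        assert estimate_mi_plugin(x, x, base="bits").value == pytest.approx(
            1.0, abs=1e-12)

    def test_worked_joint_table(self):
        # joint frequencies {(0,0):0.4, (0,1):0.1, (1,0):0.1, (1,1):0.4}
        x = np.array([0] * 4 + [0] + [1] + [1] * 4)
        y = np.array([0] * 4 + [1] + [0] + [1] * 4)
        est = estimate_mi_plugin(x, y, base="bits")
        assert est.value == pytest.approx(0.27807, abs=1e-5)
        assert est.value == pytest.approx(brute_force_mi(x, y, "bits"),
                                          abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 6, 80)
        y = (x + r.integers(0, 3, 80)) % 6
        assert estimate_mi_plugin(x, y).value == pytest.approx(
            brute_force_mi(x, y), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_and_nonnegativity(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 4, 60)
        y = r.integers(0, 4, 60)
        fwd = estimate_mi_plugin(x, y).value
        assert fwd >= 0.0
        assert fwd == estimate_mi_plugin(y, x).value

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_label_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 5, 70)
        y = (2 * x + r.integers(0, 2, 70)) % 5
        perm = r.permutation(5)
        assert estimate_mi_plugin(perm[x], y).value == pytest.approx(
            estimate_mi_plugin(x, y).value, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(PairedSampleError):
            estimate_mi_plugin(np.arange(5), np.arange(6))

    def test_empty_input_raises(self):
        with pytest.raises(InputError):
            estimate_mi_plugin(np.array([], dtype=int), np.array([], dtype=int))

    def test_continuous_input_rejected(self):
        with pytest.raises(InputError):
            estimate_mi_plugin(np.random.default_rng(0).standard_normal(10),
                               np.arange(10))


class TestKnn:
    def test_independent_normals_near_zero(self):
        r = np.random.default_rng(11)
        x, y = r.standard_normal(2000), r.standard_normal(2000)
        assert estimate_mi_knn(x, y, k=5).value < 0.05

    def test_gaussian_closed_form(self, gaussian_pair):
        x, y, truth = gaussian_pair
        assert estimate_mi_knn(x, y, k=5).value == pytest.approx(
            truth, abs=0.08)

    def test_monotone_transform_invariance(self, gaussian_pair):
        x, y, _ = gaussian_pair
        base = estimate_mi_knn(x, y, k=5).value
        warped = estimate_mi_knn(np.exp(x), y, k=5).value
        assert warped == pytest.approx(base, abs=0.05)

    def test_swap_symmetry_within_tolerance(self, gaussian_pair):
        x, y, _ = gaussian_pair
        assert estimate_mi_knn(x, y).value == pytest.approx(
            estimate_mi_knn(y, x).value, abs=0.02)

    def test_k_out_of_range(self):
        x = np.random.default_rng(0).standard_normal(10)
        with pytest.raises(ParameterError):
            estimate_mi_knn(x, x, k=10)

    def test_nonfinite_rejected(self):
        x = np.array([0.0, np.nan, 1.0])
        with pytest.raises(InputError):
            estimate_mi_knn(x, x, k=1)


class TestHashEnsemble:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_discrete_reduces_to_plugin_exactly(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 5, 100)
        y = (x + r.integers(0, 2, 100)) % 5
        assert estimate_mi_hash_ensemble(x, y).value == \
            estimate_mi_plugin(x, y).value

    def test_independent_continuous_near_zero(self):
        r = np.random.default_rng(13)
        x, y = r.standard_normal(2000), r.standard_normal(2000)
        assert estimate_mi_hash_ensemble(x, y).value < 0.05

    def test_gaussian_closed_form(self, gaussian_pair):
        x, y, truth = gaussian_pair
        assert estimate_mi_hash_ensemble(
            x, y, EnsembleConfig(seed=1)).value == pytest.approx(
            truth, abs=0.08)

    def test_seeded_reproducibility(self, gaussian_pair):
        x, y, _ = gaussian_pair
        a = estimate_mi_hash_ensemble(x, y, EnsembleConfig(seed=5)).value
        b = estimate_mi_hash_ensemble(x, y, EnsembleConfig(seed=5)).value
        assert a == b

    def test_swap_symmetry_within_tolerance(self, gaussian_pair):
        x, y, _ = gaussian_pair
        a = estimate_mi_hash_ensemble(x, y, EnsembleConfig(seed=2)).value
        b = estimate_mi_hash_ensemble(y, x, EnsembleConfig(seed=2)).value
        assert a == pytest.approx(b, abs=0.05)

    def test_too_few_resolutions_rejected(self):
        with pytest.raises(ConfigError):
            EnsembleConfig(resolutions=[8])

    def test_non_increasing_resolutions_rejected(self):
        with pytest.raises(ConfigError):
            EnsembleConfig(resolutions=[16, 8])

    def test_explicit_weights_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            EnsembleConfig(weighting=[0.5, 0.2, 0.2])


class TestConditionalMI:
    def test_conditioning_on_itself_is_zero(self):
        r = np.random.default_rng(17)
        x = r.integers(0, 4, 200)
        y = (x + r.integers(0, 2, 200)) % 4
        assert estimate_cmi(x, y, y, "plugin").value == pytest.approx(
            0.0, abs=1e-12)

    def test_mutual_independence_near_zero(self):
        r = np.random.default_rng(19)
        x, y, z = (r.integers(0, 3, 3000) for _ in range(3))
        assert estimate_cmi(x, y, z, "plugin").value < 0.01

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_chain_rule_identity_exact_for_plugin(self, seed):
        # I(x; (y,z)) = I(x; z) + I(x; y | z) holds exactly, with both
        # sides evaluated by the independent brute-force oracle
        r = np.random.default_rng(seed)
        x = r.integers(0, 4, 60)
        y = (x * 2) % 4  # deterministic function of x
        z = r.integers(0, 3, 60)
        cmi = estimate_cmi(x, y, z, "plugin").value
        lhs = brute_force_mi(x, list(zip(y, z)))
        rhs = brute_force_mi(x, z) + cmi
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_unknown_estimator_rejected(self):
        with pytest.raises(ConfigError):
            estimate_cmi(np.arange(4), np.arange(4), np.arange(4), "kde")


def test_estimate_mi_dispatch_unknown_id():
    with pytest.raises(ConfigError):
        estimate_mi(np.arange(4), np.arange(4), "parzen")


def test_bits_and_nats_conversion():
    x = np.array([0, 1] * 30)
    nats = estimate_mi_plugin(x, x).value
    bits = estimate_mi_plugin(x, x, base="bits").value
    assert nats == pytest.approx(bits * np.log(2.0), abs=1e-12)


def test_sample_vector_kind_inference():
    assert as_sample_vector(np.arange(4)).kind == "discrete"
    assert as_sample_vector(np.arange(4.0)).kind == "continuous"
    assert as_sample_vector(np.array(["a", "b", "a", "b"])).kind == "discrete"
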
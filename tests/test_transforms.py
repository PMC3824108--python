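"""Closure, filling value and the log-ratio transforms with exact inverses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import panbalance as pb
from panbalance.transforms import CLOSURE_RTOL

from conftest import random_sbp_codes


def direct_balances(values: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Independent oracle: each balance from its defining log-ratio of
    geometric means, sqrt(n+ n- / (n+ + n-)) * ln(g(c+) / g(c-))."""
    out = np.empty((values.shape[0], codes.shape[0]))
    for i, row in enumerate(codes):
        plus, minus = values[:, row == 1], values[:, row == -1]
        npl, nmi = plus.shape[1], minus.shape[1]
        gplus = np.exp(np.log(plus).mean(axis=1))
        gminus = np.exp(np.log(minus).mean(axis=1))
        out[:, i] = np.sqrt(npl * nmi / (npl + nmi)) * np.log(gplus / gminus)
    return out


class TestClosure:
    def test_uniform(self):
        c = pb.closure([[1, 1, 1, 1]], kappa=1.0)
        np.testing.assert_allclose(c.values, 0.25)

    def test_proportions_preserved(self):
        c = pb.closure([[2, 3, 5]], kappa=100.0)
        np.testing.assert_allclose(c.values, [[20, 30, 50]])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=(5, 4))
        once = pb.closure(x, kappa=1e6)
        twice = pb.closure(once.values, kappa=1e6)
        np.testing.assert_allclose(once.values, twice.values)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pb.closure([[1.0, 0.0, 2.0]])


class TestFillingValue:
    def test_complement_to_kappa(self):
        c = pb.add_filling_value([[1e5]], kappa=1e6, part_labels=["N"])
        assert c.part_labels == ("N", "Fv")
        np.testing.assert_allclose(c.values, [[1e5, 9e5]])

    def test_rows_close_exactly(self):
        rng = np.random.default_rng(1)
        nutrients = rng.lognormal(mean=7, size=(10, 5))
        c = pb.add_filling_value(nutrients, kappa=1e6)
        np.testing.assert_allclose(c.values.sum(axis=1), 1e6, rtol=CLOSURE_RTOL)

    def test_overfull_row_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            pb.add_filling_value([[6e5, 4e5]], kappa=1e6)

    def test_generated_tissue_has_dominant_fv(self, basis):
        comp, *_ = pb.generate_tissue(pb.GeneratorConfig(n=50, seed=3))
        fv = comp.values[:, comp.part_labels.index("Fv")]
        assert (fv > 0.5 * comp.kappa).all()  # consistent with the strongly
        # negative [Fv | nutrients] balance of foliar tissue


class TestClrAlr:
    def test_clr_uniform_is_zero(self):
        c = pb.closure([[5, 5, 5]], kappa=1.0)
        np.testing.assert_allclose(pb.clr(c), 0, atol=1e-12)

    def test_clr_hand_value(self):
        c = pb.closure([[np.e * 3.0, 3.0]], kappa=1.0)
        np.testing.assert_allclose(pb.clr(c), [[0.5, -0.5]], atol=1e-12)

    def test_clr_rows_sum_to_zero(self):
        rng = np.random.default_rng(2)
        c = pb.closure(rng.lognormal(size=(20, 7)))
        np.testing.assert_allclose(pb.clr(c).sum(axis=1), 0, atol=1e-10)

    def test_clr_invariant_to_kappa(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=(4, 5))
        np.testing.assert_allclose(
            pb.clr(pb.closure(x, kappa=1.0)), pb.clr(pb.closure(x, kappa=1e6)), atol=1e-10
        )

    def test_alr_hand_value(self):
        c = pb.closure([[2.0, 1.0]], kappa=1.0)
        np.testing.assert_allclose(pb.alr(c, "part_2"), [[np.log(2)]])

    def test_alr_unknown_denominator(self):
        c = pb.closure([[1.0, 1.0]])
        with pytest.raises(KeyError):
            pb.alr(c, "Fv")

    def test_alr_approaches_shifted_log_for_dominant_denominator(self):
        # with an overwhelming filling value, alr(x) ~ ln(x) - ln(Fv)
        nutrients = np.array([[10.0, 20.0, 5.0]])
        c = pb.add_filling_value(nutrients, kappa=1e9, part_labels=["a", "b", "c"])
        got = pb.alr(c, "Fv")
        expected = np.log(c.values[:, :3]) - np.log(c.values[:, [3]])
        np.testing.assert_allclose(got, expected, atol=1e-12)
        np.testing.assert_allclose(got, np.log(nutrients) - np.log(1e9), rtol=1e-4)


class TestIlr:
    def test_uniform_maps_to_origin(self, basis):
        c = pb.closure(np.ones((1, 12)), part_labels=basis.part_labels)
        np.testing.assert_allclose(pb.ilr(c, basis).values, 0, atol=1e-12)

    def test_two_part_hand_value(self):
        b = pb.build_basis(pb.validate_sbp([[1, -1]], ["a", "b"]))
        c = pb.closure([[np.e, 1.0]], kappa=1.0, part_labels=["a", "b"])
        np.testing.assert_allclose(pb.ilr(c, b).values, [[np.sqrt(0.5)]], atol=1e-12)

    def test_matrix_path_equals_direct_log_contrast(self, sbp, basis):
        rng = np.random.default_rng(4)
        comp, *_ = pb.generate_tissue(pb.GeneratorConfig(n=30, seed=4))
        got = pb.ilr(comp, basis).values
        np.testing.assert_allclose(got, direct_balances(comp.values, sbp.codes), atol=1e-10)

    def test_matches_reference_implementation(self, basis):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        comp, *_ = pb.generate_tissue(pb.GeneratorConfig(n=20, seed=5))
        ours = pb.ilr(comp, basis).values
        theirs = skbio_comp.ilr(skbio_comp.closure(comp.values), basis.psi)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_label_mismatch_rejected(self, basis):
        c = pb.closure(np.ones((1, 12)))
        with pytest.raises(ValueError, match="part labels"):
            pb.ilr(c, basis)

    def test_published_median_round_trip(self, basis, norms):
        comp = pb.ilr_inverse(norms.center, basis)
        z = pb.ilr(comp, basis)
        np.testing.assert_allclose(z.values[0], norms.center, atol=1e-10)

    def test_inverse_of_origin_is_uniform(self, basis):
        comp = pb.ilr_inverse(np.zeros(11), basis, kappa=12.0)
        np.testing.assert_allclose(comp.values, 1.0, atol=1e-12)

    def test_inverse_dimension_mismatch(self, basis):
        with pytest.raises(ValueError, match="ilr columns"):
            pb.ilr_inverse(np.zeros(5), basis)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(3, 10), st.integers(0, 2**31 - 1))
    def test_round_trip_under_random_sbp(self, d, seed):
        rng = np.random.default_rng(seed)
        labels = [f"p{i}" for i in range(d)]
        b = pb.build_basis(pb.validate_sbp(random_sbp_codes(d, rng), labels))
        z = rng.normal(scale=2.0, size=(3, d - 1))
        back = pb.ilr(pb.ilr_inverse(z, b), b)
        np.testing.assert_allclose(back.values, z, atol=1e-10)


class TestCompositionalProperties:
    def test_balances_without_fv_invariant_to_fv(self, basis):
        """Subcompositional coherence: perturbing Fv moves only Fv balances."""
        rng = np.random.default_rng(6)
        nutrients = rng.lognormal(mean=7, sigma=0.3, size=(5, 11))
        labels = [p for p in basis.part_labels if p != "Fv"]
        c1 = pb.add_filling_value(nutrients, part_labels=labels)
        # double the raw Fv, i.e. raise kappa for the same nutrients
        raw2 = c1.values.copy()
        raw2[:, -1] *= 2.0
        c2 = pb.closure(raw2, part_labels=c1.part_labels)
        z1, z2 = pb.ilr(c1, basis).values, pb.ilr(c2, basis).values
        touches_fv = basis.psi[:, list(basis.part_labels).index("Fv")] != 0
        np.testing.assert_allclose(z1[:, ~touches_fv], z2[:, ~touches_fv], atol=1e-10)
        assert np.abs(z1[:, touches_fv] - z2[:, touches_fv]).max() > 0.1

    def test_perturbation_moves_only_involved_balances(self, basis):
        rng = np.random.default_rng(7)
        comp, *_ = pb.generate_tissue(pb.GeneratorConfig(n=5, seed=7))
        raw = comp.values.copy()
        j = comp.part_labels.index("Mn")
        raw[:, j] *= 3.0
        c2 = pb.closure(raw, part_labels=comp.part_labels)
        z1, z2 = pb.ilr(comp, basis).values, pb.ilr(c2, basis).values
        involved = basis.psi[:, j] != 0
        np.testing.assert_allclose(z1[:, ~involved], z2[:, ~involved], atol=1e-10)
        assert np.abs(z1[:, involved] - z2[:, involved]).min() > 1e-3
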
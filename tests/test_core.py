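import math

import numpy as np
import pytest

from prism import (
    BinningModel,
    Element,
    OrderingModel,
    PrismError,
    ProbabilityModel,
    cospectrum_of,
    op_bin,
    op_freq,
    op_mean,
    op_model_fit,
    op_rank,
    op_sd,
    self_information,
    spectrum_of,
    tensor_representation,
    unobserved_self_information,
)


class TestScalarOperators:
    @pytest.mark.parametrize(
        "data, expected",
        [([1, 2, 3], 2.0), ([5], 5.0), ([-1, 1], 0.0)],
    )
    def test_mean_is_constant_vector(self, data, expected):
        out = op_mean(data)
        assert out.shape == (len(data),)
        assert np.allclose(out, expected)

    def test_mean_empty_dataset(self):
        with pytest.raises(PrismError, match="empty-dataset"):
            op_mean([])

    @pytest.mark.parametrize(
        "data, ddof, expected",
        [
            ([2, 2, 2], 0, 0.0),
            ([0, 2], 1, math.sqrt(2)),
            # frozen from the direct formula: sqrt(sum((x-mean)^2)/(n-1))
            ([1, 2, 3, 4], 1, 1.2909944487358056),
        ],
    )
    def test_sd_constant_vector(self, data, ddof, expected):
        out = op_sd(data, ddof=ddof)
        assert np.allclose(out, expected)

    def test_sd_insufficient_data(self):
        with pytest.raises(PrismError, match="insufficient-data"):
            op_sd([7], ddof=1)

    def test_rank_descending(self):
        om = OrderingModel("desc", descending=True)
        assert op_rank([5, 2, 9], om).tolist() == [2, 3, 1]

    def test_rank_tie_rules(self):
        om = OrderingModel("asc")
        data = [Element("a", 7), Element("b", 7)]
        assert op_rank(data, om, "ordinal-lexicographic").tolist() == [1, 2]
        assert op_rank(data, om, "average").tolist() == [1.5, 1.5]

    def test_bin_and_freq(self):
        bm = BinningModel.uniform("u", width=1.0)
        data = [0.1, 0.9, 1.1]
        assert op_bin(data, bm).tolist() == [0.5, 0.5, 1.5]
        assert op_freq(data, bm).tolist() == [2, 2, 1]

    def test_freq_counts_conserve_n(self, rng):
        bm = BinningModel.uniform("u", width=0.25)
        data = rng.normal(size=200).tolist()
        freq = op_freq(data, bm)
        bins = [bm.bin_of(x) for x in data]
        per_bin = {b: f for b, f in zip(bins, freq)}
        assert sum(per_bin.values()) == len(data)

    def test_model_fit_is_extension_point(self):
        with pytest.raises(PrismError, match="not-implemented"):
            op_model_fit([1, 2, 3])


class TestSelfInformation:
    def test_certainty_is_zero(self):
        m = ProbabilityModel("m", ["x"], [1.0], total_count=10)
        assert self_information(m, "x") == 0.0

    def test_uniform_4096(self, uniform_model_4096):
        h = self_information(uniform_model_4096, "ACGTAC")
        assert h == pytest.approx(math.log(4096), abs=1e-12)

    def test_empirical_counts(self):
        m = ProbabilityModel.from_counts("m", {"A": 2, "B": 1, "C": 1})
        assert self_information(m, "A") == pytest.approx(-math.log(0.5))

    def test_unobserved_pseudo_count(self):
        m = ProbabilityModel.from_counts("m", {"A": 2, "B": 1, "C": 1})
        assert m.unobserved("Z")
        assert self_information(m, "Z") == pytest.approx(
            -math.log(0.5 / 4.5)
        )
        # pseudo-count h exceeds every observed h and grows with sample size
        assert self_information(m, "Z") > self_information(m, "B")
        assert unobserved_self_information(100) > unobserved_self_information(10)

    def test_strictly_decreasing_in_p(self):
        ps = np.linspace(0.05, 1.0, 20)
        m = ProbabilityModel("m", list(range(20)), ps / ps.sum(), 100)
        hs = [self_information(m, b) for b in range(20)]
        assert all(a > b for a, b in zip(hs, hs[1:]))

    def test_probability_model_invariants(self):
        with pytest.raises(PrismError, match="unnormalised"):
            ProbabilityModel("m", ["a", "b"], [0.5, 0.6], 10)
        with pytest.raises(PrismError, match="duplicate-bins"):
            ProbabilityModel("m", ["a", "a"], [0.5, 0.5], 10)
        # unnormalised values are legitimate for windowed-depth models
        m = ProbabilityModel("m", ["a", "b"], [0.5, 0.9], 10, normalised=False)
        assert self_information(m, "b") == pytest.approx(-math.log(0.9))


class TestTensor:
    def test_degenerate_panel_equals_scalar_operator(self):
        m = ProbabilityModel.from_counts("m", {"x": 3, "y": 1})
        data = ["x", "y", "x"]
        t = tensor_representation(data, [m], ["info"])
        assert t.values.shape == (3, 1, 1)
        direct = [self_information(m, x) for x in data]
        assert np.allclose(t.values[:, 0, 0], direct)

    def test_rank_info_cospectrum_shape(self):
        om = OrderingModel("o")
        with pytest.raises(PrismError, match="operator-model-kind-mismatch"):
            tensor_representation([1, 2], [om], ["info"])
        m1 = ProbabilityModel.from_counts("m1", {1: 3, 2: 1})
        m2 = ProbabilityModel.from_counts("m2", {1: 1, 2: 3})
        t = tensor_representation([1, 2, 1], [m1, m2], ["info"])
        cs = cospectrum_of(t, "m2")
        assert cs.values.shape == (3, 1)

    def test_duality_is_transposition(self, random_info_tensor):
        t = random_info_tensor
        for i, e in enumerate(t.element_ids):
            for j, m in enumerate(t.model_ids):
                assert (
                    cospectrum_of(t, m).values[i, 0]
                    == spectrum_of(t, e).values[j, 0]
                )

    def test_views_are_zero_copy(self, random_info_tensor):
        t = random_info_tensor
        s = spectrum_of(t, t.element_ids[0])
        t.values[0, 0, 0] = 123.0
        assert s.values[0, 0] == 123.0

    def test_unknown_id(self, random_info_tensor):
        with pytest.raises(PrismError, match="unknown-id"):
            spectrum_of(random_info_tensor, "nope")

    def test_subset_models_gives_subspectra(self, random_info_tensor):
        t = random_info_tensor
        sub = t.subset_models(t.model_ids[:2])
        s_full = spectrum_of(t, t.element_ids[3]).values[:2]
        s_sub = spectrum_of(sub, t.element_ids[3]).values
        assert np.array_equal(s_full, s_sub)
        assert s_sub.shape == (2, 1)

    def test_brute_force_loop_oracle(self, rng):
        """Tensor cells equal an element-by-element loop over operators."""
        data = [Element(f"e{i}", float(v)) for i, v in
                enumerate(rng.integers(0, 50, size=12))]
        om = OrderingModel("o")
        bm = BinningModel.uniform("b", width=10.0)
        t = tensor_representation(data, [om], ["mean", "sd", "rank"])
        assert np.allclose(t.values[:, 0, 0], op_mean(data))
        assert np.allclose(t.values[:, 0, 1], op_sd(data))
        assert np.allclose(t.values[:, 0, 2], op_rank(data, om))
        t2 = tensor_representation(data, [bm], ["bin", "freq"])
        assert np.allclose(t2.values[:, 0, 0], op_bin(data, bm))
        assert np.allclose(t2.values[:, 0, 1], op_freq(data, bm))

    def test_tsv_roundtrip(self, tmp_path, random_info_tensor):
        t = random_info_tensor
        t.flags.add((t.element_ids[2], t.model_ids[1]))
        t.to_dir(tmp_path / "tensor")
        back = type(t).from_dir(tmp_path / "tensor")
        assert back.element_ids == t.element_ids
        assert back.model_ids == t.model_ids
        assert np.allclose(back.values, t.values)
        assert (t.element_ids[2], t.model_ids[1]) in back.flags
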
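import math

import numpy as np
import pandas as pd
import pytest

from tenttail import io, simulate
from tenttail.simulate import ContaminantModel, TailModel, TitrationDesign
from tenttail.tailcall import AdapterSpec, SubstrateSpec

from _oracles import brute_force_composition


def cc_model():
    return TailModel(
        length_probs={2: 1.0},
        base_probs_by_start_position=[{"A": 1.0}, {"A": 1.0}],
        terminal_override={1: {"C": 1.0}, 2: {"C": 1.0}},
    )


class TestSampleTail:
    def test_fully_deterministic_model_yields_cc(self, rng):
        model = cc_model()
        assert all(simulate.sample_tail(model, rng) == "CC" for _ in range(20))

    def test_zero_length_model_yields_empty(self, rng):
        model = TailModel(length_probs={0: 1.0}, base_probs_by_start_position=[])
        assert simulate.sample_tail(model, rng) == ""

    def test_base_fraction_within_binomial_bound(self):
        model = TailModel(
            length_probs={1: 1.0},
            base_probs_by_start_position=[{"A": 0.5, "C": 0.5}],
        )
        rng = np.random.default_rng(42)
        n = 10_000
        frac_c = sum(simulate.sample_tail(model, rng) == "C" for _ in range(n)) / n
        assert abs(frac_c - 0.5) <= 3 * math.sqrt(0.25 / n)

    def test_length_distribution_within_binomial_se(self, tail_model):
        rng = np.random.default_rng(7)
        n = 10_000
        lengths = np.array([len(simulate.sample_tail(tail_model, rng)) for _ in range(n)])
        for length, p in tail_model.length_probs.items():
            obs = np.mean(lengths == length)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) <= 4 * se, f"length {length}: {obs} vs {p}"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(length_probs={1: 0.5}, base_probs_by_start_position=[{"A": 1.0}]),
            dict(length_probs={1: 1.0}, base_probs_by_start_position=[{"A": 0.9, "C": 0.2}]),
            dict(length_probs={-1: 1.0}, base_probs_by_start_position=[{"A": 1.0}]),
            dict(length_probs={1: 1.0}, base_probs_by_start_position=[{"A": 0.5, "X": 0.5}]),
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TailModel(**kwargs)


class TestSimulateReads:
    def test_clean_reads_have_expected_layout(self, substrate, adapter, tail_model):
        reads, truth = simulate.simulate_reads(substrate, adapter, tail_model, 100, seed=3)
        assert len(reads) == 100
        assert set(truth["class"]) == {"clean"}
        for read, (_, row) in zip(reads, truth.iterrows()):
            assert read.sequence.startswith(substrate.prefix)
            assert read.sequence.endswith(adapter.sequence)
            expected = (
                substrate.full_sequence + row["true_tail"] + adapter.sequence
            )
            assert read.sequence == expected

    @pytest.mark.parametrize(
        "contaminants, n, expected",
        [
            (ContaminantModel(fraction_no_adapter=0.1), 1000,
             {"no_adapter": 100, "clean": 900}),
            (ContaminantModel(0.04, 0.03, 0.02, 0.01), 10_000,
             {"no_prefix": 400, "no_adapter": 300, "long_insert": 200, "junk": 100, "clean": 9000}),
        ],
    )
    def test_exact_contaminant_allocation(self, substrate, adapter, tail_model, contaminants, n, expected):
        _, truth = simulate.simulate_reads(substrate, adapter, tail_model, n, contaminants, seed=5)
        assert truth["class"].value_counts().to_dict() == expected

    def test_same_seed_gives_byte_identical_fastq(self, substrate, adapter, tail_model, tmp_path):
        paths = []
        for i in range(2):
            reads, _ = simulate.simulate_reads(
                substrate, adapter, tail_model, 500, simulate.default_contaminants(), seed=11
            )
            p = tmp_path / f"run{i}.fastq"
            io.write_fastq(reads, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_truth_lengths_match_tails(self, substrate, adapter, tail_model):
        _, truth = simulate.simulate_reads(substrate, adapter, tail_model, 200, seed=1)
        assert (truth["true_tail"].str.len() == truth["true_length"]).all()

    def test_invalid_inputs(self, substrate, adapter, tail_model):
        with pytest.raises(ValueError):
            simulate.simulate_reads(substrate, adapter, tail_model, 0)
        with pytest.raises(ValueError):
            ContaminantModel(0.5, 0.4, 0.2, 0.0)
        with pytest.raises(ValueError):
            ContaminantModel(long_insert_length=80)


class TestExpectedComposition:
    def test_deterministic_cc_model(self):
        ec = simulate.expected_composition(cc_model())
        assert ec.per_position.loc[1, "C"] == 1.0
        assert ec.per_position.loc[2, "C"] == 1.0
        assert ec.coverage[1] == 1.0 and ec.coverage[2] == 1.0

    def test_coverage_is_tail_survival_function(self):
        model = TailModel(
            length_probs={1: 0.9, 2: 0.1},
            base_probs_by_start_position=[{"A": 1.0}, {"A": 1.0}],
        )
        ec = simulate.expected_composition(model)
        assert ec.coverage[1] == pytest.approx(1.0)
        assert ec.coverage[2] == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        lmax = int(rng.integers(2, 5))
        raw = rng.dirichlet(np.ones(lmax + 1))
        length_probs = {l: float(p) for l, p in enumerate(raw)}
        base_probs = [
            dict(zip("ACGT", map(float, rng.dirichlet(np.ones(4))))) for _ in range(lmax)
        ]
        override = {1: dict(zip("ACGT", map(float, rng.dirichlet(np.ones(4)))))}
        model = TailModel(length_probs, base_probs, override)
        ec = simulate.expected_composition(model)
        freq_bf, cov_bf, overall_bf = brute_force_composition(model)
        pd.testing.assert_frame_equal(ec.per_position, freq_bf, atol=1e-12, check_index_type=False)
        assert np.allclose(ec.coverage.values, cov_bf.values, atol=1e-12)
        for b in "ACGU":
            assert ec.overall[b] == pytest.approx(overall_bf[b], abs=1e-12)


class TestTitrationSimulators:
    def test_saturation_identities_noiseless(self):
        design = simulate.saturation_design(kd=250.0, noise_sd=0.0)
        data = simulate.simulate_saturation(design)
        truth = design.truth
        by_conc = {m.concentration_nm: m.anisotropy for m in data}
        # half-saturation identity at [P] = K_d (add the point explicitly)
        design2 = TitrationDesign(
            "saturation", (0.0, 250.0, 3000.0), 1, 0.0, truth, seed=0
        )
        d2 = {m.concentration_nm: m.anisotropy for m in simulate.simulate_saturation(design2)}
        assert d2[0.0] == pytest.approx(truth["a_free"])
        assert d2[250.0] == pytest.approx((truth["a_free"] + truth["a_max"]) / 2)
        assert min(by_conc) > 0  # standard design titrates 5-3000 nM

    def test_competition_identities_noiseless(self):
        truth = {"ic50": 500.0, "a_free": 0.1, "a_bound": 0.2}
        design = TitrationDesign("competition", (0.0, 500.0, 5e5), 2, 0.0, truth, seed=0)
        data = simulate.simulate_competition(design)
        for m in data:
            if m.concentration_nm == 0.0:
                assert m.anisotropy == pytest.approx(0.2)
            if m.concentration_nm == 500.0:
                assert m.anisotropy == pytest.approx(0.15)
        assert {m.experiment_id for m in data} == {"exp1", "exp2"}

    def test_same_seed_identical_tables(self):
        design = simulate.competition_design(562.0, noise_sd=0.002, seed=9)
        a = simulate.simulate_competition(design)
        b = simulate.simulate_competition(design)
        assert a == b

    @pytest.mark.parametrize(
        "mode, truth",
        [
            ("saturation", {"kd": -5.0, "a_free": 0.1, "a_max": 0.2}),
            ("competition", {"ic50": 0.0, "a_free": 0.1, "a_bound": 0.2}),
        ],
    )
    def test_invalid_truth_rejected(self, mode, truth):
        with pytest.raises(ValueError):
            TitrationDesign(mode, (1.0, 10.0), 1, 0.0, truth)

    def test_design_needs_two_distinct_concentrations(self):
        with pytest.raises(ValueError):
            TitrationDesign(
                "saturation", (5.0, 5.0), 1, 0.0, {"kd": 1.0, "a_free": 0, "a_max": 1}
            )
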
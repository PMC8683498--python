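"""Synthetic-data generator: scenario validation, read sampling, packaged
tables, dose-response construction, determinism."""

import numpy as np
import pytest
from pydantic import ValidationError

import clonedyn as cd
from clonedyn.errors import InputError
from clonedyn.synthetic import mutation_catalog


class TestScenarios:
    def test_single_clone_degenerate(self):
        sc = cd.build_scenario("single_clone")
        assert len(sc.clones) == 1
        assert sc.clones[0].per_sample_ccf == {"s1": 1.0}

    def test_p04_like_structure(self, p04_scenario):
        sc = p04_scenario
        assert len(sc.clones) == 5 and len(sc.samples) == 3
        by_id = {c.clone_id: c for c in sc.clones}
        assert by_id["C3"].parent_id == "C1"
        assert by_id["C4"].parent_id == "C2"
        assert by_id["C1"].per_sample_ccf["peritoneal"] == 1.0
        assert by_id["C3"].per_sample_ccf["peritoneal"] == 0.4
        assert all(c.n_private_mutations == 150 for c in sc.clones)
        assert all(s.purity == 0.7 and s.mean_depth == 150 for s in sc.samples)

    def test_unknown_scenario_name(self):
        with pytest.raises(InputError):
            cd.build_scenario("nope")

    def test_sum_rule_violation_rejected(self):
        with pytest.raises(ValidationError, match="sum rule"):
            cd.Scenario(
                clones=[
                    cd.CloneSpec(clone_id="C0", parent_id=None,
                                 per_sample_ccf={"s": 0.5}),
                    cd.CloneSpec(clone_id="C1", parent_id="C0",
                                 per_sample_ccf={"s": 0.8}),
                ],
                samples=[cd.SampleSpec(sample_id="s", purity=0.7, mean_depth=100)],
            )

    def test_sibling_overflow_rejected(self):
        with pytest.raises(ValidationError, match="sum rule"):
            cd.Scenario(
                clones=[
                    cd.CloneSpec(clone_id="C0", parent_id=None, per_sample_ccf={"s": 1.0}),
                    cd.CloneSpec(clone_id="C1", parent_id="C0", per_sample_ccf={"s": 0.6}),
                    cd.CloneSpec(clone_id="C2", parent_id="C0", per_sample_ccf={"s": 0.6}),
                ],
                samples=[cd.SampleSpec(sample_id="s", purity=0.7, mean_depth=100)],
            )

    def test_two_roots_rejected(self):
        with pytest.raises(ValidationError, match="root"):
            cd.Scenario(
                clones=[
                    cd.CloneSpec(clone_id="C0", parent_id=None, per_sample_ccf={"s": 1.0}),
                    cd.CloneSpec(clone_id="C1", parent_id=None, per_sample_ccf={"s": 1.0}),
                ],
                samples=[cd.SampleSpec(sample_id="s", purity=0.7, mean_depth=100)],
            )

    def test_yaml_round_trip(self, p04_scenario, tmp_path):
        path = tmp_path / "scenario.yaml"
        p04_scenario.to_yaml(path)
        again = cd.Scenario.from_yaml(path)
        assert again == p04_scenario
        assert cd.build_scenario(str(path)) == p04_scenario

    def test_random_scenarios_validate(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sc = cd.random_scenario(rng)  # Scenario() validates the sum rule
            assert len(sc.clones) == 6


class TestExpectedVaf:
    def test_diploid_clonal_limit(self):
        assert cd.expected_vaf(1.0, 1.0, 2, 1) == pytest.approx(0.5)

    def test_purity_cn_multiplicity(self):
        assert cd.expected_vaf(0.5, 0.7, 3, 2) == pytest.approx(0.7 / 2.7)


class TestSimulateBiopsy:
    def test_mean_vaf_matches_expectation(self):
        sc = cd.Scenario(
            clones=[cd.CloneSpec(clone_id="C0", parent_id=None,
                                 n_private_mutations=10_000,
                                 per_sample_ccf={"s": 0.5})],
            samples=[cd.SampleSpec(sample_id="s", purity=0.7, mean_depth=150,
                                   cn_profile=[("1", 1, 20_000_000, 2)])],
        )
        calls, _ = cd.simulate_biopsy(sc, "s", seed=11)
        expected = cd.expected_vaf(0.5, 0.7, 2, 1)
        vafs = np.array([c.alt_reads / c.total_reads for c in calls if c.total_reads])
        se = np.sqrt(expected * (1 - expected) / (len(vafs) * 150))
        assert abs(vafs.mean() - expected) < 3 * se

    def test_absent_mutations_emitted_with_zero_alt(self, p04_scenario):
        calls, _ = cd.simulate_biopsy(p04_scenario, "liver1", seed=3)
        by_clone = {e["pos"]: e["clone_id"] for e in mutation_catalog(p04_scenario)}
        absent = [c for c in calls if by_clone[c.pos] in ("C1", "C3", "C4")]
        assert len(absent) == 450
        assert all(c.alt_reads == 0 for c in absent)
        assert np.mean([c.total_reads for c in absent]) > 100  # still covered

    def test_fixed_seed_reproduces_identical_calls(self, p04_scenario):
        a, _ = cd.simulate_biopsy(p04_scenario, "peritoneal", seed=5)
        b, _ = cd.simulate_biopsy(p04_scenario, "peritoneal", seed=5)
        assert a == b
        c, _ = cd.simulate_biopsy(p04_scenario, "peritoneal", seed=6)
        assert a != c

    def test_error_shrinks_with_depth(self):
        """Empirical VAF converges to the closed form as depth grows."""
        errs = []
        for depth in (50, 5000):
            sc = cd.Scenario(
                clones=[cd.CloneSpec(clone_id="C0", parent_id=None,
                                     n_private_mutations=500,
                                     per_sample_ccf={"s": 0.8})],
                samples=[cd.SampleSpec(sample_id="s", purity=0.7, mean_depth=depth,
                                       cn_profile=[("1", 1, 10_000_000, 2)])],
            )
            calls, _ = cd.simulate_biopsy(sc, "s", seed=2)
            expected = cd.expected_vaf(0.8, 0.7, 2, 1)
            vafs = np.array([c.alt_reads / c.total_reads for c in calls if c.total_reads])
            errs.append(np.mean(np.abs(vafs - expected)))
        assert errs[1] < errs[0] / 5  # ~ sqrt(100) = 10x expected


class TestPackagedSurvivalTable:
    def test_contents(self):
        table = cd.packaged_survival_table()
        assert len(table) == 6
        by_id = {r.patient_id: r for r in table}
        assert by_id["P12"].time == 101 and by_id["P12"].event
        assert by_id["P01"].time == 636 and not by_id["P01"].event


class TestSimulateDoseResponse:
    def test_noiseless_null_is_exactly_bliss(self):
        m = cd.simulate_dose_response(delta_true=0.0, noise_sd=0.0)
        inh = 1 - m.viability
        ya = inh[0, :]  # monotherapy A row
        yb = inh[:, 0]
        bliss = ya[None, :] + yb[:, None] - ya[None, :] * yb[:, None]
        np.testing.assert_allclose(inh, bliss, atol=1e-12)

    def test_inert_drugs_give_constant_plate(self):
        m = cd.simulate_dose_response(emax_a=0.0, emax_b=0.0, noise_sd=0.0)
        np.testing.assert_allclose(m.viability, 1.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(InputError):
            cd.simulate_dose_response(noise_sd=-0.1)

    def test_grid_shape_and_normalization(self):
        m = cd.simulate_dose_response(noise_sd=0.05, seed=3)
        assert m.viability.shape == (6, 6)
        assert m.conc_a[0] == 0 and m.conc_b[0] == 0
        assert m.viability[0, 0] == 1.0
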
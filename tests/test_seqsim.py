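"""Simulator contracts: rates, selection, determinism, ground truth."""

import numpy as np
import pytest
from scipy import stats

from numtclock.alignment import genetic_code
from numtclock.io import fasta_string
from numtclock.seqsim import (
    ScenarioSpec,
    SubstitutionEngine,
    evolve_sequence,
    expected_syn_fraction,
    introgression_scenario,
    null_scenario,
    ps5_scenario,
    simulate_scenario,
    synthetic_ne_points,
)


def small_spec(**kw):
    kw.setdefault("sequence_length", 900)
    return ScenarioSpec(**kw)


class TestEvolveSequence:
    def test_zero_duration_is_identity(self):
        spec = small_spec(seed=0)
        seq = "ACGT" * 225
        out, events = evolve_sequence(seq, 0.0, "functional", spec, 1)
        assert out == seq
        assert events == []

    def test_bad_inputs_error(self):
        spec = small_spec()
        seq = "A" * 900
        with pytest.raises(ValueError, match="non-ACGT"):
            evolve_sequence("N" * 900, 1.0, "functional", spec, 1)
        with pytest.raises(ValueError, match="duration"):
            evolve_sequence(seq, -1.0, "functional", spec, 1)
        with pytest.raises(ValueError, match="length"):
            evolve_sequence("ACGT", 1.0, "functional", spec, 1)

    def test_neutral_noncoding_matches_jukes_cantor(self):
        # JC closed form as oracle: expected p = 3/4 (1 - e^(-4d/3))
        L, d = 10000, 0.045
        spec = ScenarioSpec(
            sequence_length=L, coding_map=(), omega=1.0, kappa=1.0,
            mito_rate=0.01,
        )
        eng = SubstitutionEngine(spec)
        rng = np.random.default_rng(42)
        s0 = eng.random_sequence(rng)
        s1, _ = eng.evolve(s0, d / spec.mito_rate, "functional", rng)
        p_obs = float(np.mean(s0 != s1))
        p_exp = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        assert abs(p_obs - p_exp) < 3.0 * np.sqrt(p_exp * (1 - p_exp) / L)

    def test_omega_zero_rejects_every_nonsynonymous_proposal(self):
        spec = small_spec(omega=0.0, seed=5)
        eng = SubstitutionEngine(spec)
        rng = np.random.default_rng(5)
        s0 = eng.random_sequence(rng)
        _, events = eng.evolve(s0, 5.0, "functional", rng)
        assert events  # substitutions do occur
        assert all(e.klass != "non_synonymous" for e in events)

    def test_realized_counts_are_poisson(self):
        # chi-square GOF of per-run event counts against Poisson(L*rate*T)
        L, rate, T, n_runs = 1000, 0.01, 5.0, 60
        lam = L * rate * T
        spec = ScenarioSpec(
            sequence_length=L, coding_map=(), omega=1.0, mito_rate=rate
        )
        eng = SubstitutionEngine(spec)
        counts = []
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            s0 = eng.random_sequence(rng)
            _, ev = eng.evolve(s0, T, "functional", rng)
            counts.append(len(ev))
        edges = [0, lam - 10, lam - 4, lam, lam + 4, lam + 10, np.inf]
        obs, _ = np.histogram(counts, bins=edges)
        cdf = stats.poisson(lam).cdf
        probs = np.diff([0] + [cdf(e - 0.5) for e in edges[1:-1]] + [1])
        _, p = stats.chisquare(obs, probs * n_runs)
        assert p > 0.01

    def test_poisson_rate_holds_under_selection(self):
        # rate normalization: omega reshapes, never thins, the process
        L, rate, T = 3000, 0.01, 4.0
        spec = ScenarioSpec(sequence_length=L, omega=0.1, mito_rate=rate)
        eng = SubstitutionEngine(spec)
        total = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(2000 + seed)
            _, ev = eng.evolve(
                eng.random_sequence(rng), T, "functional", rng
            )
            total += len(ev)
        lam = n_runs * L * rate * T
        assert abs(total - lam) < 4.0 * np.sqrt(lam)


class TestSelectionContrast:
    def test_neutral_syn_fraction_matches_enumeration(self):
        spec = ScenarioSpec(sequence_length=9000, omega=1.0, kappa=4.0)
        eng = SubstitutionEngine(spec)
        rng = np.random.default_rng(7)
        _, events = eng.evolve(
            eng.random_sequence(rng), 3.0, "functional", rng
        )
        syn = sum(1 for e in events if e.klass == "synonymous")
        f_exp = expected_syn_fraction(spec.coding_map, kappa=4.0)
        n = len(events)
        assert abs(syn / n - f_exp) < 3.0 * np.sqrt(f_exp * (1 - f_exp) / n)

    def test_selection_enriches_synonymous_fraction(self):
        # stochastic monotonicity: omega < 1 raises the syn fraction
        wins = 0
        for seed in range(50):
            fracs = []
            for omega in (1.0, 0.1):
                spec = ScenarioSpec(
                    sequence_length=600, omega=omega, seed=seed
                )
                eng = SubstitutionEngine(spec)
                rng = np.random.default_rng(3000 + seed)
                _, ev = eng.evolve(
                    eng.random_sequence(rng), 3.0, "functional", rng
                )
                syn = sum(1 for e in ev if e.klass == "synonymous")
                fracs.append(syn / max(1, len(ev)))
            if fracs[1] > fracs[0]:
                wins += 1
        assert wins >= 45


class TestExpectedSynFraction:
    def test_brute_force_enumeration_oracle(self):
        # independent 64 x 9 enumeration with plain dictionaries
        code = genetic_code(2)
        kappa = 3.0
        syn = tot = 0.0
        for codon, aa in code.items():
            for pos in range(3):
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    w = (
                        kappa
                        if {b, codon[pos]} in ({"A", "G"}, {"C", "T"})
                        else 1.0
                    )
                    tot += w
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if code[alt] == aa:
                        syn += w
        expected = syn / tot
        got = expected_syn_fraction(((0, 900, 0, 2),), kappa=kappa)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_fully_noncoding_map_not_applicable(self):
        with pytest.raises(ValueError, match="not applicable"):
            expected_syn_fraction(())

    def test_codes_differ_on_tga(self):
        # TGA is Trp under the mitochondrial code but stop under the
        # standard code, so the two syn fractions must differ
        assert expected_syn_fraction(
            ((0, 900, 0, 2),), kappa=1.0
        ) != expected_syn_fraction(((0, 900, 0, 1),), kappa=1.0)

    def test_unknown_code_errors(self):
        with pytest.raises(ValueError, match="genetic code"):
            expected_syn_fraction(((0, 900, 0, 999),))


class TestScenarioSpec:
    @pytest.mark.parametrize(
        "kw, msg",
        [
            (dict(ghost_split_time=5.0, insertion_time=9.5), "ghost_split"),
            (dict(insertion_time=9.0, transfer_time=9.3), "insertion_time"),
            (dict(transfer_time=-1.0, insertion_time=0.5,
                  ghost_split_time=1.0), "transfer_time"),
            (dict(omega=1.5), "omega"),
            (dict(sequence_length=0), "sequence_length"),
            (dict(mode="bogus"), "mode"),
        ],
    )
    def test_invalid_specs_name_the_violation(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            ScenarioSpec(**kw)

    def test_flat_config_round_trip(self):
        spec = introgression_scenario(seed=9, sequence_length=1200)
        again = ScenarioSpec.from_dict(
            {k: str(v) for k, v in spec.to_dict().items()}
        )
        assert again == spec


class TestSimulateScenario:
    def test_identical_seed_gives_identical_fasta_bytes(self):
        spec = ps5_scenario(seed=11, sequence_length=1500)
        a = simulate_scenario(spec)
        b = simulate_scenario(spec)
        assert fasta_string(a[0]) == fasta_string(b[0])
        assert fasta_string(a[1]) == fasta_string(b[1])
        assert a[2].to_json() == b[2].to_json()

    def test_true_stem_divergence_is_rate_times_span(self):
        for spec in (
            ps5_scenario(sequence_length=300),
            introgression_scenario(sequence_length=300, mito_rate=0.02),
        ):
            _, _, truth = simulate_scenario(spec)
            assert truth.true_stem_divergence == pytest.approx(
                spec.mito_rate
                * (spec.ghost_split_time - spec.insertion_time)
            )

    def test_null_mode_has_no_stem(self):
        _, _, truth = simulate_scenario(
            null_scenario(seed=2, sequence_length=600)
        )
        assert truth.true_stem_divergence == 0.0
        assert truth.stem_counts() is None

    def test_branch_counts_sum_to_total_mutations(self):
        _, _, truth = simulate_scenario(ps5_scenario(sequence_length=1500))
        total = sum(len(v) for v in truth.mutations.values())
        assert sum(truth.total_counts().values()) == total

    def test_clade_composition_by_mode(self):
        mt, numt, _ = simulate_scenario(ps5_scenario(sequence_length=300))
        assert set(numt.ids) == {
            "Human_numt", "Chimp_numt", "Bonobo_numt", "Gorilla_numt"
        }
        mt2, numt2, _ = simulate_scenario(
            introgression_scenario(sequence_length=300)
        )
        # HC-introgression: the NUMT arises in the Homo/Pan clade only
        assert set(numt2.ids) == {"Human_numt", "Chimp_numt", "Bonobo_numt"}
        assert set(mt.ids) == set(mt2.ids)

    def test_realized_tree_lengths_count_events(self):
        spec = ps5_scenario(seed=4, sequence_length=1200)
        _, _, truth = simulate_scenario(spec)
        for name, muts in truth.mutations.items():
            node = truth.true_tree.find(name)
            assert node.length == pytest.approx(
                len(muts) / spec.sequence_length
            )


def test_synthetic_ne_table_shape_and_determinism():
    df = synthetic_ne_points(5)
    assert list(df.columns) == ["taxon", "ne_nuc", "max_mtdna_divergence"]
    assert (df.ne_nuc > 0).all() and (df.max_mtdna_divergence >= 0).all()
    assert df.equals(synthetic_ne_points(5))
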
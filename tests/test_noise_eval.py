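import numpy as np
import pytest

from wboot import (
    Alphabet,
    ConsistencyError,
    NoiseSpec,
    add_combined_noise,
    add_indel_noise,
    add_substitution_noise,
    ls_bootstrap_deviation,
    noise_sweep,
    simulate_alignment,
    stream,
    table_from_scores,
)
from wboot.noise_eval import _indel_noise_with_audit


class TestSubstitutionNoise:
    def test_zero_rate_identity(self, primate_like):
        _, aln = primate_like
        assert add_substitution_noise(aln, 0.0, stream(1, "noise", 0)) == aln

    def test_full_rate_changes_everything(self):
        _, aln = simulate_alignment(4, 200, Alphabet.DNA, seed=1)
        noisy = add_substitution_noise(aln, 1.0, stream(1, "noise", 0))
        assert not np.any(aln.encoded() == noisy.encoded())

    def test_gaps_untouched(self):
        from wboot import Alignment

        aln = Alignment(("A", "B"), ("AC-T", "A--T"), Alphabet.DNA)
        noisy = add_substitution_noise(aln, 1.0, stream(2, "noise", 0))
        assert noisy.rows[0][2] == "-"
        assert noisy.rows[1][1:3] == "--"

    def test_changed_fraction_matches_rate(self):
        """Observed change fraction ~ NR within 3 binomial s.e."""
        _, aln = simulate_alignment(10, 10_000, Alphabet.DNA, seed=3)
        noisy = add_substitution_noise(aln, 0.1, stream(3, "noise", 0))
        frac = float((aln.encoded() != noisy.encoded()).mean())
        se = np.sqrt(0.1 * 0.9 / (aln.n * aln.l))
        assert abs(frac - 0.1) < 3 * se


class TestIndelNoise:
    def test_zero_rate_identity(self, primate_like):
        _, aln = primate_like
        assert add_indel_noise(aln, 0.0, stream(1, "noise", 0)) == aln

    def test_rectangular_output(self):
        _, aln = simulate_alignment(6, 300, Alphabet.DNA, seed=4)
        for nr in (0.02, 0.1, 0.3):
            noisy = add_indel_noise(aln, nr, stream(5, "noise", 0))
            assert len({len(r) for r in noisy.rows}) == 1

    def test_budget_accounting(self):
        _, aln = simulate_alignment(6, 300, Alphabet.DNA, seed=4)
        noisy, affected, events = _indel_noise_with_audit(
            aln, 0.1, stream(6, "noise", 0)
        )
        budget = int(np.ceil(aln.n * aln.l * 0.1))
        assert affected == budget  # last block truncated to fit exactly
        assert len(events) >= 1
        # block sizes bounded by the n*l*NR/2 .. /10 rule (up to truncation)
        hi = int(np.ceil(aln.n * aln.l * 0.1 / 2))
        assert all(size <= hi for _, _, _, size in events)

    def test_eliminations_add_gaps_insertions_grow_length(self):
        _, aln = simulate_alignment(6, 300, Alphabet.DNA, seed=4)
        noisy, _, events = _indel_noise_with_audit(aln, 0.2, stream(7, "noise", 0))
        kinds = {k for k, *_ in events}
        inserted = sum(s for k, _, _, s in events if k == "ins")
        assert noisy.l == aln.l + inserted
        if "elim" in kinds:
            assert any("-" in r for r in noisy.rows)


class TestCombinedNoise:
    def test_fifty_fifty_mix(self):
        """Strategy-1 frequency over many seeded draws ~ 0.5 within 3 s.e."""
        _, aln = simulate_alignment(4, 100, Alphabet.DNA, seed=8)
        n_subst = 0
        trials = 400
        for r in range(trials):
            noisy = add_combined_noise(aln, 0.05, stream(9, "noise", r))
            if noisy.l == aln.l:  # substitution noise never changes length
                n_subst += 1
        se = np.sqrt(0.25 / trials)
        assert abs(n_subst / trials - 0.5) < 3 * se

    def test_zero_rate_identity_and_reproducibility(self, primate_like):
        _, aln = primate_like
        assert add_combined_noise(aln, 0.0, stream(1, "noise", 0)) == aln
        a = add_combined_noise(aln, 0.1, stream(2, "noise", 0))
        b = add_combined_noise(aln, 0.1, stream(2, "noise", 0))
        assert a == b


class TestNoiseSpec:
    def test_rate_validated(self):
        with pytest.raises(Exception):
            NoiseSpec(rate=1.5)
        with pytest.raises(Exception):
            NoiseSpec(rate=0.1, strategy="bogus")


class TestLsBd:
    def test_identical_tables_zero(self):
        t = table_from_scores([90.0, 80.0], "std")
        assert ls_bootstrap_deviation(t, t) == 0.0

    def test_direct_sum(self):
        a = table_from_scores([100.0, 50.0], "std")
        b = table_from_scores([90.0, 40.0], "std")
        assert ls_bootstrap_deviation(a, b) == pytest.approx(200.0)

    def test_symmetric_and_nonnegative(self, rng):
        x = table_from_scores(rng.uniform(0, 100, 9), "std")
        y = table_from_scores(rng.uniform(0, 100, 9), "std")
        assert ls_bootstrap_deviation(x, y) == ls_bootstrap_deviation(y, x)
        assert ls_bootstrap_deviation(x, y) >= 0

    def test_split_mismatch(self):
        a = table_from_scores([1.0], "std", splits=("x",))
        b = table_from_scores([1.0], "std", splits=("y",))
        with pytest.raises(ConsistencyError):
            ls_bootstrap_deviation(a, b)


class TestNoiseSweep:
    def test_level_zero_is_exactly_baseline(self):
        _, aln = simulate_alignment(6, 250, Alphabet.DNA, seed=10)
        curve = noise_sweep(
            aln, [0.0, 0.05], strategies=("std",), N=10, repeats=2, seed=3
        )
        at_zero = curve[curve["noise"] == 0.0]
        assert np.allclose(at_zero["ls_bd"], 0.0)

    def test_one_row_per_level_and_strategy(self):
        _, aln = simulate_alignment(6, 250, Alphabet.DNA, seed=10)
        curve = noise_sweep(
            aln, [0.02, 0.05], strategies=("std", "ls"), N=8, repeats=1, seed=3
        )
        assert len(curve) == 4
        assert set(curve["strategy"]) == {"std", "ls"}

    def test_levels_must_increase(self):
        _, aln = simulate_alignment(6, 100, Alphabet.DNA, seed=10)
        with pytest.raises(Exception):
            noise_sweep(aln, [0.1, 0.05], strategies=("std",), N=5, seed=1)


class TestSimulateAlignment:
    def test_seeded_determinism(self):
        t1, a1 = simulate_alignment(6, 100, Alphabet.DNA, seed=5)
        t2, a2 = simulate_alignment(6, 100, Alphabet.DNA, seed=5)
        assert a1 == a2
        assert t1.edges == t2.edges

    def test_dimensions_and_alphabet(self):
        tree, aln = simulate_alignment(7, 123, Alphabet.PROTEIN, seed=6)
        assert (aln.n, aln.l) == (7, 123)
        assert aln.alphabet is Alphabet.PROTEIN
        assert tree.n == 7

    def test_nj_recovers_true_topology_at_long_length(self):
        """Distance + NJ consistency: long sequences recover the tree."""
        from wboot import jc69_distance, neighbor_joining, nontrivial_splits

        hits = 0
        for seed in range(10):
            tree, aln = simulate_alignment(6, 20_000, Alphabet.DNA, seed=seed)
            nj = neighbor_joining(jc69_distance(aln))
            hits += nontrivial_splits(nj) == nontrivial_splits(tree)
        assert hits == 10

    def test_mean_distance_matches_path_length(self):
        from wboot import Phylogeny, jc69_distance

        tree = Phylogeny(
            ("a", "b", "c", "d"),
            ((4, 0, 0.1), (4, 1, 0.15), (4, 5, 0.05), (5, 2, 0.1), (5, 3, 0.2)),
        )
        _, aln = simulate_alignment(4, 100_000, Alphabet.DNA, tree=tree, seed=7)
        est = jc69_distance(aln).values
        true = tree.patristic()
        assert np.all(np.abs(est - true) < 0.012)  # ~3 s.e. at this length
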
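import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wboot import (
    Alphabet,
    ConsistencyError,
    QualityVector,
    WbootError,
    average_secondary_support,
    distance_matrix,
    generate_replicates,
    ls_coefficient,
    minmax_normalize,
    neighbor_joining,
    patristic_matrix,
    replicate_ls_vector,
    stream,
    weights_from_quality,
)


class TestLSCoefficient:
    def test_zero_for_own_patristic(self, primate_like):
        _, aln = primate_like
        dm = distance_matrix(aln)
        tree = neighbor_joining(dm)
        perfect = patristic_matrix(tree)
        assert ls_coefficient(perfect, tree) == pytest.approx(0.0, abs=1e-18)

    def test_single_pair_perturbation(self, primate_like):
        _, aln = primate_like
        tree = neighbor_joining(distance_matrix(aln))
        dm = patristic_matrix(tree)
        values = dm.values.copy()
        values[0, 1] += 0.1
        values[1, 0] += 0.1
        from wboot import DistanceMatrix

        bumped = DistanceMatrix(dm.taxa, values)
        # unordered-pair convention: the 0.1 bump counts once, not twice
        assert ls_coefficient(bumped, tree) == pytest.approx(0.01)

    def test_taxon_mismatch(self, primate_like):
        _, aln = primate_like
        dm = distance_matrix(aln)
        tree = neighbor_joining(dm)
        from wboot import DistanceMatrix

        shuffled = DistanceMatrix(tuple(reversed(dm.taxa)), dm.values)
        with pytest.raises(ConsistencyError):
            ls_coefficient(shuffled, tree)


class TestReplicateLS:
    def test_constant_for_identical_replicates(self):
        # l = 1 alignments resample to themselves
        from wboot import Alignment, ReplicateSet

        aln = Alignment(tuple("ABCD"), ("A", "C", "G", "T"), Alphabet.DNA)
        reps = ReplicateSet(aln, (aln,) * 5, seed=0)
        vec = replicate_ls_vector(reps)
        assert vec.kind == "ls"
        assert np.allclose(vec.values, vec.values[0])

    def test_vector_length_and_nonnegative(self, primate_like):
        _, aln = primate_like
        reps = generate_replicates(aln, 12, seed=3)
        vec = replicate_ls_vector(reps)
        assert vec.N == 12
        assert np.all(vec.values >= 0)


class TestSecondarySupport:
    def test_bounds_and_value(self, primate_like):
        _, aln = primate_like
        tree = neighbor_joining(distance_matrix(aln))
        ss = average_secondary_support(tree, aln, Ns=10, rng=stream(1, "secondary", 0, 0))
        assert 0.0 <= ss <= 100.0
        # strong simulated signal: the tree should be well supported
        assert ss > 50.0

    def test_mean_over_branches(self):
        # hand-built: support of two branches at 100% and 50% -> mean 75
        from wboot.support import weighted_support

        ref = [frozenset({"C", "D"}), frozenset({"E", "F"})]
        reps = [
            {frozenset({"C", "D"}), frozenset({"E", "F"})},
            {frozenset({"C", "D"})},
        ]
        table = weighted_support(ref, reps, np.array([0.5, 0.5]))
        assert table.scores.mean() == 75.0

    def test_requires_positive_ns(self, primate_like):
        _, aln = primate_like
        tree = neighbor_joining(distance_matrix(aln))
        with pytest.raises(WbootError):
            average_secondary_support(tree, aln, Ns=0)


class TestMinMaxNormalize:
    def test_basic(self):
        q = QualityVector(np.array([1.0, 2.0, 3.0]), "ls")
        norm = minmax_normalize(q)
        assert norm.kind == "norm_ls"
        assert np.allclose(norm.values, [0.0, 0.5, 1.0])

    def test_constant_vector_degenerate(self):
        q = QualityVector(np.array([2.0, 2.0, 2.0]), "ls")
        norm = minmax_normalize(q)
        assert norm.degenerate
        w = weights_from_quality(norm)
        assert np.allclose(w.w, 1 / 3)

    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=30,
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
        shift=st.floats(min_value=-10, max_value=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, values, scale, shift):
        v = np.asarray(values)
        if v.max() - v.min() < 1e-3:  # near-constant: cancellation dominates
            return
        q = minmax_normalize(QualityVector(v, "ls"))
        shifted = np.maximum(scale * v + shift, 0.0)
        if not np.all(shifted == scale * v + shift):
            return  # clipped: affine map left the valid LS domain
        q2 = minmax_normalize(QualityVector(shifted, "ls"))
        assert np.allclose(q.values, q2.values, atol=1e-6)


class TestWeights:
    def test_constant_quality_gives_uniform(self):
        for kind, val in [("ls", 2.0), ("sbs", 40.0)]:
            q = QualityVector(np.full(8, val), kind)
            w = weights_from_quality(q)
            assert np.allclose(w.w, 1 / 8)

    def test_sbs_proportional(self):
        w = weights_from_quality(QualityVector(np.array([25.0, 75.0]), "sbs"))
        assert np.allclose(w.w, [0.25, 0.75])

    def test_ls_inverse_proportional(self):
        w = weights_from_quality(QualityVector(np.array([1.0, 3.0]), "ls"))
        assert np.allclose(w.w, [0.75, 0.25])

    def test_zero_ls_gets_maximal_weight(self):
        w = weights_from_quality(QualityVector(np.array([0.0, 1.0, 1.0]), "ls"))
        assert w.w[0] > 0.999
        assert np.isclose(w.w.sum(), 1.0)

    def test_norm_ls_complement(self):
        q = minmax_normalize(QualityVector(np.array([1.0, 2.0, 3.0]), "ls"))
        w = weights_from_quality(q)
        # complements (1, 0.5, 0) normalized
        assert np.allclose(w.w, [2 / 3, 1 / 3, 0.0])

    @given(
        kind=st.sampled_from(["ls", "sbs"]),
        values=st.lists(
            st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
            min_size=2,
            max_size=50,
        ),
        normalize=st.booleans(),
    )
    @settings(max_examples=150, deadline=None)
    def test_contract_and_monotonicity(self, kind, values, normalize):
        """w_t in [0,1], sums to 1; better quality never gets less weight."""
        q = QualityVector(np.asarray(values), kind)
        if normalize:
            q = minmax_normalize(q)
        w = weights_from_quality(q)
        assert np.all(w.w >= 0) and np.all(w.w <= 1)
        assert abs(w.w.sum() - 1.0) < 1e-12
        order = np.argsort(np.asarray(values))
        ordered = w.w[order]
        if kind == "sbs":  # higher quality value -> weight non-decreasing
            assert np.all(np.diff(ordered) >= -1e-12)
        else:  # ls: lower is better -> weight non-increasing in ls
            assert np.all(np.diff(ordered) <= 1e-12)
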
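"""Markov chain training, scoring, percentile cutoffs, refinement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmerbin import (
    MarkovModel,
    MixtureModel,
    ReadSet,
    RefinementConfig,
    final_genome_sizes,
    generate_genome,
    percentile_cutoff,
    random_markov_model,
    refine_assignments,
    relative_entropy,
    score_read,
    simulate_reads,
    train_markov,
)
from kmerbin._encode import revcomp
from kmerbin.assign import UNASSIGNED, ReadBinning
from kmerbin.markov import MarkovScorer

dna = st.text(alphabet="ACGTN", min_size=8, max_size=60)


def de_bruijn_sequence(k: int, alphabet: str = "ACGT") -> str:
    """Standard de Bruijn sequence B(4, k) via Lyndon words, linearised by
    appending the first k-1 symbols so every k-mer occurs exactly once."""
    n = len(alphabet)
    a = [0] * n * k
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > k:
            if k % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, n):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    s = "".join(alphabet[i] for i in seq)
    return s + s[: k - 1]


class TestTrainMarkov:
    def test_de_bruijn_uniform_transitions(self):
        """Training on a de Bruijn sequence of order 6 forces every
        transition row to exactly (0.25, 0.25, 0.25, 0.25)."""
        seq = de_bruijn_sequence(6)
        model = train_markov([seq], order=5, pseudocount=1.0)
        assert np.allclose(model.transition, 0.25, atol=1e-12)
        assert np.allclose(model.stationary, 1.0 / 1024, atol=1e-12)

    def test_homopolymer_limit(self):
        probs = []
        for pc in (1.0, 1e-3, 1e-6):
            model = train_markov(["A" * 50], order=5, pseudocount=pc)
            ctx = 0  # "AAAAA"
            probs.append(model.transition[ctx, 0])
        assert probs == sorted(probs)
        assert probs[-1] == pytest.approx(1.0, abs=1e-5)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(dna, min_size=1, max_size=5), st.integers(1, 4))
    def test_rows_sum_to_one(self, seqs, order):
        if not any(len(s.replace("N", "")) >= order + 1 for s in seqs):
            seqs = seqs + ["ACGTACGTACGT"]
        try:
            model = train_markov(seqs, order=order)
        except ValueError:
            return  # no usable window
        assert np.allclose(model.transition.sum(axis=1), 1.0, atol=1e-9)
        assert model.stationary.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(model.transition > 0)

    def test_no_usable_window_errors(self):
        with pytest.raises(ValueError):
            train_markov(["ACN"], order=5)


class TestScoreRead:
    def _uniform_model(self, order=5):
        nctx = 4**order
        return MarkovModel(
            order=order,
            transition=np.full((nctx, 4), 0.25),
            stationary=np.full(nctx, 1.0 / nctx),
        )

    def test_uniform_model_scores_log_quarter(self):
        model = self._uniform_model()
        for read in ("ACGTACGTACGT", "A" * 30, "GGGTTTAAACCCGGG"):
            assert score_read(read, model) == pytest.approx(math.log(0.25), rel=1e-12)

    def test_strand_symmetry(self):
        model = train_markov(["ACGTACCGGTTAGCAT" * 4], order=5)
        read = "ACCGGTTAGCATACGT"
        assert score_read(read, model) == pytest.approx(
            score_read(revcomp(read), model), rel=1e-12
        )

    def test_short_read_unassignable(self):
        model = self._uniform_model()
        assert score_read("ACG", model) == -np.inf

    def test_reads_score_higher_under_own_model(self, rng):
        a = random_markov_model(seed=5)
        b = random_markov_model(seed=6)
        genome = generate_genome(20000, a, seed=7)
        reads = simulate_reads(genome, coverage=1.0, paired=False, seed=8)
        sa = np.array([score_read(r, a) for r in reads[:200]])
        sb = np.array([score_read(r, b) for r in reads[:200]])
        assert np.mean(sa > sb) > 0.95


class TestPercentileCutoff:
    def test_uniform_grid(self):
        assert percentile_cutoff(np.arange(1, 101), 0.10) == 10

    def test_constant(self):
        assert percentile_cutoff([7.0] * 9, 0.3) == 7.0

    def test_monotone_in_beta(self):
        scores = np.random.default_rng(0).normal(size=101)
        assert percentile_cutoff(scores, 0.05) <= percentile_cutoff(scores, 0.10)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            percentile_cutoff([], 0.1)


class TestRelativeEntropy:
    def test_identity_zero(self):
        m = random_markov_model(seed=3)
        assert relative_entropy(m, m) == 0.0

    def test_nonnegative(self):
        a = random_markov_model(seed=1)
        b = random_markov_model(seed=2)
        assert relative_entropy(a, b) > 0.0

    def test_hand_computed_toy(self):
        # order-1 chains differing only in the A-context row
        ta = np.full((4, 4), 0.25)
        tb = np.full((4, 4), 0.25)
        ta[0] = [0.9, 0.1 / 3, 0.1 / 3, 0.1 / 3]
        tb[0] = [0.1 / 3, 0.9, 0.1 / 3, 0.1 / 3]
        pi = np.full(4, 0.25)
        a = MarkovModel(order=1, transition=ta, stationary=pi)
        b = MarkovModel(order=1, transition=tb, stationary=pi)
        kl_row = 0.9 * math.log(0.9 / (0.1 / 3)) + (0.1 / 3) * math.log((0.1 / 3) / 0.9)
        expected = 0.25 * kl_row  # symmetric, only one context differs
        assert relative_entropy(a, b) == pytest.approx(expected, rel=1e-12)

    def test_order_mismatch(self):
        with pytest.raises(ValueError):
            relative_entropy(random_markov_model(order=2, seed=1), random_markov_model(order=3, seed=1))


class TestRefinement:
    def _two_bin_reads(self, n_per=300, readlen=100):
        a = random_markov_model(seed=11)
        b = random_markov_model(seed=22)
        ga = generate_genome(60000, a, seed=1)
        gb = generate_genome(60000, b, seed=2)
        ra = simulate_reads(ga, coverage=n_per * readlen / 60000, read_length=readlen, paired=False, seed=3)
        rb = simulate_reads(gb, coverage=n_per * readlen / 60000, read_length=readlen, paired=False, seed=4)
        reads = ReadSet.from_sequences(ra + rb)
        truth = np.array([0] * len(ra) + [1] * len(rb))
        return reads, truth

    def test_well_separated_fixed_point(self):
        reads, truth = self._two_bin_reads()
        initial = ReadBinning(labels=truth.copy(), m=2)
        result = refine_assignments(reads, initial, RefinementConfig(beta=0.10))
        assert result.converged
        # bins stay essentially pure
        for j in (0, 1):
            members = result.binning.bin_members(j)
            assert np.mean(truth[members] == j) > 0.98

    def test_m1_rejects_about_beta(self):
        reads, _ = self._two_bin_reads(n_per=400)
        initial = ReadBinning(labels=np.zeros(len(reads), dtype=np.int64), m=1)
        result = refine_assignments(
            reads, initial, RefinementConfig(beta=0.10, max_iter=1)
        )
        rejected = np.mean(result.binning.labels == UNASSIGNED)
        assert 0.05 <= rejected <= 0.15

    def test_tie_breaks_to_lower_bin(self):
        base, _ = self._two_bin_reads(n_per=100)
        n = len(base)
        # two bins with identical contents: every read duplicated
        seqs = base.seqs + base.seqs
        ids = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        reads = ReadSet(ids=ids, seqs=seqs)
        labels = np.array([0] * n + [1] * n, dtype=np.int64)
        with pytest.warns(RuntimeWarning, match="emptied"):
            result = refine_assignments(
                reads, ReadBinning(labels=labels, m=2), RefinementConfig(max_iter=1)
            )
        # identical training sets -> identical models -> every assigned read
        # goes to bin 0 by the tie rule
        assigned = result.binning.labels[result.binning.labels != UNASSIGNED]
        assert assigned.size > 0
        assert np.all(assigned == 0)

    def test_all_unassigned_initial_errors(self):
        reads, _ = self._two_bin_reads(n_per=20)
        labels = np.full(len(reads), UNASSIGNED, dtype=np.int64)
        with pytest.raises(ValueError):
            refine_assignments(reads, ReadBinning(labels=labels, m=2))


class TestFinalGenomeSizes:
    def test_arithmetic(self):
        seqs = ["ACGT" * 19 for _ in range(100)]  # 76 bp -> 61 16-mer windows
        ids = [f"r{i}" for i in range(100)]
        reads = ReadSet(ids=ids, seqs=seqs)
        binning = ReadBinning(labels=np.zeros(100, dtype=np.int64), m=1)
        model = MixtureModel(alphas=[1.0], lambdas=[6.1])
        sizes = final_genome_sizes(binning, reads, model, k=16)
        assert sizes[0] == pytest.approx(100 * 61 / 6.1)

    def test_empty_bin_zero_with_warning(self):
        reads = ReadSet(ids=["a"], seqs=["A" * 20])
        binning = ReadBinning(labels=np.array([0]), m=2)
        model = MixtureModel(alphas=[0.5, 0.5], lambdas=[5.0, 5.0])
        with pytest.warns(RuntimeWarning):
            sizes = final_genome_sizes(binning, reads, model, k=16)
        assert sizes[1] == 0.0


def test_scorer_batch_matches_scalar():
    model = train_markov(["ACGTACCGGTTAGCAT" * 4], order=5)
    reads = ["ACCGGTTAGCATACGTAC", "A" * 10, "ACG", "ACGTNNNACGTACGTACG"]
    scorer = MarkovScorer(reads, order=5)
    batch = scorer.scores(model)
    for i, r in enumerate(reads):
        assert batch[i] == pytest.approx(score_read(r, model), rel=1e-12) or (
            batch[i] == -np.inf and score_read(r, model) == -np.inf
        )
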
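"""Profile construction: weights, frequencies, pseudocounts, log-odds."""

import math

import numpy as np
import pytest

import agalchap as ac
from agalchap.errors import ConfigurationError
from agalchap.pssm import (
    PssmParams,
    apply_pseudocounts,
    build_pssm,
    column_frequencies,
    sequence_weights,
)
from agalchap.seqio import RESIDUES, Alignment

IDX = {r: i for i, r in enumerate(RESIDUES)}


def naive_pssm_scores(aln, params):
    """Independent, loop-everything reimplementation of the profile recipe.

    Mirrors the documented formulas directly: per-column Henikoff mass,
    weighted frequencies, pseudocount mixing, scaled log2 odds with
    half-away-from-zero rounding. No shared code with the implementation.
    """
    n = len(aln.sequences)
    ncol = len(aln.sequences[0][1])
    # -- weights
    if params.weighting == "uniform":
        weights = [1.0] * n
    else:
        raw = [0.0] * n
        types_per_col = []
        for c in range(ncol):
            col = [seq[c] for _, seq in aln.sequences]
            present = {}
            for i, ch in enumerate(col):
                if ch in IDX:
                    present.setdefault(ch, []).append(i)
            if not present:
                continue
            types_per_col.append(len(present))
            for members in present.values():
                for i in members:
                    raw[i] += 1.0 / (len(present) * len(members))
        total = sum(raw)
        n_eff = sum(types_per_col) / len(types_per_col)
        weights = [w / total * n_eff for w in raw]
    n_eff = sum(weights)
    # -- per query position
    qrow = aln.sequences[aln.query_index][1]
    cols = [c for c in range(ncol) if qrow[c] != "-"]
    bg = params.background
    prior = params.substitution_prior
    out = []
    for c in cols:
        freq = [0.0] * 20
        for (name, seq), w in zip(aln.sequences, weights):
            ch = seq[c]
            if ch in IDX:
                freq[IDX[ch]] += w
        tot = sum(freq)
        f = [x / tot for x in freq]
        alpha, beta = n_eff - 1.0, params.pseudocount_weight
        if alpha + beta == 0:
            p = f
        else:
            g = [sum(f[a] * prior[a][b] for a in range(20)) for b in range(20)]
            p = [(alpha * f[b] + beta * g[b]) / (alpha + beta) for b in range(20)]
            s = sum(p)
            p = [x / s for x in p]
        row = {}
        for b, r in enumerate(RESIDUES):
            if p[b] <= 0:
                row[r] = params.score_floor
            else:
                x = params.scale * math.log2(p[b] / bg[b])
                rounded = int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)
                row[r] = max(rounded, params.score_floor)
        out.append(row)
    return out


class TestSequenceWeights:
    def test_identical_pair_henikoff(self):
        aln = Alignment([("a", "ACDE"), ("b", "ACDE")])
        w = sequence_weights(aln, "henikoff")
        assert w == pytest.approx([0.5, 0.5])

    def test_unique_sequence_gets_maximal_weight(self):
        aln = Alignment(
            [
                ("a", "ACDEFG"),
                ("b", "ACDEFG"),
                ("c", "ACDEFG"),
                ("d", "WYWYWY"),  # unique at every column
            ]
        )
        w = sequence_weights(aln, "henikoff")
        assert w[3] == max(w)
        # brute-force bookkeeping: each column has 2 types; the outlier owns
        # one type alone (mass 1/2), the other three split 1/2 -> 1/6 each
        raw = [1 / 6 * 6, 1 / 6 * 6, 1 / 6 * 6, 1 / 2 * 6]
        n_eff = 2.0
        expected = [r / sum(raw) * n_eff for r in raw]
        assert w == pytest.approx(expected)

    def test_uniform_scheme_all_ones(self):
        aln = Alignment([("a", "ACDE"), ("b", "AWDE"), ("c", "ACDY")])
        assert sequence_weights(aln, "uniform") == pytest.approx([1, 1, 1])

    def test_weights_sum_to_effective_count(self):
        aln = Alignment([("a", "AAAA"), ("b", "AAAC"), ("c", "CCCC")])
        w = sequence_weights(aln, "henikoff")
        # n_eff = mean distinct types per column = (2+2+2+2)/4 = 2
        assert w.sum() == pytest.approx(2.0)


class TestColumnFrequencies:
    def test_pure_column(self):
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "A"), ("d", "A")])
        f = column_frequencies(aln, np.ones(4))[0]
        assert f[IDX["A"]] == pytest.approx(1.0)

    def test_gap_excluded_from_denominator(self):
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "C"), ("d", "-")])
        f = column_frequencies(aln, np.ones(4))[0]
        assert f[IDX["A"]] == pytest.approx(2 / 3)
        assert f[IDX["C"]] == pytest.approx(1 / 3)

    def test_weighted_column(self):
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "C")])
        f = column_frequencies(aln, np.array([2.0, 1.0, 1.0]))[0]
        assert f[IDX["A"]] == pytest.approx(0.75)


class TestApplyPseudocounts:
    def test_beta_zero_passes_observations_through(self):
        params = PssmParams(pseudocount_weight=0.0)
        f = np.zeros(20)
        f[IDX["A"]] = 1.0
        assert apply_pseudocounts(f, params, n_eff=5.0) == pytest.approx(f)

    def test_single_observation_yields_prior_push(self):
        params = PssmParams(pseudocount_weight=10.0)
        f = np.zeros(20)
        f[IDX["A"]] = 1.0
        p = apply_pseudocounts(f, params, n_eff=1.0)
        expected = params.substitution_prior[IDX["A"]]
        assert p == pytest.approx(expected / expected.sum())

    def test_pure_column_mixing_matches_direct_formula(self):
        # beta=10, n_eff=11: smoothed = (10 f + 10 g) / 20, renormalised
        params = PssmParams(pseudocount_weight=10.0)
        f = np.zeros(20)
        f[IDX["A"]] = 1.0
        g = params.substitution_prior[IDX["A"]]
        expected = (10.0 * f + 10.0 * g) / 20.0
        expected = expected / expected.sum()
        assert apply_pseudocounts(f, params, n_eff=11.0) == pytest.approx(expected)

    def test_output_sums_to_one(self):
        params = PssmParams()
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(20))
        assert apply_pseudocounts(f, params, 8.0).sum() == pytest.approx(1.0)


class TestBuildPssm:
    def test_single_sequence_beta_zero(self):
        params = PssmParams(pseudocount_weight=0.0)
        aln = Alignment([("q", "AW")])
        pssm = build_pssm(aln, params)
        for pos, res in ((1, "A"), (2, "W")):
            expected = params.scale * math.log2(1.0 / params.background[IDX[res]])
            assert pssm.score(pos, res) == int(math.floor(expected + 0.5))
            others = [r for r in RESIDUES if r != res]
            assert all(
                pssm.score(pos, r) == params.score_floor for r in others
            )

    def test_all_residues_uniform_background_scores_zero(self):
        seqs = [(f"s{i}", r) for i, r in enumerate(RESIDUES)]
        params = PssmParams(
            background=np.full(20, 0.05),
            pseudocount_weight=0.0,
            weighting="uniform",
        )
        pssm = build_pssm(Alignment(seqs, query_index=0), params)
        assert all(s == 0 for s in pssm.scores[0].values())

    def test_matches_naive_oracle_on_synthetic_alignment(self, mixed_profile):
        aln = ac.sample_alignment(mixed_profile, 13, gap_rate=0.05, seed=11)
        for params in (PssmParams(), PssmParams(weighting="uniform")):
            pssm = build_pssm(aln, params)
            assert pssm.scores == naive_pssm_scores(aln, params)

    def test_deterministic(self, mixed_profile):
        aln = ac.sample_alignment(mixed_profile, 13, gap_rate=0.05, seed=2)
        assert build_pssm(aln) == build_pssm(aln)

    def test_score_monotone_in_observed_frequency(self):
        # more observed A at a fixed position never lowers A's score
        params = PssmParams()
        prev = None
        for k in range(1, 7):
            seqs = [("q", "A")] + [
                (f"h{i}", "A" if i < k else "C") for i in range(1, 7)
            ]
            pssm = build_pssm(Alignment(seqs), params)
            score = pssm.score(1, "A")
            if prev is not None:
                assert score >= prev
            prev = score

    def test_probabilities_sum_to_one(self, small_pssm):
        for row in small_pssm.probabilities:
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-9)

    def test_query_gap_columns_dropped(self):
        aln = Alignment([("q", "A-C"), ("h", "AWC")])
        pssm = build_pssm(aln)
        assert pssm.query == "AC" and len(pssm) == 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            PssmParams(background=np.full(20, 0.1))  # does not sum to 1
        with pytest.raises(ConfigurationError):
            PssmParams(scale=0.0)
        with pytest.raises(ConfigurationError):
            PssmParams(weighting="phylogenetic")


class TestProfileRecovery:
    def test_smoothed_probabilities_approach_generating_profile(
        self, mixed_profile
    ):
        """With smoothing off, the estimated frequency layer converges to
        the generating profile as the alignment deepens."""
        params = PssmParams(weighting="uniform", pseudocount_weight=0.0)
        errs = {}
        for n in (50, 500):
            aln = ac.sample_alignment(mixed_profile, n, gap_rate=0.05, seed=7)
            pssm = build_pssm(aln, params)
            probs = np.array(
                [[row[r] for r in RESIDUES] for row in pssm.probabilities]
            )
            errs[n] = np.max(np.abs(probs - mixed_profile.distributions))
        assert errs[500] <= 0.05
        assert errs[500] <= errs[50] / 2
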
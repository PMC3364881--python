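"""Profile construction, Viterbi/forward scoring, calibration, E-values."""
import numpy as np
import pytest
from scipy import stats

from dscamscan.alphabet import AA_INDEX, AA_LETTERS, robinson_background
from dscamscan.errors import (BuildError, CalibrationError, UncalibratedError,
                              ValidationError)
from dscamscan.phmm import (build_profile, calibrate, evalue, evalues_array,
                            forward, profile_from_rows, read_profile,
                            sample_background, viterbi, write_profile)


class TestBuildProfile:
    def test_identical_rows_alpha_zero_gives_point_emissions(self):
        h = profile_from_rows(["ACDEF"] * 3, alpha=0.0)
        assert h.L == 5
        for j, res in enumerate("ACDEF"):
            assert h.match_emissions[j, AA_INDEX[res]] == pytest.approx(1.0)

    def test_majority_gap_column_is_not_a_match_state(self):
        h = profile_from_rows(["A-DEF", "A-DEF", "ACDEF"], alpha=1.0)
        assert h.L == 4  # column 1 is gap in 2 of 3 rows

    def test_pseudocount_estimator_hand_value(self):
        # 4 rows, one substitution in one column, alpha=1, uniform background:
        # majority emission = (3 + 1/20) / (4 + 1) = 0.61
        h = profile_from_rows(["ACDEF", "ACDEF", "ACDEF", "AGDEF"],
                              alpha=1.0, background=np.full(20, 0.05))
        assert h.match_emissions[1, AA_INDEX["C"]] == pytest.approx(0.61)

    def test_normalization_invariants(self, hmms):
        for h in hmms:
            h.validate()  # emission rows and transition groups sum to 1

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(BuildError):
            profile_from_rows(["---", "---"])

    def test_file_round_trip_exact(self, tmp_path, hmms):
        h = hmms[0]
        path = tmp_path / "p.phmm"
        write_profile(h, path)
        h2 = read_profile(path)
        assert h2.name == h.name and h2.L == h.L
        np.testing.assert_allclose(h2.match_emissions, h.match_emissions,
                                   atol=1e-9)
        np.testing.assert_allclose(h2.background, h.background, atol=1e-9)
        for k in h.transitions:
            np.testing.assert_allclose(h2.transitions[k], h.transitions[k],
                                       atol=1e-9)
        assert h2.calibration == pytest.approx(h.calibration, abs=1e-9)


class TestViterbi:
    def test_consensus_beats_reversal(self, hmms):
        h = hmms[0]
        cons = "".join(AA_LETTERS[int(np.argmax(h.match_emissions[j]))]
                       for j in range(h.L))
        assert viterbi(h, cons).score > viterbi(h, cons[::-1]).score

    def test_self_alignment_covers_whole_sequence(self):
        seq = "MKVLAWECHDFNPQRSTYIG"
        h = profile_from_rows([seq, seq], alpha=1.0)
        m = viterbi(h, seq)
        assert (m.start, m.end) == (0, len(seq))

    def test_local_score_never_drops_when_appending_residues(self, hmms, rng):
        h = hmms[1]
        cons = "".join(AA_LETTERS[int(np.argmax(h.match_emissions[j]))]
                       for j in range(h.L))
        base = viterbi(h, cons).score
        for _ in range(5):
            tail = "".join(rng.choice(list(AA_LETTERS), size=30))
            assert viterbi(h, cons + tail).score >= base - 1e-9

    def test_empty_sequence_sentinel(self, hmms):
        m = viterbi(hmms[0], "")
        assert m.score == float("-inf") and (m.start, m.end) == (0, 0)

    def test_stop_symbol_rejected(self, hmms):
        with pytest.raises(ValidationError):
            viterbi(hmms[0], "ACD*EF")


class TestForward:
    def test_forward_dominates_viterbi_on_random_sequences(self, hmms, rng):
        h = hmms[2]
        for _ in range(100):
            seq = "".join(rng.choice(list(AA_LETTERS), size=40))
            assert forward(h, seq) >= viterbi(h, seq).score - 1e-9

    def test_single_path_profile_forward_close_to_viterbi(self):
        # deterministic M->M transitions: the optimal full-chain path holds
        # almost all probability mass; local entry/exit keeps a small set of
        # partial-coverage subpaths, so the gap is fractions of a bit
        seq = "ACDEFGHIKLMNPQRSTVWY" * 2
        h = profile_from_rows([seq] * 3, alpha=0.0)
        gap = forward(h, seq) - viterbi(h, seq).score
        assert 0.0 <= gap < 0.5

    def test_forward_consensus_beats_shuffles(self, hmms, rng):
        h = hmms[3]
        cons = "".join(AA_LETTERS[int(np.argmax(h.match_emissions[j]))]
                       for j in range(h.L))
        ref = forward(h, cons)
        wins = 0
        for _ in range(40):
            perm = "".join(rng.permutation(list(cons)))
            if ref > forward(h, perm):
                wins += 1
        assert wins >= 38  # 95%


class TestCalibration:
    def test_same_seed_reproduces_parameters(self, blocks):
        h = build_profile(blocks[0])
        c1 = calibrate(h, 500, 60, seed=9)
        c2 = calibrate(h, 500, 60, seed=9)
        assert c1.calibration == c2.calibration

    def test_gumbel_location_identity(self, hmms):
        # P(S > mu) = 1 - exp(-1) ~ 0.632 for a fresh null sample
        h = hmms[0]
        mu, _ = h.calibration
        rng = np.random.default_rng(31)
        sample = sample_background(h.background, 1000, 100, rng)
        offs = np.arange(0, 1001 * 100, 100, dtype=np.int64)
        sv, _, _ = h.score_segments(sample.ravel(), offs, "viterbi")
        frac = (sv > mu).mean()
        assert frac == pytest.approx(0.632, abs=3 * 0.0153)  # 3 binomial sd

    @pytest.mark.parametrize("p", [0.1, 0.01])
    def test_pvalue_counts_match_nominal_rate(self, hmms, p):
        # simulation against the fitted null, pooled over the ten profiles:
        # the observed exceedance rate matches the nominal p within the
        # calibration's documented CDF accuracy plus binomial noise
        pv = []
        for bi, h in enumerate(hmms):
            mu, lam = h.calibration
            rng = np.random.default_rng(570 + bi)
            sample = sample_background(h.background, 200, 100, rng)
            offs = np.arange(0, 201 * 100, 100, dtype=np.int64)
            sv, _, _ = h.score_segments(sample.ravel(), offs, "viterbi")
            pv.append(-np.expm1(-np.exp(-lam * (sv - mu))))
        pv = np.concatenate(pv)
        n = pv.shape[0]
        rate = (pv <= p).mean()
        tol = 0.04 + 3 * np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) <= tol

    def test_pvalues_uniform_pooled_ks(self, hmms):
        # fresh null p-values pooled over the ten block profiles
        pooled = []
        for bi, h in enumerate(hmms):
            mu, lam = h.calibration
            rng = np.random.default_rng(8800 + bi)
            fresh = sample_background(h.background, 100, 100, rng)
            offs = np.arange(0, 101 * 100, 100, dtype=np.int64)
            sv, _, _ = h.score_segments(fresh.ravel(), offs, "viterbi")
            pooled.append(-np.expm1(-np.exp(-lam * (sv - mu))))
        ks = stats.kstest(np.concatenate(pooled), "uniform").statistic
        assert ks < 0.08  # preset bound; acceptance applies its own

    def test_too_few_samples_rejected(self, blocks):
        with pytest.raises(ValidationError):
            calibrate(build_profile(blocks[0]), 50, 100, seed=0)


class TestEvalue:
    def test_closed_form_at_mu(self, hmms):
        h = hmms[0]
        mu, _ = h.calibration
        assert evalue(mu, h, 1) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_linear_in_db_size(self, hmms):
        h = hmms[0]
        s = h.calibration[0] + 5.0
        assert evalue(s, h, 2000) == pytest.approx(2 * evalue(s, h, 1000))

    def test_strictly_decreasing_in_score(self, hmms):
        h = hmms[0]
        mu = h.calibration[0]
        es = [evalue(mu + d, h, 100) for d in (0.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_uncalibrated_profile_raises(self, blocks):
        h = build_profile(blocks[0])
        with pytest.raises(UncalibratedError):
            evalue(10.0, h, 100)


class TestCrossEngine:
    def test_bit_scores_rank_correlate_with_pyhmmer(self, blocks):
        # advisory cross-check against an independent HMM engine built from
        # the same block alignment
        pyhmmer = pytest.importorskip("pyhmmer")
        b = blocks[0]
        rows = [s for _, s in b.sub_alignment.sequences]
        alpha = pyhmmer.easel.Alphabet.amino()
        msa = pyhmmer.easel.TextMSA(name=b"blk", sequences=[
            pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=r)
            for i, r in enumerate(rows)]).digitize(alpha)
        hmm3, _, _ = pyhmmer.plan7.Builder(alpha).build_msa(
            msa, pyhmmer.plan7.Background(alpha))
        mine = build_profile(b)
        rng = np.random.default_rng(0)
        cons = "".join(AA_LETTERS[int(np.argmax(mine.match_emissions[j]))]
                       for j in range(mine.L))
        targets = []
        for rate in np.linspace(0, 0.8, 40):
            s = list(cons)
            for i in range(len(s)):
                if rng.random() < rate:
                    s[i] = AA_LETTERS[rng.integers(0, 20)]
            targets.append("".join(s))
        my_scores = [viterbi(mine, t).score for t in targets]
        dseqs = [pyhmmer.easel.TextSequence(name=f"t{i}".encode(),
                                            sequence=t).digitize(alpha)
                 for i, t in enumerate(targets)]
        pipeline = pyhmmer.plan7.Pipeline(
            alpha, background=pyhmmer.plan7.Background(alpha),
            bias_filter=False, F1=1.0, F2=1.0, F3=1.0)
        hits = pipeline.search_hmm(
            hmm3, pyhmmer.easel.DigitalSequenceBlock(alpha, dseqs))
        h3 = {(h.name.decode() if isinstance(h.name, bytes) else h.name):
              h.score for h in hits}
        pairs = [(my_scores[i], h3[f"t{i}"]) for i in range(len(targets))
                 if f"t{i}" in h3]
        assert len(pairs) >= 20
        a, b2 = zip(*pairs)
        rho = stats.spearmanr(a, b2).statistic
        assert rho > 0.9
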
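"""Six-frame translation, genome scanning, k-of-n calling, hit chaining."""
import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from dscamscan.alphabet import AA_LETTERS, reverse_complement
from dscamscan.errors import UncalibratedError, ValidationError
from dscamscan.genome_scan import (HmmHit, call_candidates, chain_gene_model,
                                   scan_genome, six_frame_translate)
from dscamscan.phmm import build_profile
from dscamscan.synthetic_data import _reverse_translate


class TestSixFrameTranslate:
    def test_forward_frame_zero(self):
        segs = [s for s in six_frame_translate("ATGAAA")
                if s.strand == "+" and s.frame == 0]
        assert len(segs) == 1
        assert segs[0].aa == "MK" and (segs[0].nt_start, segs[0].nt_end) == (0, 6)

    def test_reverse_strand_maps_to_forward_coordinates(self):
        segs = [s for s in six_frame_translate("TTTCAT")
                if s.strand == "-" and s.frame == 0]
        assert segs[0].aa == "MK"
        assert (segs[0].nt_start, segs[0].nt_end) == (0, 6)

    def test_split_at_stop_codon(self):
        segs = [s for s in six_frame_translate("ATGTAAATG")
                if s.strand == "+" and s.frame == 0]
        assert [(s.aa, s.nt_start, s.nt_end) for s in segs] == \
            [("M", 0, 3), ("M", 6, 9)]

    def test_short_input_empty(self):
        assert six_frame_translate("AT") == []

    def test_ambiguous_codons_become_x(self):
        segs = [s for s in six_frame_translate("ATGNNN")
                if s.strand == "+" and s.frame == 0]
        assert segs[0].aa == "MX"

    def test_coordinate_round_trip_random_scaffolds(self, rng):
        # translating genome[nt interval] on the recorded strand/frame
        # reproduces the stored residues (Biopython as oracle)
        for _ in range(10):
            scaffold = "".join(rng.choice(list("ACGT"), size=200))
            for seg in six_frame_translate(scaffold):
                piece = scaffold[seg.nt_start:seg.nt_end]
                if seg.strand == "-":
                    piece = reverse_complement(piece)
                assert str(Seq(piece).translate()) == seg.aa


def _consensus(hmm):
    return "".join(AA_LETTERS[int(np.argmax(hmm.match_emissions[j]))]
                   for j in range(hmm.L))


class TestScanGenome:
    def test_back_translated_consensus_found_at_planted_interval(self, hmms):
        h = hmms[0]
        rng = np.random.default_rng(7)
        genome = {"s1": _reverse_translate(_consensus(h), rng)}
        hits = scan_genome([h], genome, e_cutoff=0.001)
        mine = [x for x in hits if x.block == 0 and x.strand == "+"]
        assert len(mine) == 1
        assert (mine[0].nt_start, mine[0].nt_end) == (0, 3 * h.L)
        assert mine[0].aa == _consensus(h)

    def test_all_n_scaffold_yields_no_hits(self, hmms):
        assert scan_genome(hmms, {"s1": "N" * 3000}, e_cutoff=0.01) == []

    def test_reverse_strand_planting_scores_equally(self, hmms):
        h = hmms[1]
        rng = np.random.default_rng(8)
        cds = _reverse_translate(_consensus(h), rng)
        fwd = scan_genome([h], {"s": cds}, e_cutoff=0.001)
        rev = scan_genome([h], {"s": reverse_complement(cds)},
                          e_cutoff=0.001)
        assert fwd and rev
        assert fwd[0].score == pytest.approx(rev[0].score)
        assert rev[0].strand == "-"

    def test_output_invariant_to_scaffold_order(self, hmms, rng):
        h = hmms[2]
        cds = _reverse_translate(_consensus(h), np.random.default_rng(1))
        noise = "".join(rng.choice(list("ACGT"), size=3000))
        g1 = {"a": noise, "b": cds}
        g2 = {"b": cds, "a": noise}
        r1 = scan_genome([h], g1, e_cutoff=0.01)
        r2 = scan_genome([h], g2, e_cutoff=0.01)
        assert [(x.scaffold, x.nt_start, x.score, x.evalue) for x in r1] == \
               [(x.scaffold, x.nt_start, x.score, x.evalue) for x in r2]

    def test_uncalibrated_profile_rejected(self, blocks):
        h = build_profile(blocks[0])
        with pytest.raises(UncalibratedError):
            scan_genome([h], {"s": "ACGT" * 100}, e_cutoff=0.01)

    def test_coordinate_round_trip_on_real_hits(self, hmms):
        h = hmms[0]
        rng = np.random.default_rng(9)
        pad = "".join(rng.choice(list("ACGT"), size=301))
        genome = {"s": pad + _reverse_translate(_consensus(h), rng)}
        for hit in scan_genome([h], genome, e_cutoff=0.001):
            piece = genome["s"][hit.nt_start:hit.nt_end]
            if hit.strand == "-":
                piece = reverse_complement(piece)
            assert str(Seq(piece).translate()) == hit.aa


def _mk_hit(block, start, length=30, score=50.0, strand="+", scaffold="s"):
    return HmmHit(block=block, scaffold=scaffold, strand=strand, frame=0,
                  aa_start=0, aa_end=length // 3, nt_start=start,
                  nt_end=start + length, score=score, evalue=1e-9,
                  aa="A" * (length // 3))


def brute_force_best_subset(hits, increasing=True):
    """Exhaustive heaviest collinear subset (block-sorted enumeration)."""
    sign = 1 if increasing else -1
    hits = sorted(hits, key=lambda h: (h.block, sign * h.nt_mid))
    best = (0, 0.0)
    for r in range(1, len(hits) + 1):
        for comb in itertools.combinations(range(len(hits)), r):
            hs = [hits[i] for i in comb]
            if all(a.block < b.block and sign * a.nt_mid < sign * b.nt_mid
                   for a, b in zip(hs, hs[1:])):
                best = max(best, (len(hs), sum(h.score for h in hs)))
    return best


def brute_force_best_chain(hits, pen):
    hits = sorted(hits, key=lambda h: (h.block, h.nt_mid))
    best = max((h.score for h in hits), default=0.0)
    for r in range(2, len(hits) + 1):
        for comb in itertools.combinations(range(len(hits)), r):
            hs = [hits[i] for i in comb]
            ok, val = True, hs[0].score
            for a, b in zip(hs, hs[1:]):
                if not (a.block < b.block and b.nt_start >= a.nt_end):
                    ok = False
                    break
                val += b.score - pen * (b.nt_start - a.nt_end)
            if ok:
                best = max(best, val)
    return best


class TestCallCandidates:
    def test_all_blocks_in_order_single_candidate(self):
        hits = [_mk_hit(b, 300 * b) for b in range(10)]
        out = call_candidates(hits, 10, 6, 0.001)
        assert len(out) == 1 and out[0].matched_in_order == 10

    def test_swapping_two_blocks_drops_count_to_eight(self):
        # genomic order of blocks (1-based): 1,2,7,4,5,6,3,8,9,10
        order = [1, 2, 7, 4, 5, 6, 3, 8, 9, 10]
        hits = [_mk_hit(blk - 1, 300 * pos) for pos, blk in enumerate(order)]
        out = call_candidates(hits, 10, 6, 0.001)
        assert out[0].matched_in_order == 8

    def test_below_k_min_not_called(self):
        hits = [_mk_hit(b, 300 * b) for b in range(5)]
        assert call_candidates(hits, 10, 6, 0.001) == []

    def test_reverse_strand_requires_decreasing_midpoints(self):
        hits = [_mk_hit(b, 300 * (9 - b), strand="-") for b in range(10)]
        out = call_candidates(hits, 10, 6, 0.001)
        assert len(out) == 1 and out[0].strand == "-"

    def test_matched_in_order_bounded(self, rng):
        for _ in range(50):
            hits = [_mk_hit(int(rng.integers(0, 6)),
                            int(rng.integers(0, 900)) * 3,
                            score=float(rng.uniform(5, 60)))
                    for _ in range(int(rng.integers(1, 9)))]
            out = call_candidates(hits, 6, 1, 1.0)
            for c in out:
                assert c.matched_in_order <= len({h.block for h in hits})
                mids = [h.nt_mid for h in c.hits]
                assert mids == sorted(mids)

    def test_agrees_with_exhaustive_enumeration(self, rng):
        for _ in range(200):
            hits = [_mk_hit(int(rng.integers(0, 6)),
                            int(rng.integers(0, 900)) * 3,
                            length=int(rng.integers(10, 30)) * 3,
                            score=float(rng.uniform(5, 60)))
                    for _ in range(int(rng.integers(1, 11)))]
            out = call_candidates(hits, 6, 1, 1.0)
            count, score = brute_force_best_subset(hits)
            assert out[0].matched_in_order == count
            assert out[0].total_score == pytest.approx(score)

    def test_k_min_validation(self):
        with pytest.raises(ValidationError):
            call_candidates([], 10, 0, 0.001)


class TestChainGeneModel:
    def test_single_hit_chain(self):
        h = _mk_hit(0, 300)
        res = chain_gene_model([h])
        assert res.hits == [h] and res.protein == h.aa

    def test_higher_scoring_alternative_wins(self):
        h1 = _mk_hit(0, 300, score=30.0)
        h2 = _mk_hit(0, 900, score=20.0)
        h3 = _mk_hit(1, 1500, score=10.0)
        res = chain_gene_model([h1, h2, h3])
        assert res.hits == [h1, h3]

    def test_agrees_with_exhaustive_enumeration(self, rng):
        for _ in range(200):
            hits = [_mk_hit(int(rng.integers(0, 6)),
                            int(rng.integers(0, 900)) * 3,
                            length=int(rng.integers(10, 30)) * 3,
                            score=float(rng.uniform(5, 60)))
                    for _ in range(int(rng.integers(1, 11)))]
            res = chain_gene_model(hits, gap_penalty=1e-3)
            assert res.score == pytest.approx(
                brute_force_best_chain(hits, 1e-3))

    def test_empty_input_warns(self):
        res = chain_gene_model([])
        assert res.hits == [] and res.warnings

    def test_gapped_model_warning_lists_missing_blocks(self):
        res = chain_gene_model([_mk_hit(0, 0), _mk_hit(2, 600)], n_blocks=4)
        assert any("1, 3" in w or "[1, 3]" in w for w in res.warnings)

    def test_stitched_mrna_translates_to_protein(self, hmms):
        h = hmms[0]
        rng = np.random.default_rng(3)
        cons = _consensus(h)
        genome = {"s": _reverse_translate(cons, rng)}
        hits = scan_genome([h], genome, e_cutoff=0.001)
        hit = [x for x in hits if x.strand == "+"][0]
        res = chain_gene_model([hit], scaffold_seq=genome["s"])
        assert str(Seq(res.mrna).translate()) == res.protein == cons
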
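"""Six-frame genome scanning, ordered k-of-n candidate calling, hit chaining.

Scaffolds are conceptually translated in all six reading frames, split into
stop-free segments, and every segment is scored against every block profile.
A scaffold becomes a gene candidate when at least ``k_min`` of the ``n``
block profiles hit it with E <= cutoff *in the genomic order matching block
order* (strictly increasing hit midpoints by block index on the + strand,
strictly decreasing on -). Candidate hits are then chained into a gene model
by collinear dynamic programming and stitched into protein/mRNA sequences.

Coordinates are 0-based half-open on the forward strand throughout; a hit of
``a`` residues always spans ``3a`` nucleotides.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

from .alphabet import (STOP_CODE, codon_aa_table, decode_protein, encode_nt,
                       revcomp_codes)
from .errors import UncalibratedError, ValidationError
from .phmm import ProfileHMM, evalues_array

GenomeLike = Union[str, Path, Mapping[str, str], Iterable[tuple[str, str]]]


def as_scaffold_dict(genome: GenomeLike) -> dict[str, str]:
    """Accept a FASTA path, a mapping, or (id, seq) pairs."""
    if isinstance(genome, (str, Path)):
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(str(genome), "fasta")}
    if isinstance(genome, Mapping):
        return {k: v.upper() for k, v in genome.items()}
    return {k: v.upper() for k, v in genome}


@dataclass
class FrameSegment:
    """One stop-free run of one reading frame of one scaffold."""
    scaffold: str
    strand: str                  # '+' or '-'
    frame: int                   # 0..2, offset into the (rc-)sequence
    aa: str                      # stop-free amino acids (N codons -> X)
    nt_start: int                # forward-strand interval [nt_start, nt_end)
    nt_end: int
    aa_start: int                # segment start in frame-local aa coords

    def __post_init__(self):
        if 3 * len(self.aa) != self.nt_end - self.nt_start:
            raise ValidationError("segment nt span must be 3x aa length")


@dataclass
class HmmHit:
    """One block-profile match on one translated frame."""
    block: int
    scaffold: str
    strand: str
    frame: int
    aa_start: int               # frame-local aa interval [aa_start, aa_end)
    aa_end: int
    nt_start: int               # forward-strand nt interval
    nt_end: int
    score: float                # bits
    evalue: float
    aa: str = ""                # matched residues

    @property
    def nt_mid(self) -> float:
        return 0.5 * (self.nt_start + self.nt_end)


@dataclass
class GeneCandidate:
    """A scaffold-level gene call satisfying the ordered k-of-n rule."""
    scaffold: str
    strand: str
    hits: list[HmmHit]
    matched_in_order: int
    total_score: float
    nt_start: int
    nt_end: int


@dataclass
class ChainResult:
    hits: list[HmmHit]
    score: float
    protein: str
    mrna: str
    warnings: list[str] = field(default_factory=list)


# --- translation ----------------------------------------------------------

def _frame_codes(enc: np.ndarray, offset: int, codon_table: np.ndarray
                 ) -> np.ndarray:
    """Translate one frame of an encoded strand; returns residue codes
    (STOP_CODE at stops, X for N-containing codons)."""
    n = (enc.shape[0] - offset) // 3
    if n <= 0:
        return np.empty(0, dtype=np.uint8)
    codons = enc[offset:offset + 3 * n].reshape(n, 3).astype(np.int64)
    ambiguous = (codons >= 4).any(axis=1)
    idx = 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2]
    idx[ambiguous] = 0
    aa = codon_table[idx].copy()
    aa[ambiguous] = 20  # X
    return aa


def _segments_of_frame(aa_codes: np.ndarray) -> list[tuple[int, int]]:
    """Maximal stop-free [start, end) runs with at least one residue."""
    stops = np.flatnonzero(aa_codes == STOP_CODE)
    bounds = np.concatenate([[-1], stops, [aa_codes.shape[0]]])
    return [(int(a) + 1, int(b)) for a, b in zip(bounds[:-1], bounds[1:])
            if b - a > 1]


def _iter_frames(enc: np.ndarray, codon_table: np.ndarray):
    """Yield (strand, frame, frame_codes) for all six frames."""
    rc = revcomp_codes(enc)
    for strand, arr in (("+", enc), ("-", rc)):
        for frame in range(3):
            yield strand, frame, _frame_codes(arr, frame, codon_table)


def _nt_interval(strand: str, frame: int, aa_start: int, aa_end: int,
                 scaffold_len: int) -> tuple[int, int]:
    """Forward-strand nt interval of frame-local aa interval [aa_start, aa_end)."""
    lo = frame + 3 * aa_start
    hi = frame + 3 * aa_end
    if strand == "+":
        return lo, hi
    return scaffold_len - hi, scaffold_len - lo


def six_frame_translate(scaffold: str, code_id: int = 1,
                        scaffold_id: str = "scaffold"
                        ) -> list[FrameSegment]:
    """Conceptually translate a scaffold in six frames, split at stops."""
    if len(scaffold) < 3:
        return []
    enc = encode_nt(scaffold)
    table = codon_aa_table(code_id)
    out = []
    for strand, frame, codes in _iter_frames(enc, table):
        for a, b in _segments_of_frame(codes):
            nt_start, nt_end = _nt_interval(strand, frame, a, b, len(scaffold))
            out.append(FrameSegment(
                scaffold=scaffold_id, strand=strand, frame=frame,
                aa=decode_protein(codes[a:b]), nt_start=nt_start,
                nt_end=nt_end, aa_start=a))
    return out


# --- scanning -------------------------------------------------------------

class _TranslatedScaffold:
    """Per-scaffold translation prepared for batch kernel scoring."""

    __slots__ = ("scaffold_id", "length", "frames", "n_segments")

    def __init__(self, scaffold_id: str, seq: str, codon_table: np.ndarray):
        self.scaffold_id = scaffold_id
        self.length = len(seq)
        self.frames = []   # (strand, frame, codes, offsets array)
        self.n_segments = 0
        if self.length >= 3:
            enc = encode_nt(seq)
            for strand, frame, codes in _iter_frames(enc, codon_table):
                segs = _segments_of_frame(codes)
                if not segs:
                    continue
                offsets = np.empty(2 * len(segs), dtype=np.int64)
                offsets[0::2] = [a for a, _ in segs]
                offsets[1::2] = [b for _, b in segs]
                self.frames.append((strand, frame, codes, segs))
                self.n_segments += len(segs)


def scan_genome(hmms: Sequence[ProfileHMM], genome: GenomeLike,
                e_cutoff: float = 0.001, top_m: int = 2,
                code_id: int = 1) -> list[HmmHit]:
    """Score every (segment, profile) pair; report hits with E <= cutoff.

    Per (scaffold, profile) only the ``top_m`` strongest passing hits are
    retained. The E-value database size is the total number of translated
    segments in this search, so output is independent of scaffold order.
    """
    if e_cutoff <= 0:
        raise ValidationError("e_cutoff must be > 0")
    for h in hmms:
        if h.calibration is None:
            raise UncalibratedError(f"profile '{h.name}' is not calibrated")
    scaffolds = as_scaffold_dict(genome)
    table = codon_aa_table(code_id)
    translated = [_TranslatedScaffold(sid, seq, table)
                  for sid, seq in scaffolds.items()]
    db_size = sum(t.n_segments for t in translated)
    if db_size == 0:
        return []

    hits: list[HmmHit] = []
    for t in translated:
        per_hmm: dict[int, list[HmmHit]] = {}
        for strand, frame, codes, segs in t.frames:
            starts = np.array([a for a, _ in segs], dtype=np.int64)
            ends = np.array([b for _, b in segs], dtype=np.int64)
            flat_offsets = _flatten_segments(starts, ends)
            for bi, hmm in enumerate(hmms):
                # one Viterbi kernel call over all segments of this frame
                sc, st, en = hmm.score_segments(codes, flat_offsets, "viterbi")
                seg_scores, seg_starts, seg_ends = _collect(sc, st, en, starts)
                evs = evalues_array(seg_scores, hmm, db_size)
                for k in np.flatnonzero(evs <= e_cutoff):
                    a = int(seg_starts[k])
                    b = int(seg_ends[k])
                    nt_start, nt_end = _nt_interval(strand, frame, a, b,
                                                    t.length)
                    per_hmm.setdefault(bi, []).append(HmmHit(
                        block=bi, scaffold=t.scaffold_id, strand=strand,
                        frame=frame, aa_start=a, aa_end=b,
                        nt_start=nt_start, nt_end=nt_end,
                        score=float(seg_scores[k]), evalue=float(evs[k]),
                        aa=decode_protein(codes[a:b])))
        for bi in sorted(per_hmm):
            block_hits = sorted(per_hmm[bi],
                                key=lambda h: (-h.score, h.nt_start))
            hits.extend(block_hits[:top_m])
    hits.sort(key=lambda h: (h.scaffold, h.block, -h.score, h.nt_start))
    return hits


def _flatten_segments(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Interleave [start, end) runs into a kernel offsets array.

    The kernel scores seq[offsets[i]:offsets[i+1]] for every i; inter-segment
    gaps (the stop codons) appear as length-1 throwaway runs that are
    discarded by :func:`_collect`.
    """
    out = np.empty(2 * starts.shape[0], dtype=np.int64)
    out[0::2] = starts
    out[1::2] = ends
    return out


def _collect(scores, starts, ends, seg_starts):
    """Keep every other kernel run (the real segments) and shift the
    segment-local alignment coordinates to frame-local ones."""
    sc = scores[0::2]
    st = starts[0::2] + seg_starts
    en = ends[0::2] + seg_starts
    return sc, st, en


# --- ordered k-of-n candidate calling ------------------------------------

def _best_ordered_subset(hits: list[HmmHit], increasing: bool
                         ) -> tuple[list[HmmHit], float]:
    """Heaviest collinear subset: at most one hit per block, block indices
    strictly increasing, nt midpoints strictly monotone. Maximizes hit count,
    ties broken by total bit score."""
    sign = 1.0 if increasing else -1.0
    order = sorted(range(len(hits)),
                   key=lambda i: (hits[i].block, sign * hits[i].nt_mid))
    count = [1] * len(order)
    score = [hits[i].score for i in order]
    prev = [-1] * len(order)
    for a in range(len(order)):
        ha = hits[order[a]]
        for b in range(a):
            hb = hits[order[b]]
            if hb.block >= ha.block:
                continue
            if sign * hb.nt_mid >= sign * ha.nt_mid:
                continue
            cand_count = count[b] + 1
            cand_score = score[b] + ha.score
            if (cand_count, cand_score) > (count[a], score[a]):
                count[a] = cand_count
                score[a] = cand_score
                prev[a] = b
    if not order:
        return [], 0.0
    best = max(range(len(order)), key=lambda a: (count[a], score[a]))
    chain = []
    a = best
    while a != -1:
        chain.append(hits[order[a]])
        a = prev[a]
    chain.reverse()
    return chain, score[best]


def call_candidates(hits: Sequence[HmmHit], n_blocks: int, k_min: int,
                    e_cutoff: float, same_strand: bool = True
                    ) -> list[GeneCandidate]:
    """Call gene candidates with the ordered k-of-n co-occurrence rule.

    Per scaffold and strand (or per scaffold pooled over strands when
    ``same_strand`` is False), the heaviest collinear subset of passing hits
    is found; a candidate is emitted iff it covers >= ``k_min`` blocks.
    """
    if not (1 <= k_min <= n_blocks):
        raise ValidationError("need 1 <= k_min <= n_blocks")
    passing = [h for h in hits if h.evalue <= e_cutoff and h.block < n_blocks]
    groups: dict[tuple, list[HmmHit]] = {}
    for h in passing:
        key = (h.scaffold, h.strand) if same_strand else (h.scaffold,)
        groups.setdefault(key, []).append(h)

    candidates = []
    for key in sorted(groups):
        ghits = groups[key]
        if same_strand:
            strand = key[1]
            chain, total = _best_ordered_subset(ghits, strand == "+")
        else:
            fwd = _best_ordered_subset(ghits, True)
            rev = _best_ordered_subset(ghits, False)
            chain, total = max(fwd, rev, key=lambda c: (len(c[0]), c[1]))
            strand = chain[0].strand if chain else "+"
        if len(chain) >= k_min:
            candidates.append(GeneCandidate(
                scaffold=key[0], strand=strand, hits=chain,
                matched_in_order=len(chain), total_score=total,
                nt_start=min(h.nt_start for h in chain),
                nt_end=max(h.nt_end for h in chain)))
    candidates.sort(key=lambda c: (-c.total_score, c.scaffold, c.strand))
    return candidates


# --- gene-model chaining --------------------------------------------------

def _chain_ok(h1: HmmHit, h2: HmmHit, strand: str) -> Optional[int]:
    """Gap (nt) between consecutive chain hits, or None if not chainable."""
    if h2.block <= h1.block:
        return None
    if strand == "+":
        gap = h2.nt_start - h1.nt_end
    else:
        gap = h1.nt_start - h2.nt_end
    return gap if gap >= 0 else None


def chain_gene_model(hits: Sequence[HmmHit], gap_penalty: float = 1e-4,
                     scaffold_seq: Optional[str] = None,
                     n_blocks: Optional[int] = None) -> ChainResult:
    """Chain block hits of one scaffold/strand into a gene model.

    Maximizes sum(bit scores) - gap_penalty * sum(inter-hit nt gaps) over
    chains with strictly increasing block index and non-overlapping,
    collinear genomic intervals. The stitched protein concatenates matched
    residues in chain order; the mRNA concatenates the genomic slices (on
    the gene's strand) when ``scaffold_seq`` is given.
    """
    hits = list(hits)
    warnings: list[str] = []
    if not hits:
        return ChainResult([], 0.0, "", "", ["no hits to chain"])
    if len({h.scaffold for h in hits}) > 1 or len({h.strand for h in hits}) > 1:
        raise ValidationError("chain hits must share scaffold and strand")
    strand = hits[0].strand
    sign = 1.0 if strand == "+" else -1.0
    order = sorted(range(len(hits)),
                   key=lambda i: (hits[i].block, sign * hits[i].nt_mid))
    val = [hits[i].score for i in order]
    prev = [-1] * len(order)
    for a in range(len(order)):
        ha = hits[order[a]]
        for b in range(a):
            hb = hits[order[b]]
            gap = _chain_ok(hb, ha, strand)
            if gap is None:
                continue
            cand = val[b] + ha.score - gap_penalty * gap
            if cand > val[a]:
                val[a] = cand
                prev[a] = b
    best = max(range(len(order)), key=lambda a: val[a])
    chain = []
    a = best
    while a != -1:
        chain.append(hits[order[a]])
        a = prev[a]
    chain.reverse()

    covered = {h.block for h in chain}
    if n_blocks is not None:
        missing = sorted(set(range(n_blocks)) - covered)
        if missing:
            warnings.append(f"gapped model: unmatched blocks {missing}")
    protein = "".join(h.aa for h in chain)
    mrna = ""
    if scaffold_seq is not None:
        from .alphabet import reverse_complement
        parts = []
        for h in chain:
            piece = scaffold_seq[h.nt_start:h.nt_end]
            parts.append(reverse_complement(piece) if strand == "-" else piece)
        mrna = "".join(parts)
    return ChainResult(chain, float(val[best]), protein, mrna, warnings)
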
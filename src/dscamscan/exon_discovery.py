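"""Hypervariable-exon discovery in intronic regions between anchor exons.

The mutually exclusive alternative-splicing clusters (Ig2, Ig3, Ig7) sit as
tandem exon-variant arrays inside the introns between constant "anchor"
exons of a Dscam-hv gene. Each intronic region is translated in all six
reading frames — so an inverted (opposite-strand) exon variant is still
detected and flagged — and scanned with the cluster's profile HMM(s).
Overlapping hits are resolved greedily by ascending E-value.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alphabet import reverse_complement
from .errors import UncalibratedError, ValidationError
from .genome_scan import GenomeLike, as_scaffold_dict, six_frame_translate
from .phmm import ProfileHMM, evalues_array

CLUSTERS = ("Ig2", "Ig3", "Ig7")


@dataclass
class IntronicRegion:
    """The interval between two consecutive anchor exons of one cluster."""
    scaffold: str
    cluster: str
    start: int                 # forward-strand [start, end)
    end: int
    strand: str = "+"          # host-gene strand

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError("region start must be <= end")


@dataclass
class ExonVariantHit:
    cluster: str
    scaffold: str
    nt_start: int              # forward-strand interval within the region
    nt_end: int
    strand: str                # strand of the matching frame
    frame: int
    score: float
    evalue: float
    inverted: bool             # hit strand opposite to the host gene strand
    nt_seq: str                # genome slice, reverse-complemented if the
                               # hit is on the - strand of the forward axis


def extract_intronic_regions(anchors: Mapping[str, Sequence[tuple[int, int]]],
                             scaffold: str,
                             genome: Optional[GenomeLike] = None,
                             strand: str = "+") -> list[IntronicRegion]:
    """One region per consecutive anchor pair per cluster.

    ``anchors`` maps a cluster label to the ordered, non-overlapping anchor
    exon intervals flanking it; empty regions (adjacent anchors) are dropped.
    """
    scaffold_len = None
    if genome is not None:
        scaffolds = as_scaffold_dict(genome)
        if scaffold not in scaffolds:
            raise ValidationError(f"no scaffold '{scaffold}' in genome")
        scaffold_len = len(scaffolds[scaffold])
    regions = []
    for cluster, intervals in anchors.items():
        intervals = list(intervals)
        for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
            if b1 > a2 or a1 >= b1 or a2 >= b2:
                raise ValidationError(
                    f"anchors for '{cluster}' must be ordered and "
                    "non-overlapping")
            if scaffold_len is not None and b2 > scaffold_len:
                raise ValidationError(
                    f"anchor [{a2}, {b2}) exceeds scaffold '{scaffold}'")
            if b1 < a2:
                regions.append(IntronicRegion(
                    scaffold=scaffold, cluster=cluster, start=b1, end=a2,
                    strand=strand))
    return regions


def _overlap_frac(a: ExonVariantHit, b: ExonVariantHit) -> float:
    inter = min(a.nt_end, b.nt_end) - max(a.nt_start, b.nt_start)
    if inter <= 0:
        return 0.0
    shorter = min(a.nt_end - a.nt_start, b.nt_end - b.nt_start)
    return inter / shorter


def scan_exon_variants(cluster_hmms: Mapping[str, Union[ProfileHMM,
                                                        Sequence[ProfileHMM]]],
                       regions: Sequence[IntronicRegion],
                       genome: GenomeLike,
                       e_cutoff: float = 0.001,
                       code_id: int = 1) -> list[ExonVariantHit]:
    """Six-frame scan of intronic regions for exon variants.

    Per cluster, the E-value database size is the number of translated
    segments over all that cluster's regions. Hits with E <= cutoff are
    resolved greedily by ascending E-value: a hit overlapping a kept hit by
    more than 50% of the shorter interval is discarded.
    """
    if e_cutoff <= 0:
        raise ValidationError("e_cutoff must be > 0")
    scaffolds = as_scaffold_dict(genome)
    hmm_sets: dict[str, list[ProfileHMM]] = {}
    for label, hs in cluster_hmms.items():
        hmm_sets[label] = [hs] if isinstance(hs, ProfileHMM) else list(hs)
        for h in hmm_sets[label]:
            if h.calibration is None:
                raise UncalibratedError(
                    f"profile '{h.name}' is not calibrated")

    # translate every region once
    region_segments = []
    per_cluster_db: dict[str, int] = {}
    for ri, region in enumerate(regions):
        seq = scaffolds[region.scaffold][region.start:region.end]
        segs = six_frame_translate(seq, code_id=code_id,
                                   scaffold_id=region.scaffold)
        region_segments.append(segs)
        per_cluster_db[region.cluster] = (
            per_cluster_db.get(region.cluster, 0) + len(segs))

    raw: list[tuple[int, ExonVariantHit]] = []
    from .alphabet import encode_protein
    for ri, region in enumerate(regions):
        db = max(per_cluster_db.get(region.cluster, 1), 1)
        region_len = region.end - region.start
        for hmm in hmm_sets.get(region.cluster, ()):
            for seg in region_segments[ri]:
                codes = encode_protein(seg.aa)
                # a tandem array can put several exon variants into one
                # stop-free segment: take the best local hit, then recurse
                # into the flanking sub-intervals until nothing passes
                for sc, a, b, ev in _iterated_hits(hmm, codes, db, e_cutoff):
                    lo = seg.frame + 3 * (seg.aa_start + a)
                    hi = seg.frame + 3 * (seg.aa_start + b)
                    if seg.strand == "-":
                        lo, hi = region_len - hi, region_len - lo
                    nt_start = region.start + lo
                    nt_end = region.start + hi
                    slice_nt = scaffolds[region.scaffold][nt_start:nt_end]
                    if seg.strand == "-":
                        slice_nt = reverse_complement(slice_nt)
                    raw.append((ri, ExonVariantHit(
                        cluster=region.cluster, scaffold=region.scaffold,
                        nt_start=nt_start, nt_end=nt_end, strand=seg.strand,
                        frame=seg.frame, score=sc, evalue=ev,
                        inverted=(seg.strand != region.strand),
                        nt_seq=slice_nt)))

    # greedy overlap resolution per region
    kept: list[ExonVariantHit] = []
    for ri in range(len(regions)):
        mine = sorted((h for r, h in raw if r == ri),
                      key=lambda h: (h.evalue, -h.score, h.nt_start))
        chosen: list[ExonVariantHit] = []
        for h in mine:
            if all(_overlap_frac(h, k) <= 0.5 for k in chosen):
                chosen.append(h)
        kept.extend(sorted(chosen, key=lambda h: h.nt_start))
    return kept


def _iterated_hits(hmm: ProfileHMM, codes: np.ndarray, db: int,
                   e_cutoff: float) -> list[tuple[float, int, int, float]]:
    """Non-overlapping passing local hits of one profile on one segment.

    Best-hit-then-split recursion: the optimal local alignment is recorded
    and the intervals left and right of it are searched independently.
    Returns (score, aa_start, aa_end, evalue) tuples.
    """
    out = []
    stack = [(0, len(codes))]
    while stack:
        a, b = stack.pop()
        if b - a < 1:
            continue
        offs = np.array([a, b], dtype=np.int64)
        sc, st, en = hmm.score_segments(codes, offs, "viterbi")
        ev = float(evalues_array(sc, hmm, db)[0])
        if ev > e_cutoff:
            continue
        lo, hi = a + int(st[0]), a + int(en[0])
        out.append((float(sc[0]), lo, hi, ev))
        stack.append((a, lo))
        stack.append((hi, b))
    return out


def variant_summary(hits: Sequence[ExonVariantHit],
                    genome_label: str = "genome") -> pd.DataFrame:
    """Per-cluster variant counts (all canonical clusters always listed)."""
    counts: dict[str, int] = {c: 0 for c in CLUSTERS}
    for h in hits:
        counts[h.cluster] = counts.get(h.cluster, 0) + 1
    rows = [{"genome": genome_label, "cluster": c, "n_variants": n}
            for c, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["genome", "cluster", "n_variants"])
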
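"""Readers and writers for the pipeline's tabular and annotation formats.

Internally everything is 0-based half-open; GFF3 output converts to 1-based
inclusive at the boundary. TSV columns follow the hit table contract:
scaffold, block, strand, frame, nt_start, nt_end, score, evalue.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError
from .genome_scan import GeneCandidate, HmmHit


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70
                ) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def hits_to_frame(hits: Sequence[HmmHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"scaffold": h.scaffold, "block": h.block, "strand": h.strand,
          "frame": h.frame, "nt_start": h.nt_start, "nt_end": h.nt_end,
          "score": round(h.score, 4), "evalue": h.evalue}
         for h in hits],
        columns=["scaffold", "block", "strand", "frame", "nt_start",
                 "nt_end", "score", "evalue"])


def write_hits_tsv(path, hits: Sequence[HmmHit]) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _gff3_line(seqid, source, ftype, start0, end0, score, strand, attrs):
    score_s = "." if score is None else f"{score:.3f}"
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return (f"{seqid}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t{score_s}"
            f"\t{strand}\t.\t{attr_s}")


def write_hits_gff3(path, hits: Sequence[HmmHit],
                    source: str = "dscamscan") -> None:
    lines = ["##gff-version 3"]
    for i, h in enumerate(hits):
        lines.append(_gff3_line(
            h.scaffold, source, "protein_match", h.nt_start, h.nt_end,
            h.score, h.strand,
            {"ID": f"hit{i + 1}", "block": h.block, "frame": h.frame,
             "evalue": f"{h.evalue:.3g}"}))
    Path(path).write_text("\n".join(lines) + "\n")


def write_candidates_gff3(path, candidates: Sequence[GeneCandidate],
                          source: str = "dscamscan") -> None:
    lines = ["##gff-version 3"]
    for ci, c in enumerate(candidates):
        gid = f"candidate{ci + 1}"
        lines.append(_gff3_line(
            c.scaffold, source, "gene", c.nt_start, c.nt_end,
            c.total_score, c.strand,
            {"ID": gid, "matched_in_order": c.matched_in_order}))
        for h in c.hits:
            lines.append(_gff3_line(
                c.scaffold, source, "protein_match", h.nt_start, h.nt_end,
                h.score, h.strand,
                {"Parent": gid, "block": h.block, "frame": h.frame,
                 "evalue": f"{h.evalue:.3g}"}))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_gff3(path, features, source: str = "dscamscan-synthetic"
                     ) -> None:
    lines = ["##gff-version 3"]
    for fi, f in enumerate(features):
        fid = f"{f.kind}{fi + 1}"
        lo, hi = f.span
        lines.append(_gff3_line(
            f.scaffold, source, "region", lo, hi, None, f.strand,
            {"ID": fid, "kind": f.kind, "source_id": f.source_id,
             **({"cluster": f.cluster} if f.cluster else {})}))
        for a, b in f.exon_intervals:
            lines.append(_gff3_line(
                f.scaffold, source, "exon", a, b, None, f.strand,
                {"Parent": fid}))
    Path(path).write_text("\n".join(lines) + "\n")


def write_variants(prefix, hits) -> dict[str, Path]:
    """FASTA + GFF3 + TSV summary for exon-variant hits; prefix is a path
    stem."""
    from .exon_discovery import variant_summary
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fasta")
    gff = prefix.with_suffix(".gff3")
    tsv = prefix.with_suffix(".tsv")
    write_fasta(fasta, [
        (f"{h.cluster}_{h.scaffold}_{h.nt_start}_{h.nt_end}_{h.strand}",
         h.nt_seq) for h in hits])
    lines = ["##gff-version 3"]
    for i, h in enumerate(hits):
        lines.append(_gff3_line(
            h.scaffold, "dscamscan", "exon", h.nt_start, h.nt_end, h.score,
            h.strand,
            {"ID": f"variant{i + 1}", "cluster": h.cluster,
             "inverted": str(h.inverted).lower(),
             "evalue": f"{h.evalue:.3g}"}))
    gff.write_text("\n".join(lines) + "\n")
    variant_summary(hits).to_csv(tsv, sep="\t", index=False)
    return {"fasta": fasta, "gff3": gff, "tsv": tsv}


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader: chrom, start, end, optional name."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{ln}: BED needs >= 3 columns")
        out.append((parts[0], int(parts[1]), int(parts[2]),
                    parts[3] if len(parts) > 3 else ""))
    return out
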
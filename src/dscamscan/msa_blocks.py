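"""Conserved-block extraction from exon-annotated protein alignments.

The gene-family search rests on short, highly conserved stretches of a
protein alignment that do not cross any member's exon boundary: an intron
interrupts translation, so a profile built across a boundary could never
match a single translated genomic segment. Blocks are chosen greedily by a
deterministic conservation score (mean per-column majority-residue identity,
gaps scoring 0) among boundary-free windows.

Also provides representative-leaf selection on a guide tree for building
exon-cluster profile training sets (one medoid leaf per clade obtained by
cutting the tree at a height threshold).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import AlignIO

from .errors import FormatError, ValidationError

GAP_CHARS = ("-", ".")


@dataclass
class AnnotatedAlignment:
    """A protein multiple alignment with per-sequence exon boundaries.

    ``boundaries[seq_id]`` lists 0-based positions in that sequence's
    *ungapped* coordinates; boundary ``b`` falls immediately before residue
    ``b``.
    """
    sequences: list[tuple[str, str]]
    boundaries: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise ValidationError("alignment needs at least 2 sequences")
        ncol = len(self.sequences[0][1])
        if ncol < 1:
            raise ValidationError("alignment must have at least one column")
        for sid, row in self.sequences:
            if len(row) != ncol:
                raise FormatError(f"ragged alignment at sequence '{sid}'")
        ids = {sid for sid, _ in self.sequences}
        for sid, bl in self.boundaries.items():
            if sid not in ids:
                raise ValidationError(f"boundary row for unknown id '{sid}'")
            ug = self.ungapped_length(sid)
            if any(b2 <= b1 for b1, b2 in zip(bl, bl[1:])):
                raise ValidationError(
                    f"boundaries for '{sid}' must be strictly increasing")
            if any(b < 0 or b > ug for b in bl):
                raise ValidationError(
                    f"boundary out of range for '{sid}' (ungapped length {ug})")
        for sid, _ in self.sequences:
            self.boundaries.setdefault(sid, [])

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    def row(self, sid: str) -> str:
        for s, r in self.sequences:
            if s == sid:
                return r
        raise KeyError(sid)

    def ungapped_length(self, sid: str) -> int:
        return sum(1 for c in self.row(sid) if c not in GAP_CHARS)

    def column_to_ungapped(self, sid: str) -> np.ndarray:
        """Residues consumed up to (excluding) each column, per sequence."""
        row = self.row(sid)
        consumed = np.cumsum([0] + [0 if c in GAP_CHARS else 1 for c in row])
        return consumed  # length n_columns + 1

    def slice_columns(self, start: int, end: int) -> "AnnotatedAlignment":
        sub = [(sid, row[start:end]) for sid, row in self.sequences]
        out = object.__new__(AnnotatedAlignment)
        out.sequences = sub
        out.boundaries = {sid: [] for sid, _ in sub}
        return out


@dataclass
class BlockDefinition:
    """One ordered conserved block: a column interval of the alignment."""
    index: int
    start: int                      # [start, end) in alignment columns
    end: int
    sub_alignment: AnnotatedAlignment
    score: float = 0.0

    def to_json_dict(self) -> dict:
        return {"index": self.index, "start": self.start, "end": self.end,
                "score": self.score,
                "members": [sid for sid, _ in self.sub_alignment.sequences]}


def read_annotated_alignment(alignment_path, boundary_path=None
                             ) -> AnnotatedAlignment:
    """Read a FASTA or Stockholm alignment plus an optional boundary table.

    The boundary table is tab-separated: sequence id, comma-separated integer
    boundary positions (ungapped coordinates). Sequences absent from the
    table get an empty boundary list.
    """
    alignment_path = Path(alignment_path)
    fmt = None
    first = alignment_path.read_text().lstrip()[:11]
    if first.startswith(">"):
        fmt = "fasta"
    elif first.startswith("# STOCKHOLM"):
        fmt = "stockholm"
    else:
        raise FormatError(f"{alignment_path}: neither FASTA nor Stockholm")
    try:
        aln = AlignIO.read(str(alignment_path), fmt)
    except ValueError as exc:
        raise FormatError(f"{alignment_path}: {exc}") from exc
    sequences = [(rec.id, str(rec.seq)) for rec in aln]

    boundaries: dict[str, list[int]] = {}
    if boundary_path is not None:
        ids = {sid for sid, _ in sequences}
        for line in Path(boundary_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            sid = parts[0]
            if sid not in ids:
                raise ValidationError(
                    f"boundary table id '{sid}' not in alignment")
            vals = []
            if len(parts) > 1 and parts[1].strip():
                vals = [int(v) for v in parts[1].split(",")]
            boundaries[sid] = vals
    return AnnotatedAlignment(sequences=sequences, boundaries=boundaries)


# --- block extraction -----------------------------------------------------

def _conservation(aln: AnnotatedAlignment) -> np.ndarray:
    """Per-column majority-residue identity; gaps score 0."""
    mat = np.array([[c for c in row.upper()] for _, row in aln.sequences])
    n = mat.shape[0]
    scores = np.zeros(mat.shape[1])
    for col in range(mat.shape[1]):
        col_vals = mat[:, col]
        residues = col_vals[(col_vals != "-") & (col_vals != ".")]
        if residues.size == 0:
            continue
        _, counts = np.unique(residues, return_counts=True)
        scores[col] = counts.max() / n
    return scores


def _window_crosses_boundary(aln: AnnotatedAlignment, start: int, end: int,
                             consumed: dict[str, np.ndarray]) -> bool:
    for sid, _ in aln.sequences:
        c = consumed[sid]
        u_start, u_end = int(c[start]), int(c[end])
        for b in aln.boundaries.get(sid, ()):
            if u_start < b < u_end:
                return True
    return False


def extract_blocks(aln: AnnotatedAlignment, n_blocks: int, min_len: int,
                   max_len: int, warnings: Optional[list] = None
                   ) -> list[BlockDefinition]:
    """Greedy selection of up to ``n_blocks`` conserved, boundary-free windows.

    Candidate windows have length in [min_len, max_len]; score = mean column
    conservation; ties broken by leftmost start, then shorter window. Chosen
    windows never overlap. If fewer than ``n_blocks`` boundary-free windows
    exist, the shortfall is recorded in ``warnings`` (if given).
    """
    if n_blocks < 0:
        raise ValidationError("n_blocks must be >= 0")
    if n_blocks == 0:
        return []
    if not (1 <= min_len <= max_len <= aln.n_columns):
        raise ValidationError("need 1 <= min_len <= max_len <= n_columns")
    cons = _conservation(aln)
    csum = np.concatenate([[0.0], np.cumsum(cons)])
    consumed = {sid: aln.column_to_ungapped(sid) for sid, _ in aln.sequences}

    candidates = []   # (-score, start, length)
    for length in range(min_len, max_len + 1):
        for start in range(aln.n_columns - length + 1):
            end = start + length
            if _window_crosses_boundary(aln, start, end, consumed):
                continue
            score = (csum[end] - csum[start]) / length
            candidates.append((-score, start, length))
    candidates.sort()

    chosen: list[tuple[int, int, float]] = []
    for negscore, start, length in candidates:
        if len(chosen) == n_blocks:
            break
        end = start + length
        if any(start < e and s < end for s, e, _ in chosen):
            continue
        chosen.append((start, end, -negscore))
    if len(chosen) < n_blocks and warnings is not None:
        warnings.append(
            f"only {len(chosen)} boundary-free windows of length >= "
            f"{min_len} found (requested {n_blocks})")
    chosen.sort()
    return [BlockDefinition(index=i, start=s, end=e,
                            sub_alignment=aln.slice_columns(s, e), score=sc)
            for i, (s, e, sc) in enumerate(chosen)]


def write_blocks_json(blocks: Sequence[BlockDefinition], path) -> None:
    Path(path).write_text(json.dumps(
        [b.to_json_dict() for b in blocks], indent=2) + "\n")


# --- representative selection --------------------------------------------

def select_representatives(newick: str, height: float) -> list[str]:
    """One representative leaf per clade after cutting the tree at a height.

    The tree is cut at cumulative root distance (tree height - ``height``);
    each subtree hanging below the cut is a cluster (leaves closer to the
    root than the cut are their own clusters). The representative is the
    cluster medoid: the leaf with smallest mean patristic distance to the
    other cluster members, ties broken by lexicographic id.
    """
    if height < 0:
        raise ValidationError("height threshold must be >= 0")
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise FormatError(f"invalid Newick: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise FormatError("empty tree")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None:
            raise FormatError("tree has unlabeled leaves")

    depth = {}
    for nd in tree.preorder_node_iter():
        el = nd.edge.length or 0.0
        depth[nd] = (depth[nd.parent_node] if nd.parent_node else 0.0) + el
    tree_height = max(depth[lf] for lf in tree.leaf_node_iter())
    cutoff = tree_height - height

    clusters: list[list[str]] = []
    if cutoff <= 0:
        clusters.append([lf.taxon.label for lf in tree.leaf_node_iter()])
    else:
        def walk(nd):
            if depth[nd] >= cutoff:
                clusters.append([lf.taxon.label
                                 for lf in nd.leaf_iter()])
                return
            if nd.is_leaf():
                clusters.append([nd.taxon.label])
                return
            for ch in nd.child_nodes():
                walk(ch)
        walk(tree.seed_node)

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    reps = []
    for members in clusters:
        if len(members) == 1:
            reps.append(members[0])
            continue
        best = None
        for m in sorted(members):
            mean_d = float(np.mean([
                pdm.patristic_distance(taxa[m], taxa[o])
                for o in members if o != m]))
            if best is None or mean_d < best[0] - 1e-12:
                best = (mean_d, m)
        reps.append(best[1])
    return sorted(reps)
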
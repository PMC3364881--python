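"""Seeded synthetic genomes with truth annotations.

Emulates the statistical structure the detection pipeline assumes: random-
composition scaffolds (negative controls), planted multi-exon genes derived
from a source protein (introns open with GT, close with AG, and contain an
in-frame stop near their 5' end, which is what confines block profiles to
single exons), and tandem arrays of diverged exon variants standing in for
the mutually exclusive alternative-splicing clusters.

Every generator is a pure function of (spec, seed): identical inputs yield
byte-identical genomes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .alphabet import (AA_LETTERS, decode_nt, reverse_complement,
                       robinson_background, stop_codons, synonymous_codons)
from .errors import PlacementError, ValidationError

_NT = "ACGT"


@dataclass
class PlantSpec:
    """A multi-exon gene to plant: source protein, exon/intron plan, site."""
    source_protein: str
    exon_plan: list[int]               # exon lengths in aa, sums to protein
    intron_lengths: list[int]          # nt, one fewer than exons, each >= 8
    mutation_rate: float               # per-nt substitution probability
    scaffold: str
    offset: int
    strand: str = "+"
    source_id: str = "gene"

    def __post_init__(self):
        if sum(self.exon_plan) != len(self.source_protein):
            raise ValidationError("exon plan must sum to protein length")
        if len(self.intron_lengths) != len(self.exon_plan) - 1:
            raise ValidationError("need len(introns) = len(exons) - 1")
        if any(l < 8 for l in self.intron_lengths):
            raise ValidationError("introns need >= 8 nt for GT..stop..AG")
        if not (0 <= self.mutation_rate < 1):
            raise ValidationError("mutation rate must be in [0, 1)")
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")


@dataclass
class SyntheticGenomeSpec:
    n_scaffolds: int
    scaffold_len: int
    gc: float = 0.5
    seed: int = 0
    plants: list[PlantSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.n_scaffolds < 1:
            raise ValidationError("n_scaffolds must be >= 1")
        if self.scaffold_len < 3:
            raise ValidationError("scaffold_len must be >= 3")
        if not (0.0 <= self.gc <= 1.0):
            raise ValidationError("gc must be in [0, 1]")


@dataclass
class TruthFeature:
    """One planted feature with its exact genomic intervals."""
    kind: str                          # 'gene' or 'exon_array'
    scaffold: str
    strand: str
    exon_intervals: list[tuple[int, int]]
    source_id: str
    mutations: int = 0
    cluster: Optional[str] = None      # exon arrays only

    @property
    def span(self) -> tuple[int, int]:
        return (min(a for a, _ in self.exon_intervals),
                max(b for _, b in self.exon_intervals))


@dataclass
class SyntheticGenome:
    scaffolds: dict[str, str]
    features: list[TruthFeature] = field(default_factory=list)

    def occupied(self, scaffold: str) -> list[tuple[int, int]]:
        out = []
        for f in self.features:
            if f.scaffold == scaffold:
                lo = min(a for a, _ in f.exon_intervals)
                hi = max(b for _, b in f.exon_intervals)
                out.append((lo, hi))
        return out


def scaffold_name(i: int) -> str:
    return f"scaffold_{i + 1:05d}"


def random_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """I.i.d. nucleotides with P(G or C) = gc, split evenly; seeded."""
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2,
                  (1 - spec.gc) / 2])
    scaffolds = {}
    for i in range(spec.n_scaffolds):
        codes = rng.choice(4, size=spec.scaffold_len, p=p).astype(np.uint8)
        scaffolds[scaffold_name(i)] = decode_nt(codes)
    genome = SyntheticGenome(scaffolds=scaffolds)
    for k, plant in enumerate(spec.plants):
        genome = plant_gene(genome, plant, seed=spec.seed + 1 + k)
    return genome


def _reverse_translate(protein: str, rng: np.random.Generator,
                       code_id: int = 1) -> str:
    syn = synonymous_codons(code_id)
    return "".join(syn[a][rng.integers(0, len(syn[a]))] for a in protein)


def _mutate(seq: str, rate: float, rng: np.random.Generator
            ) -> tuple[str, int]:
    """Per-nt substitution at ``rate``, uniform over the 3 alternatives."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.shape[0]) < rate)
    for i in hit:
        alternatives = [b for b in _NT if b != chr(arr[i])]
        arr[i] = ord(alternatives[rng.integers(0, 3)])
    return arr.tobytes().decode(), int(hit.size)


def _check_placement(genome: SyntheticGenome, scaffold: str, start: int,
                     end: int) -> None:
    if scaffold not in genome.scaffolds:
        raise PlacementError(f"no scaffold '{scaffold}'")
    if start < 0 or end > len(genome.scaffolds[scaffold]):
        raise PlacementError(
            f"feature [{start}, {end}) exceeds scaffold '{scaffold}'")
    for lo, hi in genome.occupied(scaffold):
        if start < hi and lo < end:
            raise PlacementError(
                f"feature [{start}, {end}) overlaps planted [{lo}, {hi})")


def _make_intron(length: int, rng: np.random.Generator) -> str:
    """GT ... AG intron whose first in-frame codon (phase 0) is a stop.

    Layout: GT + A + TAA + random + AG, so reading on from the upstream exon
    (which ends at a codon boundary) hits a stop within the first 6 nt.
    """
    middle = "".join(_NT[rng.integers(0, 4)] for _ in range(length - 8))
    return "GTA" + "TAA" + middle + "AG"


def plant_gene(genome: SyntheticGenome, plant: PlantSpec, seed: int
               ) -> SyntheticGenome:
    """Insert a multi-exon gene; returns a new genome with a truth record."""
    rng = np.random.default_rng(seed)
    cds = _reverse_translate(plant.source_protein, rng)
    exon_nt = []
    pos = 0
    for aa_len in plant.exon_plan:
        exon_nt.append(cds[3 * pos:3 * (pos + aa_len)])
        pos += aa_len
    pieces = []
    local_exons = []     # gene-local intervals
    cursor = 0
    for i, exon in enumerate(exon_nt):
        local_exons.append((cursor, cursor + len(exon)))
        pieces.append(exon)
        cursor += len(exon)
        if i < len(plant.intron_lengths):
            intron = _make_intron(plant.intron_lengths[i], rng)
            pieces.append(intron)
            cursor += len(intron)
    gene = "".join(pieces)
    gene, n_mut = _mutate(gene, plant.mutation_rate, rng)

    start = plant.offset
    end = start + len(gene)
    _check_placement(genome, plant.scaffold, start, end)
    insert = gene if plant.strand == "+" else reverse_complement(gene)
    if plant.strand == "+":
        fwd_exons = [(start + a, start + b) for a, b in local_exons]
    else:
        fwd_exons = [(start + len(gene) - b, start + len(gene) - a)
                     for a, b in local_exons]
        fwd_exons.reverse()
    seq = genome.scaffolds[plant.scaffold]
    new_seq = seq[:start] + insert + seq[end:]
    scaffolds = dict(genome.scaffolds)
    scaffolds[plant.scaffold] = new_seq
    feature = TruthFeature(kind="gene", scaffold=plant.scaffold,
                           strand=plant.strand, exon_intervals=fwd_exons,
                           source_id=plant.source_id, mutations=n_mut)
    return SyntheticGenome(scaffolds=scaffolds,
                           features=genome.features + [feature])


def _mutate_exon_no_stop(exon: str, rate: float, rng: np.random.Generator,
                         code_id: int = 1) -> str:
    """Mutate an exon, resampling substitutions that create in-frame stops."""
    stops = set(stop_codons(code_id))
    out, _ = _mutate(exon, rate, rng)
    chars = list(out)
    for _ in range(100):
        bad = [i for i in range(0, len(chars) - 2, 3)
               if "".join(chars[i:i + 3]) in stops]
        if not bad:
            break
        for i in bad:
            j = i + int(rng.integers(0, 3))
            chars[j] = _NT[rng.integers(0, 4)]
    return "".join(chars)


def plant_exon_array(genome: SyntheticGenome, base_exon: str, n_variants: int,
                     divergence: float, spacer_len: int,
                     scaffold: str, offset: int, seed: int,
                     cluster: str = "Ig2", strand: str = "+",
                     source_id: str = "exon_array") -> SyntheticGenome:
    """Plant a tandem array of diverged copies of ``base_exon``.

    Each variant is independently mutated at ``divergence`` per nt
    (stop-introducing substitutions resampled); variants are separated by
    random spacers of ``spacer_len`` nt.
    """
    if n_variants < 1:
        raise ValidationError("n_variants must be >= 1")
    if not (0 <= divergence < 1):
        raise ValidationError("divergence must be in [0, 1)")
    if len(base_exon) % 3 != 0:
        raise ValidationError("base exon length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    pieces = []
    local = []
    cursor = 0
    for v in range(n_variants):
        variant = _mutate_exon_no_stop(base_exon, divergence, rng)
        local.append((cursor, cursor + len(variant)))
        pieces.append(variant)
        cursor += len(variant)
        if v < n_variants - 1:
            spacer = "".join(_NT[rng.integers(0, 4)]
                             for _ in range(spacer_len))
            pieces.append(spacer)
            cursor += spacer_len
    array = "".join(pieces)
    start, end = offset, offset + len(array)
    _check_placement(genome, scaffold, start, end)
    insert = array if strand == "+" else reverse_complement(array)
    if strand == "+":
        fwd = [(start + a, start + b) for a, b in local]
    else:
        fwd = [(start + len(array) - b, start + len(array) - a)
               for a, b in local]
        fwd.reverse()
    seq = genome.scaffolds[scaffold]
    scaffolds = dict(genome.scaffolds)
    scaffolds[scaffold] = seq[:start] + insert + seq[end:]
    feature = TruthFeature(kind="exon_array", scaffold=scaffold,
                           strand=strand, exon_intervals=fwd,
                           source_id=source_id, cluster=cluster)
    return SyntheticGenome(scaffolds=scaffolds,
                           features=genome.features + [feature])


# --- synthetic protein family --------------------------------------------

@dataclass
class SyntheticFamily:
    """A block-structured protein family for end-to-end benchmarks."""
    alignment: "AnnotatedAlignment"
    ancestor: str                     # planted-gene source protein
    exon_plan: list[int]              # aa lengths between boundaries
    block_spans: list[tuple[int, int]]  # true conserved islands (aa coords)


def make_block_family(seed: int = 0, n_members: int = 5, n_blocks: int = 10,
                      block_len: int = 40, linker_len: int = 12,
                      block_rate: float = 0.15, linker_rate: float = 0.6
                      ) -> SyntheticFamily:
    """Generate a family with conserved islands separated by diverged linkers.

    The ancestor protein alternates linkers and blocks; members carry few
    substitutions inside blocks and many inside linkers, so the blocks are
    the highest-conservation windows. Exon boundaries sit mid-linker between
    consecutive blocks, so no block window crosses a boundary. Default rates
    emulate training sets of cross-species paralogs: ~72% pairwise identity
    inside conserved blocks, ~25% in linkers, with 40-residue blocks on the
    scale of the conserved stretches of real Ig/FN-domain proteins.
    """
    from .msa_blocks import AnnotatedAlignment

    rng = np.random.default_rng(seed)
    bg = robinson_background()
    total = n_blocks * block_len + (n_blocks + 1) * linker_len
    ancestor_codes = rng.choice(20, size=total, p=bg)
    ancestor = "".join(AA_LETTERS[c] for c in ancestor_codes)

    block_spans = []
    for i in range(n_blocks):
        s = linker_len + i * (block_len + linker_len)
        block_spans.append((s, s + block_len))
    in_block = np.zeros(total, dtype=bool)
    for s, e in block_spans:
        in_block[s:e] = True

    members = []
    for m in range(n_members):
        codes = ancestor_codes.copy()
        rates = np.where(in_block, block_rate, linker_rate)
        hit = rng.random(total) < rates
        for i in np.flatnonzero(hit):
            alt = rng.integers(0, 19)
            codes[i] = alt if alt < codes[i] else alt + 1
        members.append((f"member_{m + 1}",
                        "".join(AA_LETTERS[c] for c in codes)))

    # boundaries in the middle of each inter-block linker (shared by all
    # members: the alignment has no indels)
    boundaries_pos = []
    for i in range(1, n_blocks):
        prev_end = block_spans[i - 1][1]
        boundaries_pos.append(prev_end + linker_len // 2)
    boundaries = {sid: list(boundaries_pos) for sid, _ in members}
    aln = AnnotatedAlignment(sequences=members, boundaries=boundaries)

    exon_plan = []
    prev = 0
    for b in boundaries_pos:
        exon_plan.append(b - prev)
        prev = b
    exon_plan.append(total - prev)
    return SyntheticFamily(alignment=aln, ancestor=ancestor,
                           exon_plan=exon_plan, block_spans=block_spans)


# --- benchmark bundle -----------------------------------------------------

DEFAULT_BUNDLE_CONFIG = {
    "seed": 0,
    "n_scaffolds": 8,
    "scaffold_len": 30_000,
    "gc": 0.5,
    "gene_scaffold_index": 2,
    "gene_offset": 4_000,
    "gene_mutation_rate": 0.0,
    "intron_len": 300,
    "exon_arrays": {"Ig2": 12, "Ig3": 48, "Ig7": 33},
    "array_divergence": 0.10,
    "array_exon_len_aa": 55,
    "array_spacer_len": 120,
    "negative_n_scaffolds": 8,
}


def benchmark_bundle(out_dir, config: Optional[dict] = None) -> dict:
    """Emit a complete seeded fixture directory.

    Writes a block-training alignment + boundary table, a positive genome
    with one planted gene and three exon-variant arrays, a negative random
    genome, a truth GFF3 and an expected-counts manifest. Returns the paths.
    """
    from .formats import write_fasta, write_truth_gff3

    cfg = dict(DEFAULT_BUNDLE_CONFIG)
    if config:
        cfg.update(config)
    seed = int(cfg["seed"])
    out_dir = Path(out_dir)
    (out_dir / "blocks").mkdir(parents=True, exist_ok=True)

    family = make_block_family(seed=seed)
    aln_path = out_dir / "blocks" / "family_alignment.fasta"
    write_fasta(aln_path, family.alignment.sequences)
    bt_path = out_dir / "blocks" / "boundaries.tsv"
    bt_path.write_text("".join(
        f"{sid}\t{','.join(map(str, bl))}\n"
        for sid, bl in family.alignment.boundaries.items()))

    spec = SyntheticGenomeSpec(n_scaffolds=int(cfg["n_scaffolds"]),
                               scaffold_len=int(cfg["scaffold_len"]),
                               gc=float(cfg["gc"]), seed=seed)
    genome = random_genome(spec)
    gene_scaffold = scaffold_name(int(cfg["gene_scaffold_index"]))
    plant = PlantSpec(
        source_protein=family.ancestor, exon_plan=family.exon_plan,
        intron_lengths=[int(cfg["intron_len"])] * (len(family.exon_plan) - 1),
        mutation_rate=float(cfg["gene_mutation_rate"]),
        scaffold=gene_scaffold, offset=int(cfg["gene_offset"]),
        source_id="planted_gene")
    genome = plant_gene(genome, plant, seed=seed + 101)

    rng = np.random.default_rng(seed + 202)
    array_scaffolds = [i for i in range(int(cfg["n_scaffolds"]))
                       if i != int(cfg["gene_scaffold_index"])]
    for ci, (cluster, n_var) in enumerate(sorted(cfg["exon_arrays"].items())):
        base_exon = _reverse_translate(
            "".join(AA_LETTERS[c] for c in
                    rng.choice(20, size=int(cfg["array_exon_len_aa"]),
                               p=robinson_background())), rng)
        genome = plant_exon_array(
            genome, base_exon, n_variants=int(n_var),
            divergence=float(cfg["array_divergence"]),
            spacer_len=int(cfg["array_spacer_len"]),
            scaffold=scaffold_name(array_scaffolds[ci]), offset=1_000,
            seed=seed + 303 + ci, cluster=cluster,
            source_id=f"{cluster}_array")

    neg_spec = SyntheticGenomeSpec(
        n_scaffolds=int(cfg["negative_n_scaffolds"]),
        scaffold_len=int(cfg["scaffold_len"]), gc=float(cfg["gc"]),
        seed=seed + 404)
    negative = random_genome(neg_spec)

    paths = {
        "alignment": aln_path, "boundaries": bt_path,
        "genome": out_dir / "genome.fasta",
        "negative_genome": out_dir / "genome_negative.fasta",
        "truth": out_dir / "truth.gff3",
        "expected": out_dir / "expected.json",
    }
    write_fasta(paths["genome"], genome.scaffolds.items())
    write_fasta(paths["negative_genome"], negative.scaffolds.items())
    write_truth_gff3(paths["truth"], genome.features)
    expected = {
        "planted_genes": sum(1 for f in genome.features if f.kind == "gene"),
        "exon_arrays": {f.cluster: len(f.exon_intervals)
                        for f in genome.features if f.kind == "exon_array"},
        "n_blocks": len(family.block_spans),
        "seed": seed,
    }
    paths["expected"].write_text(json.dumps(expected, indent=2) + "\n")
    return {"paths": paths, "genome": genome, "family": family,
            "expected": expected}
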
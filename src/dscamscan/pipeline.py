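"""End-to-end pipeline: blocks -> profiles -> calibrate -> scan -> call.

``run_pipeline`` wires the library modules together, writes the standard
output files (hits TSV, candidate GFF3, optional exon-variant FASTA/GFF3,
summary JSON) and logs the resolved configuration and seeds first, so every
run is reproducible from its own log. Any stage failure raises
:class:`~dscamscan.errors.PipelineError` naming the stage.
"""
from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .errors import DscamscanError, PipelineError
from .exon_discovery import extract_intronic_regions, scan_exon_variants, variant_summary
from .formats import (read_bed, write_candidates_gff3, write_hits_gff3,
                      write_hits_tsv, write_variants)
from .genome_scan import call_candidates, chain_gene_model, scan_genome
from .msa_blocks import extract_blocks, read_annotated_alignment, write_blocks_json
from .phmm import build_profile, calibrate, write_profile


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full gene-candidate pipeline; returns a result summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    log_lines = [f"dscamscan {__version__}",
                 "resolved config: " + json.dumps(config.resolved(),
                                                  sort_keys=True),
                 f"seed: {config.seed}"]

    with _stage("blocks"):
        if config.alignment is None:
            raise DscamscanError("no alignment path configured")
        aln = read_annotated_alignment(config.alignment, config.boundaries)
        warnings: list[str] = []
        blocks = extract_blocks(aln, config.n_blocks, config.block_min_len,
                                config.block_max_len, warnings=warnings)
        log_lines += [f"blocks: {len(blocks)} extracted"] + warnings
        write_blocks_json(blocks, out / "blocks.json")

    with _stage("build"):
        hmms = [build_profile(b, alpha=config.pseudocount) for b in blocks]

    with _stage("calibrate"):
        hmms = [calibrate(h, n_samples=config.calibration_n_samples,
                          sample_len=config.calibration_sample_len,
                          seed=config.seed + i)
                for i, h in enumerate(hmms)]
        hmm_dir = out / "profiles"
        hmm_dir.mkdir(exist_ok=True)
        for h in hmms:
            write_profile(h, hmm_dir / f"{h.name}.phmm")

    with _stage("scan"):
        if config.genome is None or not Path(config.genome).exists():
            raise DscamscanError(f"genome not found: {config.genome}")
        hits = scan_genome(hmms, config.genome,
                           e_cutoff=config.gene_e_cutoff,
                           top_m=config.top_m, code_id=config.genetic_code)
        write_hits_tsv(out / "hits.tsv", hits)
        write_hits_gff3(out / "hits.gff3", hits)
        log_lines.append(f"scan: {len(hits)} hits at E <= "
                         f"{config.gene_e_cutoff}")

    with _stage("call"):
        candidates = call_candidates(hits, n_blocks=len(hmms),
                                     k_min=config.k_min,
                                     e_cutoff=config.gene_e_cutoff,
                                     same_strand=config.same_strand)
        write_candidates_gff3(out / "candidates.gff3", candidates)
        chains = []
        from .genome_scan import as_scaffold_dict
        scaffolds = as_scaffold_dict(config.genome)
        for c in candidates:
            chain = chain_gene_model(c.hits, gap_penalty=config.gap_penalty,
                                     scaffold_seq=scaffolds[c.scaffold],
                                     n_blocks=len(hmms))
            chains.append(chain)
        log_lines.append(f"call: {len(candidates)} candidates at k_min = "
                         f"{config.k_min}")

    variants = []
    if config.anchors_bed is not None:
        with _stage("exons"):
            # BED name column carries "cluster" labels; rows grouped per
            # scaffold into ordered anchor lists
            anchors_by_scaffold: dict[str, dict[str, list]] = {}
            for chrom, start, end, name in read_bed(config.anchors_bed):
                anchors_by_scaffold.setdefault(chrom, {}).setdefault(
                    name or "Ig2", []).append((start, end))
            regions = []
            for scaffold, anchors in sorted(anchors_by_scaffold.items()):
                regions += extract_intronic_regions(anchors, scaffold,
                                                    genome=config.genome)
            cluster_hmms = {label: hmms for label in
                            {r.cluster for r in regions}}
            variants = scan_exon_variants(cluster_hmms, regions,
                                          config.genome,
                                          e_cutoff=config.exon_e_cutoff,
                                          code_id=config.genetic_code)
            write_variants(out / "variants", variants)
            log_lines.append(f"exons: {len(variants)} variant hits")

    with _stage("report"):
        summary = {
            "version": __version__,
            "seed": config.seed,
            "n_blocks": len(hmms),
            "n_hits": len(hits),
            "n_candidates": len(candidates),
            "candidates": [
                {"scaffold": c.scaffold, "strand": c.strand,
                 "matched_in_order": c.matched_in_order,
                 "total_score": round(c.total_score, 3),
                 "nt_start": c.nt_start, "nt_end": c.nt_end,
                 "protein_length": len(ch.protein),
                 "chain_warnings": ch.warnings}
                for c, ch in zip(candidates, chains)],
            "n_exon_variants": len(variants),
            "exon_variant_counts": (
                variant_summary(variants).set_index("cluster")["n_variants"]
                .to_dict() if variants else {}),
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        log_path.write_text("\n".join(log_lines) + "\n")
    return summary
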
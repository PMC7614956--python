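"""End-to-end pipeline: design -> off-target filter -> pack -> simulate
readout -> count -> test, on disk, with a provenance manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import read_genome, read_features, write_features, write_genome
from .cassette import pack_oligos, manifest_to_tsv, pool_to_fasta
from .config import PipelineConfig
from .design import DesignParams, design_library, library_to_tsv
from .offtarget import build_site_index, filter_offtargets
from .quantify import CountTable, SampleSheet, Sample, quantify_fastq
from .simulate import (
    DEFAULT_FLANK,
    ScreenSimParams,
    simulate_genome,
    simulate_reads,
    write_fastq,
)
from .stats import (
    ScreenDesign,
    estimate_dispersion,
    fold_coverage,
    glm_lrt,
    low_count_filter,
    rle_norm_factors,
    summarize_genes,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a remedy hint."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def design_params(config: PipelineConfig) -> DesignParams:
    return DesignParams(
        window_upstream=config.window_upstream,
        window_downstream=config.window_downstream,
        bin_region=config.bin_region,
        bin_width=config.bin_width,
        max_per_feature=config.max_per_feature,
        pam=config.pam,
    )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    genome_path: str | Path | None = None,
    features_path: str | Path | None = None,
) -> dict:
    """Run the whole workflow into ``outdir``; simulated inputs are generated
    when no genome/features are supplied.  Deterministic given the config.

    Returns a summary dict (also written as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    if genome_path is None or features_path is None:
        genome, features = simulate_genome(
            n_features=12, promoter_pam_min=8, length=20_000, seed=config.seed
        )
        genome_path = outdir / "genome.fa"
        features_path = outdir / "features.bed"
        write_genome(genome, genome_path)
        write_features(features, features_path)
    else:
        genome_path = Path(genome_path)
        features_path = Path(features_path)
        if not genome_path.exists():
            raise PipelineError(
                f"design: genome file {genome_path} not found "
                "(check the --genome path)"
            )
        if not features_path.exists():
            raise PipelineError(
                f"design: feature file {features_path} not found "
                "(check the --features path)"
            )
        genome = read_genome(genome_path)
        features = read_features(features_path)
    inputs["genome"] = _sha256(Path(genome_path))
    inputs["features"] = _sha256(Path(features_path))

    params = design_params(config)
    library = design_library(genome, features, params)
    if not library:
        raise PipelineError(
            "design: no guides found; check PAM availability near the TSSs"
        )
    index = build_site_index(genome, params)
    flagged = filter_offtargets(library, index, config.min_mismatch)
    kept = [g for g in flagged if g.offtarget_ok]
    library_to_tsv(flagged, outdir / "library.tsv")
    if not kept:
        raise PipelineError(
            "offtarget: every guide was filtered; lower --min-mm or "
            "use a less repetitive genome"
        )

    # Guides carrying (or junction-creating) the BspQI site cannot be
    # synthesized in the cassette; drop them before packing.
    from .cassette import CassetteError

    synthesizable = []
    for g in kept:
        try:
            pack_oligos([g.protospacer])
        except CassetteError:
            continue
        synthesizable.append(g)
    kept = synthesizable
    if not kept:
        raise PipelineError("pack: no cassette-compatible guides remain")
    pool = pack_oligos([g.protospacer for g in kept])
    pool_to_fasta(pool, outdir / "oligos.fa")
    manifest_to_tsv(pool, outdir / "oligo_manifest.tsv")

    # Simulated readout for the kept library.
    lib_map = {g.guide_id: g.protospacer for g in kept}
    sim = ScreenSimParams(
        n_guides=len(kept),
        n_samples_per_group=2,
        mean_depth=150.0,
        dispersion=0.15,
        spike_fraction=0.1,
        spike_log2fc=4.0,
        seed=config.seed,
    )
    from .simulate import simulate_screen_counts

    table, truth = simulate_screen_counts(sim)
    table = CountTable(
        counts=table.counts.set_axis(list(lib_map), axis=0),
        fractions=table.fractions,
    )
    truth.index = list(lib_map)
    sheet = SampleSheet(
        tuple(
            Sample(sid, bc, "screen1", table.fractions[sid], 1 + i % 2)
            for i, (sid, bc) in enumerate(
                zip(table.sample_ids, ("ACGT", "CAGT", "GTCA", "TGAC"))
            )
        )
    )
    reads = simulate_reads(table, lib_map, sheet, seed=config.seed)
    fastq_path = outdir / "reads.fastq"
    write_fastq(reads, fastq_path)

    counted = quantify_fastq(fastq_path, sheet, list(lib_map.values()), DEFAULT_FLANK)
    # Recover guide ids from protospacers for the stats stage.
    proto_to_id = {v: k for k, v in lib_map.items()}
    counted = CountTable(
        counts=counted.counts.rename(index=proto_to_id),
        fractions=counted.fractions,
        unassigned=counted.unassigned,
    )
    counted.to_tsv(outdir / "counts.tsv")

    filtered, filter_report = low_count_filter(
        counted, config.min_cpm, config.min_sample_fraction
    )
    factors = rle_norm_factors(filtered)
    disp = estimate_dispersion(filtered, factors)
    results = glm_lrt(
        filtered,
        factors,
        disp,
        lfc_threshold=config.lfc_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    results.to_csv(outdir / "results.tsv", sep="\t", index=False)
    guide_to_gene = {g.guide_id: g.feature_id for g in kept}
    genes = summarize_genes(
        results, guide_to_gene, config.lfc_threshold, config.gene_fdr_threshold
    )
    genes.to_csv(outdir / "gene_summary.tsv", sep="\t", index=False)

    coverage = fold_coverage(
        ScreenDesign(
            n_droplets=int(len(kept) * 20 / config.loading_lambda),
            lam=config.loading_lambda,
            library_size=len(kept),
        )
    )
    summary = {
        "version": __version__,
        "parameters": {
            "window_upstream": config.window_upstream,
            "window_downstream": config.window_downstream,
            "bin_region": config.bin_region,
            "bin_width": config.bin_width,
            "min_mismatch": config.min_mismatch,
            "lfc_threshold": config.lfc_threshold,
            "fdr_threshold": config.fdr_threshold,
            "seed": config.seed,
        },
        "input_checksums": inputs,
        "n_features": len(features),
        "n_designed": len(library),
        "n_kept": len(kept),
        "n_oligos": len(pool.oligos),
        "n_tested": int(filter_report["kept"]),
        "dispersion_common": float(disp.common),
        "n_enriched": int(results["enriched"].sum()),
        "n_genes": int(len(genes)),
        "fold_coverage_example": coverage,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
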
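"""One-command synthetic demo: toy genome, 2 marks x 2 conditions, and a
full pipeline run against the generated inputs."""
from __future__ import annotations

from dataclasses import replace
from pathlib import Path

from .genome_model import GenomicInterval
from .pipeline import PipelineConfig, run_pipeline
from .synthetic_data import (
    EnrichmentTruth,
    SimulationConfig,
    ToyGenome,
    enhancer_fold_regions,
    make_toy_genome,
    simulate_capture_library,
    simulate_expression_table,
)
from .tag_processing import write_bed_reads

MARKS = ("5mC", "5hmC")
BASELINE = "siNTC"
PERTURBED = "siTET"


def _promoter_flank_regions(toy: ToyGenome, fold: float, n: int):
    """Enrichment at promoter flanks of the first n genes."""
    out = []
    for g in toy.genes[:n]:
        tss = g.tss
        out.append((GenomicInterval(g.chrom, max(0, tss - 1000), tss + 1000),
                    fold))
    return out


def build_demo_inputs(
    outdir: str | Path,
    seed: int = 0,
    config: SimulationConfig | None = None,
    n_diff_regions: int = 30,
    n_lost_enhancers: int = 25,
) -> tuple[PipelineConfig, dict]:
    """Generate toy genome + four capture libraries + expression table, and
    return a ready-to-run PipelineConfig plus the planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = replace(config, seed=seed) if config else SimulationConfig(seed=seed)
    toy = make_toy_genome(config, outdir)

    # baseline enrichment structure shared between conditions
    base_5hmc = _promoter_flank_regions(toy, 4.0, n_diff_regions * 2)
    enh = enhancer_fold_regions(toy.enhancers)
    lost_idx = list(range(min(n_lost_enhancers, len(toy.enhancers))))
    truth: dict = {"lost_enhancers": lost_idx, "diff_promoters": []}

    libraries: dict[tuple[str, str], str] = {}
    for mark in MARKS:
        for cond in (BASELINE, PERTURBED):
            regions = list(base_5hmc) if mark == "5hmC" else list(
                _promoter_flank_regions(toy, 2.0, n_diff_regions * 2)
            )
            if mark == "5hmC":
                if cond == PERTURBED:
                    # first half of promoter regions lose their enrichment
                    kept = regions[n_diff_regions:]
                    lost = [
                        (iv, 1.0) for iv, _ in regions[:n_diff_regions]
                    ]
                    regions = kept + lost
                    truth["diff_promoters"] = [
                        g.gene_id for g in toy.genes[:n_diff_regions]
                    ]
                    # enhancers lose interior 5hmC
                    enh_cond = []
                    for j, iv in enumerate(toy.enhancers):
                        if j in lost_idx:
                            enh_cond.append((iv, 1.0))
                        else:
                            enh_cond.extend(enhancer_fold_regions([iv]))
                    regions = regions + enh_cond
                else:
                    regions = regions + enh
            lib_truth = EnrichmentTruth(
                mark=mark, condition=cond, planted_regions=regions
            )
            reads = simulate_capture_library(lib_truth, config)
            path = outdir / f"reads_{mark}_{cond}.bed"
            write_bed_reads(reads, str(path))
            libraries[(mark, cond)] = str(path)

    linked_genes = [
        toy.enhancer_nearest_gene[j][0]
        for j in lost_idx
        if toy.enhancer_nearest_gene[j][1] <= 20_000
    ]
    expr, expr_truth = simulate_expression_table(
        [g.gene_id for g in toy.genes], BASELINE, [PERTURBED],
        {PERTURBED: linked_genes}, config,
    )
    expr_path = outdir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t", index=False)
    truth["expression"] = expr_truth
    truth["linked_genes"] = linked_genes

    pipe = PipelineConfig(
        reads={
            mark: {BASELINE: libraries[(mark, BASELINE)],
                   PERTURBED: libraries[(mark, PERTURBED)]}
            for mark in MARKS
        },
        annotation=toy.paths["refflat"],
        chrom_sizes=toy.paths["chrom_sizes"],
        cgi_bed=toy.paths["cgi_bed"],
        enhancer_bed=toy.paths["enhancer_bed"],
        fasta=toy.paths.get("fasta"),
        expression=str(expr_path),
        outdir=str(outdir / "results"),
        baseline_condition=BASELINE,
        seed=seed,
    )
    return pipe, truth


def run_demo(outdir: str | Path, seed: int = 0,
             config: SimulationConfig | None = None) -> Path:
    pipe, _ = build_demo_inputs(outdir, seed=seed, config=config)
    return run_pipeline(pipe)
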
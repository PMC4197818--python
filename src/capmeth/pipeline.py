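"""End-to-end orchestration: reads + annotation -> islands, differential
regions, change tables, profiles, and enrichment reports."""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .feature_annotation import (
    GenomeAnnotation,
    count_genes_by_region_class,
    gene_change_calls,
    shore_change_calls,
)
from .genome_model import (
    load_gene_annotation,
    read_bed_intervals,
    read_chrom_sizes,
    select_representative,
)
from .island_caller import (
    IslandCallerConfig,
    call_differential_regions,
    call_islands,
    write_differential_bed,
    write_islands_bed,
)
from .profiles import ProfileSpec, composite_gene_profile, scaled_interval_profile
from .set_enrichment import (
    classify_expression,
    enhancer_gene_linkage,
    write_gene_set,
)
from .tag_processing import deduplicate_reads, read_bed_reads, reads_to_tags

log = logging.getLogger("capmeth")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    # reads[mark][condition] -> BED path; first condition is the reference
    reads: dict[str, dict[str, str]]
    annotation: str
    chrom_sizes: str
    outdir: str
    baseline_condition: str
    cgi_bed: str | None = None
    enhancer_bed: str | None = None
    fasta: str | None = None
    expression: str | None = None
    annotation_format: str = "refFlat"
    seed: int = 0
    shore_analysis: bool = True
    caller: IslandCallerConfig = field(default_factory=IslandCallerConfig)
    profile: ProfileSpec = field(default_factory=ProfileSpec)
    lfc_threshold: float = 0.585
    linkage_max_distance: int = 20_000

    def validate(self) -> None:
        paths = [self.annotation, self.chrom_sizes]
        for mark in self.reads.values():
            paths.extend(mark.values())
        for extra in (self.cgi_bed, self.enhancer_bed, self.fasta,
                      self.expression):
            if extra is not None:
                paths.append(extra)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing input files: {missing}")
        if self.shore_analysis and self.cgi_bed is None:
            raise PipelineError("shore analysis requested but no CGI BED given")
        for mark, conds in self.reads.items():
            if self.baseline_condition not in conds:
                raise PipelineError(
                    f"mark {mark!r} lacks the baseline condition "
                    f"{self.baseline_condition!r}"
                )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        caller = IslandCallerConfig(**raw.pop("caller", {}))
        prof_kwargs = raw.pop("profile", {})
        if "body_range" in prof_kwargs:
            prof_kwargs["body_range"] = tuple(prof_kwargs["body_range"])
        profile = ProfileSpec(**prof_kwargs)
        return cls(caller=caller, profile=profile, **raw)

    def to_yaml(self, path: str) -> None:
        raw = dataclasses.asdict(self)
        raw["profile"]["body_range"] = list(raw["profile"]["body_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; deterministic given config + seed."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    log.info("capmeth %s starting; parameters: %s", __version__,
             json.dumps(dataclasses.asdict(config.caller)))

    stage = "load-annotation"
    try:
        chrom_sizes = read_chrom_sizes(config.chrom_sizes)
        genes = select_representative(
            load_gene_annotation(config.annotation, config.annotation_format)
        )
        cgis = read_bed_intervals(config.cgi_bed) if config.cgi_bed else []
        enhancers = (
            read_bed_intervals(config.enhancer_bed)
            if config.enhancer_bed else []
        )
        annotation = GenomeAnnotation.build(
            genes, cgis=cgis, enhancers=enhancers, chrom_sizes=chrom_sizes
        )
        log.info("annotation: %d genes, %d CGIs, %d enhancers",
                 len(genes), len(cgis), len(enhancers))

        stage = "tags"
        island_tags = {}
        profile_tags = {}
        for mark, conds in config.reads.items():
            for cond, path in conds.items():
                reads = read_bed_reads(path)
                island_tags[(mark, cond)] = reads_to_tags(
                    deduplicate_reads(reads, 1),
                    config.caller.fragment_size, chrom_sizes,
                )
                profile_tags[(mark, cond)] = reads_to_tags(
                    deduplicate_reads(reads, 2),
                    config.caller.fragment_size, chrom_sizes,
                )
                log.info("%s/%s: %d reads -> %d island tags", mark, cond,
                         len(reads), island_tags[(mark, cond)].library_size)

        stage = "islands"
        for (mark, cond), tags in island_tags.items():
            islands = call_islands(tags, config.caller, chrom_sizes)
            write_islands_bed(islands, outdir / f"islands_{mark}_{cond}.bed")
            log.info("%s/%s: %d islands", mark, cond, len(islands))

        stage = "differential"
        diff_by_mark = {}
        for mark, conds in config.reads.items():
            base = island_tags[(mark, config.baseline_condition)]
            for cond in conds:
                if cond == config.baseline_condition:
                    continue
                regions = call_differential_regions(
                    island_tags[(mark, cond)], base, config.caller, chrom_sizes
                )
                diff_by_mark[(mark, cond)] = regions
                write_differential_bed(
                    regions, outdir / f"differential_{mark}_{cond}.bed"
                )
                log.info("%s/%s vs %s: %d significant regions", mark, cond,
                         config.baseline_condition, len(regions))

        stage = "change-tables"
        import pandas as pd

        tables = []
        for (mark, cond), regions in diff_by_mark.items():
            tbl = gene_change_calls(regions, annotation, mark=f"{mark}:{cond}")
            tables.append(tbl)
        tables = [t for t in tables if len(t)]
        change_table = (
            pd.concat(tables, ignore_index=True) if tables else
            gene_change_calls([], annotation)
        )
        change_table.to_csv(outdir / "gene_change_table.tsv", sep="\t",
                            index=False)
        count_genes_by_region_class(change_table).to_csv(
            outdir / "gene_change_counts.tsv", sep="\t", index=False
        )
        if config.shore_analysis and annotation.shore_set is not None:
            shore_tables = []
            shore_summaries = []
            for (mark, cond), regions in diff_by_mark.items():
                calls, summary = shore_change_calls(regions, annotation)
                calls.insert(0, "mark", f"{mark}:{cond}")
                summary.insert(0, "mark", f"{mark}:{cond}")
                shore_tables.append(calls)
                shore_summaries.append(summary)
            if shore_tables:
                pd.concat(shore_tables, ignore_index=True).to_csv(
                    outdir / "shore_calls.tsv", sep="\t", index=False
                )
                pd.concat(shore_summaries, ignore_index=True).to_csv(
                    outdir / "shore_summary.tsv", sep="\t", index=False
                )

        stage = "profiles"
        profdir = outdir / "profiles"
        profdir.mkdir(exist_ok=True)
        for (mark, cond), tags in profile_tags.items():
            prof = composite_gene_profile(tags, genes, config.profile,
                                          chrom_sizes)
            prof.to_tsv(profdir / f"genes_{mark}_{cond}.tsv")
            if cgis:
                cgi_spec = ProfileSpec(
                    flank_bp=4000, n_flank_bins=40,
                    n_body_bins=config.profile.n_body_bins,
                    body_range=(0, 100),
                )
                scaled_interval_profile(
                    tags, cgis, cgi_spec, chrom_sizes=chrom_sizes
                ).to_tsv(profdir / f"cgi_{mark}_{cond}.tsv")
            if enhancers:
                enh_spec = ProfileSpec(
                    flank_bp=config.profile.flank_bp,
                    n_flank_bins=config.profile.n_flank_bins,
                    n_body_bins=config.profile.n_body_bins,
                    body_range=(0, 100),
                )
                scaled_interval_profile(
                    tags, enhancers, enh_spec, chrom_sizes=chrom_sizes
                ).to_tsv(profdir / f"enhancer_{mark}_{cond}.tsv")

        stage = "enrichment"
        enrdir = outdir / "enrichment"
        enrdir.mkdir(exist_ok=True)
        if config.expression is not None:
            expr = pd.read_csv(config.expression, sep="\t")
            conds = [
                c for c in expr.columns
                if c not in ("gene_id", "tier", config.baseline_condition)
            ]
            classes = classify_expression(
                expr, config.baseline_condition, conds,
                lfc_threshold=config.lfc_threshold,
            )
            classes.table.to_csv(enrdir / "expression_classes.tsv", sep="\t",
                                 index=False)
            if enhancers:
                universe = {g.gene_id for g in genes}
                for (mark, cond), regions in diff_by_mark.items():
                    lost = [
                        e for e in enhancers
                        if any(
                            r.direction == "hypo" and r.chrom == e.chrom
                            and r.start < e.end and r.end > e.start
                            for r in regions
                        )
                    ]
                    if f"down_{cond}" not in classes.table.columns:
                        continue
                    linkage = enhancer_gene_linkage(
                        lost, genes, classes.repressed(cond),
                        universe=universe,
                        max_distance=config.linkage_max_distance,
                    )
                    linkage.links.to_csv(
                        enrdir / f"enhancer_linkage_{mark}_{cond}.tsv",
                        sep="\t", index=False,
                    )
                    write_gene_set(
                        linkage.linked_genes,
                        enrdir / f"enhancer_linked_genes_{mark}_{cond}.txt",
                    )
                    if linkage.overlap is not None:
                        with open(
                            enrdir / f"enhancer_linkage_{mark}_{cond}.json", "w"
                        ) as fh:
                            json.dump(
                                {
                                    "k": linkage.overlap.table.k,
                                    "n_linked": linkage.overlap.table.n1,
                                    "n_repressed": linkage.overlap.table.n2,
                                    "universe": linkage.overlap.table.N,
                                    "fisher_p_two_tailed":
                                        linkage.overlap.fisher_p_two_tailed,
                                    "ease_p": linkage.overlap.ease_p,
                                    "fraction_repression_explained":
                                        linkage.fraction_repression_explained,
                                },
                                fh, indent=1,
                            )
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    config.to_yaml(str(outdir / "effective_config.yaml"))
    log.info("pipeline complete: %s", outdir)
    return outdir
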
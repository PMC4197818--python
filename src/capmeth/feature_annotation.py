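"""Region-to-feature annotation and per-gene-region change calls.

Maps called islands / differential regions onto gene region classes
(promoter, 5'UTR, exon, coding exon, 3'UTR, intron, TTS flank), CpG
islands, shores, and enhancers by any-overlap (>= 1 bp), then derives the
per-(gene, region class) hypo/hyper change table stratified by two-fold
and four-fold magnitude, and the promoter-shore hypermethylation summary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    GeneModel,
    GeneRegions,
    GenomicInterval,
    ShoreSet,
    classify_cgi_locations,
    compute_cgi_shores,
    derive_gene_regions,
)
from .island_caller import DifferentialRegion

GENE_REGION_CLASSES = (
    "promoter", "utr5", "exon", "coding_exon", "utr3", "intron", "tts_flank",
)
FEATURE_CLASSES = GENE_REGION_CLASSES + ("cgi", "shore", "enhancer")


@dataclass
class RegionAssignment:
    region_index: int
    # (feature_class, feature_id, overlap_bp)
    assignments: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def is_intergenic(self) -> bool:
        return len(self.assignments) == 0


@dataclass
class GenomeAnnotation:
    """Feature catalog against which regions are annotated."""

    genes: list[GeneModel]
    gene_regions: dict[str, GeneRegions]
    shore_set: ShoreSet | None = None
    enhancers: list[GenomicInterval] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    _catalog: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        genes: Sequence[GeneModel],
        cgis: Sequence[GenomicInterval] = (),
        enhancers: Sequence[GenomicInterval] = (),
        chrom_sizes: dict[str, int] | None = None,
    ) -> "GenomeAnnotation":
        chrom_sizes = dict(chrom_sizes or {})
        regions = {
            g.gene_id: derive_gene_regions(g, chrom_sizes.get(g.chrom))
            for g in genes
        }
        shore_set = None
        if cgis:
            shore_set = compute_cgi_shores(list(cgis), chrom_sizes)
            classify_cgi_locations(shore_set, list(genes))
        ann = cls(
            genes=list(genes), gene_regions=regions, shore_set=shore_set,
            enhancers=list(enhancers), chrom_sizes=chrom_sizes,
        )
        ann._build_catalog()
        return ann

    def _build_catalog(self) -> None:
        """Per-chromosome arrays of (start, end) per feature class."""
        rows: dict[str, dict[str, list]] = {}

        def add(chrom: str, fclass: str, start: int, end: int, fid: str) -> None:
            d = rows.setdefault(chrom, {}).setdefault(
                fclass, {"start": [], "end": [], "id": []}
            )
            d["start"].append(start)
            d["end"].append(end)
            d["id"].append(fid)

        for gid, gr in self.gene_regions.items():
            add(gr.promoter.chrom, "promoter", gr.promoter.start,
                gr.promoter.end, gid)
            if gr.tts_flank is not None:
                add(gr.tts_flank.chrom, "tts_flank", gr.tts_flank.start,
                    gr.tts_flank.end, gid)
            for name, ivs in (
                ("utr5", gr.utr5), ("utr3", gr.utr3), ("exon", gr.exons),
                ("coding_exon", gr.coding_exons), ("intron", gr.introns),
            ):
                for iv in ivs:
                    add(iv.chrom, name, iv.start, iv.end, gid)
        if self.shore_set is not None:
            for i, isl in enumerate(self.shore_set.islands):
                add(isl.chrom, "cgi", isl.start, isl.end, f"cgi_{i}")
            for j, sh in enumerate(self.shore_set.shores):
                add(sh.interval.chrom, "shore", sh.interval.start,
                    sh.interval.end, f"shore_{j}")
        for i, iv in enumerate(self.enhancers):
            add(iv.chrom, "enhancer", iv.start, iv.end, f"enh_{i}")
        self._catalog = {
            chrom: {
                fclass: {
                    "start": np.array(d["start"], dtype=np.int64),
                    "end": np.array(d["end"], dtype=np.int64),
                    "id": np.array(d["id"], dtype=object),
                }
                for fclass, d in classes.items()
            }
            for chrom, classes in rows.items()
        }

    def overlapping_features(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[str, str, int]]:
        out: list[tuple[str, str, int]] = []
        for fclass, d in self._catalog.get(chrom, {}).items():
            hit = (d["start"] < end) & (d["end"] > start)
            if not hit.any():
                continue
            ov = np.minimum(d["end"][hit], end) - np.maximum(d["start"][hit], start)
            out.extend(
                (fclass, str(fid), int(o))
                for fid, o in zip(d["id"][hit], ov)
            )
        return out


def annotate_regions(
    regions: Sequence, annotation: GenomeAnnotation
) -> list[RegionAssignment]:
    """Any-overlap assignment of each region to all feature classes it
    touches; regions touching nothing are intergenic."""
    out = []
    for i, r in enumerate(regions):
        hits = annotation.overlapping_features(r.chrom, r.start, r.end)
        out.append(RegionAssignment(region_index=i, assignments=hits))
    return out


def _stratum(abs_log2fc: float) -> str:
    if abs_log2fc >= 2.0:
        return ">=4x"
    if abs_log2fc >= 1.0:
        return "2-4x"
    return "none"


def gene_change_calls(
    diff_regions: Sequence[DifferentialRegion],
    annotation: GenomeAnnotation,
    mark: str = "",
) -> pd.DataFrame:
    """Per-(gene, region class) change calls from significant differential
    regions.

    A (gene, region class) pair is called when any region overlaps that
    class; its direction and magnitude stratum come from the overlapping
    region of maximal |log2FC| (ties: larger overlap, then smaller start).
    A pair whose best |log2FC| is below two-fold is reported with
    direction/stratum 'none'.
    """
    best: dict[tuple[str, str], tuple[float, int, int, DifferentialRegion]] = {}
    for r in diff_regions:
        for fclass, fid, ov in annotation.overlapping_features(
            r.chrom, r.start, r.end
        ):
            if fclass not in GENE_REGION_CLASSES:
                continue
            key = (fid, fclass)
            rank = (abs(r.log2_fc), ov, -r.start)
            if key not in best or rank > (
                abs(best[key][3].log2_fc), best[key][1], -best[key][3].start
            ):
                best[key] = (abs(r.log2_fc), ov, r.start, r)
    rows = []
    for (gid, fclass), (_, ov, _, r) in sorted(best.items()):
        stratum = _stratum(abs(r.log2_fc))
        rows.append(
            {
                "gene_id": gid,
                "region_class": fclass,
                "mark": mark,
                "direction": r.direction if stratum != "none" else "none",
                "log2_fc": r.log2_fc,
                "stratum": stratum,
                "overlap_bp": ov,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "region_class", "mark", "direction", "log2_fc",
                 "stratum", "overlap_bp"],
    )


def count_genes_by_region_class(change_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(region class, direction) gene counts — the pie-chart tabulation."""
    called = change_table[change_table["direction"] != "none"]
    out = (
        called.groupby(["region_class", "direction", "stratum"])["gene_id"]
        .nunique()
        .reset_index(name="n_genes")
    )
    return out


def shore_change_calls(
    diff_regions: Sequence[DifferentialRegion],
    annotation: GenomeAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-shore (and per-island) direction calls plus the promoter-shore
    summary: the fraction of promoter-CGI genes whose shore is
    hypermethylated, and per-location-class hyper fractions.
    """
    ss = annotation.shore_set
    if ss is None:
        raise ValueError("annotation has no CpG island set")
    features = (
        [("cgi", i, isl) for i, isl in enumerate(ss.islands)]
        + [("shore", sh.island_index, sh.interval) for sh in ss.shores]
    )
    rows = []
    for ftype, island_idx, iv in features:
        best_fc = 0.0
        for r in diff_regions:
            if r.chrom == iv.chrom and r.start < iv.end and r.end > iv.start:
                if abs(r.log2_fc) > abs(best_fc):
                    best_fc = r.log2_fc
        stratum = _stratum(abs(best_fc))
        direction = "none"
        if stratum != "none":
            direction = "hyper" if best_fc > 0 else "hypo"
        rows.append(
            {
                "feature_type": ftype,
                "island_index": island_idx,
                "location_class": ss.location_class[island_idx]
                if ss.location_class else "unknown",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "direction": direction,
                "log2_fc": best_fc,
                "stratum": stratum,
            }
        )
    calls = pd.DataFrame(rows)

    # promoter-CGI genes whose island has a hypermethylated shore
    island_gene: dict[int, set[str]] = {}
    for i, isl in enumerate(ss.islands):
        genes = set()
        for gid, gr in annotation.gene_regions.items():
            if isl.overlaps(gr.promoter):
                genes.add(gid)
        if genes:
            island_gene[i] = genes
    prom_cgi_genes = set().union(*island_gene.values()) if island_gene else set()
    shore_calls = calls[calls["feature_type"] == "shore"]
    hyper_islands = set(
        shore_calls.loc[shore_calls["direction"] == "hyper", "island_index"]
    )
    hyper_genes = set()
    for i in hyper_islands:
        hyper_genes |= island_gene.get(i, set())
    summary_rows = [
        {
            "statistic": "promoter_shore_hyper_fraction",
            "feature_type": "shore",
            "location_class": "promoter",
            "n_hyper": len(hyper_genes),
            "n_total": len(prom_cgi_genes),
            "fraction": len(hyper_genes) / len(prom_cgi_genes)
            if prom_cgi_genes else 0.0,
        }
    ]
    for ftype in ("cgi", "shore"):
        sub = calls[calls["feature_type"] == ftype]
        for loc in ("promoter", "gene_body", "intergenic"):
            loc_sub = sub[sub["location_class"] == loc]
            n = len(loc_sub)
            n_hyper = int((loc_sub["direction"] == "hyper").sum())
            summary_rows.append(
                {
                    "statistic": "hyper_fraction",
                    "feature_type": ftype,
                    "location_class": loc,
                    "n_hyper": n_hyper,
                    "n_total": n,
                    "fraction": n_hyper / n if n else 0.0,
                }
            )
    return calls, pd.DataFrame(summary_rows)
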
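"""Synthetic toy genomes, capture libraries, and expression tables.

Everything downstream of read alignment can be exercised against planted
truth: genes with promoter CpG-class motifs, CpG islands in promoter /
gene-body / intergenic locations, enhancers with a known nearest gene,
capture libraries drawn from an inhomogeneous Poisson-rate landscape with
planted fold-enrichment per mark and condition, and expression tables with
high/moderate/low tiers plus condition-specific repression tied to
enhancer 5hmC loss.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    GeneModel,
    GenomicInterval,
    write_bed_intervals,
    write_chrom_sizes,
    write_refflat,
)
from .tag_processing import READ_COLUMNS


class SimulationError(ValueError):
    pass


# Promoter-class motifs. Each unit length divides the 500-bp classification
# window, so every sliding window sees the same base composition:
#   HCP: GC = 0.8, CpG O/E = 2.5    LCP: no CpG anywhere
#   ICP: GC = 0.5, CpG O/E = 0.64  (between the 0.48 and 0.75 cutoffs)
HCP_UNIT = "CGCGA"
LCP_UNIT = "ATTGA"
ICP_UNIT = "CGT" * 4 + "CA" * 21 + "GA" * 21 + "T" * 4


@dataclass
class SimulationConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_genes: int = 300
    n_cgis: int = 150
    n_enhancers: int = 100
    read_length: int = 50
    fragment_length: int = 300
    n_fragments: int = 200_000
    seed: int = 0
    promoter_cgi_fraction: float = 0.5
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"HCP": 0.4, "ICP": 0.3, "LCP": 0.3}
    )
    write_fasta: bool = True


@dataclass
class EnrichmentTruth:
    mark: str
    condition: str
    planted_regions: list[tuple[GenomicInterval, float]]
    background_rate: float = 1e-4  # expected fragments per bp (relative)

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise SimulationError("background_rate must be positive")
        for iv, fold in self.planted_regions:
            if fold < 0:
                raise SimulationError(f"negative fold at {iv}")


@dataclass
class ToyGenome:
    config: SimulationConfig
    genes: list[GeneModel]
    cgis: list[GenomicInterval]
    enhancers: list[GenomicInterval]
    enhancer_nearest_gene: list[tuple[str, int]]  # (gene_id, distance)
    promoter_classes: dict[str, str]
    paths: dict[str, str] = field(default_factory=dict)


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Named RNG substream: adding a library never perturbs the others."""
    entropy = [seed] + [zlib.crc32(l.encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

def _random_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    length = end - start
    n_exons = int(rng.integers(2, 11))
    n_parts = 2 * n_exons - 1
    min_part = 60
    if length < n_parts * min_part:
        n_exons = max(2, length // (2 * min_part))
        n_parts = 2 * n_exons - 1
    extra = length - n_parts * min_part
    weights = rng.dirichlet(np.ones(n_parts))
    sizes = (min_part + np.floor(weights * extra)).astype(int)
    sizes[-1] += length - sizes.sum()
    edges = start + np.concatenate(([0], np.cumsum(sizes)))
    return [(int(edges[2 * i]), int(edges[2 * i + 1])) for i in range(n_exons)]


def make_toy_genome(
    config: SimulationConfig, outdir: str | Path | None = None
) -> ToyGenome:
    """Build a mutually consistent toy annotation set (and optional FASTA).

    Genes are laid out on a regular grid with jitter, 2-10 exons each;
    a configurable fraction of promoters carry a CpG island; promoter
    sequences are constructed from class-specific motifs so the CpG-density
    classifier can recover the planted HCP/ICP/LCP labels.
    """
    rng = substream(config.seed, "toy_genome")
    total_len = sum(config.chrom_sizes.values())
    genes: list[GeneModel] = []
    margin = 25_000
    gene_no = 0
    slots: list[tuple[str, int, int]] = []
    for chrom, size in config.chrom_sizes.items():
        n_chrom = round(config.n_genes * size / total_len)
        usable = size - 2 * margin
        slot = usable // max(n_chrom, 1)
        if slot < 30_000:
            raise SimulationError(
                "requested features exceed genome capacity; "
                "reduce n_genes or enlarge chromosomes"
            )
        for i in range(n_chrom):
            slots.append((chrom, margin + i * slot, margin + (i + 1) * slot))
    for chrom, slot_s, slot_e in slots:
        tx_len = int(rng.integers(4_000, 16_000))
        lo = slot_s + 8_000  # leave room for flanks/enhancers in the slot
        hi = slot_e - 8_000 - tx_len
        tx_s = int(rng.integers(lo, max(hi, lo + 1)))
        tx_e = tx_s + tx_len
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _random_exons(rng, tx_s, tx_e)
        cds_s = exons[0][0] + min(30, exons[0][1] - exons[0][0] - 1)
        cds_e = exons[-1][1] - min(30, exons[-1][1] - exons[-1][0] - 1)
        genes.append(
            GeneModel(
                gene_id=f"gene_{gene_no:04d}", chrom=chrom, strand=strand,
                start=tx_s, end=tx_e, cds_start=cds_s, cds_end=cds_e,
                exons=exons,
            )
        )
        gene_no += 1

    # planted promoter CpG classes
    labels = list(config.class_fractions)
    fracs = np.array([config.class_fractions[l] for l in labels], dtype=float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * len(genes)).astype(int)
    counts[0] += len(genes) - counts.sum()
    planted = [l for l, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(planted)
    promoter_classes = {g.gene_id: c for g, c in zip(genes, planted)}

    # CpG islands: promoter / gene body / intergenic
    n_prom = round(config.n_cgis * config.promoter_cgi_fraction)
    n_rest = config.n_cgis - n_prom
    n_body = n_rest // 2
    cgis: list[GenomicInterval] = []
    cgi_class: list[str] = []
    order = rng.permutation(len(genes))
    for gi in order[:n_prom]:
        g = genes[gi]
        half = int(rng.integers(250, 600))
        cgis.append(GenomicInterval(g.chrom, g.tss - half, g.tss + half))
        cgi_class.append("promoter")
    for gi in order[n_prom:n_prom + n_body]:
        g = genes[gi]
        mid = (g.start + g.end) // 2
        half = int(rng.integers(250, 500))
        # keep clear of the promoter window around the TSS
        if abs(mid - g.tss) < 2_000 + half:
            mid = g.tss + (2_000 + half) * (1 if g.strand == "+" else -1)
        cgis.append(GenomicInterval(g.chrom, mid - half, mid + half))
        cgi_class.append("gene_body")
    n_inter = n_rest - n_body
    inter_slots = rng.choice(len(slots), size=n_inter, replace=False)
    for si in inter_slots:
        chrom, slot_s, _ = slots[si]
        half = int(rng.integers(250, 500))
        mid = slot_s + 3_500  # in the inter-gene margin of the slot
        cgis.append(GenomicInterval(chrom, mid - half, mid + half))
        cgi_class.append("intergenic")
    keep = _drop_overlaps(cgis)
    cgis = [cgis[i] for i in keep]
    cgi_class = [cgi_class[i] for i in keep]

    # enhancers: placed upstream of a host gene's promoter inside its slot,
    # so the host TSS is the nearest TSS
    n_enh = min(config.n_enhancers, len(slots))
    enh_slots = rng.choice(len(slots), size=n_enh, replace=False)
    slot_gene = {i: g for i, g in enumerate(genes)}  # slot i -> gene i
    enhancers: list[GenomicInterval] = []
    enhancer_nearest: list[tuple[str, int]] = []
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for c in tss_by_chrom.values():
        c.sort()
    for si in enh_slots:
        g = slot_gene[int(si)]
        chrom, slot_s, slot_e = slots[int(si)]
        length = int(rng.integers(1_000, 2_000))
        room = (g.tss - slot_s if g.strand == "+" else slot_e - g.tss) - length
        max_dist = min(13_000, room)
        if max_dist <= 4_000:
            continue
        dist = int(rng.integers(4_000, max_dist))
        if g.strand == "+":
            e = g.tss - dist
            s = e - length
        else:
            s = g.tss + dist
            e = s + length
        if s < slot_s or e > slot_e:
            continue
        iv = GenomicInterval(chrom, s, e)
        gene_id, d = _nearest_tss(iv, tss_by_chrom[chrom])
        enhancers.append(iv)
        enhancer_nearest.append((gene_id, d))

    toy = ToyGenome(
        config=config, genes=genes, cgis=cgis, enhancers=enhancers,
        enhancer_nearest_gene=enhancer_nearest,
        promoter_classes=promoter_classes,
    )
    if outdir is not None:
        _write_toy_genome(toy, cgi_class, Path(outdir))
    return toy


def _drop_overlaps(intervals: list[GenomicInterval]) -> list[int]:
    order = sorted(range(len(intervals)),
                   key=lambda i: (intervals[i].chrom, intervals[i].start))
    keep: list[int] = []
    last: dict[str, int] = {}
    for i in order:
        iv = intervals[i]
        if iv.start >= last.get(iv.chrom, -1):
            keep.append(i)
            last[iv.chrom] = iv.end
    return sorted(keep)


def _nearest_tss(iv: GenomicInterval, tss_sorted: list[tuple[int, str]]) -> tuple[str, int]:
    best: tuple[int, int, str] | None = None  # (distance, gene_start_proxy, id)
    for tss, gid in tss_sorted:
        if iv.start <= tss < iv.end:
            d = 0
        elif tss < iv.start:
            d = iv.start - tss
        else:
            d = tss - iv.end
        if best is None or (d, tss) < (best[0], best[1]):
            best = (d, tss, gid)
    assert best is not None
    return best[2], best[0]


def _write_toy_genome(toy: ToyGenome, cgi_class: list[str], outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config = toy.config
    paths = {
        "refflat": str(outdir / "genes.refFlat"),
        "cgi_bed": str(outdir / "cgi.bed"),
        "enhancer_bed": str(outdir / "enhancers.bed"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
        "truth": str(outdir / "genome_truth.json"),
    }
    write_refflat(toy.genes, paths["refflat"])
    write_bed_intervals(
        toy.cgis, paths["cgi_bed"],
        names=[f"cgi_{i}_{c}" for i, c in enumerate(cgi_class)],
    )
    write_bed_intervals(
        toy.enhancers, paths["enhancer_bed"],
        names=[f"enh_{i}" for i in range(len(toy.enhancers))],
    )
    write_chrom_sizes(config.chrom_sizes, paths["chrom_sizes"])
    if config.write_fasta:
        paths["fasta"] = str(outdir / "genome.fa")
        _write_fasta(toy, paths["fasta"])
    truth = {
        "promoter_classes": toy.promoter_classes,
        "cgi_location": cgi_class,
        "enhancer_nearest_gene": [
            {"enhancer": i, "gene": gid, "distance": d}
            for i, (gid, d) in enumerate(toy.enhancer_nearest_gene)
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    toy.paths = paths


def _write_fasta(toy: ToyGenome, path: str) -> None:
    from .genome_model import CPG_CLASS_DOWNSTREAM, CPG_CLASS_UPSTREAM

    rng = substream(toy.config.seed, "toy_genome", "fasta")
    units = {"HCP": HCP_UNIT, "ICP": ICP_UNIT, "LCP": LCP_UNIT}
    with open(path, "w") as fh:
        for chrom, size in toy.config.chrom_sizes.items():
            seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=size)
            for g in toy.genes:
                if g.chrom != chrom:
                    continue
                unit = units[toy.promoter_classes[g.gene_id]]
                if g.strand == "+":
                    s = g.tss - CPG_CLASS_UPSTREAM
                    e = g.tss + CPG_CLASS_DOWNSTREAM
                else:
                    s = g.tss - CPG_CLASS_DOWNSTREAM
                    e = g.tss + CPG_CLASS_UPSTREAM
                s = max(0, s)
                motif = (unit * (-(-(e - s) // len(unit))))[: e - s]
                seq[s:e] = np.frombuffer(motif.encode(), dtype=np.uint8)
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode("ascii")
            for i in range(0, size, 80):
                fh.write(raw[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# Capture libraries
# ---------------------------------------------------------------------------

def simulate_capture_library(
    truth: EnrichmentTruth, config: SimulationConfig,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Draw ``n_fragments`` aligned reads from a piecewise-constant
    fragment-midpoint rate: background everywhere, multiplied by the
    planted fold inside each planted region (fold 0 excludes fragments).

    Each fragment emits one ``read_length`` read from its 5' end on a
    uniformly random strand. Returns a coordinate-sorted read table.
    """
    sizes = chrom_sizes or config.chrom_sizes
    half = config.fragment_length // 2
    rng = substream(config.seed, "library", truth.mark, truth.condition)

    seg_chrom: list[str] = []
    seg_start: list[int] = []
    seg_end: list[int] = []
    seg_fold: list[float] = []
    regions_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for iv, fold in truth.planted_regions:
        if iv.chrom not in sizes:
            raise SimulationError(f"planted region on unknown chrom {iv.chrom}")
        if iv.end > sizes[iv.chrom]:
            raise SimulationError(f"planted region beyond chromosome end: {iv}")
        regions_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, fold))
    for chrom, size in sizes.items():
        lo, hi = half, size - half  # midpoints keeping fragments in bounds
        regs = sorted(regions_by_chrom.get(chrom, []))
        for (s1, e1, _), (s2, e2, _) in zip(regs, regs[1:]):
            if s2 < e1:
                raise SimulationError(f"overlapping planted regions on {chrom}")
        pos = lo
        for s, e, fold in regs:
            s, e = max(s, lo), min(e, hi)
            if s > pos:
                seg_chrom.append(chrom); seg_start.append(pos)
                seg_end.append(s); seg_fold.append(1.0)
            if e > s:
                seg_chrom.append(chrom); seg_start.append(s)
                seg_end.append(e); seg_fold.append(fold)
            pos = max(pos, e)
        if hi > pos:
            seg_chrom.append(chrom); seg_start.append(pos)
            seg_end.append(hi); seg_fold.append(1.0)

    starts = np.array(seg_start, dtype=np.int64)
    ends = np.array(seg_end, dtype=np.int64)
    folds = np.array(seg_fold, dtype=float)
    weights = truth.background_rate * folds * (ends - starts)
    total = weights.sum()
    if total <= 0:
        raise SimulationError("zero total rate; nothing to sample")
    counts = rng.multinomial(config.n_fragments, weights / total)

    chroms_out: list[np.ndarray] = []
    mids_out: list[np.ndarray] = []
    for i, c in enumerate(counts):
        if c == 0:
            continue
        mids_out.append(rng.integers(starts[i], ends[i], size=c))
        chroms_out.append(np.full(c, i))
    seg_idx = np.concatenate(chroms_out)
    mids = np.concatenate(mids_out)
    chrom_arr = np.array(seg_chrom, dtype=object)[seg_idx]
    strand_plus = rng.random(len(mids)) < 0.5
    read_start = np.where(
        strand_plus, mids - half, mids + half - config.read_length
    )
    read_end = read_start + config.read_length
    df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "start": read_start.astype(np.int64),
            "end": read_end.astype(np.int64),
            "strand": np.where(strand_plus, "+", "-"),
        }
    )
    return df.sort_values(["chrom", "start", "end", "strand"],
                          kind="stable").reset_index(drop=True)[READ_COLUMNS]


def enhancer_fold_regions(
    enhancers: list[GenomicInterval], interior_fold: float = 6.0,
    edge_fold: float = 0.5, edge_bp: int = 200,
) -> list[tuple[GenomicInterval, float]]:
    """Planted enhancer structure: elevated interior with a fold dip in the
    outermost ``edge_bp`` on both sides (the boundary 'gutter')."""
    regions: list[tuple[GenomicInterval, float]] = []
    for iv in enhancers:
        if iv.length() <= 2 * edge_bp:
            regions.append((iv, interior_fold))
            continue
        regions.append(
            (GenomicInterval(iv.chrom, iv.start, iv.start + edge_bp), edge_fold)
        )
        regions.append(
            (GenomicInterval(iv.chrom, iv.start + edge_bp, iv.end - edge_bp),
             interior_fold)
        )
        regions.append(
            (GenomicInterval(iv.chrom, iv.end - edge_bp, iv.end), edge_fold)
        )
    return regions


def cgi_border_fold_regions(
    islands: list[GenomicInterval], spike_fold: float = 8.0,
    border_bp: int = 200,
) -> list[tuple[GenomicInterval, float]]:
    """Fold spikes straddling both island/shore borders of each island."""
    regions: list[tuple[GenomicInterval, float]] = []
    for iv in islands:
        regions.append(
            (GenomicInterval(iv.chrom, max(0, iv.start - border_bp),
                             iv.start + border_bp), spike_fold)
        )
        regions.append(
            (GenomicInterval(iv.chrom, iv.end - border_bp, iv.end + border_bp),
             spike_fold)
        )
    return regions


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def simulate_expression_table(
    gene_ids: list[str],
    baseline: str,
    perturbed_conditions: list[str],
    repression_links: dict[str, list[str]],
    config: SimulationConfig,
    noise_sd: float = 0.1,
    min_repression_log2: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Log-normal baseline expression with exact high/moderate/low tertile
    tiers; genes named in ``repression_links[condition]`` are repressed at
    least two-fold in that condition, all others get noise only.

    Returns the expression table (linear scale) and a truth sidecar dict.
    """
    for cond, linked in repression_links.items():
        if cond not in perturbed_conditions:
            raise KeyError(f"unknown condition in links: {cond}")
        unknown = set(linked) - set(gene_ids)
        if unknown:
            raise KeyError(f"unknown gene ids in links: {sorted(unknown)[:3]}")
    rng = substream(config.seed, "expression")
    n = len(gene_ids)
    log2_base = rng.normal(5.0, 2.0, size=n)
    order = np.lexsort((np.arange(n), log2_base))  # stable rank
    tier = np.empty(n, dtype=object)
    for rank, gi in enumerate(order):
        tier[gi] = ("low", "moderate", "high")[3 * rank // n]
    df = pd.DataFrame({"gene_id": gene_ids, "tier": tier, baseline: 2.0 ** log2_base})
    truth: dict = {"tiers": dict(zip(gene_ids, tier)), "repressed": {}}
    for cond in perturbed_conditions:
        linked = set(repression_links.get(cond, []))
        noise = rng.normal(0.0, noise_sd, size=n)
        lfc = noise.copy()
        is_linked = np.array([g in linked for g in gene_ids])
        planted = min_repression_log2 + rng.uniform(0.0, 1.0, size=n)
        lfc[is_linked] = -planted[is_linked] + noise[is_linked] * 0.0
        df[cond] = 2.0 ** (log2_base + lfc)
        truth["repressed"][cond] = sorted(linked)
    return df, truth
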
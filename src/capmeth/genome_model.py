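"""Genome annotation model and derived region classes.

Provides interval / gene-model types, readers for refFlat and GTF, and the
derivation of analysis region classes: promoters (TSS +/- 1 kb), gene-body
subregions (5'UTR, exon, coding exon, 3'UTR, intron), the 1-kb TTS flank,
CpG-island shores (2-kb flanks), CGI location classes, and CpG-density
promoter classes (HCP / ICP / LCP).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PROMOTER_FLANK = 1000
TTS_FLANK = 1000
SHORE_WIDTH = 2000

# CpG-density promoter classification parameters (sliding-window criteria)
CPG_CLASS_UPSTREAM = 700
CPG_CLASS_DOWNSTREAM = 200
CPG_WINDOW = 500
CPG_STEP = 5
HCP_GC_MIN = 0.55
HCP_OE_MIN = 0.75
LCP_OE_MAX = 0.48


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """One representative transcript per gene."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"{self.gene_id}: empty transcript span")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not (self.start <= self.cds_start <= self.cds_end <= self.end):
            raise AnnotationError(f"{self.gene_id}: CDS outside transcript")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: no exons")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise AnnotationError(f"{self.gene_id}: overlapping exons")
        for s, e in exons:
            if s >= e:
                raise AnnotationError(f"{self.gene_id}: empty exon")
            if s < self.start or e > self.end:
                raise AnnotationError(f"{self.gene_id}: exon outside transcript")
        self.exons = exons

    @property
    def tx(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start


@dataclass
class GeneRegions:
    gene_id: str
    promoter: GenomicInterval
    utr5: list[GenomicInterval]
    utr3: list[GenomicInterval]
    exons: list[GenomicInterval]
    coding_exons: list[GenomicInterval]
    introns: list[GenomicInterval]
    tts_flank: GenomicInterval | None


@dataclass
class Shore:
    interval: GenomicInterval
    island_index: int
    side: str  # {"upstream", "downstream"} in genome coordinates


@dataclass
class ShoreSet:
    islands: list[GenomicInterval]
    shores: list[Shore]
    location_class: list[str] = field(default_factory=list)


@dataclass
class PromoterCpGClass:
    gene_id: str
    cpg_class: str  # {"HCP", "ICP", "LCP"}
    best_window_gc: float
    best_window_oe: float


# ---------------------------------------------------------------------------
# Annotation readers / writers
# ---------------------------------------------------------------------------

def _parse_block_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def load_refflat(path: str) -> list[GeneModel]:
    """Read an 11-column refFlat file (0-based half-open coordinates)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 11 refFlat columns, got {len(fields)}"
                )
            try:
                (name, _txname, chrom, strand, tx_s, tx_e, cds_s, cds_e,
                 n_exons, ex_starts, ex_ends) = fields[:11]
                starts = _parse_block_list(ex_starts)
                ends = _parse_block_list(ex_ends)
                if len(starts) != int(n_exons) or len(ends) != int(n_exons):
                    raise ValueError("exonCount mismatch")
                gene = GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=int(tx_s),
                    end=int(tx_e),
                    cds_start=int(cds_s),
                    cds_end=int(cds_e),
                    exons=list(zip(starts, ends)),
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def write_refflat(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    [g.gene_id, g.gene_id, g.chrom, g.strand, str(g.start),
                     str(g.end), str(g.cds_start), str(g.cds_end),
                     str(len(g.exons)), starts, ends]
                )
                + "\n"
            )


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_gtf(path: str) -> list[GeneModel]:
    """Read a GTF 2.2 file; 1-based closed coordinates converted on read.

    Transcript structure is assembled from ``exon`` and ``CDS`` features
    grouped by ``transcript_id``; the gene identifier comes from ``gene_id``.
    """
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}"
                )
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                s0, e0 = int(start) - 1, int(end)  # to 0-based half-open
                if s0 < 0 or e0 <= s0:
                    raise ValueError("bad coordinates")
                attrs = _parse_gtf_attributes(attr)
                tid = attrs["transcript_id"]
                gid = attrs.get("gene_id", tid)
            except (ValueError, KeyError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            meta = tx_meta.setdefault(tid, (gid, chrom, strand))
            if meta[1:] != (chrom, strand):
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tid} changes chrom/strand"
                )
            (tx_cds if feature == "CDS" else tx_exons).setdefault(tid, []).append(
                (s0, e0)
            )
    genes: list[GeneModel] = []
    for tid, exons in tx_exons.items():
        gid, chrom, strand = tx_meta[tid]
        exons = sorted(exons)
        cds = sorted(tx_cds.get(tid, []))
        start, end = exons[0][0], exons[-1][1]
        cds_start = cds[0][0] if cds else start
        cds_end = cds[-1][1] if cds else start
        genes.append(
            GeneModel(gene_id=gid, chrom=chrom, strand=strand, start=start,
                      end=end, cds_start=cds_start, cds_end=cds_end, exons=exons)
        )
    return genes


def load_gene_annotation(path: str, fmt: str = "refFlat") -> list[GeneModel]:
    if fmt.lower() in ("refflat", "ref_flat"):
        return load_refflat(path)
    if fmt.lower() == "gtf":
        return load_gtf(path)
    raise AnnotationError(f"unknown annotation format {fmt!r}")


def select_representative(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """One transcript per gene id: longest tx span, ties to smallest start."""
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None:
            best[g.gene_id] = g
            continue
        key = (g.end - g.start, -g.start)
        cur_key = (cur.end - cur.start, -cur.start)
        if key > cur_key:
            best[g.gene_id] = g
    return sorted(best.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


# ---------------------------------------------------------------------------
# Region derivation
# ---------------------------------------------------------------------------

def derive_gene_regions(
    gene: GeneModel, chrom_size: int | None = None
) -> GeneRegions:
    """Derive promoter, UTR/exon/intron partition, and the TTS flank.

    The promoter spans [TSS-1000, TSS+1000) and the TTS flank extends
    1000 bp downstream of the TTS in the direction of transcription, both
    clipped to the chromosome (and the flank to a nonempty interval).
    """
    tss, tts = gene.tss, gene.tts
    lo = max(0, tss - PROMOTER_FLANK)
    hi = tss + PROMOTER_FLANK
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    promoter = GenomicInterval(gene.chrom, lo, hi, gene.strand)

    if gene.strand == "+":
        fs, fe = tts, tts + TTS_FLANK
    else:
        fs, fe = tts - TTS_FLANK, tts
    fs = max(0, fs)
    if chrom_size is not None:
        fe = min(fe, chrom_size)
    tts_flank = (
        GenomicInterval(gene.chrom, fs, fe, gene.strand) if fe > fs else None
    )

    exons = [
        GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in gene.exons
    ]
    introns = [
        GenomicInterval(gene.chrom, e1, s2, gene.strand)
        for (_, e1), (s2, _) in zip(gene.exons, gene.exons[1:])
        if s2 > e1
    ]

    coding_exons: list[GenomicInterval] = []
    utr5: list[GenomicInterval] = []
    utr3: list[GenomicInterval] = []
    if gene.is_coding:
        for s, e in gene.exons:
            cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
            if ce > cs:
                coding_exons.append(
                    GenomicInterval(gene.chrom, cs, ce, gene.strand)
                )
            if s < gene.cds_start:
                left = GenomicInterval(
                    gene.chrom, s, min(e, gene.cds_start), gene.strand
                )
                (utr5 if gene.strand == "+" else utr3).append(left)
            if e > gene.cds_end:
                right = GenomicInterval(
                    gene.chrom, max(s, gene.cds_end), e, gene.strand
                )
                (utr3 if gene.strand == "+" else utr5).append(right)
    return GeneRegions(
        gene_id=gene.gene_id,
        promoter=promoter,
        utr5=utr5,
        utr3=utr3,
        exons=exons,
        coding_exons=coding_exons,
        introns=introns,
        tts_flank=tts_flank,
    )


def compute_cgi_shores(
    islands: Sequence[GenomicInterval], chrom_sizes: dict[str, int]
) -> ShoreSet:
    """2-kb flanks on either side of each island, truncated at chromosome
    ends and at neighboring islands (shores never absorb island sequence)."""
    order = sorted(range(len(islands)), key=lambda i: (islands[i].chrom,
                                                       islands[i].start))
    by_chrom: dict[str, list[int]] = {}
    for i in order:
        by_chrom.setdefault(islands[i].chrom, []).append(i)
    shores: list[Shore] = []
    for chrom, idxs in by_chrom.items():
        size = chrom_sizes.get(chrom)
        if size is None:
            raise AnnotationError(f"no chromosome size for {chrom}")
        for pos, i in enumerate(idxs):
            isl = islands[i]
            prev_end = islands[idxs[pos - 1]].end if pos > 0 else 0
            next_start = (
                islands[idxs[pos + 1]].start if pos + 1 < len(idxs) else size
            )
            if prev_end > isl.start:
                raise AnnotationError(
                    f"overlapping islands on {chrom} near {isl.start}"
                )
            up_s = max(isl.start - SHORE_WIDTH, prev_end, 0)
            if up_s < isl.start:
                shores.append(
                    Shore(GenomicInterval(chrom, up_s, isl.start), i, "upstream")
                )
            dn_e = min(isl.end + SHORE_WIDTH, next_start, size)
            if dn_e > isl.end:
                shores.append(
                    Shore(GenomicInterval(chrom, isl.end, dn_e), i, "downstream")
                )
    return ShoreSet(islands=list(islands), shores=shores)


def classify_cgi_location(
    island: GenomicInterval, genes: Sequence[GeneModel]
) -> str:
    """Priority classification: promoter > gene_body > intergenic."""
    for g in genes:
        if g.chrom != island.chrom:
            continue
        tss = g.tss
        if island.start < tss + PROMOTER_FLANK and island.end > tss - PROMOTER_FLANK:
            return "promoter"
    for g in genes:
        if g.chrom == island.chrom and island.start < g.end and island.end > g.start:
            return "gene_body"
    return "intergenic"


def classify_cgi_locations(
    shore_set: ShoreSet, genes: Sequence[GeneModel]
) -> ShoreSet:
    shore_set.location_class = [
        classify_cgi_location(isl, genes) for isl in shore_set.islands
    ]
    return shore_set


# ---------------------------------------------------------------------------
# CpG-density promoter classification
# ---------------------------------------------------------------------------

def _window_stats(seq: str, window: int, step: int):
    """Per-window (gc_fraction, cpg_oe) excluding ambiguous bases."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_n = (~np.isin(arr, [ord(b) for b in "ACGT"])).astype(np.int64)
    is_cg = np.zeros_like(is_c)
    if len(arr) > 1:
        is_cg[:-1] = (is_c[:-1] & is_g[1:]).astype(np.int64)

    def cum(x):
        out = np.zeros(len(x) + 1, dtype=np.int64)
        np.cumsum(x, out=out[1:])
        return out

    cc, cg_, cn, ccg = cum(is_c), cum(is_g), cum(is_n), cum(is_cg)
    n = len(arr)
    if n < window:
        starts = np.array([0])
        window = n
    else:
        starts = np.arange(0, n - window + 1, step)
    ends = starts + window
    nC = cc[ends] - cc[starts]
    nG = cg_[ends] - cg_[starts]
    nN = cn[ends] - cn[starts]
    nCG = ccg[ends] - ccg[starts]
    eff_len = (ends - starts) - nN
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(eff_len > 0, (nC + nG) / eff_len, 0.0)
        oe = np.where((nC > 0) & (nG > 0), nCG * eff_len / (nC * nG), 0.0)
    return gc, oe


def classify_promoter_cpg_density(
    promoter_seq: str, gene_id: str = "", window: int = CPG_WINDOW,
    step: int = CPG_STEP,
) -> PromoterCpGClass:
    """HCP if any window has GC >= 0.55 and CpG O/E >= 0.75; LCP if no
    window reaches O/E >= 0.48; ICP otherwise.

    O/E = (#CpG * window_length) / (#C * #G), with ambiguous bases excluded
    from all counts and from the window length.
    """
    if len(promoter_seq) == 0:
        raise AnnotationError("empty promoter sequence")
    if len(promoter_seq) < window:
        warnings.warn(
            "sequence shorter than one window; classifying as a single window",
            stacklevel=2,
        )
    gc, oe = _window_stats(promoter_seq, window, step)
    hcp = (gc >= HCP_GC_MIN) & (oe >= HCP_OE_MIN)
    # best window: maximal O/E, ties by GC
    best = int(np.lexsort((gc, oe))[-1])
    if hcp.any():
        cls = "HCP"
    elif (oe >= LCP_OE_MAX).any():
        cls = "ICP"
    else:
        cls = "LCP"
    return PromoterCpGClass(
        gene_id=gene_id,
        cpg_class=cls,
        best_window_gc=float(gc[best]),
        best_window_oe=float(oe[best]),
    )


def promoter_classification_interval(gene: GeneModel) -> GenomicInterval:
    """Genomic span read for CpG-density classification: 700 bp upstream to
    200 bp downstream of the TSS in transcription direction."""
    if gene.strand == "+":
        s, e = gene.tss - CPG_CLASS_UPSTREAM, gene.tss + CPG_CLASS_DOWNSTREAM
    else:
        s, e = gene.tss - CPG_CLASS_DOWNSTREAM, gene.tss + CPG_CLASS_UPSTREAM
    return GenomicInterval(gene.chrom, max(0, s), e, gene.strand)


def classify_gene_promoters(
    genes: Sequence[GeneModel], fasta_path: str
) -> list[PromoterCpGClass]:
    """Classify each gene's promoter from an indexed FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    out = []
    for g in genes:
        iv = promoter_classification_interval(g)
        seq = str(fa[g.chrom][iv.start:iv.end])
        out.append(classify_promoter_cpg_density(seq, gene_id=g.gene_id))
    return out


def read_bed_intervals(path: str) -> list[GenomicInterval]:
    """Read BED (>=3 columns) into intervals; strand from column 6 if present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                strand = fields[5] if len(fields) >= 6 else "."
                out.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]),
                                    strand if strand in "+-" else ".")
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str,
                        names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                     f"{iv.strand if iv.strand in '+-' else '.'}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
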
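"""FPKM-scaled composite tag-density profiles.

Features are mapped onto a shared coordinate system of absolute flank
segments and relative-length interior segments; tag midpoints are counted
per bin, scaled to FPKM by bin length and library size, and averaged over
features (minus-strand features are flipped so bins run in transcription
direction).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneModel, GenomicInterval
from .tag_processing import TagSet, fpkm_density


class ProfileError(ValueError):
    pass


@dataclass
class ProfileSpec:
    flank_bp: int = 5000
    n_flank_bins: int = 100
    n_body_bins: int = 50
    body_range: tuple[float, float] = (25.0, 75.0)
    dedup_max: int = 2

    def __post_init__(self) -> None:
        if min(self.n_flank_bins, self.n_body_bins) < 1:
            raise ProfileError("bin counts must be >= 1")
        lo, hi = self.body_range
        if not (0 <= lo < hi <= 100):
            raise ProfileError("body_range must satisfy 0 <= low < high <= 100")


@dataclass
class SegmentProfile:
    name: str
    mean_density: np.ndarray       # per-bin mean FPKM over contributing features
    n_features: np.ndarray         # contributing features per bin
    total_counts: np.ndarray       # summed raw tag counts per bin (conservation)


@dataclass
class DensityProfile:
    segments: list[SegmentProfile]
    library_size: int
    n_features_total: int
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            for b in range(len(seg.mean_density)):
                rows.append(
                    {
                        "segment": seg.name,
                        "bin": b,
                        "mean_density": seg.mean_density[b],
                        "n_features": int(seg.n_features[b]),
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def log2_display(density: np.ndarray, eps: float = 0.01) -> np.ndarray:
    """Presentation-only log2 transform; stored profiles stay linear."""
    return np.log2(np.asarray(density) + eps)


def _bin_counts(mids: np.ndarray | None, edges: np.ndarray) -> np.ndarray:
    if mids is None or len(mids) == 0:
        return np.zeros(len(edges) - 1, dtype=np.int64)
    return np.diff(np.searchsorted(mids, edges)).astype(np.int64)


class _Accumulator:
    def __init__(self, name: str, n_bins: int) -> None:
        self.name = name
        self.density_sum = np.zeros(n_bins)
        self.n = np.zeros(n_bins, dtype=np.int64)
        self.count_sum = np.zeros(n_bins, dtype=np.int64)

    def add(self, counts: np.ndarray, bin_len: float, library_size: int,
            flip: bool) -> None:
        if flip:
            counts = counts[::-1]
        dens = np.array(
            [fpkm_density(c, bin_len, library_size) for c in counts]
        )
        self.density_sum += dens
        self.count_sum += counts
        self.n += 1

    def finish(self) -> SegmentProfile:
        with np.errstate(invalid="ignore"):
            mean = np.where(self.n > 0, self.density_sum / np.maximum(self.n, 1),
                            0.0)
        return SegmentProfile(
            name=self.name, mean_density=mean, n_features=self.n,
            total_counts=self.count_sum,
        )


def composite_gene_profile(
    tags: TagSet,
    genes: Sequence[GeneModel],
    spec: ProfileSpec,
    chrom_sizes: dict[str, int] | None = None,
) -> DensityProfile:
    """TSS-flank / relative gene-body / TTS-flank composite profile.

    Segments: [TSS - flank, TSS + flank) in absolute bins, the gene body
    from ``body_range`` low% to high% of transcript length in
    relative-length bins, and [TTS - flank, TTS + flank) in absolute bins.
    Genes whose flanks leave the chromosome or whose body is shorter than
    one bin per relative window are skipped and counted.
    """
    if not genes:
        raise ProfileError("empty gene list")
    sizes = chrom_sizes or {}
    lo_frac, hi_frac = spec.body_range[0] / 100.0, spec.body_range[1] / 100.0
    acc_tss = _Accumulator("tss_flank", 2 * spec.n_flank_bins)
    acc_body = _Accumulator("gene_body", spec.n_body_bins)
    acc_tts = _Accumulator("tts_flank", 2 * spec.n_flank_bins)
    flank_bin = spec.flank_bp / spec.n_flank_bins
    lib = tags.library_size
    if lib <= 0:
        raise ProfileError("empty tag library")
    skipped = 0
    used = 0
    for g in genes:
        size = sizes.get(g.chrom)
        mids = tags.midpoints.get(g.chrom)
        tss, tts = g.tss, g.tts
        if tss - spec.flank_bp < 0 or tts - spec.flank_bp < 0:
            skipped += 1
            continue
        if size is not None and max(tss, tts) + spec.flank_bp > size:
            skipped += 1
            continue
        length = g.end - g.start
        b0 = g.start + lo_frac * length
        b1 = g.start + hi_frac * length
        if (b1 - b0) < spec.n_body_bins:
            skipped += 1
            continue
        flip = g.strand == "-"
        tss_edges = np.linspace(
            tss - spec.flank_bp, tss + spec.flank_bp, 2 * spec.n_flank_bins + 1
        )
        tts_edges = np.linspace(
            tts - spec.flank_bp, tts + spec.flank_bp, 2 * spec.n_flank_bins + 1
        )
        body_edges = np.linspace(b0, b1, spec.n_body_bins + 1)
        acc_tss.add(_bin_counts(mids, tss_edges), flank_bin, lib, flip)
        acc_body.add(
            _bin_counts(mids, body_edges),
            (b1 - b0) / spec.n_body_bins, lib, flip,
        )
        acc_tts.add(_bin_counts(mids, tts_edges), flank_bin, lib, flip)
        used += 1
    if used == 0:
        raise ProfileError("no usable genes for profiling")
    return DensityProfile(
        segments=[acc_tss.finish(), acc_body.finish(), acc_tts.finish()],
        library_size=lib, n_features_total=used, n_skipped=skipped,
    )


def scaled_interval_profile(
    tags: TagSet,
    intervals: Sequence[GenomicInterval],
    spec: ProfileSpec,
    n_interior_bins: int | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> DensityProfile:
    """Interval profile: absolute flanks plus a 0-100% relative interior.

    Used for CpG islands (flanks covering the 2-kb shores and beyond),
    enhancers, and exons.
    """
    if not intervals:
        raise ProfileError("empty interval list")
    n_int = n_interior_bins or spec.n_body_bins
    sizes = chrom_sizes or {}
    acc_up = _Accumulator("upstream_flank", spec.n_flank_bins)
    acc_in = _Accumulator("interior", n_int)
    acc_dn = _Accumulator("downstream_flank", spec.n_flank_bins)
    flank_bin = spec.flank_bp / spec.n_flank_bins
    lib = tags.library_size
    if lib <= 0:
        raise ProfileError("empty tag library")
    skipped = 0
    used = 0
    for iv in intervals:
        size = sizes.get(iv.chrom)
        mids = tags.midpoints.get(iv.chrom)
        if iv.start - spec.flank_bp < 0:
            skipped += 1
            continue
        if size is not None and iv.end + spec.flank_bp > size:
            skipped += 1
            continue
        if iv.length() < n_int:
            skipped += 1
            continue
        flip = iv.strand == "-"
        up_edges = np.linspace(iv.start - spec.flank_bp, iv.start,
                               spec.n_flank_bins + 1)
        in_edges = np.linspace(iv.start, iv.end, n_int + 1)
        dn_edges = np.linspace(iv.end, iv.end + spec.flank_bp,
                               spec.n_flank_bins + 1)
        up = _bin_counts(mids, up_edges)
        ins = _bin_counts(mids, in_edges)
        dn = _bin_counts(mids, dn_edges)
        if flip:
            up, dn = dn, up
        acc_up.add(up, flank_bin, lib, flip)
        acc_in.add(ins, iv.length() / n_int, lib, flip)
        acc_dn.add(dn, flank_bin, lib, flip)
        used += 1
    if used == 0:
        raise ProfileError("no usable intervals for profiling")
    return DensityProfile(
        segments=[acc_up.finish(), acc_in.finish(), acc_dn.finish()],
        library_size=lib, n_features_total=used, n_skipped=skipped,
    )
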
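"""Aligned reads -> deduplicated, 3'-extended fragment-midpoint tags.

Reads are held in a pandas DataFrame with columns ``chrom, start, end,
strand`` (0-based half-open). Two dedup policies coexist: max 1 read per
(chrom, 5' position, strand) for island calling, max 2 for profile work.
Each fragment contributes one midpoint tag after extension to the fragment
length in the 3' direction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

READ_COLUMNS = ["chrom", "start", "end", "strand"]


class TagError(ValueError):
    pass


@dataclass
class TagSet:
    """Per-chromosome sorted fragment-midpoint arrays."""

    midpoints: dict[str, np.ndarray]
    fragment_length: int
    dedup_max: int | None = None

    @property
    def library_size(self) -> int:
        return int(sum(len(v) for v in self.midpoints.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        mids = self.midpoints.get(chrom)
        if mids is None:
            return 0
        return int(np.searchsorted(mids, end) - np.searchsorted(mids, start))

    def count_in_many(self, chrom: str, starts, ends) -> np.ndarray:
        mids = self.midpoints.get(chrom)
        if mids is None:
            return np.zeros(len(starts), dtype=np.int64)
        return (np.searchsorted(mids, ends) - np.searchsorted(mids, starts)).astype(
            np.int64
        )


@dataclass
class WindowCounts:
    window_size: int
    counts: dict[str, np.ndarray]
    library_size: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return int(sum(len(v) for v in self.counts.values()))


def read_bed_reads(path: str) -> pd.DataFrame:
    """Read aligned reads from BED6 (name/score columns ignored)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 5], names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    _validate_reads(df)
    return df


def read_sam_reads(path: str, min_mapq: int = 1) -> pd.DataFrame:
    """Read aligned reads from SAM/BAM, dropping unmapped, secondary,
    supplementary, and low-MAPQ (multi-mapping) records."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            rows.append(
                (rec.reference_name, rec.reference_start, rec.reference_end,
                 "-" if rec.is_reverse else "+")
            )
    df = pd.DataFrame(rows, columns=READ_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _validate_reads(df)
    return df


def _validate_reads(df: pd.DataFrame) -> None:
    if isinstance(df, TagSet):
        raise TypeError("expected aligned reads, got a TagSet")
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise TagError(f"read table missing columns {missing}")
    if len(df) and not (df["end"] > df["start"]).all():
        raise TagError("reads must have positive length")


def deduplicate_reads(reads: pd.DataFrame, max_per_position: int) -> pd.DataFrame:
    """Keep at most ``max_per_position`` reads per (chrom, 5' start, strand).

    Retention is deterministic: the first occurrences in coordinate-sorted
    order are kept.
    """
    _validate_reads(reads)
    if max_per_position < 1:
        raise TagError("max_per_position must be >= 1")
    if len(reads) == 0:
        return reads.copy()
    df = reads.sort_values(
        ["chrom", "start", "end", "strand"], kind="stable"
    ).reset_index(drop=True)
    pos5 = np.where(df["strand"].to_numpy() == "+", df["start"], df["end"])
    df = df.assign(_pos5=pos5)
    keep = df.groupby(["chrom", "_pos5", "strand"]).cumcount() < max_per_position
    return df.loc[keep, READ_COLUMNS].reset_index(drop=True)


def reads_to_tags(
    reads: pd.DataFrame,
    fragment_length: int = 300,
    chrom_sizes: dict[str, int] | None = None,
) -> TagSet:
    """Extend each read to ``fragment_length`` in its 3' direction and take
    the fragment midpoint as the tag position.

    Fragments protruding past a chromosome edge are clipped first; the
    midpoint is then taken on the clipped interval, so no read is discarded.
    """
    _validate_reads(reads)
    if len(reads) and fragment_length < int((reads["end"] - reads["start"]).max()):
        raise TagError("fragment_length shorter than read length")
    midpoints: dict[str, np.ndarray] = {}
    for chrom, grp in reads.groupby("chrom", sort=True):
        start = grp["start"].to_numpy(np.int64)
        end = grp["end"].to_numpy(np.int64)
        plus = grp["strand"].to_numpy() == "+"
        frag_s = np.where(plus, start, end - fragment_length)
        frag_e = np.where(plus, start + fragment_length, end)
        frag_s = np.maximum(frag_s, 0)
        if chrom_sizes is not None:
            size = chrom_sizes.get(str(chrom))
            if size is not None:
                frag_e = np.minimum(frag_e, size)
        mids = (frag_s + frag_e) // 2
        mids.sort()
        midpoints[str(chrom)] = mids
    return TagSet(midpoints=midpoints, fragment_length=fragment_length)


def count_window_tags(
    tags: TagSet, window_size: int = 200,
    chrom_sizes: dict[str, int] | None = None,
) -> WindowCounts:
    """Count tag midpoints in non-overlapping windows tiling each chromosome."""
    if not isinstance(tags, TagSet):
        raise TypeError("expected a TagSet")
    if window_size <= 0:
        raise TagError("window_size must be positive")
    sizes = dict(chrom_sizes) if chrom_sizes else {}
    if not sizes:
        sizes = {
            chrom: int(mids[-1]) + 1 if len(mids) else window_size
            for chrom, mids in tags.midpoints.items()
        }
    counts: dict[str, np.ndarray] = {}
    for chrom, size in sizes.items():
        n_win = -(-size // window_size)
        mids = tags.midpoints.get(chrom)
        if mids is None or len(mids) == 0:
            counts[chrom] = np.zeros(n_win, dtype=np.int64)
            continue
        idx = mids // window_size
        counts[chrom] = np.bincount(idx, minlength=n_win).astype(np.int64)
    return WindowCounts(
        window_size=window_size, counts=counts,
        library_size=tags.library_size, chrom_sizes=sizes,
    )


def fpkm_density(count: float, feature_length_bp: float, library_size: float) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if feature_length_bp <= 0:
        raise TagError("feature length must be positive")
    if library_size <= 0:
        raise TagError("library size must be positive")
    return count / (feature_length_bp / 1000.0) / (library_size / 1e6)


def write_bedgraph(window_counts: WindowCounts, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(window_counts.counts):
            vec = window_counts.counts[chrom]
            w = window_counts.window_size
            size = window_counts.chrom_sizes.get(chrom, len(vec) * w)
            for i, c in enumerate(vec):
                if c:
                    fh.write(f"{chrom}\t{i * w}\t{min((i + 1) * w, size)}\t{c}\n")


def write_bed_reads(reads: pd.DataFrame, path: str) -> None:
    df = reads.copy()
    df.insert(3, "name", [f"read_{i}" for i in range(len(df))])
    df.insert(4, "score", 0)
    df.to_csv(path, sep="\t", header=False, index=False)
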
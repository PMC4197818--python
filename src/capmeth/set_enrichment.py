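"""Gene-set overlap statistics, expression tiers, and enhancer-gene linkage.

Overlap significance uses the exact two-tailed Fisher test (sum of
hypergeometric outcomes no more probable than the observed table) plus the
conservative EASE variant: the one-tailed enrichment p recomputed after
decrementing the overlap cell by one (floored at zero).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GeneModel, GenomicInterval

_TIE_SLACK = 1 + 1e-12  # float tolerance for pmf ties in the two-tailed sum


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    k: int   # overlap
    n1: int  # size of set A
    n2: int  # size of set B
    N: int   # universe

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n1, self.n2)):
            raise EnrichmentError("overlap exceeds a set size")
        if max(self.n1, self.n2) > self.N:
            raise EnrichmentError("set larger than universe")
        if self.k < self.n1 + self.n2 - self.N:
            raise EnrichmentError("overlap below the feasible minimum")


@dataclass
class OverlapResult:
    table: ContingencyTable
    fisher_p_two_tailed: float
    ease_p: float
    enrichment_p: float  # one-tailed, undecremented
    odds_ratio: float
    direction: str  # {"over", "under"}


def ease_fisher(table: ContingencyTable, ease: bool = True) -> OverlapResult:
    """Exact two-tailed Fisher p plus the (optionally disabled) EASE p.

    The EASE p is the one-tailed enrichment tail P(X >= k-1) with the
    overlap decremented by one and floored at zero, so k <= 1 gives 1.0.
    Odds ratio uses a Haldane 0.5 correction when a cell is zero.
    Direction is "over" only for strictly greater-than-expected overlap.
    """
    k, n1, n2, N = table.k, table.n1, table.n2, table.N
    lo = max(0, n1 + n2 - N)
    hi = min(n1, n2)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, n1, n2)
    p_obs = pmf[k - lo]
    p_two = float(min(1.0, pmf[pmf <= p_obs * _TIE_SLACK].sum()))
    enrichment_p = float(min(1.0, stats.hypergeom.sf(k - 1, N, n1, n2)))
    k_ease = max(k - 1, 0)
    ease_p = float(min(1.0, stats.hypergeom.sf(k_ease - 1, N, n1, n2)))
    a, b, c, d = k, n1 - k, n2 - k, N - n1 - n2 + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    direction = "over" if k * N > n1 * n2 else "under"
    return OverlapResult(
        table=table,
        fisher_p_two_tailed=p_two,
        ease_p=ease_p if ease else enrichment_p,
        enrichment_p=enrichment_p,
        odds_ratio=float(odds),
        direction=direction,
    )


def set_overlap_test(
    sets: dict[str, set], universe: set
) -> tuple[dict[tuple[str, str], OverlapResult], dict[tuple[str, ...], int]]:
    """Pairwise overlap tests plus Venn region counts for up to 3 sets."""
    for name, s in sets.items():
        extra = s - universe
        if extra:
            raise EnrichmentError(
                f"set {name!r} has elements outside the universe: "
                f"{sorted(extra)[:3]}"
            )
    names = list(sets)
    pairwise: dict[tuple[str, str], OverlapResult] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            tbl = ContingencyTable(
                k=len(sets[a] & sets[b]), n1=len(sets[a]), n2=len(sets[b]),
                N=len(universe),
            )
            pairwise[(a, b)] = ease_fisher(tbl)
    venn: dict[tuple[str, ...], int] = {}
    if len(names) <= 3:
        import itertools

        for r in range(1, len(names) + 1):
            for combo in itertools.combinations(names, r):
                inside = set.intersection(*(sets[c] for c in combo))
                outside = set().union(
                    *(sets[n] for n in names if n not in combo), set()
                )
                venn[combo] = len(inside - outside)
    return pairwise, venn


@dataclass
class ExpressionClasses:
    table: pd.DataFrame  # gene_id, tier, log2_fc_<cond>, up_<cond>, down_<cond>
    baseline: str
    conditions: list[str]
    lfc_threshold: float

    def tier_sets(self) -> dict[str, set]:
        return {
            t: set(self.table.loc[self.table["tier"] == t, "gene_id"])
            for t in ("high", "moderate", "low")
        }

    def repressed(self, condition: str) -> set:
        return set(self.table.loc[self.table[f"down_{condition}"], "gene_id"])

    def activated(self, condition: str) -> set:
        return set(self.table.loc[self.table[f"up_{condition}"], "gene_id"])


def classify_expression(
    expression: pd.DataFrame,
    baseline: str,
    conditions: Sequence[str] = (),
    lfc_threshold: float = 0.585,
) -> ExpressionClasses:
    """Tertile high/moderate/low tiers on baseline expression plus per-
    condition up/down flags at |log2FC| >= threshold.

    Tie handling is deterministic: genes are ranked by (value, input order),
    so equal values are assigned tiers by stable rank.
    """
    if baseline not in expression.columns:
        raise EnrichmentError(f"missing baseline column {baseline!r}")
    df = expression.reset_index(drop=True).copy()
    n = len(df)
    if n == 0:
        raise EnrichmentError("empty expression table")
    values = df[baseline].to_numpy(dtype=float)
    order = np.lexsort((np.arange(n), values))
    tier = np.empty(n, dtype=object)
    for rank, gi in enumerate(order):
        tier[gi] = ("low", "moderate", "high")[3 * rank // n]
    out = pd.DataFrame({"gene_id": df["gene_id"], "tier": tier})
    for cond in conditions:
        if cond not in df.columns:
            raise EnrichmentError(f"missing condition column {cond!r}")
        with np.errstate(divide="ignore"):
            lfc = np.log2(df[cond].to_numpy(dtype=float) / values)
        out[f"log2_fc_{cond}"] = lfc
        out[f"up_{cond}"] = lfc >= lfc_threshold
        out[f"down_{cond}"] = lfc <= -lfc_threshold
    return ExpressionClasses(
        table=out, baseline=baseline, conditions=list(conditions),
        lfc_threshold=lfc_threshold,
    )


@dataclass
class LinkageResult:
    links: pd.DataFrame  # enhancer, gene_id, distance, repressed
    overlap: OverlapResult | None
    linked_genes: set
    fraction_repression_explained: float


def enhancer_gene_linkage(
    enhancers_with_loss: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    repressed_genes: set,
    universe: set | None = None,
    max_distance: int = 20_000,
) -> LinkageResult:
    """Assign each enhancer to the nearest-TSS gene within ``max_distance``
    (distance 0 when the TSS lies inside the enhancer; ties to the gene
    with smaller transcript start), then test the assigned genes for
    over-representation of the repressed set.
    """
    universe = universe if universe is not None else {g.gene_id for g in genes}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    linked_genes: set = set()
    for i, iv in enumerate(enhancers_with_loss):
        best: tuple[int, int, str] | None = None
        for g in by_chrom.get(iv.chrom, []):
            tss = g.tss
            if iv.start <= tss < iv.end:
                d = 0
            elif tss < iv.start:
                d = iv.start - tss
            else:
                d = tss - iv.end
            if best is None or (d, g.start) < (best[0], best[1]):
                best = (d, g.start, g.gene_id)
        if best is None or best[0] > max_distance:
            continue
        linked_genes.add(best[2])
        rows.append(
            {
                "enhancer": f"{iv.chrom}:{iv.start}-{iv.end}",
                "gene_id": best[2],
                "distance": best[0],
                "repressed": best[2] in repressed_genes,
            }
        )
    links = pd.DataFrame(
        rows, columns=["enhancer", "gene_id", "distance", "repressed"]
    )
    repressed_in_universe = repressed_genes & universe
    overlap = None
    if universe:
        overlap = ease_fisher(
            ContingencyTable(
                k=len(linked_genes & repressed_in_universe),
                n1=len(linked_genes),
                n2=len(repressed_in_universe),
                N=len(universe),
            )
        )
    frac = (
        len(linked_genes & repressed_in_universe) / len(repressed_in_universe)
        if repressed_in_universe
        else 0.0
    )
    return LinkageResult(
        links=links, overlap=overlap, linked_genes=linked_genes,
        fraction_repression_explained=frac,
    )


def write_gene_set(genes: Iterable[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gene_set(path: str) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
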
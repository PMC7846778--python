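"""Genomic interval arithmetic and CGI annotation.

All coordinates are 0-based half-open (BED convention). Strand is ignored
for overlap operations: methylation counts are strand-combined upstream and
CGIs are unstranded features.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import fisher_exact


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.start < 0:
            raise ValueError("start must be >= 0")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: TSS positions plus transcript spans.

    ``tss`` holds point-like intervals (1 bp wide) for each annotated
    transcription start site; ``transcripts`` the full transcript spans.
    """

    gene_id: str
    tss: tuple[GenomicInterval, ...]
    transcripts: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        for t in self.tss:
            if not any(t.chrom == tx.chrom and tx.start <= t.start < tx.end
                       for tx in self.transcripts):
                raise ValueError(
                    f"TSS {t.chrom}:{t.start} of {self.gene_id} outside all transcripts"
                )


@dataclass(frozen=True)
class AnnotationResult:
    """Positional category of a CGI relative to gene models."""

    cgi: GenomicInterval
    category: str  # "TSS" | "gene_body" | "intergenic"
    assigned_genes: tuple[str, ...]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (and book-ended) intervals per chromosome.

    Returns a sorted, pairwise-disjoint list covering the same bases.
    Book-ended intervals (one ending where the next starts) are merged,
    matching the common merge-tool default.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    return dict(trees)


def filter_intervals(
    intervals: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval] = (),
    allowed_chroms: Iterable[str] | None = None,
) -> list[GenomicInterval]:
    """Drop intervals on disallowed chromosomes or touching a blacklist region.

    Any overlap (>= 1 bp) with a blacklist interval removes the interval,
    mirroring the exclusion of blacklist-listed regions and non-autosomal
    CGIs from all analyses.
    """
    allowed = set(allowed_chroms) if allowed_chroms is not None else None
    trees = _build_trees(blacklist)
    out = []
    for iv in intervals:
        if allowed is not None and iv.chrom not in allowed:
            continue
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            continue
        out.append(iv)
    return out


def annotate_cgis(
    cgis: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> list[AnnotationResult]:
    """Categorise CGIs as TSS, gene_body or intergenic.

    Precedence: a CGI overlapping any protein-coding TSS is "TSS"; otherwise
    one overlapping any transcript is "gene_body"; the rest are "intergenic".
    Categories are exhaustive and mutually exclusive.
    """
    if not genes:
        raise ValueError("gene models must be non-empty")
    tss_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    tx_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        for t in g.tss:
            tss_trees[t.chrom].addi(t.start, t.end, g.gene_id)
        for tx in g.transcripts:
            tx_trees[tx.chrom].addi(tx.start, tx.end, g.gene_id)

    results = []
    for cgi in cgis:
        tss_hits = sorted(
            {h.data for h in tss_trees.get(cgi.chrom, IntervalTree()).overlap(cgi.start, cgi.end)}
        )
        if tss_hits:
            results.append(AnnotationResult(cgi, "TSS", tuple(tss_hits)))
            continue
        tx_hits = sorted(
            {h.data for h in tx_trees.get(cgi.chrom, IntervalTree()).overlap(cgi.start, cgi.end)}
        )
        if tx_hits:
            results.append(AnnotationResult(cgi, "gene_body", tuple(tx_hits)))
        else:
            results.append(AnnotationResult(cgi, "intergenic", ()))
    return results


def map_cgis_to_genes(
    cgis: Sequence[GenomicInterval], genes: Sequence[GeneModel]
) -> dict[GenomicInterval, frozenset[str]]:
    """Assign CGIs to genes for downstream term enrichment.

    TSS-overlapping CGIs map to the genes of those TSSs; otherwise CGIs
    within a transcript map to those genes; otherwise to the closest TSS(s)
    on the chromosome, measured from the CGI edge, keeping all ties.
    CGIs on chromosomes without genes map to an empty set (unmapped).
    """
    annotated = {r.cgi: r for r in annotate_cgis(cgis, genes)}
    tss_by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for g in genes:
        for t in g.tss:
            tss_by_chrom[t.chrom].append((t.start, g.gene_id))

    mapping: dict[GenomicInterval, frozenset[str]] = {}
    for cgi in cgis:
        res = annotated[cgi]
        if res.assigned_genes:
            mapping[cgi] = frozenset(res.assigned_genes)
            continue
        positions = tss_by_chrom.get(cgi.chrom)
        if not positions:
            mapping[cgi] = frozenset()
            continue
        # distance from the nearest CGI edge to the TSS position
        def dist(pos: int) -> int:
            if pos < cgi.start:
                return cgi.start - pos
            if pos >= cgi.end:
                return pos - (cgi.end - 1)
            return 0

        dmin = min(dist(p) for p, _ in positions)
        mapping[cgi] = frozenset(g for p, g in positions if dist(p) == dmin)
    return mapping


def count_overlaps(
    fragments: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """Count fragments overlapping each region by >= 1 bp.

    A fragment spanning several regions increments each of them. Returns an
    integer array aligned with ``regions``.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, r in enumerate(regions):
        trees[r.chrom].addi(r.start, r.end, i)
    counts = np.zeros(len(regions), dtype=np.int64)
    for f in fragments:
        tree = trees.get(f.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(f.start, f.end):
            counts[hit.data] += 1
    return counts


def overlap_enrichment(
    target_set: Sequence[GenomicInterval],
    feature_peaks: Sequence[GenomicInterval],
    background: Sequence[GenomicInterval],
    sided: str = "greater",
) -> tuple[float, float, float]:
    """Fisher's exact test for peak overlap of a CGI subset vs all CGIs.

    The 2x2 table crosses membership (target vs rest of background) with
    peak overlap (any overlap >= 1 bp). Fold enrichment is the target
    overlap rate over the background (all-CGI) overlap rate.

    Returns ``(fold_enrichment, odds_ratio, p_value)``.
    """
    if not background:
        raise ValueError("background must be non-empty")
    bg = list(background)
    target = set(target_set)
    if not target.issubset(set(bg)):
        raise ValueError("target_set must be a subset of background")
    trees = _build_trees(feature_peaks)

    def hits_peak(iv: GenomicInterval) -> bool:
        tree = trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    overlap_flags = {iv: hits_peak(iv) for iv in bg}
    k_target = sum(overlap_flags[iv] for iv in bg if iv in target)
    n_target = len(target)
    k_bg = sum(overlap_flags.values())
    n_bg = len(bg)
    k_rest = k_bg - k_target
    n_rest = n_bg - n_target

    table = [[k_target, n_target - k_target], [k_rest, n_rest - k_rest]]
    alternative = {"greater": "greater", "less": "less", "two-sided": "two-sided"}[sided]
    odds_ratio, p = fisher_exact(table, alternative=alternative)
    bg_rate = k_bg / n_bg
    fold = (k_target / n_target) / bg_rate if bg_rate > 0 else np.nan
    return float(fold), float(odds_ratio), float(p)


def make_windows(
    region: GenomicInterval, window_size: int, n_windows: int
) -> list[GenomicInterval]:
    """Contiguous fixed-width windows centred on the region midpoint.

    Odd ``n_windows`` centres the middle window on the midpoint; even
    ``n_windows`` places the midpoint at the boundary between the two
    central windows. Windows are truncated at chromosome start (0); windows
    that would lie entirely before position 0 are dropped.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    mid = region.midpoint
    if n_windows % 2 == 0:
        left = mid - (n_windows // 2) * window_size
    else:
        left = mid - window_size // 2 - (n_windows // 2) * window_size
    windows = []
    for i in range(n_windows):
        s = left + i * window_size
        e = s + window_size
        if e <= 0:
            continue
        windows.append(
            GenomicInterval(region.chrom, max(s, 0), e,
                            name=f"{region.name or region.chrom}_w{i}")
        )
    return windows
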
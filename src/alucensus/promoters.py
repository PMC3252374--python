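"""Promoter-window counting and chromatin-accessibility overlap.

The unit counted per promoter is the repeat *element* carrying at least one
fully contained binder site (not the individual k-mer hit): a gene's
promoter window is the W bases strictly upstream of its transcription start
site (strand-aware, half-open, clipped at contig bounds), and an element
counts for a gene when it overlaps the window by one nucleotide or more.
The enrichment cutoff for downstream ontology analysis is
ceil(mean + k_sd * sample SD) of the per-gene counts. Accessibility uses
the same >=1-nt overlap rule against accessible-region intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware upstream window anchored at a TSS (0-based, half-open)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    clipped: bool = False


def build_promoter_windows(tss_table: pd.DataFrame, window_size: int = 5000,
                           contig_lengths: Optional[Mapping[str, int]] = None,
                           ) -> List[PromoterWindow]:
    """Upstream windows from a BED6 TSS table (start column = TSS position).

    Plus strand: [TSS - W, TSS). Minus strand: the W bases upstream are
    (TSS, TSS + W], represented half-open as [TSS + 1, TSS + 1 + W).
    Windows are clipped at position 0 and, when contig lengths are given,
    at contig ends; clipped windows are flagged. A TSS outside its contig
    raises.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    windows = []
    for row in tss_table.itertuples(index=False):
        tss = int(row.start)
        contig_len = contig_lengths.get(row.chrom) if contig_lengths else None
        if tss < 0 or (contig_len is not None and tss >= contig_len):
            raise ValueError(f"TSS {tss} of {row.name} outside contig {row.chrom}")
        if row.strand == "+":
            start, end = tss - window_size, tss
        elif row.strand == "-":
            start, end = tss + 1, tss + 1 + window_size
        else:
            raise ValueError(f"unknown strand {row.strand!r} for {row.name}")
        clipped_start = max(start, 0)
        clipped_end = min(end, contig_len) if contig_len is not None else end
        windows.append(PromoterWindow(
            gene_id=str(row.name), chrom=row.chrom, tss=tss, strand=row.strand,
            start=clipped_start, end=clipped_end,
            clipped=(clipped_start != start or clipped_end != end)))
    return windows


def _interval_of(element) -> Tuple[str, int, int]:
    if hasattr(element, "chrom"):
        return element.chrom, element.start, element.end
    chrom, start, end = element[:3]
    return chrom, int(start), int(end)


def promoter_element_counts(windows: Sequence[PromoterWindow],
                            elements: Sequence) -> Tuple[pd.DataFrame, float]:
    """Per-gene count of elements overlapping the promoter window (>=1 nt).

    ``elements`` may be RepeatFeatures or (chrom, start, end[, ...]) tuples.
    An element overlapping two promoters counts for both genes. Returns the
    per-gene table and the mean count over all genes (0.0 for no genes is
    undefined; an empty window list yields an empty frame and mean nan).
    """
    trees: Dict[str, IntervalTree] = {}
    for element in elements:
        chrom, start, end = _interval_of(element)
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    rows = []
    for w in windows:
        tree = trees.get(w.chrom)
        n = len(tree.overlap(w.start, w.end)) if tree is not None else 0
        rows.append({"gene_id": w.gene_id, "chrom": w.chrom, "tss": w.tss,
                     "strand": w.strand, "n_elements": n})
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "n_elements"])
    mean = float(frame["n_elements"].mean()) if len(frame) else float("nan")
    return frame, mean


def enrichment_cutoff(counts: pd.DataFrame | pd.Series | Mapping[str, int],
                      k_sd: float = 2.0) -> Tuple[int, List[str]]:
    """Cutoff = ceil(mean + k_sd * sample SD) of per-gene element counts.

    Genes with count >= cutoff are flagged enriched (the list feeds
    external gene-ontology tools). With a degenerate SD of 0 the cutoff is
    ceil(mean). Requires at least 2 genes.
    """
    if isinstance(counts, pd.DataFrame):
        series = counts.set_index("gene_id")["n_elements"]
    elif isinstance(counts, pd.Series):
        series = counts
    else:
        series = pd.Series(dict(counts))
    if len(series) < 2:
        raise ValueError("need >= 2 genes for an enrichment cutoff")
    mean = float(series.mean())
    sd = float(series.std(ddof=1))
    cutoff = math.ceil(mean) if sd == 0 or np.isnan(sd) else math.ceil(mean + k_sd * sd)
    enriched = sorted(str(g) for g, n in series.items() if n >= cutoff)
    return cutoff, enriched


def accessibility_overlap(elements: Sequence,
                          accessible_regions: pd.DataFrame | Sequence,
                          ) -> Tuple[pd.DataFrame, int]:
    """Overlap of elements with accessible-chromatin intervals (>=1 nt).

    Returns one row per element (id, overlap count, accessible flag) and
    the genome-wide number of accessible elements.
    """
    if isinstance(accessible_regions, pd.DataFrame):
        region_iter = accessible_regions.itertuples(index=False)
    else:
        region_iter = accessible_regions
    trees: Dict[str, IntervalTree] = {}
    for region in region_iter:
        chrom, start, end = _interval_of(region)
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    rows = []
    for element in elements:
        chrom, start, end = _interval_of(element)
        tree = trees.get(chrom)
        n = len(tree.overlap(start, end)) if tree is not None else 0
        rows.append({"chrom": chrom, "start": start, "end": end,
                     "n_overlapping_accessible_regions": n, "accessible": n >= 1})
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                        "n_overlapping_accessible_regions", "accessible"])
    total = int(frame["accessible"].sum()) if len(frame) else 0
    return frame, total


def genes_with_accessible_element(windows: Sequence[PromoterWindow],
                                  elements: Sequence,
                                  accessible_regions: pd.DataFrame | Sequence) -> int:
    """Number of genes whose promoter window overlaps >=1 accessible element."""
    overlap_frame, _ = accessibility_overlap(elements, accessible_regions)
    accessible = overlap_frame[overlap_frame["accessible"]]
    trees: Dict[str, IntervalTree] = {}
    for row in accessible.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    n_genes = 0
    for w in windows:
        tree = trees.get(w.chrom)
        if tree is not None and tree.overlap(w.start, w.end):
            n_genes += 1
    return n_genes
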
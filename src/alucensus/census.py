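"""Census tables over annotated genome hits.

Four summaries mirror the standard reporting of a repeat-family binding
site census:

* per-k-mer frequency: how many of a k-mer's genome occurrences fall inside
  repeats of a target class (e.g. the Alu families);
* per-element multiplicity: histogram of the number of sites per repeat
  copy;
* family / subfamily summary: fraction of elements of each class carrying
  at least one fully contained site;
* consensus-position histogram: where within the repeat consensus the sites
  sit (the positional peaks that distinguish younger from older families).

Only fully contained hits count as "in" a repeat. Percentages are printed
with half-up rounding to 2 decimals so that table cells are exactly
reproducible from their own integer columns.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .repeats import ALU_FAMILY_CLASSES, AnnotatedHit


def percent_half_up(numerator: int, denominator: int, ndigits: int = 2) -> Optional[float]:
    """100 * numerator / denominator, rounded half-up; None when denominator is 0.

    Computed in decimal arithmetic so boundary cases round the way printed
    tables do, not the way binary floats happen to.
    """
    if denominator == 0:
        return None
    quantum = Decimal(1).scaleb(-ndigits)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(quantum, ROUND_HALF_UP)
    return float(value)


def _contained(annotated_hits: Iterable[AnnotatedHit],
               classes: Optional[Sequence[str]]) -> List[AnnotatedHit]:
    out = []
    for a in annotated_hits:
        if a.containment != "contained":
            continue
        if classes is not None and a.repeat.family_class not in classes:
            continue
        out.append(a)
    return out


def kmer_frequency_table(annotated_hits: Sequence[AnnotatedHit],
                         target_classes: Sequence[str] = ALU_FAMILY_CLASSES,
                         kmers: Optional[Iterable[str]] = None,
                         pbm_scores: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """Per-k-mer occurrence counts inside the target class vs genome-wide.

    One row per k-mer (every k-mer seen in the hits, or the explicit
    ``kmers`` list to include zero-count rows), sorted by percent
    descending then genome count descending. ``percent`` is empty (NaN)
    for k-mers with no genome occurrences.
    """
    genome_counts = Counter(a.hit.kmer_id for a in annotated_hits)
    class_counts = Counter(a.hit.kmer_id for a in _contained(annotated_hits, target_classes))
    universe = sorted(set(kmers) if kmers is not None else set(genome_counts))
    rows = []
    for kmer in universe:
        n_genome = genome_counts.get(kmer, 0)
        n_class = class_counts.get(kmer, 0)
        rows.append({
            "sequence": kmer,
            "pbm_score": pbm_scores.get(kmer) if pbm_scores else None,
            "n_in_class": n_class,
            "n_in_genome": n_genome,
            "percent": percent_half_up(n_class, n_genome),
        })
    frame = pd.DataFrame(rows, columns=["sequence", "pbm_score", "n_in_class",
                                        "n_in_genome", "percent"])
    frame["percent"] = pd.to_numeric(frame["percent"])  # None -> NaN
    return frame.sort_values(["percent", "n_in_genome", "sequence"],
                             ascending=[False, False, True],
                             na_position="last").reset_index(drop=True)


def multiplicity_distribution(annotated_hits: Sequence[AnnotatedHit],
                              class_filter: Optional[Sequence[str]] = ALU_FAMILY_CLASSES,
                              ) -> Tuple[pd.DataFrame, Tuple[int, int]]:
    """Histogram of sites per repeat element, plus (elements, sites) totals.

    Every contained hit counts as a site, including repeat occurrences of
    the same k-mer within one element.
    """
    per_element = Counter(a.repeat.key for a in _contained(annotated_hits, class_filter))
    histogram = Counter(per_element.values())
    rows = [{"sites_per_element": k, "n_elements": n, "n_sites": k * n}
            for k, n in sorted(histogram.items())]
    frame = pd.DataFrame(rows, columns=["sites_per_element", "n_elements", "n_sites"])
    totals = (int(frame["n_elements"].sum()) if len(frame) else 0,
              int(frame["n_sites"].sum()) if len(frame) else 0)
    return frame, totals


def family_summary(annotated_hits: Sequence[AnnotatedHit],
                   annotation: Sequence,
                   level: str = "family",
                   classes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Elements with >=1 contained site per family class or subfamily.

    ``annotation`` is the full repeat feature list (denominators come from
    it, not from the hits). ``classes`` restricts the rows, e.g. to the Alu
    family classes or to ``other_named`` subfamilies. Rows are sorted by
    n_with_site descending; re-sort by ``percent`` for the
    prevalence-ordered view.
    """
    if level not in ("family", "subfamily"):
        raise ValueError("level must be 'family' or 'subfamily'")

    def group_of(feature) -> str:
        return feature.family_class if level == "family" else feature.subfamily

    totals: Dict[str, set] = defaultdict(set)
    for feature in annotation:
        totals[group_of(feature)].add(feature.key)
    with_site: Dict[str, set] = defaultdict(set)
    for a in _contained(annotated_hits, None):
        with_site[group_of(a.repeat)].add(a.repeat.key)

    rows = []
    for name in sorted(totals):
        if classes is not None and name not in classes:
            continue
        n_total = len(totals[name])
        n_with = len(with_site.get(name, ()))
        rows.append({"family_or_subfamily": name, "n_with_site": n_with,
                     "n_total": n_total, "percent": percent_half_up(n_with, n_total)})
    frame = pd.DataFrame(rows, columns=["family_or_subfamily", "n_with_site",
                                        "n_total", "percent"])
    return frame.sort_values(["n_with_site", "family_or_subfamily"],
                             ascending=[False, True]).reset_index(drop=True)


def position_histogram(annotated_hits: Sequence[AnnotatedHit],
                       family_class: Optional[str] = None,
                       subfamily: Optional[str] = None,
                       bin_width: int = 1) -> pd.Series:
    """Counts of contained-hit consensus positions for one repeat class.

    Positions are 1-based consensus coordinates of the hit start; bins of
    ``bin_width`` are labelled by their lowest position.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    counts: Counter = Counter()
    for a in _contained(annotated_hits, None):
        if family_class is not None and a.repeat.family_class != family_class:
            continue
        if subfamily is not None and a.repeat.subfamily != subfamily:
            continue
        binned = ((a.consensus_position - 1) // bin_width) * bin_width + 1
        counts[binned] += 1
    series = pd.Series(dict(sorted(counts.items())), dtype=int)
    series.index.name = "position"
    series.name = "count"
    return series
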
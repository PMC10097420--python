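"""Genomic-context classification of candidate imprinted genes.

Novel candidates are placed in one of three classes by proximity to other
called genes, using the interval-gap metric (0 for overlapping intervals,
infinite across chromosomes):

* class3 — within the window (default 1 Mb) of a known imprinted gene;
* class2 — not class3, but within the window of another novel candidate
  (a novel cluster);
* class1 — a novel singleton, beyond the window from every other called gene.

Known genes keep the label "known". Class-3 genes are further positioned
within their linked cluster (flanked by known genes on both sides vs
peripheral) and oriented relative to the cluster's imprinting control region
(preferred allele on the chromosome carrying the methylated or unmethylated
ICR copy).
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .errors import RecordValidationError
from .registry import GeneRecord, ICRRecord

DEFAULT_WINDOW = 1_000_000  # "within 1 Mb" means gap <= window


def interval_distance(a: GeneRecord, b: GeneRecord) -> float:
    """Gap in bp between two intervals; 0 if they overlap or touch ends,
    infinite on different chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _near_other_set(queries: list[GeneRecord], targets: list[GeneRecord], window: int) -> dict[str, bool]:
    """For each query, whether some target on the same chromosome lies within
    ``window`` bp (gap metric). Sorted sweep with prefix maxima, O(n log n)."""
    by_chrom: dict[str, list[GeneRecord]] = defaultdict(list)
    for t in targets:
        by_chrom[t.chrom].append(t)
    prepared = {}
    for chrom, recs in by_chrom.items():
        starts = np.array(sorted(r.start for r in recs))
        ends = np.array([e for _, e in sorted((r.start, r.end) for r in recs)])
        prefix_max_end = np.maximum.accumulate(ends)
        prepared[chrom] = (starts, prefix_max_end)
    out = {}
    for q in queries:
        hit = False
        if q.chrom in prepared:
            starts, prefix_max_end = prepared[q.chrom]
            k = int(np.searchsorted(starts, q.end + window, side="right"))
            # among targets with start <= q.end + window, the gap condition
            # reduces to end >= q.start - window
            hit = k > 0 and prefix_max_end[k - 1] >= q.start - window
        out[q.gene_id] = bool(hit)
    return out


def _near_own_set(records: list[GeneRecord], window: int) -> dict[str, bool]:
    """For each record, whether another record of the same list lies within
    ``window`` bp. Uses the start-sorted order: any later-starting record
    automatically satisfies the lower gap bound, so only the next start and
    the prefix maximum of earlier ends need checking."""
    by_chrom: dict[str, list[GeneRecord]] = defaultdict(list)
    for r in records:
        by_chrom[r.chrom].append(r)
    out = {}
    for recs in by_chrom.values():
        recs = sorted(recs, key=lambda r: (r.start, r.end, r.gene_id))
        ends = np.array([r.end for r in recs])
        prefix_max_end = np.maximum.accumulate(ends)
        for i, r in enumerate(recs):
            before = i > 0 and prefix_max_end[i - 1] >= r.start - window
            after = i + 1 < len(recs) and recs[i + 1].start <= r.end + window
            out[r.gene_id] = bool(before or after)
    return out


def assign_class(
    candidates: list[GeneRecord],
    knowns: list[GeneRecord],
    window: int = DEFAULT_WINDOW,
) -> dict[str, str]:
    """Assign "known"/"class1"/"class2"/"class3" labels.

    ``candidates`` are the novel genes; ``knowns`` the previously established
    imprinted genes. Class-3 takes precedence over class-2 (the classes are
    disjoint). A gene appearing in both lists is a conflict.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    dup = {c.gene_id for c in candidates} & {k.gene_id for k in knowns}
    if dup:
        raise RecordValidationError(f"genes in both candidate and known lists: {sorted(dup)}")
    near_known = _near_other_set(candidates, knowns, window)
    near_novel = _near_own_set(candidates, window)
    labels = {k.gene_id: "known" for k in knowns}
    for c in candidates:
        if near_known[c.gene_id]:
            labels[c.gene_id] = "class3"
        elif near_novel[c.gene_id]:
            labels[c.gene_id] = "class2"
        else:
            labels[c.gene_id] = "class1"
    return labels


def periphery_status(gene: GeneRecord, cluster_knowns: list[GeneRecord]) -> str:
    """"flanked" iff known cluster members lie strictly on both sides of the
    gene's midpoint (same chromosome); otherwise "peripheral"."""
    if not cluster_knowns:
        raise ValueError(f"{gene.gene_id}: empty cluster")
    mid = gene.midpoint
    same = [k for k in cluster_knowns if k.chrom == gene.chrom]
    left = any(k.midpoint < mid for k in same)
    right = any(k.midpoint > mid for k in same)
    return "flanked" if left and right else "peripheral"


def icr_orientation(preferred_parent: str, icr: ICRRecord | None) -> str:
    """Orient a gene's preferred allele relative to its cluster's ICR.

    "meth_icr" when the preferred parent carries the methylated ICR copy,
    "un_icr" when it carries the unmethylated copy, "both" for genes whose
    preferred parent differs by tissue, "no_icr" when the cluster has no
    linked ICR.
    """
    if icr is None:
        return "no_icr"
    if preferred_parent == "both":
        return "both"
    if preferred_parent not in ("maternal", "paternal"):
        raise ValueError(f"invalid preferred_parent: {preferred_parent!r}")
    return "meth_icr" if preferred_parent == icr.methylated_parent else "un_icr"
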
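import math

import numpy as np
import pytest

from poebias.registry import GeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20230314)


def brute_force_classes(candidates, knowns, window=1_000_000):
    """Independent O(n^2) all-pairs oracle for the class assignment.

    Plain-Python gap arithmetic over every pair; shares no code with the
    sorted-sweep implementation.
    """

    def gap(a, b):
        if a.chrom != b.chrom:
            return math.inf
        if a.start < b.end and b.start < a.end:
            return 0
        return b.start - a.end if b.start >= a.end else a.start - b.end

    labels = {}
    for c in candidates:
        if any(gap(c, k) <= window for k in knowns):
            labels[c.gene_id] = "class3"
        elif any(gap(c, o) <= window for o in candidates if o.gene_id != c.gene_id):
            labels[c.gene_id] = "class2"
        else:
            labels[c.gene_id] = "class1"
    return labels


def random_registry(rng, n_candidates=50, n_knowns=8, n_chroms=3, span=20_000_000):
    """Random gene placement for oracle comparisons (no constructed truth)."""

    def rand_records(prefix, n):
        recs = []
        for i in range(n):
            chrom = f"chr{rng.integers(1, n_chroms + 1)}"
            start = int(rng.integers(0, span))
            length = int(rng.integers(500, 50_000))
            recs.append(GeneRecord(f"{prefix}{i}", chrom, start, start + length))
        return recs

    return rand_records("cand", n_candidates), rand_records("known", n_knowns)
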
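"""Cross-study overlap of called genes.

Builds a boolean gene x study (or gene x study-tissue) membership matrix
after alias merging, then counts genes by the number of studies they appear
in (degree) and by the exact study subset — the numbers behind Euler-diagram
style comparisons.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .registry import _UnionFind


def build_membership(
    calls: pd.DataFrame,
    alias_map: list[tuple[str, str]] = (),
    by_tissue: bool = False,
    tissue: str | None = None,
) -> pd.DataFrame:
    """Boolean membership matrix from long-format study calls.

    ``calls`` needs columns ``gene_id``, ``study`` and (if tissue-resolved)
    ``tissue``. Gene names connected under the alias closure collapse to one
    row, labelled by the smallest member name. With ``by_tissue`` the columns
    are "study|tissue" pairs; ``tissue`` restricts to calls from one
    (harmonised) tissue name.
    """
    required = {"gene_id", "study"} | ({"tissue"} if by_tissue or tissue else set())
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table missing columns {sorted(missing)}")
    df = calls.copy()
    if tissue is not None:
        df = df[df["tissue"] == tissue]
    uf = _UnionFind()
    for name in df["gene_id"].unique():
        uf.find(name)
    for a, b in alias_map:
        uf.union(a, b)
    df["merged_id"] = [uf.find(n) for n in df["gene_id"]]
    col = (df["study"] + "|" + df["tissue"]) if by_tissue else df["study"]
    matrix = pd.crosstab(df["merged_id"], col).astype(bool)
    matrix.index.name = "gene_id"
    matrix.columns.name = "study_tissue" if by_tissue else "study"
    empty = ~matrix.any(axis=1)
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} gene(s) with no memberships")
        matrix = matrix[~empty]
    return matrix


def overlap_counts(
    matrix: pd.DataFrame,
    stratify_by: pd.Series | dict | None = None,
) -> dict:
    """Degree and exact-subset counts from a membership matrix.

    Returns ``{"degree": {k: n_genes in exactly k studies},
    "subset": {tuple(sorted studies): n_genes}}``; with ``stratify_by`` (a
    gene_id -> label mapping, e.g. class labels) a ``"by_stratum"`` entry
    holds the same counts per label, and the strata partition the totals.
    """
    if matrix.empty:
        return {"degree": {}, "subset": {}}
    degree = matrix.sum(axis=1)
    subsets = matrix.apply(lambda row: tuple(sorted(matrix.columns[row.values])), axis=1)
    result = {
        "degree": {int(k): int(v) for k, v in degree.value_counts().sort_index().items()},
        "subset": {k: int(v) for k, v in subsets.value_counts().items()},
    }
    if stratify_by is not None:
        strat = pd.Series(stratify_by)
        unknown = set(matrix.index) - set(strat.index)
        if unknown:
            raise ValueError(f"stratify attribute missing for genes: {sorted(unknown)[:5]}...")
        by_stratum = {}
        for label, idx in matrix.groupby(strat.loc[matrix.index]).groups.items():
            by_stratum[label] = overlap_counts(matrix.loc[idx])
        result["by_stratum"] = by_stratum
    return result
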
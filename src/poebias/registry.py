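"""Gene and imprinting-control-region (ICR) registries.

Genomic intervals are held 0-based half-open (BED convention) throughout the
package. A :class:`GeneRecord` carries a primary identifier plus the full set
of names it is known by, because the source studies annotate the same
transcript under different symbols; :func:`merge_aliases` collapses records
whose name sets are connected under a user-supplied alias relation.

A :class:`KnownRegistry` binds known imprinted genes to their cluster and,
where the cluster has a characterised ICR, to the parental origin of the
germline methylation mark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import AliasConflictError, ParseError, RecordValidationError

VALID_STRANDS = {"+", "-", "."}

GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "names"]
ICR_TSV_COLUMNS = ["icr_id", "chrom", "start", "end", "methylated_parent", "cluster_id"]


@dataclass(frozen=True)
class GeneRecord:
    """A named genomic interval; the unit that is classified and overlapped.

    ``names`` always contains ``gene_id``. ``strand`` is '+', '-' or '.'
    (unknown). Coordinates are 0-based half-open.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    names: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.chrom:
            raise RecordValidationError(f"{self.gene_id}: empty chromosome")
        if not (0 <= self.start < self.end):
            raise RecordValidationError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise RecordValidationError(
                f"{self.gene_id}: strand must be one of {sorted(VALID_STRANDS)}"
            )
        object.__setattr__(self, "names", frozenset(self.names) | {self.gene_id})

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class ICRRecord:
    """An imprinting control region with the parental origin of its germline
    methylation mark."""

    icr_id: str
    chrom: str
    start: int
    end: int
    methylated_parent: str  # "maternal" | "paternal"
    cluster_id: str

    def __post_init__(self):
        if self.methylated_parent not in ("maternal", "paternal"):
            raise RecordValidationError(
                f"{self.icr_id}: methylated_parent must be 'maternal' or "
                f"'paternal', got {self.methylated_parent!r}"
            )
        if not (0 <= self.start < self.end):
            raise RecordValidationError(
                f"{self.icr_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class KnownRegistry:
    """Known imprinted genes with cluster membership and optional ICR links.

    ``status`` maps gene_id -> "known" | "novel"; ``cluster_of`` maps known
    gene_ids to a cluster label; ``icrs`` maps cluster_id -> ICRRecord for
    clusters whose control region is characterised.
    """

    genes: list[GeneRecord]
    status: dict[str, str]
    cluster_of: dict[str, str] = field(default_factory=dict)
    icrs: dict[str, ICRRecord] = field(default_factory=dict)

    def __post_init__(self):
        ids = {g.gene_id for g in self.genes}
        for gid, st in self.status.items():
            if st not in ("known", "novel"):
                raise RecordValidationError(f"{gid}: status must be known/novel")
            if gid not in ids:
                raise RecordValidationError(f"{gid}: status for unlisted gene")
        by_id = {g.gene_id: g for g in self.genes}
        chrom_of_cluster: dict[str, str] = {}
        for gid, cl in self.cluster_of.items():
            chrom = by_id[gid].chrom
            prev = chrom_of_cluster.setdefault(cl, chrom)
            if prev != chrom:
                raise RecordValidationError(
                    f"cluster {cl}: members on different chromosomes ({prev}, {chrom})"
                )

    def known_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if self.status.get(g.gene_id) == "known"]

    def novel_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if self.status.get(g.gene_id) == "novel"]

    def icr_for_gene(self, gene_id: str) -> ICRRecord | None:
        cl = self.cluster_of.get(gene_id)
        return self.icrs.get(cl) if cl is not None else None


def _parse_int(text: str, what: str, path, line: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"non-integer {what}: {text!r}", path, line) from None


def read_gene_table(path, fmt: str = "tsv") -> list[GeneRecord]:
    """Read gene records from a BED (4-6 column) or headered TSV file.

    TSV header: ``gene_id chrom start end strand names`` with names
    comma-separated. Coordinates are taken as 0-based half-open in both
    formats. Malformed rows raise :class:`ParseError` with the line number;
    invalid intervals raise :class:`RecordValidationError`.
    """
    path = Path(path)
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"fmt must be 'bed' or 'tsv', got {fmt!r}")
    records: list[GeneRecord] = []
    lines = path.read_text().splitlines()
    if fmt == "bed":
        for i, raw in enumerate(lines, start=1):
            if not raw.strip() or raw.startswith(("track", "browser", "#")):
                continue
            fields = raw.split()
            if len(fields) < 4:
                raise ParseError(f"BED needs >=4 columns, got {len(fields)}", path, i)
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "."
            records.append(
                GeneRecord(
                    gene_id=name,
                    chrom=chrom,
                    start=_parse_int(start, "start", path, i),
                    end=_parse_int(end, "end", path, i),
                    strand=strand if strand in VALID_STRANDS else ".",
                )
            )
        return records
    # TSV
    if not lines:
        return records
    header = lines[0].rstrip("\n").split("\t")
    if header[: len(GENE_TSV_COLUMNS)] != GENE_TSV_COLUMNS:
        raise ParseError(
            f"TSV header must start with {GENE_TSV_COLUMNS}, got {header}", path, 1
        )
    for i, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 6:
            raise ParseError(f"expected 6 columns, got {len(fields)}", path, i)
        gene_id, chrom, start, end, strand, names = fields[:6]
        name_set = frozenset(n for n in names.split(",") if n)
        records.append(
            GeneRecord(
                gene_id=gene_id,
                chrom=chrom,
                start=_parse_int(start, "start", path, i),
                end=_parse_int(end, "end", path, i),
                strand=strand,
                names=name_set,
            )
        )
    return records


def write_gene_table(records: list[GeneRecord], path) -> None:
    """Write records as the canonical TSV dialect (round-trips exactly)."""
    rows = [
        {
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "names": ",".join(sorted(r.names)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_icr_table(path) -> list[ICRRecord]:
    """Read an ICR TSV with header
    ``icr_id chrom start end methylated_parent cluster_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ICR_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"ICR table missing columns {missing}", path, 1)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        out.append(
            ICRRecord(
                icr_id=row.icr_id,
                chrom=row.chrom,
                start=_parse_int(row.start, "start", path, i),
                end=_parse_int(row.end, "end", path, i),
                methylated_parent=row.methylated_parent,
                cluster_id=row.cluster_id,
            )
        )
    return out


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label wins
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def merge_aliases(
    records: list[GeneRecord],
    alias_map: list[tuple[str, str]] = (),
) -> list[GeneRecord]:
    """Merge records that represent the same transcript under different names.

    Records are merged when their name sets intersect under the transitive
    closure of ``alias_map`` (plus any names shared outright). A merged record
    spans the union of the member intervals and unions the name sets; its
    gene_id is the lexicographically smallest member id, making the result
    independent of input order. Merging across chromosomes raises
    :class:`AliasConflictError`. Alias names that match no record are ignored
    with a warning. The operation is idempotent.
    """
    uf = _UnionFind()
    known_names = set()
    for r in records:
        first = None
        for n in sorted(r.names):
            known_names.add(n)
            if first is None:
                first = n
            else:
                uf.union(first, n)
    for a, b in alias_map:
        unknown = [n for n in (a, b) if n not in known_names]
        if unknown:
            warnings.warn(f"alias name(s) {unknown} not present in any record")
            continue
        uf.union(a, b)

    groups: dict[str, list[GeneRecord]] = {}
    for r in records:
        groups.setdefault(uf.find(sorted(r.names)[0]), []).append(r)

    merged: list[GeneRecord] = []
    for members in groups.values():
        chroms = {m.chrom for m in members}
        if len(chroms) > 1:
            ids = sorted(m.gene_id for m in members)
            raise AliasConflictError(
                f"alias closure merges {ids} across chromosomes {sorted(chroms)}"
            )
        if len(members) == 1:
            merged.append(members[0])
            continue
        names = frozenset().union(*(m.names for m in members))
        strands = {m.strand for m in members} - {"."}
        merged.append(
            GeneRecord(
                gene_id=min(m.gene_id for m in members),
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                strand=strands.pop() if len(strands) == 1 else ".",
                names=names,
            )
        )
    merged.sort(key=lambda r: (r.chrom, r.start, r.gene_id))
    return merged
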
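"""Strand-aware promoter windows and interval-signal summaries.

The promoter of a gene is the 500 bp immediately upstream of its
transcriptional start site: for a + strand gene the window ends at the
annotated start, for a - strand gene it begins at the annotated end.
Signal tracks (e.g. fraction CpG methylation or ChIP enrichment) are read
from bedGraph and summarised as a base-pair-weighted mean over the covered
part of the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StrandError
from .registry import GeneRecord

DEFAULT_PROMOTER_SIZE = 500


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int


def promoter_window(gene: GeneRecord, size: int = DEFAULT_PROMOTER_SIZE) -> Window:
    """The ``size`` bp upstream of the TSS, clipped at the chromosome origin.

    Requires a known strand: assuming '+' for an unknown strand would place
    half the promoters on the wrong side, so unknown strands are an error.
    """
    if size <= 0:
        raise ValueError("promoter size must be positive")
    if gene.strand == "+":
        start = gene.start - size
        if start < 0:
            warnings.warn(f"{gene.gene_id}: promoter clipped at chromosome start")
            start = 0
        return Window(gene.chrom, start, gene.start)
    if gene.strand == "-":
        return Window(gene.chrom, gene.end, gene.end + size)
    raise StrandError(f"{gene.gene_id}: promoter window needs a known strand")


class SignalTrack:
    """An interval-valued signal track (bedGraph semantics, 0-based
    half-open). Overlapping input intervals are resolved by averaging the
    overlapping values, with a warning."""

    def __init__(self, intervals: pd.DataFrame):
        required = {"chrom", "start", "end", "value"}
        if not required <= set(intervals.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if (intervals["start"] >= intervals["end"]).any():
            raise ValueError("track intervals must have start < end")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in intervals.groupby("chrom", sort=True):
            s, e, v = self._resolve(
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )
            self._by_chrom[str(chrom)] = (s, e, v)

    @staticmethod
    def _resolve(starts, ends, values):
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.all(starts[1:] >= ends[:-1]):
            return starts, ends, values
        warnings.warn("overlapping track intervals resolved by averaging")
        bounds = np.unique(np.concatenate([starts, ends]))
        seg_s, seg_e = bounds[:-1], bounds[1:]
        total = np.zeros(seg_s.size)
        cover = np.zeros(seg_s.size)
        for s, e, v in zip(starts, ends, values):
            i, j = np.searchsorted(bounds, s), np.searchsorted(bounds, e)
            total[i:j] += v
            cover[i:j] += 1
        keep = cover > 0
        return seg_s[keep], seg_e[keep], total[keep] / cover[keep]

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].isin(["track", "browser"])]
        df = df.astype({"start": int, "end": int, "value": float})
        return cls(df)

    def mean_signal(self, window: Window, zero_fill: bool = False) -> float | None:
        """Base-pair-weighted mean over the window's covered bases.

        Returns None when nothing overlaps. With ``zero_fill`` uncovered
        bases count as 0 signal and the mean is over the whole window.
        """
        if window.start >= window.end:
            raise ValueError("empty window")
        data = self._by_chrom.get(window.chrom)
        if data is None:
            return 0.0 if zero_fill else None
        starts, ends, values = data
        lo = np.minimum(np.maximum(starts, window.start), window.end)
        hi = np.maximum(np.minimum(ends, window.end), window.start)
        span = hi - lo
        covered = int(span.sum())
        if covered == 0:
            return 0.0 if zero_fill else None
        weighted = float(np.dot(span, values))
        denom = (window.end - window.start) if zero_fill else covered
        return weighted / denom


def mean_signal(track: SignalTrack, window: Window, zero_fill: bool = False) -> float | None:
    """Functional alias for :meth:`SignalTrack.mean_signal`."""
    return track.mean_signal(window, zero_fill=zero_fill)


def promoter_signal_table(
    genes: list[GeneRecord],
    track: SignalTrack,
    size: int = DEFAULT_PROMOTER_SIZE,
    zero_fill: bool = False,
) -> pd.DataFrame:
    """Per-gene promoter-window mean signal as a tidy table."""
    rows = []
    for g in genes:
        w = promoter_window(g, size=size)
        rows.append(
            {
                "gene_id": g.gene_id,
                "window_chrom": w.chrom,
                "window_start": w.start,
                "window_end": w.end,
                "mean_signal": track.mean_signal(w, zero_fill=zero_fill),
            }
        )
    return pd.DataFrame(rows)
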
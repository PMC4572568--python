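"""Interval algebra and annotation-track preparation.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  A point variant at position ``p`` overlaps an interval
iff ``start <= p < end``.  Adjacent (touching) intervals are merged because
they are indistinguishable for point-overlap queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class CoordinateError(ValueError):
    """Raised for malformed genomic coordinates."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally carrying a peak summit.

    ``summit`` is an absolute coordinate (not an offset from ``start``)
    and, when present, must lie inside the interval.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.start < 0:
            raise CoordinateError(
                f"interval {self.chrom}:{self.start}-{self.end} has negative start"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise CoordinateError(
                f"summit {self.summit} outside interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationTrack:
    """A named, sorted collection of genomic intervals.

    Construction sorts by (chrom, start); call :func:`merge_track` to
    obtain the minimal non-overlapping representation.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, cached; requires sorted intervals."""
        if self._arrays is None:
            arrays: dict[str, tuple[list[int], list[int]]] = {}
            for iv in self.intervals:
                s, e = arrays.setdefault(iv.chrom, ([], []))
                s.append(iv.start)
                e.append(iv.end)
            self._arrays = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in arrays.items()
            }
        return self._arrays

    def covered_bases(self) -> int:
        return sum(len(iv) for iv in merge_track(self).intervals)


def merge_track(track: AnnotationTrack) -> AnnotationTrack:
    """Merge overlapping and touching intervals into a minimal covering set.

    The total number of covered bases is preserved.  Summits are dropped
    from merged output (a merged interval has no single summit).
    """
    merged: list[GenomicInterval] = []
    for iv in track.intervals:  # already sorted
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end, summit=None)
        else:
            merged.append(replace(iv, summit=None) if iv.summit is not None else iv)
    return AnnotationTrack(track.name, merged)


def union_tracks(tracks: Sequence[AnnotationTrack], name: str | None = None) -> AnnotationTrack:
    """Union of several tracks: a base is covered iff covered in any input."""
    if not tracks:
        raise ValueError("union_tracks requires at least one track")
    if name is None:
        name = "+".join(t.name for t in tracks)
    ivs = [iv for t in tracks for iv in t.intervals]
    return merge_track(AnnotationTrack(name, ivs))


def summit_windows(track: AnnotationTrack, flank: int = 100) -> AnnotationTrack:
    """Replace each peak by a fixed window around its summit.

    The window is ``[summit - flank, summit + flank + 1)`` — 2*flank+1
    bases including the summit base — clipped at coordinate 0, then
    merged.  Every interval must carry a summit.
    """
    out = []
    for iv in track.intervals:
        if iv.summit is None:
            raise CoordinateError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} has no summit; "
                "summit_windows requires narrowPeak-style input"
            )
        start = max(0, iv.summit - flank)
        out.append(GenomicInterval(iv.chrom, start, iv.summit + flank + 1))
    return merge_track(AnnotationTrack(f"{track.name}.summits", out))


def median_size(track: AnnotationTrack) -> int:
    """Median interval length in base pairs (lower median for even counts)."""
    if not track.intervals:
        raise ValueError(f"track {track.name!r} is empty; median size undefined")
    lengths = sorted(len(iv) for iv in track.intervals)
    return lengths[(len(lengths) - 1) // 2]


# ---------------------------------------------------------------------------
# Readers / writers


def read_bed(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read BED3/BED6 (tab-delimited, 0-based half-open) into a track."""
    path = Path(path)
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CoordinateError(f"{path}:{lineno}: expected >=3 tab-delimited fields")
            try:
                ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except (ValueError, CoordinateError) as exc:
                raise CoordinateError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationTrack(name or path.stem, ivs)


def read_narrowpeak(path: str | Path, name: str | None = None) -> AnnotationTrack:
    """Read ENCODE narrowPeak (BED6+4); field 10 is the summit offset from start.

    A summit offset of -1 (summit not called) yields an interval without a
    summit.
    """
    path = Path(path)
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise CoordinateError(f"{path}:{lineno}: narrowPeak needs 10 fields")
            start, end = int(fields[1]), int(fields[2])
            offset = int(fields[9])
            summit = start + offset if offset >= 0 else None
            try:
                ivs.append(GenomicInterval(fields[0], start, end, summit=summit))
            except CoordinateError as exc:
                raise CoordinateError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationTrack(name or path.stem, ivs)


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track as BED3."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Gene annotations

#: default promoter size: first 500 bp upstream of the TSS, strand-aware
PROMOTER_BP = 500


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited transcript table.

    Required columns: chrom, strand, txStart, txEnd, exonStarts, exonEnds,
    name.  Exon columns are comma-separated coordinate lists (trailing
    comma tolerated, UCSC style).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "name": str})
    required = {"chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def _parse_coord_list(text: str) -> list[int]:
    return [int(x) for x in str(text).strip(",").split(",") if x != ""]


def gene_tracks(genes: pd.DataFrame, promoter_bp: int = PROMOTER_BP) -> dict[str, AnnotationTrack]:
    """Derive merged annotation tracks from a transcript table.

    Returns tracks for whole gene bodies (``genes``), ``exons``,
    ``introns`` and strand-aware ``promoters`` (``promoter_bp`` bases
    immediately upstream of the TSS).
    """
    gene_ivs, exon_ivs, intron_ivs, prom_ivs = [], [], [], []
    for row in genes.itertuples(index=False):
        chrom = row.chrom
        gene_ivs.append(GenomicInterval(chrom, int(row.txStart), int(row.txEnd)))
        starts = _parse_coord_list(row.exonStarts)
        ends = _parse_coord_list(row.exonEnds)
        for s, e in zip(starts, ends):
            exon_ivs.append(GenomicInterval(chrom, s, e))
        for e_prev, s_next in zip(ends[:-1], starts[1:]):
            if s_next > e_prev:
                intron_ivs.append(GenomicInterval(chrom, e_prev, s_next))
        if row.strand == "+":
            p_start = max(0, int(row.txStart) - promoter_bp)
            if p_start < int(row.txStart):
                prom_ivs.append(GenomicInterval(chrom, p_start, int(row.txStart)))
        else:
            prom_ivs.append(GenomicInterval(chrom, int(row.txEnd), int(row.txEnd) + promoter_bp))
    return {
        "genes": merge_track(AnnotationTrack("genes", gene_ivs)),
        "exons": merge_track(AnnotationTrack("exons", exon_ivs)),
        "introns": merge_track(AnnotationTrack("introns", intron_ivs)),
        "promoters": merge_track(AnnotationTrack("promoters", prom_ivs)),
    }


def tss_tes(genes: pd.DataFrame) -> pd.DataFrame:
    """Strand-aware TSS/TES positions per transcript.

    TSS is txStart on the + strand and txEnd - 1 on the - strand; TES is
    the opposite end.
    """
    plus = genes["strand"] == "+"
    tss = np.where(plus, genes["txStart"], genes["txEnd"] - 1)
    tes = np.where(plus, genes["txEnd"] - 1, genes["txStart"])
    return pd.DataFrame(
        {"chrom": genes["chrom"], "name": genes["name"], "tss": tss, "tes": tes}
    )


def positions_in_track(
    chroms: Iterable[str] | np.ndarray,
    positions: np.ndarray,
    track: AnnotationTrack,
) -> np.ndarray:
    """Vectorised point-in-track test for parallel chrom/position arrays.

    The track must be merged.  Returns a boolean array.
    """
    chroms = np.asarray(list(chroms) if not isinstance(chroms, np.ndarray) else chroms)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.zeros(len(positions), dtype=bool)
    arrays = track.by_chrom()
    for chrom in np.unique(chroms):
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        mask = chroms == chrom
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        out[mask] = hit
    return out
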
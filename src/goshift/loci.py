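"""Construction of shiftable loci from proxy sets and an annotation track.

A locus is the region between the furthest SNPs linked to an index SNP,
extended by twice the median annotation size on each side so that even a
locus defined by a lone index variant is large enough for the shifting
null to realise both overlap and non-overlap states.  SNP positions and
annotation intervals are stored in locus-relative coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import AnnotationTrack
from .ld import ProxySet


@dataclass
class Locus:
    index_id: str
    chrom: str
    window_start: int
    window_end: int
    snp_positions: np.ndarray  # locus-relative, sorted
    x_intervals: list[tuple[int, int]] = field(default_factory=list)  # locus-relative

    def __post_init__(self) -> None:
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)
        if self.window_start >= self.window_end:
            raise ValueError(f"locus {self.index_id}: empty window")
        L = len(self)
        if self.snp_positions.size and (
            self.snp_positions.min() < 0 or self.snp_positions.max() >= L
        ):
            raise ValueError(f"locus {self.index_id}: SNP position outside window")
        for s, e in self.x_intervals:
            if not (0 <= s < e <= L):
                raise ValueError(f"locus {self.index_id}: interval ({s},{e}) outside window")

    def __len__(self) -> int:
        return self.window_end - self.window_start


def define_locus(proxyset: ProxySet, median_x: int) -> Locus:
    """Build the shiftable window for one index SNP.

    The window spans the furthest proxies extended by ``2 * median_x`` on
    each side (clipped at coordinate 0); the right edge includes the
    furthest proxy base, so the window length is at least
    ``4 * median_x + 1``.
    """
    if median_x < 1:
        raise ValueError("median_x must be >= 1")
    positions = proxyset.positions()
    start = max(0, int(positions.min()) - 2 * median_x)
    end = int(positions.max()) + 2 * median_x + 1
    rel = np.unique(positions - start)
    return Locus(
        index_id=proxyset.index.id,
        chrom=proxyset.index.chrom,
        window_start=start,
        window_end=end,
        snp_positions=rel,
    )


def attach_annotation(locus: Locus, track: AnnotationTrack) -> Locus:
    """Clip the annotation to the locus window, in relative coordinates.

    The track must be merged.  Intervals partially overlapping the window
    are clipped at its edges.
    """
    arrays = track.by_chrom()
    x: list[tuple[int, int]] = []
    if locus.chrom in arrays:
        starts, ends = arrays[locus.chrom]
        lo = int(np.searchsorted(ends, locus.window_start, side="right"))
        hi = int(np.searchsorted(starts, locus.window_end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), locus.window_start) - locus.window_start
            e = min(int(ends[i]), locus.window_end) - locus.window_start
            if s < e:
                x.append((s, e))
    return Locus(
        index_id=locus.index_id,
        chrom=locus.chrom,
        window_start=locus.window_start,
        window_end=locus.window_end,
        snp_positions=locus.snp_positions,
        x_intervals=x,
    )


def build_loci(
    proxysets: list[ProxySet], track: AnnotationTrack, median_x: int | None = None
) -> list[Locus]:
    """Define and annotate one locus per proxy set against a merged track."""
    from .intervals import median_size, merge_track

    merged = merge_track(track)
    if median_x is None:
        median_x = median_size(merged)
    return [attach_annotation(define_locus(ps, median_x), merged) for ps in proxysets]
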
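"""Linkage-disequilibrium computation, proxy expansion and variant filtering.

LD is measured as r², the squared allelic correlation between two loci,
computed from phased haplotypes.  Trait-associated index SNPs are expanded
to their proxies (r² strictly above a threshold, 0.8 by default) and sets
of index SNPs are pruned to be mutually independent (pairwise r² <= 0.1
and >= 100 kb apart by default, with the removed member of a violating
pair chosen at random).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MonomorphicError(ValueError):
    """LD with a monomorphic locus is undefined."""


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int
    maf: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"variant {self.id}: negative position {self.pos}")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"variant {self.id}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class ProxySet:
    """An index variant together with its LD proxies.

    The index is always a member of its own proxy set with r² = 1.
    """

    index: Variant
    proxies: list[tuple[Variant, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(v.id == self.index.id for v, _ in self.proxies):
            self.proxies.insert(0, (self.index, 1.0))

    def variants(self) -> list[Variant]:
        return [v for v, _ in self.proxies]

    def positions(self) -> np.ndarray:
        return np.asarray([v.pos for v, _ in self.proxies], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.proxies)


@dataclass
class HaplotypePanel:
    """Phased haplotypes: one row per variant, one column per haplotype (0/1)."""

    variants: list[Variant]
    haplotypes: np.ndarray  # (n_variants, n_haplotypes) of 0/1

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != len(self.variants):
            raise ValueError("haplotype matrix shape does not match variant list")
        self._by_id = {v.id: i for i, v in enumerate(self.variants)}
        if len(self._by_id) != len(self.variants):
            raise ValueError("duplicate variant ids in panel")

    def row(self, variant_id: str) -> int:
        try:
            return self._by_id[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not found in panel") from None


def r_squared(haplotypes_a: np.ndarray, haplotypes_b: np.ndarray) -> float:
    """Squared allelic correlation between two loci on phased haplotypes.

    r² = (p_AB - p_A p_B)² / (p_A(1-p_A) p_B(1-p_B)); symmetric and
    invariant under allele relabeling.
    """
    a = np.asarray(haplotypes_a, dtype=float)
    b = np.asarray(haplotypes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("haplotype vectors must be equal-length 1-D with >=2 entries")
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        raise MonomorphicError("monomorphic locus: r^2 undefined")
    pab = (a * b).mean()
    return float((pab - pa * pb) ** 2 / (va * vb))


def _r2_one_vs_many(panel: HaplotypePanel, row: int, rows: np.ndarray) -> np.ndarray:
    """Vectorised r² of one panel row against many (sample covariances)."""
    h = panel.haplotypes
    a = h[row].astype(float)
    b = h[rows].astype(float)
    pa = a.mean()
    pb = b.mean(axis=1)
    va = pa * (1 - pa)
    vb = pb * (1 - pb)
    cov = (b @ a) / a.size - pa * pb
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((va > 0) & (vb > 0), cov**2 / (va * vb), 0.0)
    return r2


def expand_proxies(
    index: Variant,
    panel: HaplotypePanel,
    r2_threshold: float = 0.8,
    window: int = 1_000_000,
) -> ProxySet:
    """All panel variants within ``window`` of the index with r² strictly above
    the threshold, plus the index itself.
    """
    row = panel.row(index.id)
    positions = np.asarray([v.pos for v in panel.variants], dtype=np.int64)
    chroms = np.asarray([v.chrom for v in panel.variants])
    near = np.flatnonzero(
        (chroms == index.chrom) & (np.abs(positions - index.pos) <= window)
    )
    r2 = _r2_one_vs_many(panel, row, near)
    proxies = []
    for i, r2i in zip(near, r2):
        if i == row:
            proxies.append((panel.variants[i], 1.0))
        elif r2i > r2_threshold:
            proxies.append((panel.variants[i], float(r2i)))
    return ProxySet(index=index, proxies=proxies)


def prune_independent(
    variants: list[Variant],
    panel: HaplotypePanel | None,
    r2_max: float = 0.1,
    min_distance: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> list[Variant]:
    """Prune a variant list to mutual independence.

    For every pair on the same chromosome with r² > ``r2_max`` or distance
    < ``min_distance``, one member (chosen by seeded RNG) is removed.
    Pairs are visited in position order; the surviving set satisfies both
    constraints for all pairs.  ``panel`` may be None when only the
    distance rule applies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = sorted(variants, key=lambda v: (v.chrom, v.pos))
    alive = {v.id for v in keep}
    for i, a in enumerate(keep):
        if a.id not in alive:
            continue
        for b in keep[i + 1 :]:
            if b.chrom != a.chrom:
                break
            if b.id not in alive:
                continue
            violates = (b.pos - a.pos) < min_distance
            if not violates and panel is not None:
                try:
                    r2 = r_squared(
                        panel.haplotypes[panel.row(a.id)], panel.haplotypes[panel.row(b.id)]
                    )
                except (KeyError, MonomorphicError):
                    r2 = 0.0
                violates = r2 > r2_max
            if violates:
                alive.discard(a.id if rng.random() < 0.5 else b.id)
                if a.id not in alive:
                    break
    return [v for v in variants if v.id in alive]


#: sentinel returned by select_best_tag when fallback is disabled and no tag exists
NO_TAG = None


def select_best_tag(
    functional: Variant,
    tag_panel: list[Variant],
    panel: HaplotypePanel,
    r2_min: float = 0.8,
    fallback_to_self: bool = True,
) -> Variant | None:
    """Best tag SNP for a functional variant: maximal r² >= ``r2_min``.

    Ties are broken by smallest distance to the functional variant, then
    smallest position.  When no tag qualifies, the functional variant
    itself is returned (``fallback_to_self``), or None when disabled.
    """
    row = panel.row(functional.id)
    candidates = [v for v in tag_panel if v.chrom == functional.chrom]
    if candidates:
        rows = np.asarray([panel.row(v.id) for v in candidates])
        r2 = _r2_one_vs_many(panel, row, rows)
        best, best_key = None, None
        for v, r2i in zip(candidates, r2):
            if v.id == functional.id:
                r2i = 1.0
            if r2i < r2_min:
                continue
            key = (-r2i, abs(v.pos - functional.pos), v.pos)
            if best_key is None or key < best_key:
                best, best_key = v, key
        if best is not None:
            return best
    return functional if fallback_to_self else NO_TAG
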
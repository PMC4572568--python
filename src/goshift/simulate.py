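"""Synthetic-genome generator and simulation studies.

The generator builds a desk-scale stand-in for a reference haplotype
panel plus annotation tracks: chromosomes carry LD blocks of variants
that are noisy copies of a block founder haplotype (per-site flip
probability tuned to a target within-block r²), annotation intervals are
placed independently of variant positions (optionally with a second,
colocalizing track), and genes are laid down for the matching covariates.

On top of the generator sit the study designs used to characterise the
shifting test: functional SNP sets with a planted proportion of causal
variants inside an annotation (reported through their best tag SNP, with
a 100-kb independence filter), power / type-I-error curves across causal
fractions, and inference of the causal proportion from an observed
delta-overlap by matching it against simulated delta distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import AnnotationTrack, GenomicInterval, merge_track, median_size, positions_in_track
from .ld import ProxySet, Variant
from .loci import Locus, attach_annotation
from .matching import GeneIndex, MatchedPanel, matching_test
from .shifter import enrichment_test, expected_null_overlap, locus_overlaps


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class Colocalization:
    """Rule for placing a partner track Y relative to X.

    With probability ``prob`` each X interval receives a Y interval whose
    start is jittered by up to ``jitter`` bp and whose length is
    ``size_factor`` times the X interval's, so X and Y overlap partially
    rather than nest.  ``background_density`` adds X-independent Y cover.
    """

    prob: float = 1.0
    jitter: int = 300
    size_factor: float = 1.0
    background_density: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults give a 384-Mb genome (48 chromosomes of 8 Mb) with ~1 common
    variant per 5 kb in 20-kb LD blocks of high internal correlation, an
    annotation covering 16% of the genome with a 500-bp median interval,
    and the trait-set conditions used throughout: ~200-locus SNP sets,
    best tags at r² >= 0.8, and a 100-kb independence filter.
    """

    n_chromosomes: int = 48
    chrom_length: int = 8_000_000
    n_variants: int = 76_800
    n_haplotypes: int = 200
    ld_block_length: int = 20_000
    within_block_r2: float = 0.9
    ld_block_r2_choices: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    maf_min: float = 0.05
    annotation_density: float = 0.16
    annotation_median_size: int = 500
    annotation_size_sigma: float = 0.5
    colocalization: Colocalization | None = None
    genes_per_mb: float = 8.0
    gene_median_length: int = 20_000
    n_loci_per_set: int = 200
    causal_fraction: float = 0.0
    tag_r2_min: float = 0.8
    proxy_r2_threshold: float = 0.8
    min_spacing: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.annotation_density < 1.0:
            raise ConfigError("annotation_density must be in [0, 1)")
        if self.annotation_median_size >= self.chrom_length:
            raise ConfigError("annotation intervals larger than a chromosome")
        if self.ld_block_length < 1 or self.chrom_length < 1:
            raise ConfigError("lengths must be >= 1")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ConfigError("causal_fraction must be in [0, 1]")

    @property
    def genome_length(self) -> int:
        return self.n_chromosomes * self.chrom_length


@dataclass
class SimGenome:
    """A realized synthetic genome: variant panel, haplotypes and tracks."""

    config: SimConfig
    chrom_names: list[str]
    chroms: np.ndarray  # per-variant chromosome index
    positions: np.ndarray  # per-variant position
    mafs: np.ndarray
    blocks: np.ndarray  # per-variant global LD-block id
    haplotypes: np.ndarray  # (n_variants, n_haplotypes) uint8
    tracks: dict[str, AnnotationTrack]
    genes: pd.DataFrame | None = None
    _variants: list[Variant] | None = field(default=None, repr=False)
    _block_rows: dict[int, np.ndarray] | None = field(default=None, repr=False)
    _r2_cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _proxy_cache: dict[float, list[np.ndarray]] = field(default_factory=dict, repr=False)
    _in_track_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    def chrom_of(self, i: int) -> str:
        return self.chrom_names[self.chroms[i]]

    def variant(self, i: int) -> Variant:
        return self.panel_variants()[i]

    def panel_variants(self) -> list[Variant]:
        if self._variants is None:
            self._variants = [
                Variant(f"snp{i}", self.chrom_names[c], int(p), float(m))
                for i, (c, p, m) in enumerate(zip(self.chroms, self.positions, self.mafs))
            ]
        return self._variants

    def block_rows(self, block: int) -> np.ndarray:
        if self._block_rows is None:
            order = np.argsort(self.blocks, kind="stable")
            bounds = np.searchsorted(self.blocks[order], np.unique(self.blocks), side="left")
            uniq = np.unique(self.blocks)
            self._block_rows = {
                int(b): np.sort(order[s:e])
                for b, s, e in zip(
                    uniq, bounds, np.append(bounds[1:], len(order))
                )
            }
        return self._block_rows[int(block)]

    def block_r2(self, block: int) -> np.ndarray:
        """Pairwise sample r² among the variants of one LD block."""
        if block not in self._r2_cache:
            rows = self.block_rows(block)
            h = self.haplotypes[rows].astype(float)
            z = h - h.mean(axis=1, keepdims=True)
            sd = z.std(axis=1)
            sd[sd == 0] = np.inf
            corr = (z @ z.T) / h.shape[1] / np.outer(sd, sd)
            self._r2_cache[int(block)] = corr**2
        return self._r2_cache[int(block)]

    def proxy_rows(self, i: int, r2_threshold: float | None = None) -> np.ndarray:
        """Panel rows of the proxies of variant i (r² strictly above the
        threshold, within the variant's LD block), including i itself."""
        thr = self.config.proxy_r2_threshold if r2_threshold is None else r2_threshold
        rows = self.block_rows(self.blocks[i])
        r2 = self.block_r2(self.blocks[i])
        k = int(np.searchsorted(rows, i))
        mask = r2[k] > thr
        mask[k] = True
        return rows[mask]

    def proxy_positions(self, r2_threshold: float | None = None) -> list[np.ndarray]:
        """Proxy position arrays for every panel variant (cached)."""
        thr = self.config.proxy_r2_threshold if r2_threshold is None else r2_threshold
        if thr not in self._proxy_cache:
            out: list[np.ndarray] = [None] * self.n_variants  # type: ignore[list-item]
            for b in np.unique(self.blocks):
                rows = self.block_rows(b)
                r2 = self.block_r2(b)
                pos = self.positions[rows]
                for k, i in enumerate(rows):
                    mask = r2[k] > thr
                    mask[k] = True
                    out[int(i)] = pos[mask]
            self._proxy_cache[thr] = out
        return self._proxy_cache[thr]

    def ld_counts(self, r2_threshold: float | None = None) -> np.ndarray:
        """Number of proxies (excluding self) per panel variant."""
        return np.asarray([len(p) - 1 for p in self.proxy_positions(r2_threshold)])

    def proxy_set(self, i: int, r2_threshold: float | None = None) -> ProxySet:
        thr = self.config.proxy_r2_threshold if r2_threshold is None else r2_threshold
        rows = self.block_rows(self.blocks[i])
        r2 = self.block_r2(self.blocks[i])
        k = int(np.searchsorted(rows, i))
        proxies = [
            (self.variant(int(j)), float(min(r2[k, m], 1.0)))
            for m, j in enumerate(rows)
            if j == i or r2[k, m] > thr
        ]
        return ProxySet(index=self.variant(i), proxies=proxies)

    def in_track(self, name: str) -> np.ndarray:
        """Per-variant flag: does the variant's own position lie in the track?"""
        if name not in self._in_track_cache:
            chrom_labels = np.asarray([self.chrom_names[c] for c in self.chroms])
            self._in_track_cache[name] = positions_in_track(
                chrom_labels, self.positions, self.tracks[name]
            )
        return self._in_track_cache[name]


def _flip_prob(target_r2: float, founder_freq: float) -> float:
    """Per-site flip probability for a copy-with-mutation block so that two
    independent noisy copies of the founder correlate at ~target_r2.

    For copies X = F xor A with flip probability e, corr(X, F) depends on
    the founder frequency p, and corr(X, Y) = corr(X, F)^2; e is solved by
    bisection so that corr(X, Y)^2 hits the target.
    """
    target_r2 = min(max(target_r2, 0.0), 1.0)
    if target_r2 >= 1.0:
        return 0.0
    p = founder_freq
    target_a = target_r2**0.25  # required corr(X, F)

    def corr_xf(e: float) -> float:
        q = p + e - 2 * p * e
        if q <= 0 or q >= 1:
            return 0.0
        return (p * (1 - e) - p * q) / np.sqrt(p * (1 - p) * q * (1 - q))

    lo, hi = 0.0, 0.5
    for _ in range(40):
        mid = (lo + hi) / 2
        if corr_xf(mid) > target_a:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _place_intervals(
    rng: np.random.Generator,
    n_chromosomes: int,
    chrom_length: int,
    target_bases: int,
    median_size_bp: int,
    sigma: float,
    name: str,
    chrom_names: list[str],
) -> AnnotationTrack:
    """Place lognormal-length intervals uniformly until the merged track
    covers the target number of bases."""
    mean_len = median_size_bp * float(np.exp(sigma**2 / 2))
    track = AnnotationTrack(name, [])
    covered = 0
    ivs: list[GenomicInterval] = []
    while covered < target_bases:
        n_batch = max(1, int(0.9 * (target_bases - covered) / mean_len))
        lengths = np.maximum(
            1, np.round(rng.lognormal(np.log(median_size_bp), sigma, size=n_batch))
        ).astype(int)
        chrom_idx = rng.integers(0, n_chromosomes, size=n_batch)
        starts = rng.integers(0, chrom_length, size=n_batch)
        for c, s, ln in zip(chrom_idx, starts, lengths):
            e = min(int(s) + int(ln), chrom_length)
            if e > s:
                ivs.append(GenomicInterval(chrom_names[c], int(s), e))
        track = merge_track(AnnotationTrack(name, ivs))
        ivs = list(track.intervals)
        covered = sum(len(iv) for iv in ivs)
    return track


def _simulate_genes(
    rng: np.random.Generator, config: SimConfig, chrom_names: list[str]
) -> pd.DataFrame:
    rows = []
    n_per_chrom = max(1, int(round(config.chrom_length / 1e6 * config.genes_per_mb)))
    gid = 0
    for chrom in chrom_names:
        for _ in range(n_per_chrom):
            length = int(
                min(
                    max(1_000, rng.lognormal(np.log(config.gene_median_length), 0.6)),
                    config.chrom_length // 2,
                )
            )
            tx_start = int(rng.integers(0, config.chrom_length - length))
            tx_end = tx_start + length
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(rng.integers(tx_start + 1, tx_end, size=2 * n_exons - 2))
            bounds = np.concatenate([[tx_start], cuts, [tx_end]])
            exon_starts = bounds[0::2][:n_exons]
            exon_ends = bounds[1::2][:n_exons]
            keep = exon_ends > exon_starts
            rows.append(
                {
                    "chrom": chrom,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "txStart": tx_start,
                    "txEnd": tx_end,
                    "exonStarts": ",".join(str(int(x)) for x in exon_starts[keep]),
                    "exonEnds": ",".join(str(int(x)) for x in exon_ends[keep]),
                    "name": f"gene{gid}",
                }
            )
            gid += 1
    return pd.DataFrame(rows)


def _colocalized_track(
    rng: np.random.Generator,
    x_track: AnnotationTrack,
    rule: Colocalization,
    config: SimConfig,
    chrom_names: list[str],
) -> AnnotationTrack:
    ivs: list[GenomicInterval] = []
    for iv in x_track.intervals:
        if rng.random() >= rule.prob:
            continue
        length = max(50, int(round(len(iv) * rule.size_factor)))
        start = iv.start + int(rng.integers(-rule.jitter, rule.jitter + 1))
        start = max(0, min(start, config.chrom_length - 1))
        end = min(start + length, config.chrom_length)
        if end > start:
            ivs.append(GenomicInterval(iv.chrom, start, end))
    track = merge_track(AnnotationTrack("Y", ivs))
    if rule.background_density > 0:
        bg = _place_intervals(
            rng,
            config.n_chromosomes,
            config.chrom_length,
            int(rule.background_density * config.genome_length),
            config.annotation_median_size,
            config.annotation_size_sigma,
            "Ybg",
            chrom_names,
        )
        track = merge_track(AnnotationTrack("Y", list(track.intervals) + list(bg.intervals)))
    return track


def simulate_genome(config: SimConfig) -> SimGenome:
    """Realize a synthetic genome from its configuration (seed-reproducible)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # variant positions, one draw per chromosome
    n_per_chrom = config.n_variants // config.n_chromosomes
    chroms_l, pos_l = [], []
    for c in range(config.n_chromosomes):
        pos = np.unique(rng.integers(0, config.chrom_length, size=n_per_chrom))
        pos_l.append(pos)
        chroms_l.append(np.full(len(pos), c))
    chroms = np.concatenate(chroms_l)
    positions = np.concatenate(pos_l)

    # LD blocks: fixed-width bins; haplotypes are noisy copies of a block founder
    blocks_per_chrom = -(-config.chrom_length // config.ld_block_length)
    blocks = chroms * blocks_per_chrom + positions // config.ld_block_length
    n_hap = config.n_haplotypes
    haplotypes = np.zeros((len(positions), n_hap), dtype=np.uint8)
    uniq_blocks = np.unique(blocks)
    if config.ld_block_r2_choices is not None:
        values, probs = config.ld_block_r2_choices
        block_r2_targets = rng.choice(values, size=len(uniq_blocks), p=probs)
    else:
        block_r2_targets = np.full(len(uniq_blocks), config.within_block_r2)
    for b, target in zip(uniq_blocks, block_r2_targets):
        rows = np.flatnonzero(blocks == b)
        freq = rng.uniform(0.05, 0.5)
        founder = (rng.random(n_hap) < freq).astype(np.uint8)
        flips = rng.random((len(rows), n_hap)) < _flip_prob(float(target), freq)
        haplotypes[rows] = founder[None, :] ^ flips.astype(np.uint8)

    freqs = haplotypes.mean(axis=1)
    mafs = np.minimum(freqs, 1 - freqs)
    keep = mafs >= config.maf_min
    chroms, positions, mafs = chroms[keep], positions[keep], mafs[keep]
    blocks, haplotypes = blocks[keep], haplotypes[keep]

    tracks: dict[str, AnnotationTrack] = {}
    target = int(config.annotation_density * config.genome_length)
    if target > 0:
        tracks["X"] = _place_intervals(
            rng,
            config.n_chromosomes,
            config.chrom_length,
            target,
            config.annotation_median_size,
            config.annotation_size_sigma,
            "X",
            chrom_names,
        )
        realized = sum(len(iv) for iv in tracks["X"].intervals)
        if abs(realized - target) > 0.1 * target:
            raise ConfigError(
                f"realized annotation coverage {realized} deviates >10% from target {target}"
            )
    else:
        tracks["X"] = AnnotationTrack("X", [])
    if config.colocalization is not None:
        tracks["Y"] = _colocalized_track(
            rng, tracks["X"], config.colocalization, config, chrom_names
        )

    genes = _simulate_genes(rng, config, chrom_names)
    return SimGenome(
        config=config,
        chrom_names=chrom_names,
        chroms=chroms,
        positions=positions,
        mafs=mafs,
        blocks=blocks,
        haplotypes=haplotypes,
        tracks=tracks,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# Functional SNP sets


@dataclass
class FunctionalSet:
    """A simulated trait-associated SNP set with its ground truth."""

    index_rows: np.ndarray  # panel rows of the reported (tag) SNPs
    truth: pd.DataFrame  # causal_row, causal_pos, causal_in_category, index_row


def _best_tag_row(genome: SimGenome, causal: int, tag_r2_min: float) -> int:
    """Best tag for a causal variant: the other variant with the greatest
    r² >= tag_r2_min (ties to the nearest, then smallest position); the
    causal variant itself when no tag qualifies."""
    rows = genome.block_rows(genome.blocks[causal])
    r2 = genome.block_r2(genome.blocks[causal])
    k = int(np.searchsorted(rows, causal))
    best, best_key = causal, None
    for m, j in enumerate(rows):
        if j == causal or r2[k, m] < tag_r2_min:
            continue
        key = (
            -r2[k, m],
            abs(int(genome.positions[j]) - int(genome.positions[causal])),
            int(genome.positions[j]),
        )
        if best_key is None or key < best_key:
            best, best_key = int(j), key
    return best


def draw_functional_set(
    genome: SimGenome,
    category: str | None,
    n_loci: int,
    causal_fraction: float,
    tag_r2_min: float | None = None,
    seed: int | np.random.Generator = 0,
    min_ld_count: int | None = None,
) -> FunctionalSet:
    """Draw a SNP set with a planted share of causal variants in a category.

    ``causal_fraction`` of the loci get a causal variant drawn inside the
    named annotation track and the remainder outside it; ``category=None``
    draws unconstrained (variants independent of any annotation).  Each
    causal variant is reported through its best tag SNP, and the final
    reported set satisfies the minimum-spacing independence filter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = genome.config
    tag_r2_min = cfg.tag_r2_min if tag_r2_min is None else tag_r2_min
    eligible = np.arange(genome.n_variants)
    if min_ld_count is not None:
        eligible = eligible[genome.ld_counts()[eligible] >= min_ld_count]
    if category is None:
        pools = [(eligible, n_loci, None)]
    else:
        flags = genome.in_track(category)[eligible]
        n_in = int(round(causal_fraction * n_loci))
        pools = [
            (eligible[flags], n_in, True),
            (eligible[~flags], n_loci - n_in, False),
        ]

    accepted_pos: dict[int, list[int]] = {}
    index_rows: list[int] = []
    truth_rows: list[dict] = []

    def spaced_ok(chrom: int, pos: int) -> bool:
        return all(abs(pos - q) >= cfg.min_spacing for q in accepted_pos.get(chrom, ()))

    for pool, n_needed, in_flag in pools:
        if n_needed == 0:
            continue
        order = rng.permutation(pool)
        taken = 0
        for causal in order:
            if taken >= n_needed:
                break
            tag = _best_tag_row(genome, int(causal), tag_r2_min)
            chrom, tag_pos = int(genome.chroms[tag]), int(genome.positions[tag])
            if not spaced_ok(chrom, tag_pos):
                continue
            accepted_pos.setdefault(chrom, []).append(tag_pos)
            index_rows.append(tag)
            truth_rows.append(
                {
                    "causal_row": int(causal),
                    "causal_pos": int(genome.positions[causal]),
                    "causal_in_category": (
                        bool(genome.in_track(category)[causal]) if category else False
                    ),
                    "index_row": tag,
                }
            )
            taken += 1
        if taken < n_needed:
            raise ConfigError(
                f"genome too small to place {n_needed} loci {cfg.min_spacing} bp apart "
                f"(placed {taken})"
            )
    return FunctionalSet(
        index_rows=np.asarray(index_rows), truth=pd.DataFrame(truth_rows)
    )


def loci_for_rows(
    genome: SimGenome,
    index_rows: np.ndarray,
    track: AnnotationTrack,
    median_x: int | None = None,
    r2_threshold: float | None = None,
) -> list[Locus]:
    """Build annotated loci for panel rows used as index SNPs."""
    if median_x is None:
        median_x = median_size(track) if len(track) else 1
    proxy_pos = genome.proxy_positions(r2_threshold)
    loci = []
    for i in index_rows:
        positions = proxy_pos[int(i)]
        start = max(0, int(positions.min()) - 2 * median_x)
        end = int(positions.max()) + 2 * median_x + 1
        lc = Locus(
            index_id=f"snp{int(i)}",
            chrom=genome.chrom_of(int(i)),
            window_start=start,
            window_end=end,
            snp_positions=np.unique(positions - start),
        )
        loci.append(attach_annotation(lc, track))
    return loci


# ---------------------------------------------------------------------------
# Studies


def power_study(
    genome: SimGenome,
    fractions: list[float],
    n_sets: int = 100,
    n_iterations: int = 1000,
    alpha_levels: tuple[float, ...] = (0.05, 0.001),
    method: str = "shifting",
    category: str | None = "X",
    test_track: str = "X",
    n_loci: int | None = None,
    matching_axes: tuple[str, ...] = ("gen", "maf", "tss", "tes", "ld"),
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rate of the chosen test across planted causal fractions.

    ``category`` is the annotation that causal variants are drawn from
    (None draws them independently of every annotation, the null for
    type-I-error studies); ``test_track`` is the annotation tested for
    enrichment.  Returns one row per (fraction, alpha) with the share of
    simulated SNP sets reaching p < alpha.
    """
    if not fractions:
        raise ValueError("power_study requires at least one causal fraction")
    cfg = genome.config
    n_loci = cfg.n_loci_per_set if n_loci is None else n_loci
    track = genome.tracks[test_track]
    ss = np.random.SeedSequence(seed)
    med = median_size(track) if len(track) else 1

    panel = None
    panel_overlaps = None
    if method == "matching":
        panel = MatchedPanel(
            genome.panel_variants(),
            genes=GeneIndex(genome.genes) if genome.genes is not None else None,
            ld_counts=genome.ld_counts(),
            active_axes=matching_axes,
        )
        proxy_pos = genome.proxy_positions()
        panel_overlaps = np.asarray(
            [
                positions_in_track(
                    np.full(len(p), genome.chrom_of(i)), p, track
                ).any()
                for i, p in enumerate(proxy_pos)
            ]
        )

    rows = []
    for fraction in fractions:
        children = ss.spawn(n_sets)
        pvals = np.empty(n_sets)
        for s in range(n_sets):
            rng = np.random.default_rng(children[s])
            fset = draw_functional_set(genome, category, n_loci, fraction, seed=rng)
            if method == "shifting":
                loci = loci_for_rows(genome, fset.index_rows, track, median_x=med)
                res = enrichment_test(
                    loci, n_iterations=n_iterations, seed=int(rng.integers(2**31))
                )
                pvals[s] = res.p_value
            elif method == "matching":
                test_snps = [genome.variant(int(i)) for i in fset.index_rows]
                proxy_pos = genome.proxy_positions()
                test_proxies = {
                    v.id: proxy_pos[int(i)] for v, i in zip(test_snps, fset.index_rows)
                }
                res = matching_test(
                    test_snps,
                    panel,
                    track,
                    n_sets=n_iterations,
                    seed=int(rng.integers(2**31)),
                    test_proxies=test_proxies,
                    test_ld_counts=genome.ld_counts()[fset.index_rows],
                    panel_overlaps=panel_overlaps,
                )
                pvals[s] = res.p_value
            else:
                raise ValueError(f"unknown method {method!r}")
        for alpha in alpha_levels:
            rows.append(
                {
                    "fraction": fraction,
                    "alpha": alpha,
                    "rejection_rate": float((pvals < alpha).mean()),
                    "n_sets": n_sets,
                    "method": method,
                }
            )
    return pd.DataFrame(rows)


def delta_for_set(genome: SimGenome, index_rows: np.ndarray, track: AnnotationTrack,
                  median_x: int | None = None) -> float:
    """Noise-free delta-overlap of one SNP set: observed overlap proportion
    minus the exact expected null overlap under per-locus uniform shifts."""
    loci = loci_for_rows(genome, index_rows, track, median_x=median_x)
    observed = float(np.mean([locus_overlaps(lc) for lc in loci]))
    return observed - expected_null_overlap(loci)


class CausalProportionEstimator:
    """Infer the causal proportion behind an observed delta-overlap.

    Builds a reference library of simulated SNP sets across a grid of
    planted causal fractions and records each set's delta-overlap.  Given
    an observed delta, the sets whose delta falls within a tolerance form
    an empirical distribution over true fractions; its mean and central
    95% interval are reported.
    """

    def __init__(
        self,
        genome: SimGenome,
        category: str = "X",
        set_size: int | None = None,
        increments: np.ndarray | None = None,
        n_sets_per_increment: int = 100,
        seed: int = 0,
    ):
        self.genome = genome
        self.category = category
        cfg = genome.config
        self.set_size = cfg.n_loci_per_set if set_size is None else set_size
        self.increments = np.round(
            np.arange(0.0, 0.45 + 1e-9, 0.03) if increments is None else np.asarray(increments),
            6,
        )
        track = genome.tracks[category]
        med = median_size(track) if len(track) else 1
        ss = np.random.SeedSequence(seed)
        fracs, deltas = [], []
        for fraction in self.increments:
            children = ss.spawn(n_sets_per_increment)
            for child in children:
                rng = np.random.default_rng(child)
                fset = draw_functional_set(
                    genome, category, self.set_size, float(fraction), seed=rng
                )
                fracs.append(float(fraction))
                deltas.append(delta_for_set(genome, fset.index_rows, track, median_x=med))
        self.fractions_ = np.asarray(fracs)
        self.deltas_ = np.asarray(deltas)

    def infer(self, observed_delta: float, tolerance: float = 0.002) -> dict:
        retained = self.fractions_[np.abs(self.deltas_ - observed_delta) <= tolerance]
        if retained.size == 0:
            raise ValueError(
                f"no simulated sets within +-{tolerance} of delta {observed_delta}; "
                "widen the tolerance or the increment grid"
            )
        lo, hi = np.percentile(retained, [2.5, 97.5])
        return {
            "mean": float(retained.mean()),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "n_retained": int(retained.size),
            "fractions": retained,
        }


def infer_causal_proportion(
    observed_delta: float,
    genome: SimGenome,
    set_size: int | None = None,
    increments: np.ndarray | None = None,
    tolerance: float = 0.002,
    n_sets_per_increment: int = 100,
    seed: int = 0,
    category: str = "X",
) -> dict:
    """One-shot causal-proportion inference from an observed delta-overlap.

    See :class:`CausalProportionEstimator`; reuse the estimator when
    inferring for several observed deltas against the same genome.
    """
    est = CausalProportionEstimator(
        genome,
        category=category,
        set_size=set_size,
        increments=increments,
        n_sets_per_increment=n_sets_per_increment,
        seed=seed,
    )
    return est.infer(observed_delta, tolerance=tolerance)
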
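"""The local annotation-shifting enrichment test.

Observed statistic: the proportion of loci in which at least one SNP in LD
with the index SNP falls inside the tested annotation X.  Null: within
each locus, X is translated by a uniform random integer offset with
wrap-around at the locus boundaries ("circularization"), SNP positions
held fixed; the proportion of overlapping loci is recorded per iteration.
The p-value is the fraction of iterations whose null proportion is equal
to or greater than the observed one.

Two derived quantities accompany the p-value:

* delta-overlap — observed proportion minus the mean null proportion; the
  effect size of the enrichment (close to 0 under the null).
* overlap score — per locus, the probability l_s/n of overlapping X by
  chance under shifting; reported only for loci that overlap in the
  observed data.  Loci with low scores drive the enrichment.

Because each locus's null is a uniform draw over its possible offsets, the
per-locus chance of overlap has a closed form (the fraction of offsets
that realise an overlap), and the null count is Poisson-binomial across
loci; :func:`exact_p_value` and :func:`expected_null_overlap` use this for
noise-free results on top of the Monte Carlo test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loci import Locus


def locus_overlaps(locus: Locus) -> bool:
    """True iff any SNP position lies in any X interval (half-open)."""
    for s, e in locus.x_intervals:
        i = np.searchsorted(locus.snp_positions, s, side="left")
        if i < locus.snp_positions.size and locus.snp_positions[i] < e:
            return True
    return False


def shift_intervals(
    intervals: list[tuple[int, int]], offset: int, length: int
) -> list[tuple[int, int]]:
    """Translate intervals by ``offset`` modulo ``length`` (circularized).

    An interval crossing the boundary re-emerges on the other side as two
    pieces; the total number of covered bases is preserved.
    """
    if not 0 <= offset < length:
        raise ValueError(f"offset {offset} outside [0, {length})")
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        if not (0 <= s < e <= length):
            raise ValueError(f"interval ({s},{e}) outside [0, {length})")
        ns = (s + offset) % length
        ne = ns + (e - s)
        if ne <= length:
            out.append((ns, ne))
        else:
            out.append((ns, length))
            out.append((0, ne - length))
    return sorted(out)


def offset_overlap_profile(
    snp_positions: np.ndarray, x_intervals: list[tuple[int, int]], length: int
) -> np.ndarray:
    """Boolean array over all offsets: does shifting X by that offset overlap a SNP?

    A SNP at p is covered by interval [a, b) shifted by o iff
    (p - o) mod L lies in [a, b), i.e. o is in the modular range
    [p - b + 1, p - a].  Entry 0 equals the unshifted (observed) state.
    """
    profile = np.zeros(length, dtype=bool)
    for p in np.asarray(snp_positions, dtype=np.int64):
        for a, b in x_intervals:
            n = b - a
            if n >= length:
                profile[:] = True
                return profile
            lo = int((p - b + 1) % length)
            hi = lo + n
            if hi <= length:
                profile[lo:hi] = True
            else:
                profile[lo:] = True
                profile[: hi - length] = True
    return profile


def locus_profile(locus: Locus) -> np.ndarray:
    return offset_overlap_profile(locus.snp_positions, locus.x_intervals, len(locus))


def expected_null_overlap(loci: list[Locus]) -> float:
    """Exact mean of the null overlap proportion: mean over loci of the
    per-locus fraction of offsets realising an overlap."""
    return float(np.mean([locus_profile(lc).mean() for lc in loci]))


def exact_p_value(loci: list[Locus]) -> float:
    """Exact shifting-test p-value by the product law over independent
    per-locus offset distributions.

    The null count of overlapping loci is Poisson-binomial with per-locus
    probabilities pi_l; p = P(count >= observed count), ties included.
    """
    probs = np.array([locus_profile(lc).mean() for lc in loci])
    observed = sum(locus_overlaps(lc) for lc in loci)
    # DP over the Poisson-binomial pmf
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1 - p, p])
    return float(pmf[observed:].sum())


@dataclass
class EnrichmentResult:
    """Full output of a shifting enrichment test."""

    n_loci: int
    observed_overlap: float
    null_overlaps: np.ndarray  # per-iteration null proportions
    p_count: int  # iterations with null >= observed
    p_value: float
    delta_overlap: float
    overlap_scores: dict[str, float]  # only loci overlapping in observed data
    n_iterations: int
    seed: int
    stratify_name: str | None = None
    per_locus: dict[str, dict] = field(default_factory=dict)

    @property
    def p_display(self) -> str:
        """p rendered for reports; a zero count is reported as < 1/n."""
        if self.p_count == 0:
            return f"<{1.0 / self.n_iterations:.0e}"
        return f"{self.p_value:.4g}"


def _finalize(
    loci: list[Locus],
    observed_flags: np.ndarray,
    hits: np.ndarray,
    n_iterations: int,
    seed: int,
    add_one: bool,
    stratify_name: str | None = None,
) -> EnrichmentResult:
    n_loci = len(loci)
    observed_count = int(observed_flags.sum())
    observed = observed_count / n_loci
    null_counts = hits.sum(axis=0)
    null_overlaps = null_counts / n_loci
    p_count = int((null_counts >= observed_count).sum())
    if add_one:
        p_value = (p_count + 1) / (n_iterations + 1)
    else:
        p_value = p_count / n_iterations
    per_locus_rate = hits.mean(axis=1)
    scores = {
        lc.index_id: float(per_locus_rate[i])
        for i, lc in enumerate(loci)
        if observed_flags[i]
    }
    per_locus = {
        lc.index_id: {
            "n_snps": int(lc.snp_positions.size),
            "overlaps_observed": bool(observed_flags[i]),
            "overlap_score": float(per_locus_rate[i]),
        }
        for i, lc in enumerate(loci)
    }
    return EnrichmentResult(
        n_loci=n_loci,
        observed_overlap=observed,
        null_overlaps=null_overlaps,
        p_count=p_count,
        p_value=p_value,
        delta_overlap=observed - float(null_overlaps.mean()),
        overlap_scores=scores,
        n_iterations=n_iterations,
        seed=seed,
        stratify_name=stratify_name,
        per_locus=per_locus,
    )


def enrichment_test(
    loci: list[Locus],
    n_iterations: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> EnrichmentResult:
    """Monte Carlo shifting test.

    One independent uniform offset per locus per iteration; per-locus RNG
    streams are spawned deterministically from the root seed, so results
    do not depend on iteration order.  ``add_one`` switches the p-value
    estimator to (count + 1) / (n + 1).
    """
    if not loci:
        raise ValueError("enrichment_test requires at least one locus")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(loci))
    observed_flags = np.zeros(len(loci), dtype=bool)
    hits = np.zeros((len(loci), n_iterations), dtype=bool)
    for i, lc in enumerate(loci):
        profile = locus_profile(lc)
        observed_flags[i] = bool(profile[0])
        if profile.any():
            rng = np.random.default_rng(children[i])
            offsets = rng.integers(0, len(lc), size=n_iterations)
            hits[i] = profile[offsets]
        # loci with no X intervals never overlap, observed or null
    return _finalize(loci, observed_flags, hits, n_iterations, seed, add_one)
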
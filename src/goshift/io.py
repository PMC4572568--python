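"""File formats and result reporting.

Tab-delimited inputs: the SNP map (id, chrom, pos), the precomputed proxy
table (index_id, proxy_id, proxy_chrom, proxy_pos, r2) and phased VCF
(via cyvcf2, restricted to bi-allelic records).  All coordinates are
0-based unless a 1-based flag is given.  Outputs carry the seed in a
header line so every randomized run is reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .ld import HaplotypePanel, ProxySet, Variant
from .shifter import EnrichmentResult


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_snpmap(path: str | Path, one_based: bool = False) -> list[Variant]:
    """Read a SNP map: tab-delimited with header columns id, chrom, pos.

    Positions are 0-based by default; ``one_based`` decrements them on
    read.  Duplicate ids and negative positions are rejected with the
    offending line number.
    """
    path = Path(path)
    variants: list[Variant] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            cols = {name: header.index(name) for name in ("id", "chrom", "pos")}
        except ValueError:
            raise FormatError(f"{path}:1: header must contain id, chrom, pos") from None
        maf_col = header.index("maf") if "maf" in header else None
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                vid = fields[cols["id"]]
                chrom = fields[cols["chrom"]]
                pos = int(fields[cols["pos"]]) - (1 if one_based else 0)
                maf = float(fields[maf_col]) if maf_col is not None else 0.0
                if vid in seen:
                    raise FormatError(f"duplicate id {vid!r}")
                variant = Variant(vid, chrom, pos, maf)
            except (IndexError, ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            seen.add(vid)
            variants.append(variant)
    return variants


def write_snpmap(variants: list[Variant], path: str | Path, one_based: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\tmaf\n")
        for v in variants:
            fh.write(f"{v.id}\t{v.chrom}\t{v.pos + (1 if one_based else 0)}\t{v.maf:g}\n")


def read_proxy_table(path: str | Path, index_variants: list[Variant]) -> dict[str, ProxySet]:
    """Read precomputed LD proxies: index_id, proxy_id, proxy_chrom,
    proxy_pos, r2 (tab-delimited with header).

    Returns one ProxySet per index variant; indices with no table rows
    get a singleton set (the index alone).
    """
    path = Path(path)
    by_id = {v.id: v for v in index_variants}
    proxies: dict[str, list[tuple[Variant, float]]] = {v.id: [] for v in index_variants}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["index_id", "proxy_id", "proxy_chrom", "proxy_pos", "r2"]
        try:
            cols = {name: header.index(name) for name in expected}
        except ValueError:
            raise FormatError(f"{path}:1: header must contain {expected}") from None
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                idx = fields[cols["index_id"]]
                if idx not in by_id:
                    continue
                proxy = Variant(
                    fields[cols["proxy_id"]],
                    fields[cols["proxy_chrom"]],
                    int(fields[cols["proxy_pos"]]),
                )
                r2 = float(fields[cols["r2"]])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            proxies[idx].append((proxy, r2))
    return {vid: ProxySet(index=by_id[vid], proxies=prx) for vid, prx in proxies.items()}


def read_vcf_panel(
    path: str | Path, maf_min: float = 0.0, min_minor_copies: int = 5
) -> HaplotypePanel:
    """Read phased haplotypes from a VCF into a panel.

    Restricted to bi-allelic SNPs with at least ``min_minor_copies``
    copies of the minor allele; ``maf_min`` applies an additional
    frequency filter.  VCF positions are 1-based and converted to
    0-based.
    """
    from cyvcf2 import VCF

    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        gts = np.asarray(rec.genotype.array())
        hap = gts[:, :2].reshape(-1)
        if np.any(hap < 0):
            continue
        minor = int(min(hap.sum(), len(hap) - hap.sum()))
        maf = minor / len(hap)
        if minor < min_minor_copies or maf < maf_min:
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        variants.append(Variant(vid, rec.CHROM, rec.POS - 1, maf))
        rows.append(hap.astype(np.uint8))
    if not variants:
        raise FormatError(f"{path}: no usable bi-allelic variants")
    return HaplotypePanel(variants=variants, haplotypes=np.vstack(rows))


def write_results(result: EnrichmentResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write the summary and per-locus tables for an enrichment result.

    ``<prefix>.summary.tsv`` has one data row (n_loci, observed, mean
    null, delta, p, iterations, seed); ``<prefix>.loci.tsv`` lists the
    observed-overlapping loci sorted ascending by overlap score, since
    loci with low scores drive significant enrichment.  Reruns with the
    same seed produce byte-identical files.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    summary = prefix.with_suffix(".summary.tsv")
    per_locus = prefix.with_suffix(".loci.tsv")
    strat = f"\tstratified_on" if result.stratify_name else ""
    strat_val = f"\t{result.stratify_name}" if result.stratify_name else ""
    with open(summary, "w") as fh:
        fh.write(f"# seed={result.seed}\n")
        fh.write(
            "n_loci\tobserved_overlap\tmean_null_overlap\tdelta_overlap\tp_value\t"
            f"n_iterations\tseed{strat}\n"
        )
        fh.write(
            f"{result.n_loci}\t{result.observed_overlap:.6f}\t"
            f"{float(np.mean(result.null_overlaps)):.6f}\t{result.delta_overlap:.6f}\t"
            f"{result.p_display}\t{result.n_iterations}\t{result.seed}{strat_val}\n"
        )
    with open(per_locus, "w") as fh:
        fh.write(f"# seed={result.seed}\n")
        fh.write("index_id\tn_snps\toverlaps_observed\toverlap_score\n")
        overlapping = [
            (vid, info)
            for vid, info in result.per_locus.items()
            if info["overlaps_observed"]
        ]
        for vid, info in sorted(overlapping, key=lambda kv: (kv[1]["overlap_score"], kv[0])):
            fh.write(
                f"{vid}\t{info['n_snps']}\t{int(info['overlaps_observed'])}\t"
                f"{info['overlap_score']:.6f}\n"
            )
    return summary, per_locus
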
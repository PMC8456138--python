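"""Nei's Fst between lineage pairs from pooled allele read depths.

Allele frequencies are estimated directly from pooled read proportions
(ref / (ref + alt)); per-site Fst = (H_T - H_S) / H_T with
H_T = 2 p_bar q_bar on the mean frequency of the pair and H_S the mean
within-lineage expected heterozygosity. Sites are filtered per lineage for
quality, depth and minor-allele read fraction before entering a pair.

The allele-count table is a long-format DataFrame with columns:
site, lineage, ref_reads, alt_reads, qual, n_alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["site", "lineage", "ref_reads", "alt_reads", "qual", "n_alleles"]


def filter_sites(
    table: pd.DataFrame,
    min_maf: float = 0.1,
    min_qual: float = 30.0,
    depth_range: tuple[int, int] = (10, 100),
    max_alleles: int = 2,
) -> pd.DataFrame:
    """Keep site-lineage observations passing quality, depth, minor-allele
    fraction and biallelic filters.

    A site enters a pairwise comparison downstream only if both lineages'
    observations pass.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"allele table missing columns: {sorted(missing)}")
    depth = table["ref_reads"] + table["alt_reads"]
    with np.errstate(invalid="ignore"):
        frac = table["alt_reads"] / depth.replace(0, np.nan)
    maf = np.minimum(frac, 1.0 - frac)
    keep = (
        (table["qual"] >= min_qual)
        & (depth >= depth_range[0])
        & (depth <= depth_range[1])
        & (maf >= min_maf)
        & (table["n_alleles"] <= max_alleles)
    )
    return table.loc[keep.fillna(False)].copy()


def site_fst(counts_a: tuple[int, int], counts_b: tuple[int, int]) -> float | None:
    """Nei's Fst at one site from (ref, alt) read counts of two pools.

    Returns None (site excluded) when H_T = 0, i.e. both pools fixed for
    the same allele.
    """
    ref_a, alt_a = counts_a
    ref_b, alt_b = counts_b
    da, db = ref_a + alt_a, ref_b + alt_b
    if da == 0 or db == 0:
        raise ValueError("zero read depth")
    p_a = ref_a / da
    p_b = ref_b / db
    p_bar = (p_a + p_b) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return None
    h_s = (2.0 * p_a * (1.0 - p_a) + 2.0 * p_b * (1.0 - p_b)) / 2.0
    fst = (h_t - h_s) / h_t
    assert fst >= -1e-12, "Nei Fst cannot be negative for two populations"
    return max(fst, 0.0)


@dataclass
class FstMatrix:
    """Mean pairwise Nei Fst with per-pair site counts."""

    lineages: list[str]
    mean_fst: pd.DataFrame
    n_sites: pd.DataFrame
    per_site: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    def pair(self, a: str, b: str) -> float:
        return float(self.mean_fst.loc[a, b])


def _vectorized_site_fst(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    p_bar = (p_a + p_b) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    h_s = p_a * (1.0 - p_a) + p_b * (1.0 - p_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (h_t - h_s) / h_t
    fst[h_t == 0.0] = np.nan
    return np.clip(fst, 0.0, 1.0)


def pairwise_fst(
    table: pd.DataFrame,
    lineages: list[str] | None = None,
    apply_filters: bool = True,
    estimator: str = "mean_of_ratios",
    keep_per_site: bool = False,
    **filter_kwargs,
) -> FstMatrix:
    """Mean pairwise Nei Fst over passing sites shared by each lineage pair.

    estimator: 'mean_of_ratios' (unweighted mean of per-site Fst, the
    default) or 'ratio_of_sums' (sum(H_T - H_S) / sum(H_T)).
    """
    if estimator not in ("mean_of_ratios", "ratio_of_sums"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if apply_filters:
        table = filter_sites(table, **filter_kwargs)
    if lineages is None:
        lineages = sorted(table["lineage"].unique())
    else:
        unknown = set(lineages) - set(table["lineage"].unique())
        if unknown and len(table):
            raise ValueError(f"unknown lineages: {sorted(unknown)}")
    depth = table["ref_reads"] + table["alt_reads"]
    freq = table["ref_reads"] / depth
    wide = (
        table.assign(p=freq)
        .pivot_table(index="site", columns="lineage", values="p", aggfunc="first")
    )
    mean = pd.DataFrame(np.nan, index=lineages, columns=lineages, dtype=float)
    nsites = pd.DataFrame(0, index=lineages, columns=lineages, dtype=int)
    np.fill_diagonal(mean.values, 0.0)
    per_site: dict[tuple[str, str], pd.Series] = {}
    for a, b in combinations(lineages, 2):
        if a not in wide.columns or b not in wide.columns:
            continue
        sub = wide[[a, b]].dropna()
        if not len(sub):
            continue
        fst = _vectorized_site_fst(sub[a].to_numpy(), sub[b].to_numpy())
        defined = ~np.isnan(fst)
        n = int(defined.sum())
        nsites.loc[a, b] = nsites.loc[b, a] = n
        if n == 0:
            continue
        if estimator == "mean_of_ratios":
            val = float(np.nanmean(fst))
        else:
            p_a, p_b = sub[a].to_numpy(), sub[b].to_numpy()
            p_bar = (p_a + p_b) / 2
            h_t = 2 * p_bar * (1 - p_bar)
            h_s = p_a * (1 - p_a) + p_b * (1 - p_b)
            val = float((h_t - h_s)[defined].sum() / h_t[defined].sum())
        mean.loc[a, b] = mean.loc[b, a] = val
        if keep_per_site:
            per_site[(a, b)] = pd.Series(fst[defined], index=sub.index[defined])
    return FstMatrix(lineages=list(lineages), mean_fst=mean, n_sites=nsites, per_site=per_site)


def read_allele_table_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"allele table missing columns: {sorted(missing)}")
    return table


def write_allele_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_vcf(table: pd.DataFrame, path) -> None:
    """Write a minimal VCF: one pooled sample per lineage, AD=ref,alt.

    Site ids of the form 'contig:pos' become CHROM/POS; other ids go to a
    single synthetic contig with a running position.
    """
    lineages = sorted(table["lineage"].unique())
    wide = table.set_index(["site", "lineage"])
    sites = list(dict.fromkeys(table["site"]))
    contigs = []
    rows = []
    for i, site in enumerate(sites):
        sid = str(site)
        if ":" in sid:
            chrom, pos = sid.rsplit(":", 1)
            pos = int(pos)
        else:
            chrom, pos = sid, 1
        if chrom not in contigs:
            contigs.append(chrom)
        quals = []
        fields = []
        for lin in lineages:
            key = (site, lin)
            if key in wide.index:
                rec = wide.loc[key]
                fields.append(f"{int(rec['ref_reads'])},{int(rec['alt_reads'])}")
                quals.append(float(rec["qual"]))
            else:
                fields.append(".")
        qual = f"{min(quals):g}" if quals else "."
        rows.append((chrom, pos, qual, fields))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic read depths">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(lineages) + "\n")
        for chrom, pos, qual, fields in rows:
            fh.write(f"{chrom}\t{pos}\t.\tA\tT\t{qual}\t.\t.\tAD\t" + "\t".join(fields) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a pooled-sample VCF (AD per lineage) into the long allele table."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        lineages = list(vcf.header.samples)
        for rec in vcf:
            site = f"{rec.chrom}:{rec.pos}"
            qual = rec.qual if rec.qual is not None else np.nan
            n_alleles = len(rec.alleles) if rec.alleles else 2
            for lin in lineages:
                ad = rec.samples[lin].get("AD")
                if ad is None or ad[0] is None:
                    continue
                rows.append(
                    {
                        "site": site,
                        "lineage": lin,
                        "ref_reads": int(ad[0]),
                        "alt_reads": int(ad[1]) if len(ad) > 1 else 0,
                        "qual": qual,
                        "n_alleles": n_alleles,
                    }
                )
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
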
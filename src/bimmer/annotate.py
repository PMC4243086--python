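"""Region merging, direction labels, and gene/region-level rate summaries.

Per-bin differential calls are turned into merged regions (maximal runs of
dm=1 bins), labeled hyper- (methylation gained in cancer) or hypo-
(methylation lost in cancer), intersected with gene annotations to obtain
per-region-class and per-gene differential rates, and screened by a
circular-shift permutation test.  All interval arithmetic is 0-based
half-open; an interval overlaps a bin iff it covers at least one base of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BinnedCounts

__all__ = [
    "RegionAnnotation",
    "read_gene_table",
    "merge_dm_bins",
    "classify_direction",
    "region_differential_rates",
    "gene_differential_rates",
    "permutation_test_genes",
    "REGION_CLASSES",
]

#: Region classes summarized genome-wide: promoter = TSS +/- 2 kb,
#: enhancer = 100 kb downstream of the transcription end, both strand-aware.
REGION_CLASSES = ("promoter", "exon", "enhancer", "gene_body")
PROMOTER_PAD = 2_000
ENHANCER_LEN = 100_000


@dataclass
class RegionAnnotation:
    """One gene's coordinates (0-based half-open), strand-aware."""

    gene: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene}: tx_start must be < tx_end")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene}: exon ({s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    def region(self, cls: str) -> list[tuple[int, int]]:
        """Intervals of one region class (clipped at coordinate 0)."""
        if cls == "promoter":
            return [(max(0, self.tss - PROMOTER_PAD), self.tss + PROMOTER_PAD)]
        if cls == "enhancer":
            if self.strand == "+":
                return [(self.tes, self.tes + ENHANCER_LEN)]
            return [(max(0, self.tes - ENHANCER_LEN), self.tes)]
        if cls == "exon":
            return list(self.exons)
        if cls == "gene_body":
            return [(self.tx_start, self.tx_end)]
        raise ValueError(f"unknown region class {cls!r}")


def read_gene_table(path, one_based: bool = False) -> list[RegionAnnotation]:
    """Read a simple TSV gene table.

    Columns: gene, chrom, strand, txStart, txEnd and optionally comma-
    separated exonStarts/exonEnds (UCSC refFlat style).  ``one_based=True``
    converts 1-based inclusive start coordinates to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    off = 1 if one_based else 0
    genes = []
    for _, row in df.iterrows():
        exons = []
        es, ee = row.get("exonStarts"), row.get("exonEnds")
        if isinstance(es, str) and es.strip(","):
            starts = [int(x) - off for x in es.strip(",").split(",")]
            ends = [int(x) for x in ee.strip(",").split(",")]
            exons = list(zip(starts, ends))
        genes.append(
            RegionAnnotation(
                gene=row["gene"],
                chrom=row["chrom"],
                strand=row["strand"],
                tx_start=int(row["txStart"]) - off,
                tx_end=int(row["txEnd"]),
                exons=exons,
            )
        )
    return genes


def _coords(bins) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(bins, BinnedCounts):
        return bins.chrom, bins.start, bins.end
    chrom, start, end = bins
    return (
        np.asarray(chrom, dtype=object),
        np.asarray(start, np.int64),
        np.asarray(end, np.int64),
    )


def merge_dm_bins(
    dm: np.ndarray,
    bins,
    posterior: np.ndarray | None = None,
    direction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Merge maximal runs of consecutive dm=1 bins into regions.

    Runs never cross a chromosome boundary.  Optional per-bin posterior
    scores and direction labels are aggregated per region (mean posterior,
    majority direction).
    """
    chrom, start, end = _coords(bins)
    dm = np.asarray(dm, dtype=np.int64)
    if len(dm) != len(start):
        raise ValueError("calls and coordinates must align")
    edge = np.ones(len(dm), dtype=bool)
    edge[1:] = (chrom[1:] != chrom[:-1]) | (dm[1:] != dm[:-1])
    run_id = np.cumsum(edge) - 1
    rows = []
    for r in np.unique(run_id):
        idx = np.nonzero(run_id == r)[0]
        if dm[idx[0]] != 1:
            continue
        row = {
            "chrom": chrom[idx[0]],
            "start": int(start[idx[0]]),
            "end": int(end[idx[-1]]),
            "n_bins": len(idx),
        }
        if posterior is not None:
            row["mean_posterior"] = float(np.mean(posterior[idx]))
        if direction is not None:
            labels, counts = np.unique(direction[idx], return_counts=True)
            row["direction"] = labels[np.argmax(counts)]
        rows.append(row)
    cols = ["chrom", "start", "end", "n_bins"]
    if posterior is not None:
        cols.append("mean_posterior")
    if direction is not None:
        cols.append("direction")
    return pd.DataFrame(rows, columns=cols)


def classify_direction(
    mn: np.ndarray, mc: np.ndarray, dm: np.ndarray
) -> np.ndarray:
    """Per-bin direction label at differential bins.

    'hyper' = methylated in cancer only (mc=1, mn=0); 'hypo' = methylated in
    normal only (mc=0, mn=1); 'inconsistent' when a dm=1 call has mn == mc
    (possible when alpha > 0); '.' at non-differential bins.
    """
    mn, mc, dm = (np.asarray(x, np.int64) for x in (mn, mc, dm))
    if not (len(mn) == len(mc) == len(dm)):
        raise ValueError("chains must align")
    out = np.full(len(dm), ".", dtype=object)
    out[(dm == 1) & (mc == 1) & (mn == 0)] = "hyper"
    out[(dm == 1) & (mc == 0) & (mn == 1)] = "hypo"
    out[(dm == 1) & (mc == mn)] = "inconsistent"
    return out


def _interval_bins(
    chrom: str, s: int, e: int, bins_chrom, bins_start, bins_end
) -> np.ndarray:
    """Indices of bins overlapping [s, e) on chrom (half-open overlap)."""
    mask = (bins_chrom == chrom) & (bins_start < e) & (bins_end > s)
    return np.nonzero(mask)[0]


def _class_bins(genes, cls, chrom_sel, bins_chrom, bins_start, bins_end):
    idx: set[int] = set()
    for g in genes:
        if chrom_sel is not None and g.chrom != chrom_sel:
            continue
        for s, e in g.region(cls):
            idx.update(
                _interval_bins(g.chrom, s, e, bins_chrom, bins_start, bins_end)
            )
    return np.fromiter(idx, dtype=np.int64) if idx else np.empty(0, np.int64)


def region_differential_rates(
    dm: np.ndarray,
    bins,
    genes: list[RegionAnnotation],
    denominator: str = "class-bins",
) -> pd.DataFrame:
    """Differential rate per chromosome and region class.

    ``denominator='class-bins'`` divides differential bins in the class by
    the number of bins the class covers; ``'chromosome-bins'`` divides by
    the chromosome's total bin count (so disjoint classes sum to at most
    the chromosome-wide rate).  Empty classes report rate 0 with
    ``empty=True``.  A ``Total`` row pools all chromosomes.
    """
    if denominator not in ("class-bins", "chromosome-bins"):
        raise ValueError("denominator must be 'class-bins' or 'chromosome-bins'")
    chrom, start, end = _coords(bins)
    dm = np.asarray(dm, np.int64)
    chroms = list(dict.fromkeys(chrom))  # keep genomic order
    rows = []
    for c in chroms + ["Total"]:
        sel = None if c == "Total" else c
        n_chrom_bins = len(dm) if sel is None else int(np.sum(chrom == c))
        for cls in REGION_CLASSES:
            idx = _class_bins(genes, cls, sel, chrom, start, end)
            n_diff = int(dm[idx].sum()) if len(idx) else 0
            denom = len(idx) if denominator == "class-bins" else n_chrom_bins
            rows.append(
                {
                    "chrom": c,
                    "region_class": cls,
                    "n_class_bins": len(idx),
                    "n_diff_bins": n_diff,
                    "rate": n_diff / denom if denom else 0.0,
                    "empty": len(idx) == 0,
                }
            )
    return pd.DataFrame(rows)


def gene_differential_rates(
    dm: np.ndarray,
    bins,
    genes: list[RegionAnnotation],
    direction: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene differential rate over the bins the gene span overlaps.

    ``diff_rate = n_diff / n_bins``; genes overlapping no bin are flagged
    ``not_mapped``.  With per-bin direction labels, a gene-level direction
    is the majority label among its differential bins ('.' if none).
    """
    chrom, start, end = _coords(bins)
    dm = np.asarray(dm, np.int64)
    rows = []
    for g in genes:
        idx = _interval_bins(g.chrom, g.tx_start, g.tx_end, chrom, start, end)
        mapped = len(idx) > 0
        n_diff = int(dm[idx].sum()) if mapped else 0
        row = {
            "gene": g.gene,
            "chrom": g.chrom,
            "n_bins": len(idx),
            "n_diff": n_diff,
            "diff_rate": n_diff / len(idx) if mapped else np.nan,
            "status": "mapped" if mapped else "not_mapped",
            "_bin_idx": idx,
        }
        if direction is not None:
            if mapped and n_diff > 0:
                lab = direction[idx]
                lab = lab[(lab == "hyper") | (lab == "hypo")]
                if len(lab):
                    vals, cnt = np.unique(lab, return_counts=True)
                    row["direction"] = vals[np.argmax(cnt)]
                else:
                    row["direction"] = "."
            else:
                row["direction"] = "."
        rows.append(row)
    return pd.DataFrame(rows)


def permutation_test_genes(
    reports: pd.DataFrame,
    dm: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Circular-shift permutation p-values for per-gene differential rates.

    The genome-wide dm vector is rotated by ``n_perm`` uniform random
    offsets — preserving its run-length structure — and each gene's rate is
    recomputed on its own bin positions.  ``p = (1 + #{null >= observed}) /
    (n_perm + 1)``; genes with p < ``alpha`` are flagged significant.
    Unmapped genes get p = NaN.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dm = np.asarray(dm, np.int64)
    M = len(dm)
    offsets = rng.integers(0, M, size=n_perm)
    out = reports.copy()
    pvals = np.full(len(out), np.nan)
    bin_idx = out["_bin_idx"].to_list()
    rates = out["diff_rate"].to_numpy()
    for i, idx in enumerate(bin_idx):
        if len(idx) == 0:
            continue
        obs = rates[i]
        null = dm[(idx[None, :] + offsets[:, None]) % M].mean(axis=1)
        pvals[i] = (1.0 + np.sum(null >= obs)) / (n_perm + 1.0)
    out["p_value"] = pvals
    out["significant"] = pvals < alpha
    return out
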
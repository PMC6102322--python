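"""Runs-of-homozygosity detection and genomic inbreeding (F_ROH).

A run of homozygosity (ROH) is a contiguous stretch of homozygous genotype
calls betraying autozygosity — both chromosome copies inherited from a
single ancestral haplotype.  The caller enforces four criteria:

1. at least ``min_snps`` consecutive SNPs (default 20);
2. a minimum physical span of ``min_length_bp`` (default 2 Mb);
3. no gap between adjacent SNPs inside the run larger than ``max_gap_bp``
   (default 500 kb), so sparse regions cannot masquerade as homozygous;
4. at most ``max_missing`` missing calls (default 2) and zero heterozygous
   calls inside the run.

Semantics.  Per sample and chromosome the marker sequence is first split
at heterozygous calls and at oversized gaps.  Within each remaining
stretch of homozygous/missing calls, segments are taken greedily left to
right: at the leftmost homozygous call from which a window satisfying all
four criteria can start, the longest such window (bounded by the missing-
call budget and trimmed so both ends are homozygous non-missing calls) is
committed, and the scan resumes after it.  This "leftmost-longest
non-overlapping" rule is deterministic and order-independent, and is
checked against an exhaustive sub-interval enumeration in the test suite.
Run boundaries are SNP positions; length = end - start.

F_ROH for an individual is the summed ROH length divided by L_AUTO, the
autosomal length covered by SNPs (per-chromosome span of the post-QC
marker map, summed; overridable for exact replication of published
denominators).  Runs are binned into the conventional length classes
2-4, 4-8, 8-16 and >16 Mb (half-open on the right): under the inverse-
exponential model for identical-by-descent segment lengths (mean
100/(2g) cM for a common ancestor g generations back, ~1 cM/Mb), short
runs reflect ancient inbreeding and long runs recent inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

LENGTH_CLASS_EDGES_MB = [2, 4, 8, 16]
LENGTH_CLASS_LABELS = ["2-4", "4-8", "8-16", ">16"]

SEGMENT_COLUMNS = [
    "sample_id",
    "chromosome",
    "start_bp",
    "end_bp",
    "length_bp",
    "n_snps",
    "n_missing",
]


def expected_roh_length(generations: float) -> float:
    """Expected length (Mb) of an IBD segment from a common ancestor
    ``generations`` back: 100/(2 g) cM at ~1 cM per Mb."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    return 100.0 / (2.0 * generations)


# ----------------------------------------------------------------------
def _scan_stretch(pos, hom, miss, lo, hi, min_snps, min_length_bp, max_missing):
    """Greedy leftmost-longest segments within markers [lo, hi] (inclusive),
    which contain no heterozygous call and no oversized gap."""
    segments = []
    miss_prefix = np.concatenate([[0], np.cumsum(miss[lo : hi + 1])])  # local prefix

    def n_miss(i, j):  # global indices, inclusive
        return int(miss_prefix[j - lo + 1] - miss_prefix[i - lo])

    i = lo
    while i <= hi:
        if not hom[i]:
            i += 1
            continue
        # longest right extension from i with <= max_missing missing calls
        j = i
        while j + 1 <= hi and n_miss(i, j + 1) <= max_missing:
            j += 1
        while not hom[j]:  # trim trailing missing
            j -= 1
        n_snps = j - i + 1
        span = int(pos[j] - pos[i])
        if n_snps >= min_snps and span >= min_length_bp:
            segments.append((i, j, n_snps, span, n_miss(i, j)))
            i = j + 1
        else:
            i += 1
    return segments


def detect_roh(
    dataset: GenotypeDataset,
    min_snps: int = 20,
    min_length_bp: int = 2_000_000,
    max_gap_bp: int = 500_000,
    max_missing: int = 2,
) -> pd.DataFrame:
    """Detect ROH for every individual; returns one row per segment."""
    if min_snps < 1 or min_length_bp < 0 or max_gap_bp < 0 or max_missing < 0:
        raise ValueError("ROH thresholds must be non-negative (min_snps >= 1)")
    chroms = dataset.markers["chromosome"].to_numpy()
    pos_all = dataset.markers["position_bp"].to_numpy(np.int64)

    chrom_slices = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        p = pos_all[idx]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"markers on chromosome {chrom} are not position-sorted")
        chrom_slices.append((chrom, idx, p))

    rows = []
    for s_idx, srow in enumerate(dataset.samples.itertuples(index=False)):
        g = dataset.calls[s_idx]
        for chrom, idx, p in chrom_slices:
            gc = g[idx]
            het = gc == 1
            miss = gc == MISSING
            hom = ~het & ~miss
            # break at het calls and at gaps > max_gap_bp
            breaks = np.flatnonzero(het)
            gap_breaks = np.flatnonzero(np.diff(p) > max_gap_bp)  # break after marker k
            bounds = np.zeros(len(gc) + 1, bool)
            bounds[0] = bounds[-1] = True
            bounds[breaks] = True
            bounds[breaks + 1] = True
            bounds[gap_breaks + 1] = True
            cut = np.flatnonzero(bounds)
            for a, b in zip(cut[:-1], cut[1:]):
                lo, hi = int(a), int(b) - 1
                if hi < lo or het[lo]:
                    continue
                for i, j, n_snps, span, nm in _scan_stretch(
                    p, hom, miss, lo, hi, min_snps, min_length_bp, max_missing
                ):
                    rows.append(
                        {
                            "sample_id": srow.sample_id,
                            "chromosome": chrom,
                            "start_bp": int(p[i]),
                            "end_bp": int(p[j]),
                            "length_bp": span,
                            "n_snps": n_snps,
                            "n_missing": nm,
                        }
                    )
    segments = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return classify_segments(segments)


def classify_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Attach the length class (2-4, 4-8, 8-16, >16 Mb; right-open bins)."""
    if len(segments) and (segments["length_bp"] < LENGTH_CLASS_EDGES_MB[0] * 1e6).any():
        raise ValueError("segment shorter than the minimum length class")
    edges = [e * 1_000_000 for e in LENGTH_CLASS_EDGES_MB] + [np.inf]
    segments = segments.copy()
    segments["length_class"] = pd.cut(
        segments["length_bp"], bins=edges, labels=LENGTH_CLASS_LABELS, right=False
    ).astype(str) if len(segments) else pd.Series(dtype=str)
    return segments


# ----------------------------------------------------------------------
@dataclass
class RohSummary:
    """Per-individual and per-breed ROH statistics."""

    per_individual: pd.DataFrame  # sample_id, breed, n_roh, sum_roh_bp, froh_total, froh_<class>
    per_breed: pd.DataFrame      # breed, n, n_roh, s_roh_mb, mean_l_roh_mb, n_zero, froh means
    per_chromosome: pd.DataFrame  # breed x chromosome mean coverage fraction
    l_auto_bp: int


def compute_l_auto(dataset: GenotypeDataset) -> int:
    """Summed per-chromosome span (max - min position) of the marker map."""
    spans = dataset.markers.groupby("chromosome", sort=False)["position_bp"].agg(["min", "max"])
    if not len(spans):
        raise ValueError("no markers to compute L_AUTO from")
    return int((spans["max"] - spans["min"]).sum())


def summarize(
    segments: pd.DataFrame,
    dataset: GenotypeDataset,
    l_auto_bp: int | None = None,
) -> RohSummary:
    """Aggregate segments into F_ROH and per-breed summaries.

    nROH per breed is the total segment count; S_ROH is the mean of the
    per-individual summed ROH length (Mb), averaging over all animals in
    the breed including those without ROH; mean L_ROH is the mean segment
    length; N_0 ("n_zero") counts animals with no ROH at all.
    """
    known = set(dataset.samples["sample_id"])
    stray = set(segments["sample_id"]) - known
    if stray:
        raise ValueError(f"segments reference unknown samples: {sorted(stray)[:5]}")
    if l_auto_bp is None:
        l_auto_bp = compute_l_auto(dataset)

    base = dataset.samples[["sample_id", "breed"]].copy()
    per_ind = base.set_index("sample_id")
    grp = segments.groupby("sample_id")
    per_ind["n_roh"] = grp.size().reindex(per_ind.index, fill_value=0).astype(int)
    per_ind["sum_roh_bp"] = grp["length_bp"].sum().reindex(per_ind.index, fill_value=0).astype(np.int64)
    per_ind["froh_total"] = per_ind["sum_roh_bp"] / l_auto_bp
    for label in LENGTH_CLASS_LABELS:
        cls = segments[segments["length_class"] == label] if len(segments) else segments
        bp = cls.groupby("sample_id")["length_bp"].sum() if len(cls) else pd.Series(dtype=float)
        per_ind[f"froh_{label}"] = (
            bp.reindex(per_ind.index, fill_value=0).astype(float) / l_auto_bp
        )
    per_ind = per_ind.reset_index()

    rows = []
    for breed, sub in per_ind.groupby("breed", sort=False):
        seg_b = segments[segments["sample_id"].isin(set(sub["sample_id"]))]
        row = {
            "breed": breed,
            "n": len(sub),
            "n_roh": int(sub["n_roh"].sum()),
            "s_roh_mb": float(sub["sum_roh_bp"].mean() / 1e6),
            "mean_l_roh_mb": float(seg_b["length_bp"].mean() / 1e6) if len(seg_b) else np.nan,
            "n_zero": int((sub["n_roh"] == 0).sum()),
            "froh_total": float(sub["froh_total"].mean()),
        }
        for label in LENGTH_CLASS_LABELS:
            row[f"froh_{label}"] = float(sub[f"froh_{label}"].mean())
        rows.append(row)
    per_breed = pd.DataFrame(rows)

    # per-chromosome mean coverage fraction per breed
    spans = dataset.markers.groupby("chromosome", sort=False)["position_bp"].agg(["min", "max"])
    spans["span"] = (spans["max"] - spans["min"]).astype(np.int64)
    cov_rows = []
    breed_of = dict(zip(dataset.samples["sample_id"], dataset.samples["breed"]))
    n_by_breed = dataset.samples["breed"].value_counts()
    if len(segments):
        seg = segments.assign(breed=segments["sample_id"].map(breed_of))
        bp = seg.groupby(["breed", "chromosome"])["length_bp"].sum()
        for (breed, chrom), total in bp.items():
            cov_rows.append(
                {
                    "breed": breed,
                    "chromosome": chrom,
                    "mean_coverage_fraction": float(
                        total / (n_by_breed[breed] * spans.loc[chrom, "span"])
                    ),
                }
            )
    per_chrom = pd.DataFrame(
        cov_rows, columns=["breed", "chromosome", "mean_coverage_fraction"]
    )
    return RohSummary(
        per_individual=per_ind,
        per_breed=per_breed,
        per_chromosome=per_chrom,
        l_auto_bp=int(l_auto_bp),
    )
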
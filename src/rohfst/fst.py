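"""One-vs-rest Weir-Cockerham F_ST scan with moving-average region calling.

For each marker, the focal breed is contrasted with the pooled remaining
breeds using the two-population Weir & Cockerham (1984) unbiased estimator
theta-hat = a / (a + b + c), where a, b, c are the among-population,
among-individual-within-population, and within-individual variance
components.  With r = 2 populations of (per-marker, non-missing) sample
sizes n_1, n_2, allele-B frequencies p_1, p_2 and observed heterozygote
proportions h_1, h_2:

    n_bar = (n_1 + n_2) / 2
    n_c   = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r n_bar)
    s^2   = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)
    h_bar = sum n_i h_i / (r n_bar)

    a = n_bar/n_c * (s^2 - (p_bar(1-p_bar) - (r-1)/r s^2 - h_bar/4)/(n_bar-1))
    b = n_bar/(n_bar-1) * (p_bar(1-p_bar) - (r-1)/r s^2 - (2 n_bar - 1)/(4 n_bar) h_bar)
    c = h_bar / 2

The per-marker ratio (not a ratio of sums) is used because single-SNP
values are thresholded downstream.  Negative estimates indicate no
differentiation and are clamped to zero for smoothing, thresholding and
genome-wide averaging.  A centred moving average over 5 adjacent SNPs on
the same chromosome smooths the erratic single-SNP pattern; SNPs whose
smoothed value exceeds the 95% empirical quantile of the raw (clamped)
per-SNP distribution are called as putative selection-signature regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass
class FstTrack:
    """Per-marker raw/clamped/smoothed theta for one focal breed."""

    focal_breed: str
    markers: pd.DataFrame       # marker_id, chromosome, position_bp
    raw_theta: np.ndarray       # NaN where undefined
    clamped_theta: np.ndarray   # max(raw, 0), NaN where raw undefined
    ma_theta: np.ndarray | None = None
    window: int | None = None
    #: multi-locus ratio-of-sums estimate sum(a) / sum(a+b+c)
    weighted_theta: float = float("nan")

    @property
    def genome_mean_theta(self) -> float:
        """Mean clamped per-marker theta over defined markers.

        This is the conventional 'average F_ST across all SNPs' report.
        Note it is not a consistent estimator of the drift parameter: the
        per-marker ratio a/(a+b+c) has frequency-split-dependent
        denominators, so its mean sits below the multi-locus
        :attr:`weighted_theta` when differentiation is strong.
        """
        return float(np.nanmean(self.clamped_theta))

    def to_frame(self) -> pd.DataFrame:
        out = self.markers[["marker_id", "chromosome", "position_bp"]].copy()
        out["raw_theta"] = self.raw_theta
        out["clamped_theta"] = self.clamped_theta
        if self.ma_theta is not None:
            out["ma_theta"] = self.ma_theta
        return out


@dataclass
class RegionSet:
    """Called selection-signature intervals for one focal breed."""

    focal_breed: str
    regions: pd.DataFrame  # chromosome, start_bp, end_bp, n_markers, peak_ma_theta, peak_marker_id
    threshold_used: float
    quantile_level: float

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open BED representation."""
        bed = pd.DataFrame(
            {
                "chrom": self.regions["chromosome"],
                "chromStart": self.regions["start_bp"].astype(np.int64) - 1,
                "chromEnd": self.regions["end_bp"].astype(np.int64),
                "name": [
                    f"{self.focal_breed}_region_{i + 1}" for i in range(len(self.regions))
                ],
                "score": self.regions["peak_ma_theta"],
            }
        )
        return bed


# ----------------------------------------------------------------------
def _group_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker (n called, allele-B frequency, het proportion) for a group."""
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(np.float64)
    het = (calls == 1).sum(axis=0)
    dose = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose / (2 * n)
        h = het / n
    return n, p, h


def wc_theta(
    dataset: GenotypeDataset,
    focal_breed: str,
    exclude_breeds: tuple[str, ...] = (),
) -> FstTrack:
    """Per-marker two-population Weir-Cockerham theta, focal vs pooled rest.

    Markers where either group has fewer than 2 non-missing calls are left
    undefined (NaN).  ``exclude_breeds`` removes breeds from the pooled
    complement (e.g. to scan indigenous breeds without an exotic outlier).
    """
    focal = dataset.breed_mask(focal_breed)
    rest = ~focal
    for b in exclude_breeds:
        if b == focal_breed:
            raise ValueError("cannot exclude the focal breed")
        rest &= ~dataset.breed_mask(b)
    if not rest.any():
        raise ValueError("complement of the focal breed is empty")

    n1, p1, h1 = _group_counts(dataset.calls[focal])
    n2, p2, h2 = _group_counts(dataset.calls[rest])

    defined = (n1 >= 2) & (n2 >= 2)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        theta = a / (a + b + c)

    # monomorphic across both groups: a+b+c = 0 -> no information
    theta[~defined] = np.nan
    theta[defined & ~np.isfinite(theta)] = np.nan
    clamped = np.where(np.isnan(theta), np.nan, np.maximum(theta, 0.0))
    use = defined & np.isfinite(a) & np.isfinite(a + b + c)
    weighted = float(a[use].sum() / (a + b + c)[use].sum()) if use.any() else float("nan")
    return FstTrack(
        focal_breed=focal_breed,
        markers=dataset.markers[["marker_id", "chromosome", "position_bp"]].copy(),
        raw_theta=theta,
        clamped_theta=clamped,
        weighted_theta=weighted,
    )


# ----------------------------------------------------------------------
def moving_average(track: FstTrack, window: int = 5) -> FstTrack:
    """Fill the centred per-chromosome moving average of clamped theta.

    The window must be odd.  A value is produced only where the full window
    of ``window`` adjacent markers lies on one chromosome; undefined theta
    values inside a window are skipped and the mean taken over the defined
    ones (NaN if none).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    half = window // 2
    ma = np.full(track.clamped_theta.shape, np.nan)
    chroms = track.markers["chromosome"].to_numpy()
    small = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        vals = track.clamped_theta[idx]
        if idx.size < window:
            small.append(str(chrom))
            continue
        s = pd.Series(vals)
        m = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
        m[:half] = np.nan
        m[len(m) - half :] = np.nan
        ma[idx] = m
    if small:
        warnings.warn(
            f"chromosomes with fewer than {window} markers get no moving "
            f"average: {small}",
            stacklevel=2,
        )
    return FstTrack(
        focal_breed=track.focal_breed,
        markers=track.markers,
        raw_theta=track.raw_theta,
        clamped_theta=track.clamped_theta,
        ma_theta=ma,
        window=window,
        weighted_theta=track.weighted_theta,
    )


def call_regions(track: FstTrack, quantile_level: float = 0.95) -> RegionSet:
    """Call maximal runs of adjacent SNPs whose smoothed theta exceeds the
    empirical ``quantile_level`` quantile of the clamped raw values.

    The threshold comes from the raw (clamped, defined) per-SNP distribution,
    not the smoothed one; comparison is strict (>).  Runs never span
    chromosomes and are broken by SNPs with undefined smoothed values.
    """
    if track.ma_theta is None:
        raise ValueError("run moving_average before call_regions")
    defined = ~np.isnan(track.clamped_theta)
    if not defined.any():
        raise ValueError("no defined theta values")
    threshold = float(np.quantile(track.clamped_theta[defined], quantile_level))

    above = np.zeros(track.ma_theta.shape, bool)
    ok = ~np.isnan(track.ma_theta)
    above[ok] = track.ma_theta[ok] > threshold

    chroms = track.markers["chromosome"].to_numpy()
    pos = track.markers["position_bp"].to_numpy(np.int64)
    ids = track.markers["marker_id"].to_numpy()
    rows = []
    i, n = 0, len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        seg = slice(i, j + 1)
        peak = int(np.nanargmax(track.ma_theta[seg])) + i
        rows.append(
            {
                "chromosome": chroms[i],
                "start_bp": int(pos[i]),
                "end_bp": int(pos[j]),
                "n_markers": j - i + 1,
                "peak_ma_theta": float(track.ma_theta[peak]),
                "peak_marker_id": ids[peak],
            }
        )
        i = j + 1
    regions = pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "n_markers", "peak_ma_theta", "peak_marker_id"],
    )
    return RegionSet(
        focal_breed=track.focal_breed,
        regions=regions,
        threshold_used=threshold,
        quantile_level=quantile_level,
    )


def fst_scan(
    dataset: GenotypeDataset,
    focal_breed: str,
    window: int = 5,
    quantile_level: float = 0.95,
    exclude_breeds: tuple[str, ...] = (),
) -> tuple[FstTrack, RegionSet]:
    """Convenience: theta -> moving average -> region calling."""
    track = moving_average(
        wc_theta(dataset, focal_breed, exclude_breeds=exclude_breeds), window=window
    )
    return track, call_regions(track, quantile_level=quantile_level)
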
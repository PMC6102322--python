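"""Sample- and marker-level genotype quality control.

The filter battery mirrors standard SNP-array practice for multi-breed
diversity panels:

1. samples with a missing-call fraction at or above a cutoff (default 0.10)
   are dropped;
2. markers are then screened, in order, for call rate (< 0.95 removed),
   minor allele frequency (< 0.05 removed, strict), non-autosomal placement,
   departure from Hardy-Weinberg equilibrium (exact test, p < 0.001), and
   finally unknown position (chromosome "0" or position 0).

Marker statistics are computed once on the sample-filtered data, pooling
all breeds; each removed marker is attributed to the first filter in the
order above that rejects it.  The HWE test is the exact conditional test
on the heterozygote count (Wigginton, Cutler & Abecasis 2005), two-sided,
without mid-p correction — the PLINK 1.9 default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

MARKER_FILTER_ORDER = ["marker_call_rate", "maf", "non_autosomal", "hwe", "unknown_position"]


class QcError(ValueError):
    """Raised when a filter would leave no samples or no markers."""


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------
def hwe_exact_pvalue(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic marker.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.  The
    conditional distribution is built by the standard ratio recurrence from
    the modal heterozygote count, which keeps the computation stable for
    thousands of genotypes.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_a, n_hom_b) + n_het  # copies of the rarer allele
    # heterozygote counts share the parity of the rare-allele count
    h_values = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(h_values.size, dtype=float)
    # start from the (approximate) mode and recurse outward
    mid = rare * (2 * n - rare) / (2 * n)
    start = int(np.argmin(np.abs(h_values - mid)))
    probs[start] = 1.0
    # P(h+2)/P(h) = 4 * hom_r(h) * hom_c(h) / ((h+2)(h+1)); hom counts at h:
    #   hom_r = (rare - h) / 2, hom_c = n - h - hom_r
    for i in range(start, h_values.size - 1):
        h = h_values[i]
        hom_r = (rare - h) / 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for i in range(start, 0, -1):
        h = h_values[i]
        hom_r = (rare - h) / 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(h_values, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
@dataclass
class QcReport:
    """Counts of samples/markers removed at each sequential filter."""

    n_samples_in: int = 0
    n_samples_out: int = 0
    n_markers_in: int = 0
    n_markers_out: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_samples_in", self.n_samples_in), ("n_samples_out", self.n_samples_out)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [("n_markers_in", self.n_markers_in), ("n_markers_out", self.n_markers_out)]
        rows += [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
def filter_samples(
    dataset: GenotypeDataset, max_missing_rate: float = 0.1
) -> tuple[GenotypeDataset, QcReport]:
    """Drop samples whose missing-call fraction is >= ``max_missing_rate``."""
    miss_rate = (
        dataset.missing_mask().mean(axis=1)
        if dataset.n_markers
        else np.zeros(dataset.n_samples)
    )
    keep = miss_rate < max_missing_rate
    if not keep.any():
        raise QcError("sample call-rate filter removed every sample")
    report = QcReport(
        n_samples_in=dataset.n_samples,
        n_samples_out=int(keep.sum()),
        n_markers_in=dataset.n_markers,
        n_markers_out=dataset.n_markers,
        removed={"sample_call_rate": int((~keep).sum())},
        thresholds={"max_sample_missing_rate": max_missing_rate},
    )
    return dataset.subset(sample_mask=keep), report


def marker_statistics(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-marker call rate, MAF and HWE exact p-value on pooled samples."""
    calls = dataset.calls
    nonmiss = calls != MISSING
    n_called = nonmiss.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    hom_b = (calls == 2).sum(axis=0)
    hom_a = n_called - het - hom_b
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = (het + 2 * hom_b) / (2 * n_called)
    maf = np.minimum(freq_b, 1 - freq_b)
    maf[n_called == 0] = 0.0
    hwe_p = np.array(
        [hwe_exact_pvalue(int(a), int(h), int(b)) for a, h, b in zip(hom_a, het, hom_b)]
    )
    return pd.DataFrame(
        {
            "marker_id": dataset.markers["marker_id"],
            "call_rate": n_called / max(dataset.n_samples, 1),
            "maf": maf,
            "hwe_p": hwe_p,
        }
    )


def filter_markers(
    dataset: GenotypeDataset,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    autosomes: frozenset[str] | None = None,
    hwe_alpha: float = 0.001,
    per_breed_hwe: bool = False,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the marker filter battery; see module docstring for the order.

    ``per_breed_hwe`` tests HWE within each breed instead of pooled and
    rejects a marker if any breed rejects (off by default; breed structure
    itself produces Wahlund departures under pooling).
    """
    if autosomes is None:
        autosomes = dataset.autosomes
    stats = marker_statistics(dataset)

    fail = {}
    fail["marker_call_rate"] = (stats["call_rate"] < min_call_rate).to_numpy()
    fail["maf"] = (stats["maf"] < min_maf).to_numpy()
    fail["non_autosomal"] = ~dataset.markers["chromosome"].astype(str).isin(autosomes).to_numpy()
    if per_breed_hwe:
        hwe_fail = np.zeros(dataset.n_markers, bool)
        for breed in dataset.breeds:
            sub = dataset.subset(sample_mask=dataset.breed_mask(breed))
            hwe_fail |= (marker_statistics(sub)["hwe_p"] < hwe_alpha).to_numpy()
        fail["hwe"] = hwe_fail
    else:
        fail["hwe"] = (stats["hwe_p"] < hwe_alpha).to_numpy()
    fail["unknown_position"] = (
        (dataset.markers["position_bp"].astype(np.int64) == 0)
        | (dataset.markers["chromosome"].astype(str) == "0")
    ).to_numpy()

    removed = {}
    already = np.zeros(dataset.n_markers, bool)
    for name in MARKER_FILTER_ORDER:
        hit = fail[name] & ~already
        removed[name] = int(hit.sum())
        already |= hit
    keep = ~already
    if not keep.any():
        raise QcError("marker filters removed every marker")

    report = QcReport(
        n_samples_in=dataset.n_samples,
        n_samples_out=dataset.n_samples,
        n_markers_in=dataset.n_markers,
        n_markers_out=int(keep.sum()),
        removed=removed,
        thresholds={
            "min_marker_call_rate": min_call_rate,
            "min_maf": min_maf,
            "hwe_alpha": hwe_alpha,
        },
    )
    return dataset.subset(marker_mask=keep), report


def run_qc(
    dataset: GenotypeDataset,
    max_sample_missing_rate: float = 0.1,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    autosomes: frozenset[str] | None = None,
    hwe_alpha: float = 0.001,
    per_breed_hwe: bool = False,
) -> tuple[GenotypeDataset, QcReport]:
    """Sample filter followed by the marker filter battery; merged report."""
    ds, srep = filter_samples(dataset, max_sample_missing_rate)
    ds, mrep = filter_markers(
        ds,
        min_call_rate=min_call_rate,
        min_maf=min_maf,
        autosomes=autosomes,
        hwe_alpha=hwe_alpha,
        per_breed_hwe=per_breed_hwe,
    )
    report = QcReport(
        n_samples_in=dataset.n_samples,
        n_samples_out=ds.n_samples,
        n_markers_in=dataset.n_markers,
        n_markers_out=ds.n_markers,
        removed={**srep.removed, **mrep.removed},
        thresholds={**srep.thresholds, **mrep.thresholds},
    )
    return ds, report
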
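"""Canonical in-memory containers for multi-breed SNP-array genotypes.

A :class:`GenotypeDataset` bundles three aligned pieces:

* a marker map (``markers``): one row per SNP with its identifier,
  chromosome label, 1-based physical position and the two allele codes;
* a sample table (``samples``): one row per animal with its identifier
  and breed label;
* a calls matrix (``calls``): ``n_samples x n_markers`` of small integers
  counting copies of ``allele_b`` (0, 1 or 2), with :data:`MISSING` (-1)
  for no-calls.

All downstream stages (QC, similarity, F_ST scans, ROH detection) consume
this container.  Markers are kept sorted by (chromosome, position);
chromosome labels are opaque strings, ordered numerically when they parse
as integers and lexicographically otherwise, so the container is portable
across species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in the calls matrix.
MISSING = -1

MARKER_COLUMNS = ["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "breed"]


def chromosome_sort_key(label: str) -> tuple[int, float, str]:
    """Ordering key for chromosome labels: numeric labels first, in numeric
    order, then non-numeric labels lexicographically."""
    s = str(label)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0.0, s)


@dataclass
class GenotypeDataset:
    """Samples x markers allele-count matrix with marker map and breed labels."""

    markers: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    #: set of chromosome labels regarded as autosomes (default goat: "1".."29")
    autosomes: frozenset[str] = field(
        default_factory=lambda: frozenset(str(c) for c in range(1, 30))
    )

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        for col in MARKER_COLUMNS:
            if col not in self.markers.columns:
                raise ValueError(f"marker map lacks column {col!r}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample table lacks column {col!r}")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        if self.markers["marker_id"].duplicated().any():
            dups = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))[:5]} ...")
        if (self.markers["position_bp"].astype(np.int64) < 0).any():
            raise ValueError("negative marker positions")
        if len(self.samples) and (self.samples["breed"].astype(str) == "").any():
            raise ValueError("empty breed label")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["breed"]))

    def breed_mask(self, breed: str) -> np.ndarray:
        mask = (self.samples["breed"] == breed).to_numpy()
        if not mask.any():
            raise KeyError(f"breed {breed!r} not present in dataset")
        return mask

    # ------------------------------------------------------------------
    def sort_markers(self) -> "GenotypeDataset":
        """Return a copy with markers sorted by (chromosome, position).

        Position must be strictly increasing within a chromosome; co-located
        markers keep their input order and trigger a warning.
        """
        keys = [chromosome_sort_key(c) for c in self.markers["chromosome"]]
        order = sorted(
            range(self.n_markers),
            key=lambda i: (keys[i], int(self.markers["position_bp"].iloc[i])),
        )
        markers = self.markers.iloc[order].reset_index(drop=True)
        dup = markers.duplicated(subset=["chromosome", "position_bp"])
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} markers share a (chromosome, position) with "
                "another marker; input order kept for ties",
                stacklevel=2,
            )
        return GenotypeDataset(
            markers=markers,
            samples=self.samples.copy(),
            calls=self.calls[:, order],
            autosomes=self.autosomes,
        )

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        marker_mask: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        mm = np.ones(self.n_markers, bool) if marker_mask is None else np.asarray(marker_mask, bool)
        return GenotypeDataset(
            markers=self.markers.loc[mm].reset_index(drop=True),
            samples=self.samples.loc[sm].reset_index(drop=True),
            calls=self.calls[np.ix_(sm, mm)],
            autosomes=self.autosomes,
        )

    # ------------------------------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.markers[MARKER_COLUMNS].reset_index(drop=True).equals(
                other.markers[MARKER_COLUMNS].reset_index(drop=True)
            )
            and self.samples[SAMPLE_COLUMNS].reset_index(drop=True).equals(
                other.samples[SAMPLE_COLUMNS].reset_index(drop=True)
            )
            and np.array_equal(self.calls, other.calls)
        )
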
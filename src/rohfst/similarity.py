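"""Pairwise identical-by-state (IBS) genomic similarity.

For a pair of diploid individuals at one marker, each of the four ordered
allele pairings contributes 1 when the two alleles are identical by state,
so the per-marker score is the matching-pair count divided by 4:

* identical homozygotes           -> 1
* opposite homozygotes            -> 0
* any pairing involving a het     -> 1/2

The genome-wide similarity of a pair is the mean score over the markers at
which both individuals are called.  Self-similarities are included: an
individual's self-score is 1 at homozygous and 1/2 at heterozygous markers,
so the mean within-breed similarity (ordered pairs, diagonal included)
equals the expected homozygosity of the breed when data are complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray          # dense symmetric, NaN where undefined
    n_shared_markers: np.ndarray  # pairwise count of jointly called markers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def sim_matrix(dataset: GenotypeDataset, denominator: str = "pairwise") -> SimilarityMatrix:
    """IBS similarity for all ordered sample pairs, including self-pairs.

    ``denominator='pairwise'`` divides each pair's score by its own count of
    jointly non-missing markers (keeps SIM a proportion under missingness);
    ``'total'`` divides by the total marker count, the literal textbook
    formula.  A pair with zero shared markers gets NaN and a warning.
    """
    if dataset.n_markers < 1:
        raise ValueError("similarity needs at least one marker")
    if denominator not in ("pairwise", "total"):
        raise ValueError("denominator must be 'pairwise' or 'total'")
    calls = dataset.calls
    a0 = (calls == 0).astype(np.float64)
    a1 = (calls == 1).astype(np.float64)
    a2 = (calls == 2).astype(np.float64)
    valid = (calls != MISSING).astype(np.float64)

    same_hom = a0 @ a0.T + a2 @ a2.T
    any_het = a1 @ valid.T + valid @ a1.T - a1 @ a1.T
    score = same_hom + 0.5 * any_het
    n_shared = valid @ valid.T

    with np.errstate(invalid="ignore", divide="ignore"):
        if denominator == "pairwise":
            sim = score / n_shared
        else:
            sim = score / dataset.n_markers
    undefined = n_shared == 0
    if undefined.any():
        sim[undefined] = np.nan
        warnings.warn(
            f"{int(undefined.sum())} sample pairs share no called markers; "
            "similarity undefined (NaN)",
            stacklevel=2,
        )
    return SimilarityMatrix(
        sample_ids=dataset.samples["sample_id"].tolist(),
        values=sim,
        n_shared_markers=n_shared.astype(np.int64),
    )


def breed_summary(sim: SimilarityMatrix, breeds: list[str] | pd.Series) -> pd.DataFrame:
    """Breed x breed matrix of mean similarities.

    The within-breed mean (diagonal) averages all ordered pairs including
    self-pairs; between-breed means average all cross pairs.
    """
    breeds = pd.Series(list(breeds), index=sim.sample_ids)
    if len(breeds) != len(sim.sample_ids):
        raise ValueError("breed list length does not match sample count")
    labels = list(dict.fromkeys(breeds))
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    masks = {b: (breeds == b).to_numpy() for b in labels}
    for b in labels:
        if not masks[b].any():
            raise ValueError(f"breed {b!r} has no samples")
    for i, bi in enumerate(labels):
        for bj in labels[: i + 1]:
            block = sim.values[np.ix_(masks[bi], masks[bj])]
            out.loc[bi, bj] = out.loc[bj, bi] = float(np.nanmean(block))
    return out
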
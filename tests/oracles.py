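"""Independent brute-force oracles used to cross-check the package.

Each function here re-derives a quantity from first principles by direct
enumeration or exact arithmetic, sharing no code with the implementation
it checks.
"""

from __future__ import annotations

from fractions import Fraction as F

import numpy as np
from scipy.special import gammaln

MISSING = -1


# ----------------------------------------------------------------------
def wc_theta_oracle(counts1, counts2) -> float:
    """Two-population Weir-Cockerham theta from genotype counts, in exact
    rational arithmetic.  ``counts = (n_hom_a, n_het, n_hom_b)``."""

    def stats(counts):
        n_aa, n_ab, n_bb = counts
        n = n_aa + n_ab + n_bb
        return F(n), F(n_ab + 2 * n_bb, 2 * n), F(n_ab, n)

    n1, p1, h1 = stats(counts1)
    n2, p2, h2 = stats(counts2)
    r = F(2)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    den = a + b + c
    if den == 0:
        return float("nan")
    return float(a / den)


# ----------------------------------------------------------------------
def hwe_enum_pvalue(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact Hardy-Weinberg p-value by full enumeration of the conditional
    heterozygote-count distribution (log-factorial formula)."""
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_a, n_hom_b) + n_het
    hs = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hs) // 2
    homc = n - hs - homr
    logp = (
        hs * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hs + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.searchsorted(hs, n_het)]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
def roh_oracle(
    calls,
    positions,
    min_snps: int = 20,
    min_length_bp: int = 2_000_000,
    max_gap_bp: int = 500_000,
    max_missing: int = 2,
):
    """Exhaustive sub-interval enumeration ROH caller for one chromosome of
    one individual.

    Enumerates every marker interval [i, j] satisfying all criteria
    (homozygous non-missing endpoints, no heterozygote inside, all internal
    gaps <= max_gap_bp, <= max_missing missing calls, >= min_snps markers,
    span >= min_length_bp) and reduces to the leftmost-longest
    non-overlapping set.  Returns [(i, j)] marker-index pairs.
    """
    calls = np.asarray(calls)
    pos = np.asarray(positions, dtype=np.int64)
    n = len(calls)
    het = calls == 1
    miss = calls == MISSING
    hom = ~het & ~miss
    het_ps = np.concatenate([[0], np.cumsum(het)])
    miss_ps = np.concatenate([[0], np.cumsum(miss)])
    bad_gap = np.diff(pos) > max_gap_bp
    gap_ps = np.concatenate([[0], np.cumsum(bad_gap)])

    best_end: dict[int, int] = {}
    for i in range(n):
        if not hom[i]:
            continue
        for j in range(i + min_snps - 1, n):
            # all three conditions are monotone in j: once violated, stop
            if het_ps[j + 1] - het_ps[i] > 0:
                break
            if gap_ps[j] - gap_ps[i] > 0:
                break
            if miss_ps[j + 1] - miss_ps[i] > max_missing:
                break
            if not hom[j]:
                continue
            if pos[j] - pos[i] >= min_length_bp:
                best_end[i] = j  # j increasing: keeps the longest
    chosen = []
    last_end = -1
    for i in sorted(best_end):
        if i <= last_end:
            continue
        chosen.append((i, best_end[i]))
        last_end = best_end[i]
    return chosen


# ----------------------------------------------------------------------
def sim_pair_oracle(g1, g2) -> float:
    """IBS similarity of two individuals by direct enumeration of the four
    ordered allele pairings at each jointly called marker."""
    num = 0
    n_markers = 0
    for a, b in zip(g1, g2):
        if a == MISSING or b == MISSING:
            continue
        alleles1 = ["B"] * a + ["A"] * (2 - a)
        alleles2 = ["B"] * b + ["A"] * (2 - b)
        num += sum(1 for x in alleles1 for y in alleles2 if x == y)
        n_markers += 1
    return num / (4 * n_markers) if n_markers else float("nan")


# ----------------------------------------------------------------------
def moving_average_oracle(values, chroms, window: int):
    """Brute-force centred windowed mean, full same-chromosome windows only,
    NaNs inside a window skipped."""
    values = np.asarray(values, dtype=float)
    chroms = np.asarray(chroms)
    half = window // 2
    out = np.full(values.shape, np.nan)
    for m in range(len(values)):
        lo, hi = m - half, m + half
        if lo < 0 or hi >= len(values):
            continue
        if chroms[lo] != chroms[m] or chroms[hi] != chroms[m]:
            continue
        win = values[lo : hi + 1]
        good = win[~np.isnan(win)]
        if good.size:
            out[m] = good.mean()
    return out


# ----------------------------------------------------------------------
def overlap_oracle(regions, genes):
    """All-pairs closed-interval intersection.  ``regions`` and ``genes`` are
    sequences of (chromosome, start_bp, end_bp[, name]) tuples; returns the
    set of (region_index, gene_name) hits."""
    hits = set()
    for ri, region in enumerate(regions):
        rc, rs, re = region[0], region[1], region[2]
        for gene in genes:
            gc, gs, ge = gene[0], gene[1], gene[2]
            name = gene[3] if len(gene) > 3 else f"{gc}:{gs}-{ge}"
            if str(gc) == str(rc) and gs <= re and rs <= ge:
                hits.add((ri, name))
    return hits
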
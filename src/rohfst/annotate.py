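"""Candidate-gene retrieval: intersect called regions with gene intervals.

Gene models are accepted as BED (0-based half-open) or GFF3 (1-based
inclusive); internally everything is 1-based inclusive.  A gene is
reported for a region when their closed intervals share at least one
base pair — partial overlap suffices.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

GENE_COLUMNS = ["gene", "chromosome", "start_bp", "end_bp", "strand"]


def read_genes_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if bed.shape[1] < 3:
        raise ValueError("BED needs at least chrom, start, end")
    genes = pd.DataFrame(
        {
            "gene": bed[3] if bed.shape[1] > 3 else [f"feature_{i}" for i in range(len(bed))],
            "chromosome": bed[0],
            "start_bp": bed[1].astype(np.int64) + 1,  # to 1-based inclusive
            "end_bp": bed[2].astype(np.int64),
            "strand": bed[5] if bed.shape[1] > 5 else ".",
        }
    )
    _check(genes)
    return genes


def _gff3_attr(attrs: str) -> dict[str, str]:
    out = {}
    for field in attrs.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genes_gff3(path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Parse gene features from GFF3; name preference Name > gene > ID."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{i + 1}: GFF3 line has {len(parts)} columns")
            if parts[2] not in feature_types:
                continue
            attrs = _gff3_attr(parts[8])
            name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or f"feature_{i}"
            rows.append(
                {
                    "gene": name,
                    "chromosome": parts[0],
                    "start_bp": int(parts[3]),
                    "end_bp": int(parts[4]),
                    "strand": parts[6],
                }
            )
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    _check(genes)
    return genes


def read_genes(path) -> pd.DataFrame:
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_genes_gff3(path)
    return read_genes_bed(path)


def _check(genes: pd.DataFrame) -> None:
    if len(genes) and (genes["start_bp"] > genes["end_bp"]).any():
        raise ValueError("gene interval with start > end")


def overlap_genes(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map each region to the genes it overlaps (closed-interval, >= 1 bp).

    ``regions`` needs columns chromosome, start_bp, end_bp (1-based
    inclusive), as produced by the F_ST region caller.  Returns one row per
    (region, gene) hit; regions without hits appear with an empty gene.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # half-open tree coordinates: closed [s, e] -> [s, e+1)
        trees.setdefault(str(row.chromosome), IntervalTree()).addi(
            int(row.start_bp), int(row.end_bp) + 1, row.gene
        )
    unmatched = sorted(
        set(map(str, regions["chromosome"])) - set(trees)
    )
    if unmatched:
        warnings.warn(
            f"region chromosomes absent from the gene file: {unmatched}", stacklevel=2
        )
    rows = []
    for ridx, row in enumerate(regions.itertuples(index=False)):
        tree = trees.get(str(row.chromosome))
        hits = (
            sorted(iv.data for iv in tree.overlap(int(row.start_bp), int(row.end_bp) + 1))
            if tree is not None
            else []
        )
        for gene in hits or [""]:
            rows.append(
                {
                    "region_index": ridx,
                    "chromosome": row.chromosome,
                    "start_bp": int(row.start_bp),
                    "end_bp": int(row.end_bp),
                    "gene": gene,
                }
            )
    return pd.DataFrame(
        rows, columns=["region_index", "chromosome", "start_bp", "end_bp", "gene"]
    )
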
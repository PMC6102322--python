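"""PLINK PED/MAP and BED/BIM/FAM readers and writers.

Breed membership rides in the family-ID column of the FAM/PED file by
default; an explicit sample->breed mapping (dict or two-column TSV)
overrides it.  Markers are re-sorted to (chromosome, position) order on
read.  Coordinates are 1-based base pairs throughout (MAP convention).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

VALID_ALLELES = set("ACGT12")
_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major
# 2-bit codes -> allele_b copies: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_CALL = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CALL_TO_CODE = {0: 0, 1: 2, 2: 3, MISSING: 1}


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required companion file missing: {path}")
    return path


def _read_breed_table(path: str | os.PathLike) -> dict[str, str]:
    tab = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if tab.shape[1] < 2:
        raise ValueError("breed table needs two tab-separated columns: sample_id, breed")
    return dict(zip(tab[0], tab[1]))


def _resolve_breeds(sample_ids, fam_ids, breed_source) -> list[str]:
    if breed_source is None:
        return list(fam_ids)
    if isinstance(breed_source, (str, os.PathLike)):
        breed_source = _read_breed_table(breed_source)
    missing = [s for s in sample_ids if s not in breed_source]
    if missing:
        raise KeyError(f"samples absent from breed table: {missing[:5]} ...")
    return [breed_source[s] for s in sample_ids]


def _read_map(path: Path) -> pd.DataFrame:
    try:
        mp = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            {
                "chromosome": pd.Series(dtype=str),
                "marker_id": pd.Series(dtype=str),
                "position_bp": pd.Series(dtype=np.int64),
                "allele_a": pd.Series(dtype=str),
                "allele_b": pd.Series(dtype=str),
            }
        )
    if mp.shape[1] < 4:
        raise ValueError(f"{path}: MAP/BIM needs >=4 columns")
    out = pd.DataFrame(
        {
            "chromosome": mp[0],
            "marker_id": mp[1],
            "position_bp": mp[3].astype(np.int64),
        }
    )
    if mp.shape[1] >= 6:  # BIM: A1 = allele_a, A2 = allele_b
        out["allele_a"] = mp[4]
        out["allele_b"] = mp[5]
    if out["marker_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate marker ids")
    return out


def read_plink(
    path_prefix: str | os.PathLike,
    breed_source: dict[str, str] | str | os.PathLike | None = None,
    autosomes=None,
) -> GenotypeDataset:
    """Read ``<prefix>.ped/.map`` or ``<prefix>.bed/.bim/.fam`` into a dataset.

    The binary trio is preferred when both dialects are present.  ``breed_source``
    is a sample->breed dict or TSV path; by default the FAM/PED family ID is
    the breed label.
    """
    prefix = Path(path_prefix)
    kwargs = {} if autosomes is None else {"autosomes": frozenset(map(str, autosomes))}
    if prefix.with_suffix(".bed").exists():
        ds = _read_bed(prefix, breed_source)
    elif prefix.with_suffix(".ped").exists():
        ds = _read_ped(prefix, breed_source)
    else:
        raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped found")
    if kwargs:
        ds = GenotypeDataset(ds.markers, ds.samples, ds.calls, **kwargs)
    return ds.sort_markers()


def _read_ped(prefix: Path, breed_source) -> GenotypeDataset:
    markers = _read_map(_require(prefix.with_suffix(".map")))
    ped = pd.read_csv(prefix.with_suffix(".ped"), sep=r"\s+", header=None, dtype=str)
    n_markers = len(markers)
    if ped.shape[1] != 6 + 2 * n_markers:
        raise ValueError(
            f"PED has {ped.shape[1]} columns, expected {6 + 2 * n_markers} "
            f"for {n_markers} markers"
        )
    fam_ids = ped[0].tolist()
    sample_ids = ped[1].tolist()
    alleles = ped.iloc[:, 6:].to_numpy(dtype="U1")
    a1 = alleles[:, 0::2]
    a2 = alleles[:, 1::2]

    bad = set(np.unique(alleles)) - VALID_ALLELES - {"0"}
    if bad:
        raise ValueError(f"invalid allele codes in PED: {sorted(bad)}")
    if ((a1 == "0") != (a2 == "0")).any():
        raise ValueError("half-missing genotype (one allele '0') in PED")

    n_samples = len(sample_ids)
    calls = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    allele_a = np.empty(n_markers, dtype="U1")
    allele_b = np.empty(n_markers, dtype="U1")
    for k in range(n_markers):
        col = np.concatenate([a1[:, k], a2[:, k]])
        observed = sorted(set(col[col != "0"]))
        if len(observed) > 2:
            raise ValueError(
                f"marker {markers['marker_id'].iloc[k]}: >2 alleles {observed}"
            )
        # lexicographic assignment; a monomorphic marker gets allele_b='0'
        if len(observed) == 2:
            allele_a[k], allele_b[k] = observed
        elif len(observed) == 1:
            allele_a[k], allele_b[k] = observed[0], "0"
        else:
            allele_a[k], allele_b[k] = "0", "0"
        nonmiss = a1[:, k] != "0"
        calls[nonmiss, k] = (a1[nonmiss, k] == allele_b[k]).astype(np.int8) + (
            a2[nonmiss, k] == allele_b[k]
        ).astype(np.int8)

    markers = markers.assign(allele_a=allele_a, allele_b=allele_b)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "breed": _resolve_breeds(sample_ids, fam_ids, breed_source)}
    )
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


def _read_bed(prefix: Path, breed_source) -> GenotypeDataset:
    markers = _read_map(_require(prefix.with_suffix(".bim")))
    if "allele_a" not in markers.columns:
        raise ValueError("BIM file must carry allele columns 5 and 6")
    fam = pd.read_csv(_require(prefix.with_suffix(".fam")), sep=r"\s+", header=None, dtype=str)
    sample_ids = fam[1].tolist()
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic number (not SNP-major PLINK BED)")
    n_samples, n_markers = len(sample_ids), len(markers)
    bytes_per_snp = (n_samples + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * n_markers:
        raise ValueError(
            f"{prefix}.bed size inconsistent with {n_samples} samples x {n_markers} markers"
        )
    blocks = body.reshape(n_markers, bytes_per_snp)
    codes = np.empty((n_markers, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    calls = _CODE_TO_CALL[codes[:, :n_samples]].T  # samples x markers

    samples = pd.DataFrame(
        {"sample_id": sample_ids, "breed": _resolve_breeds(sample_ids, fam[0].tolist(), breed_source)}
    )
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


# ----------------------------------------------------------------------
def write_plink(
    dataset: GenotypeDataset, path_prefix: str | os.PathLike, dialect: str = "ped"
) -> None:
    """Write the dataset as ``ped`` (PED+MAP text) or ``bed`` (BED+BIM+FAM).

    The breed label is stored as the family ID.  Missing calls become
    ``0 0`` in PED and the missing 2-bit code in BED.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "ped":
        _write_ped(dataset, prefix)
    elif dialect == "bed":
        _write_bed(dataset, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'ped' or 'bed'")


def _map_lines(dataset: GenotypeDataset, with_alleles: bool) -> list[str]:
    lines = []
    for row in dataset.markers.itertuples(index=False):
        base = f"{row.chromosome}\t{row.marker_id}\t0\t{int(row.position_bp)}"
        if with_alleles:
            base += f"\t{row.allele_a}\t{row.allele_b}"
        lines.append(base + "\n")
    return lines


def _write_ped(dataset: GenotypeDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        fh.writelines(_map_lines(dataset, with_alleles=False))
    aa = dataset.markers["allele_a"].to_numpy(dtype="U1")
    ab = dataset.markers["allele_b"].to_numpy(dtype="U1")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, srow in enumerate(dataset.samples.itertuples(index=False)):
            g = dataset.calls[i]
            first = np.where(g >= 1, ab, aa)
            second = np.where(g == 2, ab, aa)
            first[g == MISSING] = "0"
            second[g == MISSING] = "0"
            geno = "\t".join(f"{x}\t{y}" for x, y in zip(first, second))
            fh.write(f"{srow.breed}\t{srow.sample_id}\t0\t0\t0\t-9\t{geno}\n")


def _write_bed(dataset: GenotypeDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        fh.writelines(_map_lines(dataset, with_alleles=True))
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for srow in dataset.samples.itertuples(index=False):
            fh.write(f"{srow.breed}\t{srow.sample_id}\t0\t0\t0\t-9\n")
    n_samples, n_markers = dataset.n_samples, dataset.n_markers
    padded = 4 * ((n_samples + 3) // 4)
    codes = np.zeros((n_markers, padded), dtype=np.uint8)
    calls_t = dataset.calls.T
    for call, code in _CALL_TO_CODE.items():
        codes[:, :n_samples][calls_t == call] = code
    blocks = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(blocks.tobytes())
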
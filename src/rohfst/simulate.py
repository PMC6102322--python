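"""Synthetic multi-breed SNP-array data with recoverable ground truth.

The generator emulates the statistical structure of a multi-breed goat
SNP-array study so every pipeline stage has a known target:

* **Breed divergence** follows the Balding-Nichols model: each marker has
  an ancestral allele frequency p ~ Uniform(maf_floor, 1 - maf_floor), and
  breed b draws its frequency from Beta(p(1-c_b)/c_b, (1-p)(1-c_b)/c_b),
  where the drift parameter c_b is the expected F_ST of the breed against
  the ancestral pool.
* **Autozygosity**: each individual receives identical-by-descent tracts
  laid down per chromosome as a Poisson number of intervals with
  Exponential lengths of mean 100/(2 g) Mb (1 cM ~ 1 Mb), truncated at the
  chromosome end; the Poisson intensity is calibrated so the expected
  merged coverage equals the target autozygous fraction f.  Markers inside
  a tract are homozygous for a single haplotype drawn once per tract from
  the breed frequencies; markers outside are Hardy-Weinberg draws.
* **Selective sweep**: inside a configured interval the focal breed's
  frequencies are replaced by a final frequency (e.g. 1.0 = fixation) with
  a linear shoulder of 10 markers on each side.
* **Missingness**: calls are masked i.i.d. at rate mu.

Everything is driven by one ``numpy.random.default_rng`` seed, so the same
configuration yields byte-identical PLINK and truth files.  The default
configuration mirrors a six-breed study: one exotic-like breed with
stronger divergence and recent inbreeding, five weakly diverged indigenous
breeds, 29 autosomes and ~43.5k markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import MISSING, GenotypeDataset

SHOULDER_MARKERS = 10


@dataclass
class BreedSpec:
    name: str
    n_samples: int
    drift_c: float              # Balding-Nichols drift, in (0, 1)
    autozygous_fraction: float = 0.0   # expected fraction f of genome in IBD tracts
    generations: float = 25.0   # age of inbreeding; tract mean length = 100/(2g) Mb

    def validate(self) -> None:
        if not 0 < self.drift_c < 1:
            raise ValueError(f"{self.name}: drift_c must be in (0,1)")
        if not 0 <= self.autozygous_fraction < 1:
            raise ValueError(f"{self.name}: autozygous_fraction must be in [0,1)")
        if self.generations <= 0:
            raise ValueError(f"{self.name}: generations must be positive")
        if self.n_samples < 1:
            raise ValueError(f"{self.name}: need at least one sample")


@dataclass
class SweepSpec:
    breed: str
    chromosome: str
    start_bp: int
    end_bp: int
    final_freq: float = 1.0


@dataclass
class SimConfig:
    seed: int = 0
    breeds: list[BreedSpec] = field(default_factory=list)
    chromosome_lengths_bp: dict[str, int] = field(default_factory=dict)
    markers_per_chromosome: int = 1500
    sweeps: list[SweepSpec] = field(default_factory=list)
    missing_rate: float = 0.0
    maf_floor: float = 0.05

    def validate(self) -> None:
        if not self.breeds:
            raise ValueError("config needs at least one breed")
        for b in self.breeds:
            b.validate()
        names = {b.name for b in self.breeds}
        for sw in self.sweeps:
            if sw.breed not in names:
                raise ValueError(f"sweep references unknown breed {sw.breed!r}")
            L = self.chromosome_lengths_bp.get(str(sw.chromosome))
            if L is None or not (1 <= sw.start_bp <= sw.end_bp <= L):
                raise ValueError("sweep interval outside chromosome bounds")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if not 0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")
        for b in self.breeds:
            mean_len = 1e6 * 100 / (2 * b.generations)
            if b.autozygous_fraction > 0 and mean_len > 2 * max(
                self.chromosome_lengths_bp.values()
            ):
                raise ValueError(
                    f"{b.name}: tract mean length exceeds chromosomes; "
                    "autozygous fraction unreachable"
                )

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            seed=raw.get("seed", 0),
            breeds=[BreedSpec(**b) for b in raw["breeds"]],
            chromosome_lengths_bp={str(k): int(v) for k, v in raw["chromosome_lengths_bp"].items()},
            markers_per_chromosome=raw.get("markers_per_chromosome", 1500),
            sweeps=[SweepSpec(**s) for s in raw.get("sweeps", [])],
            missing_rate=raw.get("missing_rate", 0.0),
            maf_floor=raw.get("maf_floor", 0.05),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "seed": self.seed,
            "breeds": [vars(b) for b in self.breeds],
            "chromosome_lengths_bp": dict(self.chromosome_lengths_bp),
            "markers_per_chromosome": self.markers_per_chromosome,
            "sweeps": [vars(s) for s in self.sweeps],
            "missing_rate": self.missing_rate,
            "maf_floor": self.maf_floor,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def default_config(seed: int = 0) -> SimConfig:
    """Desk-scale six-breed study: one diverged, inbred exotic-like breed
    (13 animals) and five weakly diverged indigenous-like breeds, 29
    autosomes totalling ~2.46 Gb, ~43.5k markers, 1% missingness, and one
    sweep fixed in the exotic-like breed."""
    lengths = {
        str(i + 1): int(round(L))
        for i, L in enumerate(np.linspace(130e6, 40e6, 29))
    }
    breeds = [
        BreedSpec("EXO", 13, drift_c=0.22, autozygous_fraction=0.14, generations=10),
        BreedSpec("IND1", 15, drift_c=0.06, autozygous_fraction=0.025, generations=4),
        BreedSpec("IND2", 29, drift_c=0.06, autozygous_fraction=0.013, generations=25),
        BreedSpec("IND3", 29, drift_c=0.06, autozygous_fraction=0.012, generations=20),
        BreedSpec("IND4", 29, drift_c=0.06, autozygous_fraction=0.012, generations=15),
        BreedSpec("IND5", 29, drift_c=0.06, autozygous_fraction=0.008, generations=10),
    ]
    return SimConfig(
        seed=seed,
        breeds=breeds,
        chromosome_lengths_bp=lengths,
        markers_per_chromosome=1500,
        sweeps=[SweepSpec(breed="EXO", chromosome="5", start_bp=40_000_000,
                          end_bp=44_000_000, final_freq=1.0)],
        missing_rate=0.01,
        maf_floor=0.05,
    )


# ----------------------------------------------------------------------
@dataclass
class TruthTable:
    """Simulator ground truth for recovery experiments."""

    tracts: pd.DataFrame          # sample_id, chromosome, start_bp, end_bp (merged)
    autozygous_fraction: pd.Series  # realized, per sample_id
    breed_c: dict[str, float]
    sweeps: list[SweepSpec]
    #: per sweep: chromosome plus first/last perturbed marker position
    #: (configured interval extended by the linear shoulders)
    sweep_intervals: pd.DataFrame
    frequencies: pd.DataFrame     # marker_id + ancestral + one column per breed

    def write_tsvs(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tracts.to_csv(outdir / "truth_tracts.tsv", sep="\t", index=False)
        self.autozygous_fraction.rename("autozygous_fraction").to_csv(
            outdir / "truth_autozygosity.tsv", sep="\t"
        )
        pd.DataFrame(
            {"breed": list(self.breed_c), "drift_c": list(self.breed_c.values())}
        ).to_csv(outdir / "truth_drift.tsv", sep="\t", index=False)
        pd.DataFrame([vars(s) for s in self.sweeps]).to_csv(
            outdir / "truth_sweeps.tsv", sep="\t", index=False
        )
        self.sweep_intervals.to_csv(outdir / "truth_sweep_intervals.tsv", sep="\t", index=False)
        self.frequencies.to_csv(outdir / "truth_frequencies.tsv", sep="\t", index=False)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _tract_intensity(f: float, mean_len: float, L: float) -> float:
    """Poisson tract count calibrated so expected merged coverage is f.

    A tract starts uniformly in [0, L] with Exponential(mean_len) raw
    length, truncated at the chromosome end, so its expected truncated
    length is mean_len - mean_len^2/L (1 - exp(-L/mean_len)).  Overlap
    between tracts is corrected through the Boolean-coverage relation
    coverage = 1 - exp(-raw_coverage), i.e. raw target -ln(1 - f).
    """
    e_trunc = mean_len - mean_len**2 / L * (1 - np.exp(-L / mean_len))
    return -np.log1p(-f) * L / e_trunc


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, TruthTable]:
    """Generate a genotype dataset plus its ground truth; deterministic in
    ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # marker map: sorted unique positions per chromosome
    chrom_names = list(config.chromosome_lengths_bp)
    marker_rows = []
    positions: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        L = config.chromosome_lengths_bp[chrom]
        m = config.markers_per_chromosome
        pos = np.unique(rng.integers(1, L + 1, size=m))
        while pos.size < m:
            pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=m - pos.size)]))
        positions[chrom] = np.sort(pos[:m])
        for p in positions[chrom]:
            marker_rows.append((f"snp_{chrom}_{p}", chrom, int(p), "A", "G"))
    markers = pd.DataFrame(
        marker_rows, columns=["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]
    )
    n_markers = len(markers)
    chrom_index = {c: np.flatnonzero(markers["chromosome"].to_numpy() == c) for c in chrom_names}

    ancestral = rng.uniform(config.maf_floor, 1 - config.maf_floor, size=n_markers)

    # per-breed frequencies under Balding-Nichols drift
    freq = {"ancestral": ancestral}
    for b in config.breeds:
        c = b.drift_c
        alpha = ancestral * (1 - c) / c
        beta = (1 - ancestral) * (1 - c) / c
        freq[b.name] = rng.beta(alpha, beta)

    # sweeps with linear shoulders
    sweep_iv_rows = []
    for sw in config.sweeps:
        idx = chrom_index[str(sw.chromosome)]
        pos = markers["position_bp"].to_numpy()[idx]
        inside = idx[(pos >= sw.start_bp) & (pos <= sw.end_bp)]
        if inside.size == 0:
            continue
        p_b = freq[sw.breed]
        p_b[inside] = sw.final_freq
        lo, hi = inside[0], inside[-1]
        left = idx[(idx < lo)][-SHOULDER_MARKERS:]
        right = idx[(idx > hi)][:SHOULDER_MARKERS]
        for shoulder in (left[::-1], right):
            for rank, k in enumerate(shoulder, start=1):
                w = 1 - rank / (len(shoulder) + 1)
                p_b[k] = w * sw.final_freq + (1 - w) * p_b[k]
        perturbed = np.concatenate([left, inside, right])
        pos_all = markers["position_bp"].to_numpy()
        sweep_iv_rows.append(
            {
                "breed": sw.breed,
                "chromosome": str(sw.chromosome),
                "start_bp": int(pos_all[perturbed].min()),
                "end_bp": int(pos_all[perturbed].max()),
            }
        )

    # genotypes
    sample_rows = []
    calls_blocks = []
    tract_rows = []
    realized = {}
    total_len = float(sum(config.chromosome_lengths_bp.values()))
    for b in config.breeds:
        p = freq[b.name]
        mean_len = 1e6 * 100 / (2 * b.generations)
        for i in range(b.n_samples):
            sid = f"{b.name}_{i + 1:03d}"
            sample_rows.append((sid, b.name))
            g = rng.binomial(1, p, size=n_markers) + rng.binomial(1, p, size=n_markers)
            covered = 0
            for chrom in chrom_names:
                L = config.chromosome_lengths_bp[chrom]
                if b.autozygous_fraction <= 0:
                    continue
                lam = _tract_intensity(b.autozygous_fraction, mean_len, L)
                n_tr = rng.poisson(lam)
                ivs = []
                for _ in range(n_tr):
                    start = int(rng.uniform(0, L))
                    length = rng.exponential(mean_len)
                    end = int(min(start + length, L))
                    if end > start:
                        ivs.append((start, end))
                    # haplotype draw per tract, markers forced homozygous
                    idx = chrom_index[chrom]
                    pos = markers["position_bp"].to_numpy()[idx]
                    hit = idx[(pos >= start) & (pos <= end)]
                    if hit.size:
                        hap = rng.binomial(1, p[hit])
                        g[hit] = 2 * hap
                for s, e in _merge_intervals(ivs):
                    covered += e - s
                    tract_rows.append((sid, chrom, s + 1, e))
            realized[sid] = covered / total_len
            calls_blocks.append(g.astype(np.int8))

    calls = np.vstack(calls_blocks)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    dataset = GenotypeDataset(
        markers=markers,
        samples=pd.DataFrame(sample_rows, columns=["sample_id", "breed"]),
        calls=calls,
        autosomes=frozenset(chrom_names),
    )
    truth = TruthTable(
        tracts=pd.DataFrame(
            tract_rows, columns=["sample_id", "chromosome", "start_bp", "end_bp"]
        ),
        autozygous_fraction=pd.Series(realized, name="autozygous_fraction"),
        breed_c={b.name: b.drift_c for b in config.breeds},
        sweeps=list(config.sweeps),
        sweep_intervals=pd.DataFrame(
            sweep_iv_rows, columns=["breed", "chromosome", "start_bp", "end_bp"]
        ),
        frequencies=pd.DataFrame({"marker_id": markers["marker_id"], **freq}),
    )
    return dataset, truth
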
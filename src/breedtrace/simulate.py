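"""Synthetic multi-breed SNP genotype panels with known ground truth.

Panels are generated under the Balding-Nichols model: an ancestral allele
frequency p_j is drawn per SNP, and each breed k receives a drifted
frequency f_kj ~ Beta with mean p_j and variance c_k * p_j (1 - p_j), where
the drift parameter c_k approximates the breed's expected differentiation
(FST) from the ancestral pool.  Individuals are unphased diploids: genotype
g_ij ~ Binomial(2, pi_ij) with pi_ij = sum_k q_ik f_kj, so mixed-ancestry
individuals follow directly from a user-supplied Q design.

Autozygosity is planted afterwards by forcing non-overlapping intervals
homozygous (one allele drawn from the individual's mixed frequency, then
doubled), which is what a run-of-homozygosity caller should recover.  The
generator records all ground truth (true Q, breed frequencies, planted
segments, realized autozygous fractions) in a :class:`SimTruth`.

The default panel mirrors a small livestock SNP-array study: 10 breeds of
25 diploids, 29 autosomes, ~5,000 markers; everything is driven by one seed
and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, write_genotypes


@dataclass
class SimConfig:
    """Panel design: breeds, map geometry, drift, ancestry, autozygosity, noise."""

    n_breeds: int = 10
    samples_per_breed: int = 25
    n_chromosomes: int = 29
    snps_per_chromosome: int = 172
    chromosome_length_bp: int = 100_000_000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    drift: float | list[float] = 0.1  # Balding-Nichols c per breed
    admixture_design: np.ndarray | None = None  # n_total x n_breeds true Q
    sample_breed_labels: list[str] | None = None  # overrides argmax(Q) labelling
    autozygosity_fraction: float = 0.0
    segment_length_range_bp: tuple[int, int] = (2_000_000, 8_000_000)
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        for r in (self.missing_rate, self.autozygosity_fraction):
            if not (0 <= r <= 1):
                raise ValueError("rates must lie in [0, 1]")
        for c in self.drift_per_breed():
            if not (0 < c < 1):
                raise ValueError("drift must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("bad ancestral frequency range")
        if self.snps_per_chromosome > self.chromosome_length_bp:
            raise ValueError("more SNPs than available positions")

    def drift_per_breed(self) -> list[float]:
        if np.isscalar(self.drift):
            return [float(self.drift)] * self.n_breeds
        if len(self.drift) != self.n_breeds:
            raise ValueError("drift list length != n_breeds")
        return [float(c) for c in self.drift]

    @property
    def n_samples(self) -> int:
        if self.admixture_design is not None:
            return int(np.asarray(self.admixture_design).shape[0])
        return self.n_breeds * self.samples_per_breed


@dataclass
class SimTruth:
    """Generator-side ground truth for recovery tests."""

    Q: np.ndarray                      # n x n_breeds true ancestry
    breed_frequencies: np.ndarray      # n_breeds x m
    ancestral_frequencies: np.ndarray  # m
    planted_segments: list[tuple[str, str, int, int]] = field(default_factory=list)
    realized_autozygosity: dict[str, float] = field(default_factory=dict)


def _breed_labels(n: int) -> list[str]:
    return [f"B{k+1:02d}" for k in range(n)]


def simulate_breed_panel(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Draw a full panel under the Balding-Nichols model (see module docs)."""
    rng = np.random.default_rng(cfg.seed)
    labels = _breed_labels(cfg.n_breeds)
    m_per = cfg.snps_per_chromosome
    m = m_per * cfg.n_chromosomes

    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=m)
    F = np.empty((cfg.n_breeds, m))
    for k, c in enumerate(cfg.drift_per_breed()):
        a = p * (1 - c) / c
        b = (1 - p) * (1 - c) / c
        F[k] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)

    if cfg.admixture_design is not None:
        Q = np.asarray(cfg.admixture_design, dtype=float)
        if Q.shape[1] != cfg.n_breeds:
            raise ValueError("admixture_design columns != n_breeds")
        if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("admixture_design rows must sum to 1")
        if cfg.sample_breed_labels is not None:
            if len(cfg.sample_breed_labels) != Q.shape[0]:
                raise ValueError("sample_breed_labels length != admixture_design rows")
            sample_breeds = list(cfg.sample_breed_labels)
        else:
            main = np.argmax(Q, axis=1)
            sample_breeds = [labels[k] for k in main]
    else:
        Q = np.repeat(np.eye(cfg.n_breeds), cfg.samples_per_breed, axis=0)
        sample_breeds = [b for b in labels for _ in range(cfg.samples_per_breed)]
    n = Q.shape[0]
    sample_ids = [f"{b}_{i:03d}" for i, b in enumerate(sample_breeds)]

    Pi = Q @ F
    calls = rng.binomial(2, Pi).astype(np.int8)

    loci_rows = []
    for c in range(cfg.n_chromosomes):
        pos = _unique_positions(rng, m_per, cfg.chromosome_length_bp)
        for j, bp in enumerate(pos):
            loci_rows.append((f"chr{c+1}_snp{j:04d}", str(c + 1), int(bp)))
    loci = pd.DataFrame(loci_rows, columns=["snp_id", "chromosome", "position_bp"])
    loci["allele1"] = "A"
    loci["allele2"] = "G"
    samples = pd.DataFrame({"sample_id": sample_ids, "breed": sample_breeds})
    ds = GenotypeDataset(samples, loci, calls)

    truth = SimTruth(Q=Q, breed_frequencies=F, ancestral_frequencies=p)

    if cfg.autozygosity_fraction > 0:
        ds, truth = plant_autozygosity(
            ds, truth, cfg.autozygosity_fraction, cfg.segment_length_range_bp,
            seed=int(rng.integers(2**31)),
            chromosome_length_bp=cfg.chromosome_length_bp,
        )
    if cfg.missing_rate > 0:
        ds = apply_missingness(ds, cfg.missing_rate, seed=int(rng.integers(2**31)))
    return ds, truth


def _unique_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=m))
    while pos.size < m:  # resample collisions (rare for m << length)
        extra = rng.integers(1, length + 1, size=m - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos)


def plant_autozygosity(
    ds: GenotypeDataset,
    truth: SimTruth,
    per_sample_fraction: float,
    segment_length_range_bp: tuple[int, int] = (2_000_000, 8_000_000),
    seed: int = 0,
    chromosome_length_bp: int | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Force non-overlapping intervals homozygous until the target coverage.

    Within each planted interval every genotype becomes 2*Bernoulli(pi_ij)
    — one allele drawn at the individual's mixed frequency and doubled —
    so planted runs carry realistic allele content but zero heterozygosity.
    """
    if per_sample_fraction == 0:
        return ds, truth
    rng = np.random.default_rng(seed)
    chroms = ds.chromosomes()
    pos = ds.loci["position_bp"].to_numpy()
    if chromosome_length_bp is None:
        chrom_len = {
            c: int(pos[ds.chromosome_slice(c).stop - 1]) for c in chroms
        }
    else:
        chrom_len = {c: int(chromosome_length_bp) for c in chroms}
    total = sum(chrom_len.values())
    target = per_sample_fraction * total
    lens = np.array([chrom_len[c] for c in chroms], dtype=float)
    chrom_prob = lens / lens.sum()

    Pi = truth.Q @ truth.breed_frequencies
    calls = ds.calls.copy()
    segments = list(truth.planted_segments)
    realized = dict(truth.realized_autozygosity)
    lo_len, hi_len = segment_length_range_bp

    for i, sid in enumerate(ds.sample_ids):
        placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        covered = 0
        attempts = 0
        if per_sample_fraction >= 0.999:  # full autozygosity: one run per chromosome
            for c in chroms:
                sl = ds.chromosome_slice(c)
                allele = rng.random(sl.stop - sl.start) < Pi[i, sl]
                calls[i, sl] = 2 * allele.astype(np.int8)
                segments.append((sid, c, 1, chrom_len[c]))
            realized[sid] = 1.0
            continue
        while covered < target:
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError(
                    "cannot place non-overlapping segments for the requested fraction"
                )
            c = chroms[rng.choice(len(chroms), p=chrom_prob)]
            seg_len = int(rng.integers(lo_len, hi_len + 1))
            # trim the final segment toward the exact target coverage
            seg_len = int(min(seg_len, max(lo_len, target - covered)))
            if seg_len >= chrom_len[c]:
                continue
            start = int(rng.integers(1, chrom_len[c] - seg_len + 1))
            end = start + seg_len
            if any(s < end and start < e for s, e in placed[c]):
                continue
            placed[c].append((start, end))
            sl = ds.chromosome_slice(c)
            cpos = pos[sl]
            a = sl.start + int(np.searchsorted(cpos, start, side="left"))
            b = sl.start + int(np.searchsorted(cpos, end, side="right"))
            if b > a:
                allele = rng.random(b - a) < Pi[i, a:b]
                calls[i, a:b] = 2 * allele.astype(np.int8)
            segments.append((sid, c, start, end))
            covered += seg_len
        realized[sid] = covered / total

    out = GenotypeDataset(ds.samples, ds.loci, calls)
    return out, SimTruth(
        Q=truth.Q,
        breed_frequencies=truth.breed_frequencies,
        ancestral_frequencies=truth.ancestral_frequencies,
        planted_segments=segments,
        realized_autozygosity=realized,
    )


def apply_missingness(ds: GenotypeDataset, rate: float, seed: int = 0) -> GenotypeDataset:
    """Independently blank each call with probability *rate*."""
    if not (0 <= rate < 1):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return ds
    rng = np.random.default_rng(seed)
    mask = rng.random(ds.calls.shape) < rate
    calls = np.where(mask, np.int8(MISSING), ds.calls)
    return GenotypeDataset(ds.samples, ds.loci, calls)


def write_fixture(
    ds: GenotypeDataset, truth: SimTruth, out_dir: str | Path,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write a PLINK-binary fixture plus ground-truth TSVs and a config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_genotypes(ds, out_dir / "panel", dialect="binary")
    paths = {
        "bed": out_dir / "panel.bed",
        "bim": out_dir / "panel.bim",
        "fam": out_dir / "panel.fam",
        "truth_Q": out_dir / "truth_Q.tsv",
        "truth_segments": out_dir / "truth_segments.tsv",
        "config": out_dir / "config.json",
    }
    qdf = pd.DataFrame(
        truth.Q, index=ds.sample_ids,
        columns=[f"Q{k+1}" for k in range(truth.Q.shape[1])],
    )
    qdf.to_csv(paths["truth_Q"], sep="\t", index_label="sample_id")
    pd.DataFrame(
        truth.planted_segments,
        columns=["sample_id", "chromosome", "start_bp", "end_bp"],
    ).to_csv(paths["truth_segments"], sep="\t", index=False)
    if config is not None:
        blob = asdict(config)
        if blob.get("admixture_design") is not None:
            blob["admixture_design"] = np.asarray(blob["admixture_design"]).tolist()
        paths["config"].write_text(json.dumps(blob, indent=2) + "\n")
    else:
        paths["config"].write_text("{}\n")
    return paths
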
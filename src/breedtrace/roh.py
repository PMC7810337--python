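"""Runs of homozygosity: consecutive-method detection, summaries, islands, F_ROH.

A run of homozygosity (ROH) is a stretch of consecutive homozygous SNP
calls in one individual, evidence that both chromosome copies descend from
a recent common ancestor.  Detection here uses the *consecutive* method: a
left-to-right scan in map order that extends the current run while its
allowances hold (heterozygous calls, missing calls, inter-marker gap) and
closes it on the first violation, with no sliding window.

Run allowances and thresholds live in :class:`RohParams`; the defaults
(>=15 SNPs, >=1 Mbp, one heterozygote allowed) are the standard settings
for 50k livestock arrays, where one stray heterozygote is more likely a
genotyping error than a true break.

Restart rule
------------
When a run closes because the next SNP would exceed the heterozygote (or
missing-call) allowance, the scan restarts at the SNP *after the first*
heterozygous (or missing) call inside the closed run, not after the
violator.  A long run that shares its tail with the closed one is therefore
still found, at the cost that reported runs of one sample may overlap; all
coverage-derived statistics (per-SNP frequency, islands, F_ROH) use the
per-sample coverage union, so they are unaffected by overlap.  The end of a
chromosome closes a run the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

#: ROH length classes in Mbp, as left-open/right-closed intervals.
LENGTH_CLASS_EDGES_MBP = (0.0, 2.0, 4.0, 8.0, 16.0, float("inf"))
LENGTH_CLASS_LABELS = ("0-2", "2-4", "4-8", "8-16", ">16")


@dataclass(frozen=True)
class RohParams:
    """Consecutive-method detection parameters.

    min_snp / min_length_bp filter the closed runs; max_het, max_miss and
    max_gap_bp are the in-run allowances.  ``max_gap_bp=None`` disables the
    gap constraint.
    """

    min_snp: int = 15
    min_length_bp: int = 1_000_000
    max_het: int = 1
    max_miss: int = 1
    max_gap_bp: int | None = 1_000_000

    def __post_init__(self):
        if self.min_snp < 2:
            raise ValueError("min_snp must be >= 2")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if self.max_het < 0 or self.max_miss < 0:
            raise ValueError("allowances must be non-negative")


@dataclass(frozen=True)
class RohSegment:
    """One detected run: its sample, chromosome, bp interval and SNP count.

    ``length_bp`` is the open difference end_bp - start_bp (the convention
    under which the 1 Mbp minimum-length filter is applied).
    """

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snp: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class RohIsland:
    """A region where >= *threshold* of a breed's samples carry overlapping ROH."""

    breed: str
    chromosome: str
    start_bp: int
    end_bp: int
    start_snp: str
    end_snp: str
    n_snp: int
    peak_frequency: float


@dataclass(frozen=True)
class FrohRecord:
    """Genomic inbreeding of one sample: ROH coverage over mapped autosome length."""

    sample_id: str
    froh_genome: float
    froh_by_chromosome: dict[str, float] = field(compare=False)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_roh_sample(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: RohParams = RohParams(),
    sample_id: str = "",
    chromosome: str = "",
) -> list[RohSegment]:
    """Consecutive-method scan of one sample's calls on one chromosome.

    *genotypes* are dosages in {0,1,2,MISSING}; *positions* the matching bp
    coordinates, strictly increasing.  Returns the runs passing the min_snp
    and min_length_bp filters; see the module docstring for the restart rule.
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    if g.shape != pos.shape:
        raise ValueError("genotypes and positions differ in length")
    n = g.size
    if n == 0:
        return []
    if n > 1 and not (np.diff(pos) > 0).all():
        raise ValueError("positions must be strictly increasing")

    het = g == 1
    miss = g == MISSING
    out: list[RohSegment] = []
    s = 0
    while s < n:
        hets = int(het[s])
        misses = int(miss[s])
        if hets > params.max_het or misses > params.max_miss:
            s += 1
            continue
        first_het = s if het[s] else -1
        first_miss = s if miss[s] else -1
        e = s
        reason = None
        while e + 1 < n:
            nxt = e + 1
            if (
                params.max_gap_bp is not None
                and pos[nxt] - pos[e] > params.max_gap_bp
            ):
                reason = "gap"
                break
            if het[nxt] and hets + 1 > params.max_het:
                reason = "het"
                break
            if miss[nxt] and misses + 1 > params.max_miss:
                reason = "miss"
                break
            e = nxt
            if het[e]:
                hets += 1
                if first_het < 0:
                    first_het = e
            elif miss[e]:
                misses += 1
                if first_miss < 0:
                    first_miss = e

        n_snp = e - s + 1
        if n_snp >= params.min_snp and pos[e] - pos[s] >= params.min_length_bp:
            out.append(
                RohSegment(sample_id, chromosome, int(pos[s]), int(pos[e]), n_snp)
            )

        if reason == "gap":
            s = e + 1
        elif reason == "het":
            s = first_het + 1 if first_het >= 0 else e + 2
        elif reason == "miss":
            s = first_miss + 1 if first_miss >= 0 else e + 2
        else:  # end of chromosome closes the run like a violation
            inside = [i for i in (first_het, first_miss) if i >= 0]
            if not inside:
                break
            s = min(inside) + 1
    return out


def detect_roh(ds: GenotypeDataset, params: RohParams = RohParams()) -> list[RohSegment]:
    """Scan every sample on every chromosome of a dataset."""
    out: list[RohSegment] = []
    for chrom in ds.chromosomes():
        sl = ds.chromosome_slice(chrom)
        pos = ds.loci["position_bp"].to_numpy()[sl]
        for i, sid in enumerate(ds.sample_ids):
            out.extend(
                detect_roh_sample(ds.calls[i, sl], pos, params, sid, chrom)
            )
    return out


# ---------------------------------------------------------------------------
# Length classes and summaries
# ---------------------------------------------------------------------------

def classify_roh_lengths(segments: list[RohSegment]) -> pd.Series:
    """Count segments per length class ((0,2], (2,4], (4,8], (8,16], (16,inf) Mbp)."""
    counts = pd.Series(0, index=list(LENGTH_CLASS_LABELS), dtype=int)
    for seg in segments:
        counts[length_class(seg.length_bp)] += 1
    return counts


def length_class(length_bp: int) -> str:
    mbp = length_bp / 1e6
    for hi, label in zip(LENGTH_CLASS_EDGES_MBP[1:], LENGTH_CLASS_LABELS):
        if mbp <= hi:
            return label
    return LENGTH_CLASS_LABELS[-1]  # pragma: no cover


def summarize_roh(
    segments: list[RohSegment], samples: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Descriptive ROH tables: per breed, per chromosome, per length class.

    Returns a dict of DataFrames:

    ``per_breed``           total / mean-per-sample ROH count and length per breed
    ``per_chromosome``      count and summed length per (breed, chromosome)
    ``class_by_breed``      per-breed distribution over length classes (rows sum to 1)
    ``breed_by_class``      per-class distribution over breeds (columns sum to 1)
    """
    breeds = samples.set_index("sample_id")["breed"]
    if (samples.groupby("breed").size() == 0).any():  # pragma: no cover
        raise ValueError("breed with zero samples")
    seg_df = segments_to_frame(segments)
    seg_df["breed"] = seg_df["sample_id"].map(breeds)
    if seg_df["breed"].isna().any():
        unknown = seg_df.loc[seg_df["breed"].isna(), "sample_id"].unique()
        raise ValueError(f"segments for unknown samples: {list(unknown)[:5]}")
    seg_df["length_bp"] = seg_df["end_bp"] - seg_df["start_bp"]
    seg_df["length_class"] = [length_class(x) for x in seg_df["length_bp"]]

    breed_sizes = breeds.groupby(breeds).size()
    per_breed = (
        seg_df.groupby("breed")
        .agg(n_roh=("sample_id", "size"), total_length_bp=("length_bp", "sum"))
        .reindex(breed_sizes.index, fill_value=0)
    )
    per_breed["n_samples"] = breed_sizes
    per_breed["mean_roh_per_sample"] = per_breed["n_roh"] / per_breed["n_samples"]

    per_chrom = (
        seg_df.groupby(["breed", "chromosome"])
        .agg(n_roh=("sample_id", "size"), total_length_bp=("length_bp", "sum"))
        .reset_index()
    )

    class_counts = (
        seg_df.groupby(["breed", "length_class"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(LENGTH_CLASS_LABELS), fill_value=0)
        .reindex(breed_sizes.index, fill_value=0)
    )
    row_tot = class_counts.sum(axis=1).replace(0, np.nan)
    col_tot = class_counts.sum(axis=0).replace(0, np.nan)
    class_by_breed = class_counts.div(row_tot, axis=0).fillna(0.0)
    breed_by_class = class_counts.div(col_tot, axis=1).fillna(0.0)

    return {
        "per_breed": per_breed.reset_index(),
        "per_chromosome": per_chrom,
        "class_by_breed": class_by_breed,
        "breed_by_class": breed_by_class,
    }


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.sample_id, s.chromosome, s.start_bp, s.end_bp, s.n_snp)
            for s in segments
        ],
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snp"],
    )


# ---------------------------------------------------------------------------
# Coverage, islands, inbreeding
# ---------------------------------------------------------------------------

def _coverage_mask(
    segments: list[RohSegment], ds: GenotypeDataset, sample_ids: list[str]
) -> np.ndarray:
    """Boolean (len(sample_ids), n_loci) mask: SNP inside any ROH of the sample."""
    row = {sid: i for i, sid in enumerate(sample_ids)}
    pos = ds.loci["position_bp"].to_numpy()
    mask = np.zeros((len(sample_ids), ds.n_loci), dtype=bool)
    chrom_slices = {c: ds.chromosome_slice(c) for c in ds.chromosomes()}
    for seg in segments:
        i = row.get(seg.sample_id)
        if i is None or seg.chromosome not in chrom_slices:
            continue
        sl = chrom_slices[seg.chromosome]
        cpos = pos[sl]
        lo = int(np.searchsorted(cpos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(cpos, seg.end_bp, side="right"))
        mask[i, sl.start + lo : sl.start + hi] = True
    return mask


def snp_roh_frequency(
    segments: list[RohSegment], ds: GenotypeDataset, breed: str
) -> np.ndarray:
    """Per-SNP fraction of the breed's samples whose ROH cover the SNP."""
    idx = ds.breed_index(breed)
    sids = [ds.sample_ids[i] for i in idx]
    mask = _coverage_mask(segments, ds, sids)
    return mask.mean(axis=0)


def detect_roh_islands(
    per_snp_frequency: np.ndarray,
    ds: GenotypeDataset,
    breed: str,
    threshold: float = 0.45,
) -> list[RohIsland]:
    """Maximal runs of consecutive SNPs with within-breed ROH frequency >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    freq = np.asarray(per_snp_frequency, dtype=float)
    if freq.shape != (ds.n_loci,):
        raise ValueError("frequency vector does not match the dataset loci")
    pos = ds.loci["position_bp"].to_numpy()
    snp_ids = ds.loci["snp_id"].to_numpy()
    out: list[RohIsland] = []
    for chrom in ds.chromosomes():
        sl = ds.chromosome_slice(chrom)
        hot = freq[sl] >= threshold
        if not hot.any():
            continue
        edges = np.diff(hot.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1))
        if hot[0]:
            starts.insert(0, 0)
        if hot[-1]:
            ends.append(hot.size - 1)
        for lo, hi in zip(starts, ends):
            a, b = sl.start + lo, sl.start + hi
            out.append(
                RohIsland(
                    breed=breed,
                    chromosome=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    start_snp=str(snp_ids[a]),
                    end_snp=str(snp_ids[b]),
                    n_snp=hi - lo + 1,
                    peak_frequency=float(freq[a : b + 1].max()),
                )
            )
    return out


def islands_to_frame(islands: list[RohIsland]) -> pd.DataFrame:
    """Island table with the conventional column order (start/end SNP, count, bp)."""
    return pd.DataFrame(
        [
            (i.breed, i.chromosome, i.start_snp, i.end_snp, i.n_snp,
             i.start_bp, i.end_bp, i.peak_frequency)
            for i in islands
        ],
        columns=["breed", "chromosome", "start_snp", "end_snp", "n_snp",
                 "start_bp", "end_bp", "peak_frequency"],
    )


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length (open-difference convention) covered by a union of intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    return total + (cur_hi - cur_lo)


def compute_froh(
    segments: list[RohSegment],
    ds: GenotypeDataset,
    chromosome_lengths: dict[str, int] | None = None,
) -> list[FrohRecord]:
    """Genomic inbreeding per sample: ROH coverage / total mapped autosome length.

    The denominator defaults to the SNP-covered map span (last minus first
    SNP bp) of each chromosome in the post-QC map; assembly chromosome
    lengths can be supplied instead.  Overlapping runs of a sample are
    unioned before summing, so values stay in [0, 1].
    """
    if ds.n_loci == 0:
        raise ValueError("empty SNP map")
    chroms = ds.chromosomes()
    pos = ds.loci["position_bp"].to_numpy()
    if chromosome_lengths is None:
        chrom_len = {}
        for c in chroms:
            sl = ds.chromosome_slice(c)
            chrom_len[c] = int(pos[sl.stop - 1] - pos[sl.start])
    else:
        chrom_len = {c: int(chromosome_lengths[c]) for c in chroms}
    total_len = sum(chrom_len.values())
    if total_len <= 0:
        raise ValueError("zero-length map")

    by_sample: dict[str, dict[str, list[tuple[int, int]]]] = {
        sid: {} for sid in ds.sample_ids
    }
    for seg in segments:
        by_sample[seg.sample_id].setdefault(seg.chromosome, []).append(
            (seg.start_bp, seg.end_bp)
        )

    out = []
    for sid in ds.sample_ids:
        per_chrom = {}
        covered = 0
        for c in chroms:
            cov = _union_length(by_sample[sid].get(c, []))
            per_chrom[c] = cov / chrom_len[c] if chrom_len[c] > 0 else 0.0
            covered += cov
        out.append(FrohRecord(sid, covered / total_len, per_chrom))
    return out


# ---------------------------------------------------------------------------
# PCA on per-chromosome ROH profiles
# ---------------------------------------------------------------------------

def roh_profile_pca(profile: pd.DataFrame):
    """PCA (column-centered SVD) of a breeds x chromosomes mean-ROH-count matrix.

    Returns ``(scores, loadings, explained_variance)``; scores is a
    DataFrame indexed like *profile*.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 breeds")
    X = profile.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    score_df = pd.DataFrame(
        scores, index=profile.index,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )
    return score_df, vt.T, explained


def roh_count_profile(
    segments: list[RohSegment], ds: GenotypeDataset
) -> pd.DataFrame:
    """Breeds x chromosomes matrix of mean ROH count per sample."""
    seg_df = segments_to_frame(segments)
    breeds = ds.samples.set_index("sample_id")["breed"]
    seg_df["breed"] = seg_df["sample_id"].map(breeds)
    sizes = breeds.groupby(breeds).size()
    counts = (
        seg_df.groupby(["breed", "chromosome"]).size().unstack(fill_value=0)
        .reindex(index=sizes.index, columns=ds.chromosomes(), fill_value=0)
    )
    return counts.div(sizes, axis=0)


def export_roh_tables(
    segments: list[RohSegment],
    ds: GenotypeDataset,
    out_dir: str | Path,
    params: RohParams = RohParams(),
    island_threshold: float = 0.45,
) -> dict[str, Path]:
    """Write the ROH tables (segments, summaries, islands, F_ROH) as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    seg_df = segments_to_frame(segments)
    seg_df["length_bp"] = seg_df["end_bp"] - seg_df["start_bp"]
    paths["segments"] = out_dir / "roh_segments.tsv"
    seg_df.to_csv(paths["segments"], sep="\t", index=False)

    tables = summarize_roh(segments, ds.samples)
    for name in ("per_breed", "per_chromosome", "class_by_breed", "breed_by_class"):
        p = out_dir / f"roh_{name}.tsv"
        tables[name].to_csv(p, sep="\t", index=name.endswith("class") or "_by_" in name)
        paths[name] = p

    islands = []
    freq_rows = []
    for breed in dict.fromkeys(ds.breeds):
        freq = snp_roh_frequency(segments, ds, breed)
        freq_rows.append(pd.Series(freq, index=ds.loci["snp_id"], name=breed))
        islands.extend(detect_roh_islands(freq, ds, breed, island_threshold))
    paths["snp_frequency"] = out_dir / "roh_snp_frequency.tsv"
    pd.DataFrame(freq_rows).T.to_csv(paths["snp_frequency"], sep="\t")
    paths["islands"] = out_dir / "roh_islands.tsv"
    islands_to_frame(islands).to_csv(paths["islands"], sep="\t", index=False)

    froh = compute_froh(segments, ds)
    froh_df = pd.DataFrame(
        [(r.sample_id, r.froh_genome) for r in froh],
        columns=["sample_id", "froh_genome"],
    )
    froh_df["breed"] = froh_df["sample_id"].map(ds.samples.set_index("sample_id")["breed"])
    paths["froh"] = out_dir / "froh.tsv"
    froh_df.to_csv(paths["froh"], sep="\t", index=False)
    return paths
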
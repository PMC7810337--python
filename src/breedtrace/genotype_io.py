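"""Reading, writing, merging and quality-filtering SNP-array genotype panels.

Genotypes travel through the pipeline as a :class:`GenotypeDataset`: a
samples x loci matrix of counted-allele dosages in {0, 1, 2} with a single
missing sentinel (:data:`MISSING`), plus a SNP map and per-sample breed
labels (stored in the PLINK family-ID field, as livestock panels
conventionally do).

Dosage convention
-----------------
A call is the count of allele-1 (the .bim A1 allele) carried by the sample.
When reading PLINK *text* files, where no A1/A2 assignment exists, allele-1
is taken as the minor allele at each SNP; ties are broken in favour of the
allele observed first in file order.  The convention is fixed and
round-trips exactly through both dialects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (text "0 0", binary code 01).
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK code -> dosage of allele-1.  00=hom A1, 01=missing, 10=het, 11=hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 3, 1: 2, 2: 0, MISSING: 1}

#: Goat autosome labels (Capra hircus has 29 autosome pairs).
GOAT_AUTOSOMES = frozenset(str(c) for c in range(1, 30))


@dataclass(frozen=True)
class SnpLocus:
    """One mapped SNP: identifier, chromosome label, bp position, allele pair."""

    snp_id: str
    chromosome: str
    position_bp: int
    alleles: tuple[str, str]  # (allele1 = counted, allele2)


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual with its breed label (PLINK family ID)."""

    sample_id: str
    breed: str


class GenotypeIOError(Exception):
    """Malformed or inconsistent genotype files / datasets."""


class GenotypeDataset:
    """Sample x SNP diploid dosage matrix with map and breed labels.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id`` and ``breed``.
    loci
        DataFrame with columns ``snp_id``, ``chromosome``, ``position_bp``,
        ``allele1``, ``allele2``.  Re-sorted by (chromosome, position) on
        construction; numeric chromosome labels sort numerically.
    calls
        int8 array of shape (n_samples, n_loci) holding values in
        {0, 1, 2, MISSING}.
    """

    def __init__(self, samples: pd.DataFrame, loci: pd.DataFrame, calls: np.ndarray):
        samples = samples.reset_index(drop=True)
        loci = loci.reset_index(drop=True)
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(loci)):
            raise GenotypeIOError(
                f"calls shape {calls.shape} != ({len(samples)}, {len(loci)})"
            )
        bad = ~np.isin(calls, [0, 1, 2, MISSING])
        if bad.any():
            raise GenotypeIOError("calls contain values outside {0,1,2,missing}")
        if samples["sample_id"].duplicated().any():
            dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"]
            raise GenotypeIOError(f"duplicate sample ids: {sorted(set(dups))}")
        if loci["snp_id"].duplicated().any():
            dups = loci.loc[loci["snp_id"].duplicated(), "snp_id"]
            raise GenotypeIOError(f"duplicate SNP ids: {sorted(set(dups))[:5]}")
        if (loci["position_bp"] < 0).any():
            raise GenotypeIOError("negative bp position in map")

        order = _map_sort_order(loci)
        self.loci = loci.iloc[order].reset_index(drop=True)
        self.samples = samples
        self.calls = np.ascontiguousarray(calls[:, order])

        for _, grp in self.loci.groupby("chromosome", sort=False):
            pos = grp["position_bp"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                dup = grp.loc[grp["position_bp"].duplicated(), "snp_id"]
                raise GenotypeIOError(
                    f"duplicate bp positions within a chromosome: {list(dup)[:5]}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    @property
    def breeds(self) -> list[str]:
        return self.samples["breed"].tolist()

    def breed_index(self, breed: str) -> np.ndarray:
        """Row indices of the samples belonging to *breed*."""
        idx = np.flatnonzero(self.samples["breed"].to_numpy() == breed)
        if idx.size == 0:
            raise KeyError(f"no samples with breed {breed!r}")
        return idx

    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.loci["chromosome"]))

    def chromosome_slice(self, chromosome: str) -> slice:
        """Contiguous locus slice of one chromosome (map is sorted)."""
        mask = (self.loci["chromosome"] == chromosome).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"no loci on chromosome {chromosome!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeDataset":
        """New dataset restricted to the given sample/locus integer indices."""
        si = (np.arange(self.n_samples) if sample_idx is None
              else np.asarray(sample_idx, dtype=np.intp))
        li = (np.arange(self.n_loci) if locus_idx is None
              else np.asarray(locus_idx, dtype=np.intp))
        return GenotypeDataset(
            self.samples.iloc[si], self.loci.iloc[li], self.calls[np.ix_(si, li)]
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples.equals(other.samples)
            and self.loci.equals(other.loci)
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeDataset({self.n_samples} samples x {self.n_loci} SNPs, "
            f"{len(set(self.breeds))} breeds)"
        )


def _map_sort_order(loci: pd.DataFrame) -> np.ndarray:
    """Stable sort order by (chromosome, position); numeric chromosomes first."""

    def chrom_key(label: str):
        s = str(label)
        return (0, int(s)) if s.isdigit() else (1, 0)

    keys = [(chrom_key(c), str(c), int(p)) for c, p in
            zip(loci["chromosome"], loci["position_bp"])]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=np.intp)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path_prefix: str | Path, dialect: str = "binary") -> GenotypeDataset:
    """Load a PLINK fileset (``text`` = .ped/.map, ``binary`` = .bed/.bim/.fam)."""
    prefix = Path(path_prefix)
    if dialect == "text":
        return _read_text(prefix)
    if dialect == "binary":
        return _read_binary(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(ds: GenotypeDataset, path_prefix: str | Path,
                    dialect: str = "binary") -> list[Path]:
    """Write *ds* as a PLINK fileset; returns the paths written."""
    if ds.n_samples == 0 or ds.n_loci == 0:
        raise GenotypeIOError("refusing to write an empty dataset")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "text":
        return _write_text(ds, prefix)
    if dialect == "binary":
        return _write_binary(ds, prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _require(path: Path) -> Path:
    if not path.exists():
        raise GenotypeIOError(f"missing companion file: {path}")
    return path


def _read_map_like(path: Path, n_cols: int) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != n_cols:
            raise GenotypeIOError(f"{path}:{ln}: expected {n_cols} columns")
        rows.append(parts)
    if not rows:
        raise GenotypeIOError(f"{path}: empty map")
    return pd.DataFrame(rows)


def _read_text(prefix: Path) -> GenotypeDataset:
    map_path = _require(prefix.with_suffix(".map"))
    ped_path = _require(prefix.with_suffix(".ped"))

    raw_map = _read_map_like(map_path, 4)
    m = len(raw_map)

    sample_rows: list[tuple[str, str]] = []
    allele_cols: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise GenotypeIOError(
                f"{ped_path}:{ln}: ragged row ({len(parts)} fields, "
                f"expected {6 + 2 * m})"
            )
        sample_rows.append((parts[1], parts[0]))  # (sample_id=IID, breed=FID)
        allele_cols.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
        )
    if not sample_rows:
        raise GenotypeIOError(f"{ped_path}: no samples")

    n = len(sample_rows)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in allele_cols[i][j]:
                if a != "0":
                    counts.setdefault(a, 0)
                    counts[a] += 1
        if len(counts) > 2:
            raise GenotypeIOError(
                f"SNP {raw_map.iloc[j, 1]}: more than two alleles {sorted(counts)}"
            )
        order = list(counts)  # first-seen order
        # counted allele = minor; ties keep first-seen order (stable sort)
        order.sort(key=lambda a: counts[a])
        a1 = order[0] if order else "0"
        a2 = order[1] if len(order) > 1 else "0"
        a1_list.append(a1)
        a2_list.append(a2)
        for i in range(n):
            x, y = allele_cols[i][j]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == a1) + (y == a1)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "breed"])
    loci = pd.DataFrame(
        {
            "snp_id": raw_map[1],
            "chromosome": raw_map[0].astype(str),
            "position_bp": raw_map[3].astype(np.int64),
            "allele1": a1_list,
            "allele2": a2_list,
        }
    )
    return GenotypeDataset(samples, loci, calls)


def _read_binary(prefix: Path) -> GenotypeDataset:
    bed_path = _require(prefix.with_suffix(".bed"))
    bim_path = _require(prefix.with_suffix(".bim"))
    fam_path = _require(prefix.with_suffix(".fam"))

    raw_bim = _read_map_like(bim_path, 6)
    raw_fam = _read_map_like(fam_path, 6)
    n, m = len(raw_fam), len(raw_bim)

    blob = bed_path.read_bytes()
    if blob[:3] != _BED_MAGIC:
        raise GenotypeIOError(f"{bed_path}: not a v1.00 SNP-major bed")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(blob) != expected:
        raise GenotypeIOError(
            f"{bed_path}: size {len(blob)} != expected {expected} for "
            f"{n} samples x {m} SNPs"
        )
    payload = np.frombuffer(blob, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # expand each byte into four 2-bit codes, low bits first
    codes = (payload[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    calls = _CODE_TO_DOSAGE[codes].T  # (n, m)

    samples = pd.DataFrame(
        {"sample_id": raw_fam[1], "breed": raw_fam[0]}
    )
    loci = pd.DataFrame(
        {
            "snp_id": raw_bim[1],
            "chromosome": raw_bim[0].astype(str),
            "position_bp": raw_bim[3].astype(np.int64),
            "allele1": raw_bim[4],
            "allele2": raw_bim[5],
        }
    )
    return GenotypeDataset(samples, loci, calls)


def _write_text(ds: GenotypeDataset, prefix: Path) -> list[Path]:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with map_path.open("w") as fh:
        for row in ds.loci.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")
    a1 = ds.loci["allele1"].to_numpy()
    a2 = ds.loci["allele2"].to_numpy()
    with ped_path.open("w") as fh:
        for i, srow in enumerate(ds.samples.itertuples(index=False)):
            fields = [srow.breed, srow.sample_id, "0", "0", "0", "-9"]
            row = ds.calls[i]
            for j in range(ds.n_loci):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a2[j], a2[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a1[j], a1[j]]
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


def _write_binary(ds: GenotypeDataset, prefix: Path) -> list[Path]:
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with bim_path.open("w") as fh:
        for row in ds.loci.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}"
                f"\t{row.allele1}\t{row.allele2}\n"
            )
    with fam_path.open("w") as fh:
        for row in ds.samples.itertuples(index=False):
            fh.write(f"{row.breed}\t{row.sample_id}\t0\t0\t0\t-9\n")

    n, m = ds.n_samples, ds.n_loci
    bytes_per_snp = (n + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        code_lut[d % 4] = c  # MISSING=-1 -> index 3
    codes = code_lut[ds.calls.T % 4].astype(np.uint8)  # (m, n)
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with bed_path.open("wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    return [bed_path, bim_path, fam_path]


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def merge_datasets(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    """Union of samples over the intersection of SNPs (matched by snp_id).

    Allele orientation is reconciled: when *b* counted the opposite allele
    of the same pair, its dosages are flipped (d -> 2-d).  Any other allele
    mismatch — including strand-ambiguous A/T and C/G pairs that a
    complement flip could "rescue" — is an error rather than a guess.
    """
    clash = set(a.sample_ids) & set(b.sample_ids)
    if clash:
        raise GenotypeIOError(f"sample id collision: {sorted(clash)[:5]}")

    ai = {s: j for j, s in enumerate(a.loci["snp_id"])}
    bi = {s: j for j, s in enumerate(b.loci["snp_id"])}
    shared = [s for s in a.loci["snp_id"] if s in bi]
    if not shared:
        raise GenotypeIOError("no SNPs in common")

    ja = np.array([ai[s] for s in shared])
    jb = np.array([bi[s] for s in shared])
    la = a.loci.iloc[ja].reset_index(drop=True)
    lb = b.loci.iloc[jb].reset_index(drop=True)

    if not (la["chromosome"].to_numpy() == lb["chromosome"].to_numpy()).all() or not (
        la["position_bp"].to_numpy() == lb["position_bp"].to_numpy()
    ).all():
        bad = la.loc[
            (la["chromosome"].to_numpy() != lb["chromosome"].to_numpy())
            | (la["position_bp"].to_numpy() != lb["position_bp"].to_numpy()),
            "snp_id",
        ]
        raise GenotypeIOError(f"inconsistent map between inputs: {list(bad)[:5]}")

    calls_b = b.calls[:, jb].copy()
    for k in range(len(shared)):
        pa = (la.at[k, "allele1"], la.at[k, "allele2"])
        pb = (lb.at[k, "allele1"], lb.at[k, "allele2"])
        ua = tuple(x for x in pa if x != "0")
        ub = tuple(x for x in pb if x != "0")
        if set(ub) <= set(ua) and pb[0] in (pa[0], "0"):
            continue  # same orientation (possibly fewer observed alleles)
        if set(ub) <= set(ua) and pb[0] == pa[1]:
            col = calls_b[:, k]
            flip = col != MISSING
            col[flip] = 2 - col[flip]
            continue
        raise GenotypeIOError(
            f"SNP {shared[k]}: alleles {pb} cannot be reconciled with {pa}"
        )

    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    calls = np.vstack([a.calls[:, ja], calls_b])
    return GenotypeDataset(samples, la, calls)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Counts removed at each quality-control step, in application order."""

    n_samples_in: int
    n_loci_in: int
    non_autosomal_removed: int
    low_call_rate_snps_removed: int
    high_missing_samples_removed: int
    n_samples_out: int
    n_loci_out: int
    snp_call_rate_min: float
    sample_missing_max: float
    filter_order: tuple[str, ...] = ("autosomes", "snp_call_rate", "sample_missing")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["metric\tvalue"] + [
            f"{k}\t{','.join(v) if isinstance(v, tuple) else v}"
            for k, v in self.__dict__.items()
        ]
        text = "\n".join(str(x) for x in lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


class QcError(Exception):
    """A QC step removed every SNP or every sample."""


def apply_qc(
    ds: GenotypeDataset,
    snp_call_rate_min: float = 0.95,
    sample_missing_max: float = 0.10,
    autosomes: frozenset[str] | set[str] = GOAT_AUTOSOMES,
    order: tuple[str, ...] = ("autosomes", "snp_call_rate", "sample_missing"),
) -> tuple[GenotypeDataset, QcReport]:
    """Quality-filter a dataset.

    Default thresholds follow common SNP-array practice: keep autosomal SNPs
    with call rate strictly above 95% and samples with missingness strictly
    below 10%, applied in that order.  The order is configurable because the
    SNP call rate changes if high-missingness samples are dropped first.
    """
    if not (0 < snp_call_rate_min <= 1) or not (0 < sample_missing_max <= 1):
        raise ValueError("thresholds must lie in (0, 1]")

    out = ds
    removed = {"autosomes": 0, "snp_call_rate": 0, "sample_missing": 0}
    for step in order:
        if step == "autosomes":
            keep = np.array(
                [str(c) in autosomes for c in out.loci["chromosome"]], dtype=bool
            )
            removed[step] = int((~keep).sum())
            if not keep.any():
                raise QcError("autosome filter removed every SNP")
            out = out.subset(locus_idx=np.flatnonzero(keep))
        elif step == "snp_call_rate":
            call_rate = (out.calls != MISSING).mean(axis=0)
            keep = call_rate > snp_call_rate_min
            removed[step] = int((~keep).sum())
            if not keep.any():
                raise QcError("SNP call-rate filter removed every SNP")
            out = out.subset(locus_idx=np.flatnonzero(keep))
        elif step == "sample_missing":
            missing = (out.calls == MISSING).mean(axis=1)
            keep = missing < sample_missing_max
            removed[step] = int((~keep).sum())
            if not keep.any():
                raise QcError("sample-missingness filter removed every sample")
            out = out.subset(sample_idx=np.flatnonzero(keep))
        else:
            raise ValueError(f"unknown QC step {step!r}")

    report = QcReport(
        n_samples_in=ds.n_samples,
        n_loci_in=ds.n_loci,
        non_autosomal_removed=removed["autosomes"],
        low_call_rate_snps_removed=removed["snp_call_rate"],
        high_missing_samples_removed=removed["sample_missing"],
        n_samples_out=out.n_samples,
        n_loci_out=out.n_loci,
        snp_call_rate_min=snp_call_rate_min,
        sample_missing_max=sample_missing_max,
        filter_order=tuple(order),
    )
    return out, report
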
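"""Configuration-driven orchestration: QC -> ROH -> structure -> DAPC.

A single :class:`PipelineConfig` (usually loaded from YAML) drives the full
workflow and every artifact lands under the output directory in
stage-named subfolders, with a manifest recording input hashes, seeds,
stage wall-times and a checksum for every emitted file.  Any stage failure
aborts with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dapc as dapc_mod
from . import roh as roh_mod
from . import structure as structure_mod
from .genotype_io import GOAT_AUTOSOMES, GenotypeDataset, apply_qc, read_genotypes
from .roh import RohParams

log = logging.getLogger("breedtrace")


@dataclass
class PipelineConfig:
    """Validated study configuration; echoed verbatim into the output dir."""

    input_prefix: str
    input_dialect: str = "binary"
    output_dir: str = "out"
    seed: int = 0

    # QC
    snp_call_rate_min: float = 0.95
    sample_missing_max: float = 0.10
    autosomes: list[str] = field(default_factory=lambda: sorted(GOAT_AUTOSOMES, key=int))

    # ROH
    roh_min_snp: int = 15
    roh_min_length_bp: int = 1_000_000
    roh_max_het: int = 1
    roh_max_miss: int = 1
    roh_max_gap_bp: int | None = 1_000_000
    roh_island_threshold: float = 0.45

    # structure
    k_min: int = 2
    k_max: int = 10
    k_cv_folds: int = 10
    admixture_restarts: int = 3

    # DAPC
    dapc_target_breed: str | None = None
    dapc_folds: int = 10
    dapc_repetitions: int = 30
    dapc_max_pc: int = 259
    dapc_grid: list[int] | None = None
    dapc_holdout_n: int = 5
    dapc_scenario_repetitions: int = 10
    dapc_train_fractions: list[float] = field(
        default_factory=lambda: [round(x, 2) for x in np.arange(0.2, 0.91, 0.1)]
    )
    run_scenarios: list[int] = field(default_factory=lambda: [1, 2, 3])

    def __post_init__(self):
        if not (0 < self.snp_call_rate_min <= 1 and 0 < self.sample_missing_max <= 1):
            raise ValueError("QC thresholds must lie in (0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("bad K range")
        if self.roh_min_snp < 2:
            raise ValueError("roh_min_snp must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**blob)

    def roh_params(self) -> RohParams:
        return RohParams(
            min_snp=self.roh_min_snp,
            min_length_bp=self.roh_min_length_bp,
            max_het=self.roh_max_het,
            max_miss=self.roh_max_miss,
            max_gap_bp=self.roh_max_gap_bp,
        )


class StageError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2) + "\n")
    manifest: dict = {"seed": cfg.seed, "stages": [], "files": {}}
    emitted: list[Path] = [out / "config.json"]
    rng = np.random.default_rng(cfg.seed)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc
            manifest["stages"].append(
                {"name": name, "wall_time_s": round(time.perf_counter() - t0, 3)}
            )
            log.info("stage %s: done", name)
            return result

        return deco

    # ----- QC ---------------------------------------------------------
    @stage("qc")
    def _qc():
        ds_raw = read_genotypes(cfg.input_prefix, dialect=cfg.input_dialect)
        for ext in (".bed", ".bim", ".fam", ".ped", ".map"):
            p = Path(cfg.input_prefix).with_suffix(ext)
            if p.exists():
                manifest["files"].setdefault("inputs", {})[p.name] = _sha256(p)
        ds_qc, report = apply_qc(
            ds_raw,
            snp_call_rate_min=cfg.snp_call_rate_min,
            sample_missing_max=cfg.sample_missing_max,
            autosomes=set(cfg.autosomes),
        )
        qdir = out / "qc"
        qdir.mkdir(exist_ok=True)
        report.to_json(qdir / "qc_report.json")
        report.to_tsv(qdir / "qc_report.tsv")
        emitted.extend([qdir / "qc_report.json", qdir / "qc_report.tsv"])
        return ds_qc

    ds: GenotypeDataset = _qc

    # ----- ROH --------------------------------------------------------
    @stage("roh")
    def _roh():
        segments = roh_mod.detect_roh(ds, cfg.roh_params())
        paths = roh_mod.export_roh_tables(
            segments, ds, out / "roh", cfg.roh_params(), cfg.roh_island_threshold
        )
        profile = roh_mod.roh_count_profile(segments, ds)
        if len(profile) >= 2:
            scores, _, explained = roh_mod.roh_profile_pca(profile)
            p = out / "roh" / "roh_profile_pca.tsv"
            scores.assign().to_csv(p, sep="\t")
            (out / "roh" / "roh_profile_pca_variance.tsv").write_text(
                "component\texplained_fraction\n"
                + "\n".join(f"PC{i+1}\t{v:.6f}" for i, v in enumerate(explained))
                + "\n"
            )
            emitted.extend([p, out / "roh" / "roh_profile_pca_variance.tsv"])
        emitted.extend(paths.values())
        return segments

    _roh  # noqa: B018 - executed above

    # ----- structure --------------------------------------------------
    @stage("structure")
    def _structure():
        sdir = out / "structure"
        sdir.mkdir(exist_ok=True)
        X, _, _ = structure_mod.standardize_genotypes(ds)
        pca = structure_mod.genotype_pca(X, n_components=10)
        pca_df = pd.DataFrame(
            pca.scores, index=ds.sample_ids,
            columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
        )
        pca_df.insert(0, "breed", ds.breeds)
        pca_df.to_csv(sdir / "genotype_pca.tsv", sep="\t", index_label="sample_id")
        emitted.append(sdir / "genotype_pca.tsv")

        report = structure_mod.select_k_cv(
            ds.calls, K_range=range(cfg.k_min, cfg.k_max + 1),
            folds=cfg.k_cv_folds, seed=int(rng.integers(2**31)),
        )
        emitted.append(structure_mod.write_k_selection(report, sdir / "k_selection.tsv"))
        fit = structure_mod.admixture_fit(
            ds.calls, report.selected_K, seed=int(rng.integers(2**31)),
            n_restarts=cfg.admixture_restarts,
        )
        paths = structure_mod.write_admixture_outputs(fit, ds, sdir)
        emitted.extend(paths.values())
        return report.selected_K

    _structure

    # ----- DAPC -------------------------------------------------------
    @stage("dapc")
    def _dapc():
        ddir = out / "dapc"
        ddir.mkdir(exist_ok=True)
        common = dict(max_pc=cfg.dapc_max_pc, grid=cfg.dapc_grid)
        if 1 in cfg.run_scenarios:
            rep = dapc_mod.scenario_supervised(
                ds, folds=cfg.dapc_folds, repetitions=cfg.dapc_repetitions,
                seed=int(rng.integers(2**31)), **common,
            )
            rep.success_by_n_pc.to_csv(ddir / "scenario1_cv.tsv", sep="\t", index=False)
            rep.per_breed_success.to_frame("success").to_csv(
                ddir / "scenario1_per_breed.tsv", sep="\t"
            )
            rep.extras["discriminant_scores"].to_csv(
                ddir / "scenario1_discriminant_scores.tsv", sep="\t",
                index_label="sample_id",
            )
            emitted.extend(
                ddir / f for f in (
                    "scenario1_cv.tsv", "scenario1_per_breed.tsv",
                    "scenario1_discriminant_scores.tsv",
                )
            )
        target = cfg.dapc_target_breed
        if target is not None and 2 in cfg.run_scenarios:
            table = dapc_mod.scenario_semisupervised(
                ds, target, holdout_n=cfg.dapc_holdout_n,
                repetitions=cfg.dapc_scenario_repetitions,
                seed=int(rng.integers(2**31)),
                cv_folds=cfg.dapc_folds, cv_repetitions=cfg.dapc_repetitions,
                **common,
            )
            table.to_csv(ddir / "scenario2_assignment.tsv", sep="\t")
            emitted.append(ddir / "scenario2_assignment.tsv")
        if target is not None and 3 in cfg.run_scenarios:
            table = dapc_mod.scenario_unsupervised(
                ds, target, train_fractions=tuple(cfg.dapc_train_fractions),
                repetitions=cfg.dapc_scenario_repetitions,
                seed=int(rng.integers(2**31)),
                cv_folds=cfg.dapc_folds, cv_repetitions=cfg.dapc_repetitions,
                **common,
            )
            table.to_csv(ddir / "scenario3_assignment.tsv", sep="\t")
            emitted.append(ddir / "scenario3_assignment.tsv")

    _dapc

    manifest["files"]["outputs"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(emitted))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def export_reports(bundle_dir: str | Path, formats: tuple[str, ...] = ("tsv",)) -> list[Path]:
    """List (and validate) the exported report files of a pipeline run."""
    bundle_dir = Path(bundle_dir)
    known = {"tsv", "json"}
    bad = set(formats) - known
    if bad:
        raise ValueError(f"unknown formats: {sorted(bad)}")
    out = []
    for fmt in formats:
        out.extend(sorted(bundle_dir.rglob(f"*.{fmt}")))
    return out
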
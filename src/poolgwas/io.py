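"""TSV schemas, configuration and the end-to-end pipeline driver.

All files are UTF-8, tab-separated with a header row; missing values use the
token ``NA``; genomic coordinates are 1-based and inclusive; floats are
written with six significant digits.  Schemas:

* intensity: ``probe_id  chrom  pos  A:<pool>  B:<pool> ...``
* pool manifest: ``pool_id  group  sex  member_ids``
* genotypes: ``sample_id  phenotype  sex  <snp_id> ...`` with 0/1/2/NA codes
* count tables: one row per SNP with the six genotype-count cells
* scan / blocks / verification report / stepwise trace / power grid: tidy
  one-row-per-record frames mirroring the in-memory results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import GenotypeCountTable, VerificationStudy
from .blocks import blocks_to_frame, find_blocks, select_index_snps
from .power import power_grid
from .risk import ForwardAICLogit
from .scan import PoolIntensityMatrix, PooledAlleleScan
from .simulate import (
    MISSING,
    GenotypeDataset,
    PlantedLocus,
    PoolAssignment,
    SimConfig,
    simulate_study,
)

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_intensity_tsv",
    "write_intensity_tsv",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_count_tables",
    "write_count_tables",
    "write_pool_manifest",
    "read_pool_manifest",
    "write_frame",
    "run_pipeline",
]

log = logging.getLogger("poolgwas")

FLOAT_FMT = "%.6g"
NA = "NA"


class SchemaError(ValueError):
    """A malformed file, reported with its row location."""


def write_frame(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=NA)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# -- intensities -------------------------------------------------------------

def write_intensity_tsv(m: PoolIntensityMatrix, path: Path | str) -> None:
    df = m.probes[["probe_id", "chrom", "pos"]].copy()
    for i, pool_id in enumerate(m.pools["pool_id"]):
        df[f"A:{pool_id}"] = m.A[i]
        df[f"B:{pool_id}"] = m.B[i]
    write_frame(df, path)


def read_intensity_tsv(path: Path | str, manifest: pd.DataFrame) -> PoolIntensityMatrix:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["probe_id", "chrom", "pos"], path)
    pool_ids = list(manifest["pool_id"])
    a_cols = [f"A:{p}" for p in pool_ids]
    b_cols = [f"B:{p}" for p in pool_ids]
    for col in a_cols + b_cols:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing signal column {col!r}")
    A = df[a_cols].to_numpy(dtype=float).T
    B = df[b_cols].to_numpy(dtype=float).T
    return PoolIntensityMatrix(
        pools=manifest[["pool_id", "group", "sex"]].reset_index(drop=True),
        probes=df[["probe_id", "chrom", "pos"]].copy(),
        A=A,
        B=B,
    )


# -- pool manifest -----------------------------------------------------------

def write_pool_manifest(pools: PoolAssignment, path: Path | str) -> None:
    write_frame(pools.manifest, path)


def read_pool_manifest(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["pool_id", "group", "sex"], path)
    bad = ~df["group"].isin(["case", "control"])
    if bad.any():
        row = int(df.index[bad][0]) + 2  # 1-based incl. header
        raise SchemaError(f"{path}: row {row}: group must be 'case' or 'control'")
    return df


# -- genotypes ---------------------------------------------------------------

def write_genotype_tsv(ds: GenotypeDataset, path: Path | str) -> None:
    out = ds.samples[["sample_id", "phenotype", "sex"]].copy()
    g = ds.genotypes.astype(object)
    g[ds.genotypes == MISSING] = NA
    geno = pd.DataFrame(g, columns=ds.snps["snp_id"], index=out.index)
    write_frame(pd.concat([out, geno], axis=1), path)


def read_genotype_tsv(path: Path | str, snp_meta: pd.DataFrame | None = None) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    _require_columns(df, ["sample_id", "phenotype", "sex"], path)
    snp_cols = [c for c in df.columns if c not in ("sample_id", "phenotype", "sex")]
    if not snp_cols:
        raise SchemaError(f"{path}: no genotype columns present")
    bad_ph = ~df["phenotype"].isin(["case", "control"])
    if bad_ph.any():
        row = int(df.index[bad_ph][0]) + 2
        raise SchemaError(f"{path}: row {row}: phenotype must be 'case' or 'control'")
    raw = df[snp_cols].to_numpy(dtype=float)
    genotypes = np.where(np.isnan(raw), MISSING, raw)
    invalid = ~np.isin(genotypes, (-1, 0, 1, 2))
    if invalid.any():
        r, c = np.argwhere(invalid)[0]
        raise SchemaError(
            f"{path}: row {int(r) + 2}, column {snp_cols[int(c)]!r}: "
            f"genotype code {raw[r, c]:g} not in 0/1/2/NA"
        )
    if snp_meta is None:
        snp_meta = pd.DataFrame(
            {"snp_id": snp_cols, "chrom": NA, "pos": 1,
             "allele_a": "A", "allele_b": "B"}
        )
    return GenotypeDataset(
        samples=df[["sample_id", "phenotype", "sex"]].copy(),
        snps=snp_meta,
        genotypes=genotypes.astype(np.int8),
    )


# -- count tables ------------------------------------------------------------

_COUNT_COLS = ["case_mm", "case_mM", "case_MM", "ctrl_mm", "ctrl_mM", "ctrl_MM"]


def write_count_tables(tables: list[GenotypeCountTable], path: Path | str) -> None:
    rows = [
        {
            "snp_id": t.snp_id,
            "region": t.region,
            "minor_allele": t.minor_allele,
            "major_allele": t.major_allele,
            **{c: getattr(t, c) for c in _COUNT_COLS},
        }
        for t in tables
    ]
    write_frame(pd.DataFrame(rows), path)


def read_count_tables(path: Path | str) -> list[GenotypeCountTable]:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["snp_id", *_COUNT_COLS], path)
    tables = []
    for i, r in df.iterrows():
        try:
            tables.append(
                GenotypeCountTable(
                    snp_id=str(r["snp_id"]),
                    minor_allele=str(r.get("minor_allele", "m")),
                    major_allele=str(r.get("major_allele", "M")),
                    region=str(r.get("region", "")),
                    **{c: int(r[c]) for c in _COUNT_COLS},
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {int(i) + 2}: {exc}") from exc
    return tables


# -- pipeline ----------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds, stage toggles and paths for an end-to-end run."""

    seed: int = 0
    sim: SimConfig | None = None
    p_block: float = 5e-3
    max_gap: int = 30_000
    p_index: float = 1e-4
    min_block_size: int = 7
    min_below_index: int = 1
    mad_threshold: float = 6.0
    alpha_adj: float = 0.05
    p_screen: float = 0.05
    run_model: bool = True
    run_power: bool = True
    n_cases_power: int = 432
    n_controls_power: int = 672

    def __post_init__(self) -> None:
        for name in ("p_block", "max_gap", "p_index", "min_block_size",
                     "alpha_adj", "mad_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            loci = [PlantedLocus(**d) for d in sim_raw.pop("planted_loci", [])]
            for key in ("case_pool_sexes", "control_pool_sexes"):
                if key in sim_raw and isinstance(sim_raw[key], str):
                    sim_raw[key] = list(sim_raw[key])
            cfg.sim = SimConfig(planted_loci=loci, seed=cfg.seed, **sim_raw)
        return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"[stage {name}] {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig, outdir: Path | str) -> dict:
    """simulate -> scan -> select -> verify -> model -> power, with artefacts.

    Returns a manifest dict (also written as ``run_manifest.json``) recording
    the package version, seed, thresholds and per-stage outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.sim or SimConfig(seed=cfg.seed)

    ds, pools, intens, truth = _stage("simulate")(simulate_study)(sim_cfg)
    write_genotype_tsv(ds, outdir / "genotypes.tsv")
    write_pool_manifest(pools, outdir / "pool_manifest.tsv")
    write_intensity_tsv(intens, outdir / "intensities.tsv")
    write_frame(truth, outdir / "truth.tsv")

    scan_res = _stage("scan")(lambda: PooledAlleleScan(intens, cfg.mad_threshold).fit())()
    write_frame(scan_res.table, outdir / "scan.tsv")
    write_frame(scan_res.qc.table, outdir / "scan_qc.tsv")
    write_frame(scan_res.qq_table(), outdir / "qq.tsv")

    blocks = _stage("select")(find_blocks)(scan_res, cfg.p_block, cfg.max_gap)
    selected = select_index_snps(
        blocks, cfg.p_index, cfg.min_block_size, cfg.min_below_index
    )
    write_frame(blocks_to_frame(selected, cfg.p_index), outdir / "blocks.tsv")
    index_ids = [b.index_snp for b in selected if b.index_snp]

    manifest = {
        "package": "poolgwas",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            k: getattr(cfg, k)
            for k in ("p_block", "max_gap", "p_index", "min_block_size",
                      "min_below_index", "mad_threshold", "alpha_adj")
        },
        "lambda": scan_res.lambda_gc,
        "pools_flagged": scan_res.qc.flagged,
        "n_blocks_selected": len(selected),
        "index_snps": index_ids,
    }

    if index_ids:
        cols = [list(ds.snps["snp_id"]).index(s) for s in index_ids]
        verify = _stage("verify")(
            lambda: VerificationStudy.from_genotypes(
                ds.genotypes[:, cols], ds.is_case, index_ids, alpha=cfg.alpha_adj
            ).fit()
        )()
        write_frame(verify.frame, outdir / "verification.tsv")
        manifest["significant_snps"] = verify.significant

        if cfg.run_model:
            model = _stage("model")(
                lambda: ForwardAICLogit(
                    ds.is_case.astype(float),
                    ds.genotypes[:, cols].astype(float),
                    index_ids,
                    p_screen=cfg.p_screen,
                ).fit()
            )()
            write_frame(model.trace, outdir / "stepwise_trace.tsv")
            manifest["final_auc"] = model.final_auc
            manifest["final_snps"] = model.final_snps

    if cfg.run_power:
        grid = _stage("power")(power_grid)(cfg.n_cases_power, cfg.n_controls_power)
        write_frame(grid, outdir / "power_grid.tsv")

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
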
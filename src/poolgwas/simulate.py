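"""Synthetic case-control genotype and pooled-intensity generator.

Emulates the data-generating process a pooled-DNA association scan assumes:
individual genotypes drawn under Hardy-Weinberg equilibrium, a per-allele
(multiplicative on the odds scale) disease model at planted risk loci,
haplotype-copy LD blocks around each planted index SNP, equimolar pooling of
``pool_size`` samples per pool, and two-channel array intensities with
multiplicative noise on each channel.

The default design mirrors a two-stage colorectal-cancer study: 18 case pools
(7 female, 11 male) and 28 control pools (15 female, 13 male) of 24 samples
each, i.e. 432 cases and 672 controls at the scan stage.

Under the per-allele model with odds ratio ``OR`` and control minor-allele
frequency ``p0``, the case-group allele frequency is

    p1 = OR * p0 / (1 + p0 * (OR - 1))

and case genotypes remain Hardy-Weinberg at ``p1`` (the multiplicative
genotype weights factorise over the two allele draws), so the population
allelic odds ratio equals ``OR`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import sort_by_position

__all__ = [
    "SimConfigError",
    "PlantedLocus",
    "SimConfig",
    "GenotypeDataset",
    "PoolAssignment",
    "simulate_genotypes",
    "simulate_ld_block",
    "pool_genotypes",
    "intensities_from_frequencies",
    "simulate_study",
]

#: sentinel for a missing genotype in the int8 matrix
MISSING = np.int8(-1)


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def case_frequency(p0: float, odds_ratio: float) -> float:
    """Case-group allele frequency implied by a per-allele odds ratio."""
    return odds_ratio * p0 / (1.0 + p0 * (odds_ratio - 1.0))


@dataclass(frozen=True)
class PlantedLocus:
    """A risk locus planted in the synthetic genome.

    The locus is an LD block of ``block_n_snps`` SNPs spread over
    ``block_span_bp`` around the index SNP at ``pos``.  Neighbour alleles are
    copied from the index haplotype and flipped independently per haplotype
    with probability ``flip_prob``; for two SNPs both at frequency 0.5 this
    yields allelic r^2 = (1 - 2*flip_prob)^2.
    """

    chrom: str
    pos: int
    maf: float
    odds_ratio: float
    block_n_snps: int = 11
    block_span_bp: int = 20_000
    flip_prob: float = 0.05
    name: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise SimConfigError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.odds_ratio <= 0:
            raise SimConfigError("odds_ratio must be positive")
        if self.block_n_snps < 1:
            raise SimConfigError("block_n_snps must be >= 1")
        if self.block_span_bp < 0:
            raise SimConfigError("block_span_bp must be >= 0")
        if not 0.0 <= self.flip_prob <= 0.5:
            raise SimConfigError("flip_prob must be in [0, 0.5]")
        if self.pos < 1:
            raise SimConfigError("pos is 1-based and must be >= 1")

    @property
    def index_id(self) -> str:
        return self.name or f"locus_{self.chrom}_{self.pos}"


def _default_case_pool_sexes() -> list[str]:
    return ["F"] * 7 + ["M"] * 11


def _default_control_pool_sexes() -> list[str]:
    return ["F"] * 15 + ["M"] * 13


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study.

    ``case_pool_sexes`` / ``control_pool_sexes`` list one sex label per pool;
    sample counts default to (number of pools) * ``pool_size``.  Set the sex
    lists to ``None`` for an un-pooled design (individual-level stages only),
    in which case ``n_cases`` / ``n_controls`` must be given explicitly.
    """

    n_cases: int | None = None
    n_controls: int | None = None
    pool_size: int = 24
    case_pool_sexes: list[str] | None = field(default_factory=_default_case_pool_sexes)
    control_pool_sexes: list[str] | None = field(default_factory=_default_control_pool_sexes)
    n_null_snps: int = 1000
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    null_snp_spacing_bp: int = 5_000
    intensity_cv: float = 0.02
    gain_mean: float = 1000.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise SimConfigError("pool_size must be >= 1")
        if self.intensity_cv < 0:
            raise SimConfigError("intensity_cv must be >= 0")
        if self.gain_mean <= 0:
            raise SimConfigError("gain_mean must be positive")
        if self.n_null_snps < 0:
            raise SimConfigError("n_null_snps must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimConfigError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for group, sexes, n in (
            ("case", self.case_pool_sexes, self.n_cases),
            ("control", self.control_pool_sexes, self.n_controls),
        ):
            if sexes is None:
                if n is None:
                    raise SimConfigError(
                        f"n_{group}s must be given when {group}_pool_sexes is None"
                    )
            elif n is not None and n != len(sexes) * self.pool_size:
                raise SimConfigError(
                    f"n_{group}s={n} inconsistent with {len(sexes)} pools of "
                    f"{self.pool_size}"
                )

    @property
    def n_cases_effective(self) -> int:
        if self.case_pool_sexes is not None:
            return len(self.case_pool_sexes) * self.pool_size
        assert self.n_cases is not None
        return self.n_cases

    @property
    def n_controls_effective(self) -> int:
        if self.control_pool_sexes is not None:
            return len(self.control_pool_sexes) * self.pool_size
        assert self.n_controls is not None
        return self.n_controls


@dataclass
class GenotypeDataset:
    """Individual-level genotypes with phenotype and SNP metadata.

    ``genotypes`` is an int8 matrix of minor-allele counts (samples x SNPs)
    with ``-1`` marking a missing call; ``samples`` carries ``sample_id``,
    ``phenotype`` ("case"/"control") and ``sex``; ``snps`` carries ``snp_id``,
    ``chrom``, ``pos``, ``allele_a`` (minor), ``allele_b`` (major).
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.snps):
            raise SimConfigError("genotype matrix shape inconsistent with metadata")
        valid = np.isin(self.genotypes, (-1, 0, 1, 2))
        if not valid.all():
            raise SimConfigError("genotype values must be in {0, 1, 2} or -1 (NA)")

    @property
    def is_case(self) -> np.ndarray:
        return (self.samples["phenotype"] == "case").to_numpy()

    def genotypes_float(self) -> np.ndarray:
        """Genotypes as float with NaN for missing calls."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        return g


@dataclass
class PoolAssignment:
    """Pool composition and the exact per-pool minor-allele frequencies."""

    manifest: pd.DataFrame  # pool_id, group, sex, member_ids
    frequencies: np.ndarray  # pools x SNPs, in [0, 1]
    snps: pd.DataFrame


def simulate_ld_block(
    index_haplotypes: np.ndarray,
    locus: PlantedLocus,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Genotype columns for the neighbours of a planted index SNP.

    ``index_haplotypes`` is a boolean (n_samples, 2) array of minor-allele
    indicators on each haplotype.  Each neighbour copies the index haplotype
    and flips every allele independently with probability ``locus.flip_prob``.
    Returns an int8 (n_samples, block_n_snps - 1) genotype matrix.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h = np.asarray(index_haplotypes, dtype=bool)
    if h.ndim != 2 or h.shape[1] != 2:
        raise SimConfigError("index_haplotypes must have shape (n, 2)")
    n_neigh = locus.block_n_snps - 1
    out = np.empty((h.shape[0], n_neigh), dtype=np.int8)
    for j in range(n_neigh):
        flips = rng.random(h.shape) < locus.flip_prob
        out[:, j] = (h ^ flips).sum(axis=1)
    return out


def _sample_haplotypes(rng: np.random.Generator, n: int, freq: float) -> np.ndarray:
    return rng.random((n, 2)) < freq


def _block_positions(locus: PlantedLocus) -> list[int]:
    """Index at ``pos``; neighbours spread evenly over the block span."""
    if locus.block_n_snps == 1:
        return [locus.pos]
    step = max(1, locus.block_span_bp // (locus.block_n_snps - 1))
    start = max(1, locus.pos - locus.block_span_bp // 2)
    positions = [start + k * step for k in range(locus.block_n_snps)]
    # place the index at the central slot, keeping its stated coordinate
    positions[locus.block_n_snps // 2] = locus.pos
    return sorted(set(positions))


def simulate_genotypes(cfg: SimConfig) -> GenotypeDataset:
    """Draw the individual-level study: null SNPs, planted LD blocks, labels.

    Null SNPs share one HWE frequency between groups (drawn uniformly from
    ``cfg.maf_range``); planted loci use the per-allele disease model.  Output
    SNPs are sorted by (chrom, pos).  Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ca = cfg.n_cases_effective
    n_co = cfg.n_controls_effective
    n = n_ca + n_co

    sexes: list[str] = []
    for group_sexes, count in (
        (cfg.case_pool_sexes, n_ca),
        (cfg.control_pool_sexes, n_co),
    ):
        if group_sexes is None:
            sexes.extend(rng.choice(["F", "M"], size=count).tolist())
        else:
            for s in group_sexes:
                sexes.extend([s] * cfg.pool_size)
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:05d}" for i in range(n)],
            "phenotype": ["case"] * n_ca + ["control"] * n_co,
            "sex": sexes,
        }
    )

    snp_rows: list[tuple[str, str, int, int]] = []  # snp_id, chrom, pos, col
    cols: list[np.ndarray] = []

    for locus in cfg.planted_loci:
        p1 = case_frequency(locus.maf, locus.odds_ratio)
        h = np.empty((n, 2), dtype=bool)
        h[:n_ca] = _sample_haplotypes(rng, n_ca, p1)
        h[n_ca:] = _sample_haplotypes(rng, n_co, locus.maf)
        positions = _block_positions(locus)
        index_slot = positions.index(locus.pos)
        neighbours = simulate_ld_block(h, locus, rng) if locus.block_n_snps > 1 else None
        k = 0
        for slot, pos in enumerate(positions):
            if slot == index_slot:
                snp_id = locus.index_id
                col = h.sum(axis=1).astype(np.int8)
            else:
                snp_id = f"{locus.index_id}_nb{k}"
                assert neighbours is not None
                col = neighbours[:, k]
                k += 1
            snp_rows.append((snp_id, locus.chrom, pos, len(cols)))
            cols.append(col)

    n_planted = len(cols)
    if cfg.n_null_snps:
        mafs = rng.uniform(*cfg.maf_range, size=cfg.n_null_snps)
        # draw in column chunks to keep the int64 intermediate small
        g_null = np.empty((n, cfg.n_null_snps), dtype=np.int8)
        chunk = 20_000
        for start in range(0, cfg.n_null_snps, chunk):
            stop = min(start + chunk, cfg.n_null_snps)
            g_null[:, start:stop] = rng.binomial(2, mafs[start:stop], size=(n, stop - start))
        chroms = [f"chr{c}" for c in range(1, 23)]
        used = {locus.chrom for locus in cfg.planted_loci}
        free = [c for c in chroms if c not in used] or chroms
        per_chrom = math.ceil(cfg.n_null_snps / len(free))
        for j in range(cfg.n_null_snps):
            chrom = free[j // per_chrom]
            pos = (j % per_chrom + 1) * cfg.null_snp_spacing_bp
            snp_rows.append((f"null{j:06d}", chrom, pos, n_planted + j))
    else:
        g_null = None

    if not snp_rows:
        raise SimConfigError("configuration defines no SNPs")

    planted = np.column_stack(cols).astype(np.int8) if cols else np.empty((n, 0), np.int8)
    full = planted if g_null is None else np.concatenate([planted, g_null], axis=1)
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos", "_col"])
    order = sort_by_position(snps)
    genotypes = full[:, order["_col"].to_numpy()]
    snps = order.drop(columns="_col")
    snps["allele_a"] = "A"
    snps["allele_b"] = "B"

    if cfg.missing_rate > 0:
        mask = rng.random(genotypes.shape) < cfg.missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = MISSING

    return GenotypeDataset(samples=samples, snps=snps, genotypes=genotypes)


def pool_genotypes(ds: GenotypeDataset, cfg: SimConfig) -> PoolAssignment:
    """Partition samples into equimolar pools and tally exact frequencies.

    Samples are grouped by (phenotype, sex) and filled into the configured
    pools in order.  The pool frequency of SNP j is the pool's minor-allele
    count over ``2 * pool_size`` (complete calls only when missingness was
    injected).
    """
    if cfg.case_pool_sexes is None or cfg.control_pool_sexes is None:
        raise SimConfigError("pooling requires pool sex layouts in the config")
    has_missing = bool((ds.genotypes == MISSING).any())
    g = ds.genotypes_float() if has_missing else ds.genotypes
    rows = []
    freqs = []
    for group, pool_sexes in (
        ("case", cfg.case_pool_sexes),
        ("control", cfg.control_pool_sexes),
    ):
        by_sex: dict[str, list[int]] = {}
        members = ds.samples.index[ds.samples["phenotype"] == group]
        for i in members:
            by_sex.setdefault(ds.samples.at[i, "sex"], []).append(i)
        needed: dict[str, int] = {}
        for s in pool_sexes:
            needed[s] = needed.get(s, 0) + cfg.pool_size
        for s, cnt in needed.items():
            if len(by_sex.get(s, [])) != cnt:
                raise SimConfigError(
                    f"{group} group has {len(by_sex.get(s, []))} samples of sex "
                    f"{s!r} but the pool layout needs {cnt}"
                )
        cursor = {s: 0 for s in needed}
        for k, s in enumerate(pool_sexes):
            idx = by_sex[s][cursor[s] : cursor[s] + cfg.pool_size]
            cursor[s] += cfg.pool_size
            sub = g[idx]
            if has_missing:
                with np.errstate(invalid="ignore"):
                    f = np.nansum(sub, axis=0) / (2.0 * np.sum(~np.isnan(sub), axis=0))
            else:
                f = sub.sum(axis=0, dtype=np.int64) / (2.0 * cfg.pool_size)
            freqs.append(f)
            prefix = "CRC" if group == "case" else "CTL"
            rows.append(
                {
                    "pool_id": f"{prefix}_{s}{k + 1:02d}",
                    "group": group,
                    "sex": s,
                    "member_ids": ",".join(ds.samples.loc[idx, "sample_id"]),
                }
            )
    return PoolAssignment(
        manifest=pd.DataFrame(rows),
        frequencies=np.vstack(freqs),
        snps=ds.snps.copy(),
    )


def intensities_from_frequencies(
    pools: PoolAssignment,
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
):
    """Two-channel array signals from true pool allele frequencies.

    Channel A carries the minor allele: ``A = gain * f * (1 + eA)`` and
    ``B = gain * (1 - f) * (1 + eB)`` with independent Gaussian relative
    errors of standard deviation ``cfg.intensity_cv``, truncated at zero.
    With ``intensity_cv = 0`` the relative allele signal A/(A+B) recovers
    ``f`` exactly.
    """
    from .scan import PoolIntensityMatrix  # deferred: avoid import cycle

    if seed is None:
        seed = cfg.seed + 1  # decouple from the genotype stream
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.asarray(pools.frequencies, dtype=float)
    if np.nanmin(f) < 0 or np.nanmax(f) > 1:
        raise SimConfigError("pool frequencies must lie in [0, 1]")
    gain = cfg.gain_mean
    noise_a = 1.0 + rng.normal(0.0, cfg.intensity_cv, f.shape) if cfg.intensity_cv else 1.0
    noise_b = 1.0 + rng.normal(0.0, cfg.intensity_cv, f.shape) if cfg.intensity_cv else 1.0
    A = np.clip(gain * f * noise_a, 0.0, None)
    B = np.clip(gain * (1.0 - f) * noise_b, 0.0, None)
    probes = pools.snps.rename(columns={"snp_id": "probe_id"}).copy()
    return PoolIntensityMatrix(
        pools=pools.manifest[["pool_id", "group", "sex"]].copy(),
        probes=probes,
        A=A,
        B=B,
    )


def simulate_study(cfg: SimConfig):
    """Generate the full study: genotypes, pools, intensities, truth table.

    Returns ``(dataset, pools, intensities, truth)`` where ``truth`` lists
    every planted locus with its parameters and index SNP id.
    """
    ds = simulate_genotypes(cfg)
    pools = pool_genotypes(ds, cfg)
    intens = intensities_from_frequencies(pools, cfg)
    truth = pd.DataFrame(
        [
            {
                "snp_id": loc.index_id,
                "chrom": loc.chrom,
                "pos": loc.pos,
                "maf": loc.maf,
                "odds_ratio": loc.odds_ratio,
                "block_n_snps": loc.block_n_snps,
                "block_span_bp": loc.block_span_bp,
                "flip_prob": loc.flip_prob,
            }
            for loc in cfg.planted_loci
        ],
        columns=[
            "snp_id", "chrom", "pos", "maf", "odds_ratio",
            "block_n_snps", "block_span_bp", "flip_prob",
        ],
    )
    return ds, pools, intens, truth
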
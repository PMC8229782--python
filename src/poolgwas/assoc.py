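"""Case-control association statistics on per-SNP genotype count tables.

This is the individual-genotyping verification stage: each SNP is summarised
as a 2 groups x 3 genotypes table of counts (mm / mM / MM, m = minor allele),
from which the module computes

* a Hardy-Weinberg goodness-of-fit p-value (chi-square, 1 df, or an exact
  conditional test), applied to controls by default;
* the allelic association: Pearson chi-square on the 2x2 allele table
  without continuity correction, and the allelic odds ratio with a Wald
  (normal-approximation) 95% CI, minor allele as exposure and the major
  allele as reference;
* the genotypic association: Cochran-Armitage trend test with scores
  (0, 1, 2), replaced by an exact conditional 2x3 Fisher test whenever any
  genotype cell is below five in either group;
* per-genotype odds ratios against the major-allele homozygote;
* Benjamini-Hochberg adjustment, applied separately to the allelic and the
  genotypic families.

``VerificationStudy`` is the model object; ``fit()`` returns
``VerificationResults`` with a per-SNP report frame and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeCountTable",
    "AllelicTest",
    "TrendTest",
    "OddsRatio",
    "hwe_test",
    "allelic_test",
    "trend_test",
    "fisher_test_2x3",
    "choose_genotype_test",
    "bh_adjust",
    "genotypic_ors",
    "tables_from_genotypes",
    "VerificationStudy",
    "VerificationResults",
    "verify_snps",
]

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype counts for one SNP in a case-control study (m = minor)."""

    snp_id: str
    case_mm: int
    case_mM: int
    case_MM: int
    ctrl_mm: int
    ctrl_mM: int
    ctrl_MM: int
    minor_allele: str = "m"
    major_allele: str = "M"
    region: str = ""

    def __post_init__(self) -> None:
        counts = (self.case_mm, self.case_mM, self.case_MM,
                  self.ctrl_mm, self.ctrl_mM, self.ctrl_MM)
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError(f"{self.snp_id}: counts must be non-negative integers")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError(f"{self.snp_id}: each group needs at least one subject")

    @property
    def n_cases(self) -> int:
        return self.case_mm + self.case_mM + self.case_MM

    @property
    def n_controls(self) -> int:
        return self.ctrl_mm + self.ctrl_mM + self.ctrl_MM

    # 2x2 allele table: a/b = control minor/major, c/d = case minor/major
    @property
    def allele_counts(self) -> tuple[int, int, int, int]:
        a = 2 * self.ctrl_mm + self.ctrl_mM
        b = 2 * self.ctrl_MM + self.ctrl_mM
        c = 2 * self.case_mm + self.case_mM
        d = 2 * self.case_MM + self.case_mM
        return a, b, c, d

    @property
    def maf_controls(self) -> float:
        a, b, _, _ = self.allele_counts
        return a / (a + b)

    @property
    def maf_cases(self) -> float:
        _, _, c, d = self.allele_counts
        return c / (c + d)

    def case_genotypes(self) -> tuple[int, int, int]:
        return self.case_mm, self.case_mM, self.case_MM

    def control_genotypes(self) -> tuple[int, int, int]:
        return self.ctrl_mm, self.ctrl_mM, self.ctrl_MM

    def swapped(self) -> "GenotypeCountTable":
        """The same SNP with case and control labels exchanged."""
        return GenotypeCountTable(
            snp_id=self.snp_id,
            case_mm=self.ctrl_mm, case_mM=self.ctrl_mM, case_MM=self.ctrl_MM,
            ctrl_mm=self.case_mm, ctrl_mM=self.case_mM, ctrl_MM=self.case_MM,
            minor_allele=self.minor_allele, major_allele=self.major_allele,
            region=self.region,
        )


class AllelicTest(NamedTuple):
    chi2: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied for a zero cell


class TrendTest(NamedTuple):
    z: float
    p: float


class OddsRatio(NamedTuple):
    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool


def hwe_test(mm: int, mM: int, MM: int, method: str = "chi2") -> float:
    """Hardy-Weinberg goodness-of-fit p-value for one genotype sample.

    ``chi2``: 1-df chi-square against expectations at the sample allele
    frequency.  ``exact``: conditional exact test summing the probabilities
    of heterozygote counts no more likely than the observed one, given the
    minor-allele total.  Monomorphic samples return p = 1 with a warning.
    """
    n = mm + mM + MM
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    n_minor = 2 * mm + mM
    if n_minor == 0 or n_minor == 2 * n:
        warnings.warn("monomorphic SNP; HWE p set to 1", RuntimeWarning)
        return 1.0
    if method == "chi2":
        p = n_minor / (2 * n)
        expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        observed = np.array([mm, mM, MM], dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, 1))
    if method == "exact":
        # P(het = h | n, n_minor) enumerated over all feasible h of obs parity
        lf = gammaln(np.arange(2 * n + 2))

        def log_prob(h: int) -> float:
            hom_m = (n_minor - h) // 2
            hom_M = n - hom_m - h
            return (
                lf[n + 1] - lf[hom_m + 1] - lf[h + 1] - lf[hom_M + 1]
                + h * np.log(2.0)
                + lf[n_minor + 1] + lf[2 * n - n_minor + 1] - lf[2 * n + 1]
            )

        hs = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
        logps = np.array([log_prob(int(h)) for h in hs])
        probs = np.exp(logps - logps.max())
        probs /= probs.sum()
        obs = probs[hs == mM][0]
        return float(probs[probs <= obs * (1 + 1e-12)].sum())
    raise ValueError(f"unknown HWE method: {method!r}")


def _wald_or(c_exp: float, c_ref: float, k_exp: float, k_ref: float,
             zero_cell: str = "haldane") -> tuple[float, float, float, bool]:
    """Wald odds ratio and 95% CI for exposure counts case/control."""
    cells = np.array([c_exp, c_ref, k_exp, k_ref], dtype=float)
    corrected = False
    if (cells == 0).any():
        if zero_cell == "haldane":
            warnings.warn("zero cell; Haldane-Anscombe +0.5 applied", RuntimeWarning)
            cells = cells + 0.5
            corrected = True
        else:
            return float("nan"), float("nan"), float("nan"), False
    c_exp, c_ref, k_exp, k_ref = cells
    or_ = (c_exp / c_ref) / (k_exp / k_ref)
    se = np.sqrt(1 / c_exp + 1 / c_ref + 1 / k_exp + 1 / k_ref)
    log_or = np.log(or_)
    return (
        float(or_),
        float(np.exp(log_or - Z_95 * se)),
        float(np.exp(log_or + Z_95 * se)),
        corrected,
    )


def allelic_test(table: GenotypeCountTable, zero_cell: str = "haldane") -> AllelicTest:
    """Pearson allele-table chi-square (no continuity correction) + Wald OR.

    The odds ratio takes the minor allele as the exposure with the major
    (more frequent) allele as reference: OR = (c/d) / (a/b) with c, d the
    case minor/major allele counts and a, b the control counts.
    """
    a, b, c, d = table.allele_counts
    obs = np.array([[c, d], [a, b]], dtype=float)
    if obs.sum(axis=0).min() > 0 and obs.sum(axis=1).min() > 0:
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    else:
        chi2, p = 0.0, 1.0
    or_, lo, hi, corrected = _wald_or(c, d, a, b, zero_cell=zero_cell)
    return AllelicTest(float(chi2), float(p), or_, lo, hi, corrected)


def trend_test(table: GenotypeCountTable) -> TrendTest:
    """Cochran-Armitage trend test with scores (0, 1, 2), two-sided.

    Positive z means the case proportion rises with the minor-allele dose.
    Degenerate margins (no spread in genotype totals or in case status)
    return p = 1 with a warning.
    """
    scores = np.array([0.0, 1.0, 2.0])
    r = np.array([table.case_MM, table.case_mM, table.case_mm], dtype=float)
    k = np.array([table.ctrl_MM, table.ctrl_mM, table.ctrl_mm], dtype=float)
    n = r + k
    N = n.sum()
    R = r.sum()
    var = R / N * (1 - R / N) * ((n * scores**2).sum() - (n * scores).sum() ** 2 / N)
    if var <= 0:
        warnings.warn("degenerate margins; trend p set to 1", RuntimeWarning)
        return TrendTest(0.0, 1.0)
    num = (scores * r).sum() - R / N * (scores * n).sum()
    z = float(num / np.sqrt(var))
    return TrendTest(z, float(2 * stats.norm.sf(abs(z))))


def fisher_test_2x3(table: GenotypeCountTable, max_tables: int = 5_000_000) -> float:
    """Exact conditional p for a 2x3 genotype table (probability ordering).

    Enumerates every table with the observed margins and sums the hypergeometric
    probabilities of those no more probable than the observed table.
    """
    row1 = np.array(table.case_genotypes(), dtype=int)
    row2 = np.array(table.control_genotypes(), dtype=int)
    r1, r2 = int(row1.sum()), int(row2.sum())
    cols = row1 + row2
    N = r1 + r2
    a_range = range(max(0, r1 - cols[1] - cols[2]), min(r1, cols[0]) + 1)
    n_tables = len(a_range) * (min(r1, cols[1]) + 1)
    if n_tables > max_tables:
        raise ValueError(
            f"{table.snp_id}: {n_tables} candidate tables exceed the enumeration "
            "limit; use the trend test for dense tables"
        )
    lf = gammaln(np.arange(N + 1) + 1.0)
    const = lf[r1] + lf[r2] + lf[cols].sum() - lf[N]

    def log_prob(a: int, b: int, c: int) -> float:
        return const - (lf[a] + lf[b] + lf[c] + lf[cols[0] - a] + lf[cols[1] - b] + lf[cols[2] - c])

    obs = log_prob(*row1)
    total = 0.0
    for a in a_range:
        b_lo = max(0, r1 - a - cols[2])
        b_hi = min(r1 - a, cols[1])
        for b in range(b_lo, b_hi + 1):
            lp = log_prob(a, b, r1 - a - b)
            if lp <= obs + 1e-7:
                total += float(np.exp(lp))
    return min(total, 1.0)


def choose_genotype_test(table: GenotypeCountTable, min_cell: int = 5) -> str:
    """``"fisher"`` when any genotype cell is below ``min_cell`` in either
    group (sparse homozygote counts), otherwise ``"trend"``."""
    cells = (*table.case_genotypes(), *table.control_genotypes())
    return "fisher" if any(c < min_cell for c in cells) else "trend"


def bh_adjust(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    finite = ~np.isnan(p)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def _genotype_label(allele_pair: str, table: GenotypeCountTable) -> str:
    mapping = {
        "mm": table.minor_allele * 2,
        "mM": table.minor_allele + table.major_allele,
        "MM": table.major_allele * 2,
    }
    return mapping[allele_pair]


def genotypic_ors(
    table: GenotypeCountTable, zero_cell: str = "haldane", method: str = "wald"
) -> list[OddsRatio]:
    """Odds ratios of the minor-homozygote and heterozygote rows against the
    major-allele homozygote reference.

    ``method="wald"`` uses the normal approximation (with optional +0.5 for
    zero cells); ``method="midp"`` returns the conditional median-unbiased
    estimate with a mid-p interval, better behaved for sparse cells.
    """
    out = []
    for lab, c_exp, k_exp in (
        ("mm", table.case_mm, table.ctrl_mm),
        ("mM", table.case_mM, table.ctrl_mM),
    ):
        if method == "wald":
            or_, lo, hi, corr = _wald_or(
                c_exp, table.case_MM, k_exp, table.ctrl_MM, zero_cell=zero_cell
            )
        elif method == "midp":
            or_, lo, hi = _midp_or(c_exp, table.case_MM, k_exp, table.ctrl_MM)
            corr = False
        else:
            raise ValueError(f"unknown OR method: {method!r}")
        out.append(OddsRatio(_genotype_label(lab, table), or_, lo, hi, corr))
    return out


def _midp_or(c_exp: int, c_ref: int, k_exp: int, k_ref: int,
             conf: float = 0.95) -> tuple[float, float, float]:
    """Conditional median-unbiased OR with mid-p CI (noncentral hypergeometric)."""
    from scipy.optimize import brentq

    x = int(c_exp)
    m1 = c_exp + c_ref          # cases (draws)
    n1 = c_exp + k_exp          # exposed column total
    N = c_exp + c_ref + k_exp + k_ref

    def cdf_parts(log_psi: float) -> tuple[float, float]:
        dist = stats.nchypergeom_fisher(N, n1, m1, np.exp(log_psi))
        lower = float(dist.cdf(x - 1)) if x > 0 else 0.0
        return lower, float(dist.pmf(x))

    def solve(target: float, upper_tail: bool) -> float:
        def f(log_psi: float) -> float:
            lower, px = cdf_parts(log_psi)
            if upper_tail:
                return (1.0 - lower - px) + 0.5 * px - target
            return lower + 0.5 * px - target

        lo, hi = -30.0, 30.0
        if f(lo) * f(hi) > 0:
            return float("inf") if upper_tail else 0.0
        return float(np.exp(brentq(f, lo, hi, xtol=1e-10)))

    alpha = 1.0 - conf
    estimate = solve(0.5, upper_tail=False)
    ci_low = solve(alpha / 2, upper_tail=True)
    ci_high = solve(alpha / 2, upper_tail=False)
    return estimate, min(ci_low, ci_high), max(ci_low, ci_high)


def tables_from_genotypes(
    genotypes: np.ndarray,
    is_case: np.ndarray,
    snp_ids: Sequence[str] | None = None,
    minor_alleles: Sequence[str] | None = None,
    major_alleles: Sequence[str] | None = None,
) -> list[GenotypeCountTable]:
    """Tally per-SNP genotype count tables from a 0/1/2 matrix.

    ``genotypes`` codes minor-allele counts with NaN or -1 for missing calls
    (complete-case per SNP).  When the coded allele exceeds 50% frequency in
    controls, the table is flipped so counts refer to the control-minor
    allele.
    """
    g = np.array(genotypes, dtype=float, copy=True)
    g[g == -1] = np.nan
    is_case = np.asarray(is_case, dtype=bool)
    if g.shape[0] != is_case.size:
        raise ValueError("genotype rows must match the phenotype vector")
    n_snps = g.shape[1]
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(n_snps)]
    tables = []
    for j in range(n_snps):
        col = g[:, j]
        ok = ~np.isnan(col)
        counts = {}
        for grp, mask in (("case", is_case & ok), ("ctrl", ~is_case & ok)):
            vals = col[mask]
            counts[grp] = [int((vals == k).sum()) for k in (2, 1, 0)]  # mm, mM, MM
        minor = minor_alleles[j] if minor_alleles is not None else "m"
        major = major_alleles[j] if major_alleles is not None else "M"
        (cmm, cmM, cMM), (kmm, kmM, kMM) = counts["case"], counts["ctrl"]
        ctrl_total = 2 * (kmm + kmM + kMM)
        if ctrl_total and (2 * kmm + kmM) > ctrl_total / 2:
            cmm, cMM = cMM, cmm
            kmm, kMM = kMM, kmm
            minor, major = major, minor
        tables.append(
            GenotypeCountTable(
                snp_id=str(snp_ids[j]),
                case_mm=cmm, case_mM=cmM, case_MM=cMM,
                ctrl_mm=kmm, ctrl_mM=kmM, ctrl_MM=kMM,
                minor_allele=minor, major_allele=major,
            )
        )
    return tables


class VerificationStudy:
    """Model object for the verification-stage association analysis.

    Parameters
    ----------
    tables : sequence of GenotypeCountTable
        One count table per verified SNP.
    alpha : float
        Significance level applied to BH-adjusted allelic p-values.
    hwe_method : str
        ``"chi2"`` or ``"exact"``; HWE is tested in controls.
    or_method : str
        ``"wald"`` or ``"midp"`` for the per-genotype odds ratios.
    """

    def __init__(
        self,
        tables: Sequence[GenotypeCountTable],
        alpha: float = 0.05,
        hwe_method: str = "chi2",
        or_method: str = "wald",
    ):
        if not tables:
            raise ValueError("at least one count table is required")
        self.tables = list(tables)
        self.alpha = float(alpha)
        self.hwe_method = hwe_method
        self.or_method = or_method

    @classmethod
    def from_genotypes(
        cls,
        genotypes: np.ndarray,
        is_case: np.ndarray,
        snp_ids: Sequence[str] | None = None,
        **kwargs,
    ) -> "VerificationStudy":
        return cls(tables_from_genotypes(genotypes, is_case, snp_ids), **kwargs)

    def fit(self) -> "VerificationResults":
        rows = []
        geno_details = {}
        for t in self.tables:
            al = allelic_test(t)
            test_name = choose_genotype_test(t)
            if test_name == "trend":
                gp = trend_test(t).p
            else:
                gp = fisher_test_2x3(t)
            ors = genotypic_ors(t, method=self.or_method)
            geno_details[t.snp_id] = ors
            rows.append(
                {
                    "snp_id": t.snp_id,
                    "region": t.region,
                    "minor_allele": t.minor_allele,
                    "maf_controls": t.maf_controls,
                    "maf_cases": t.maf_cases,
                    "allelic_chi2": al.chi2,
                    "allelic_p": al.p,
                    "allelic_or": al.odds_ratio,
                    "allelic_ci_low": al.ci_low,
                    "allelic_ci_high": al.ci_high,
                    "genotype_test": test_name,
                    "genotypic_p": gp,
                    "or_mm": ors[0].odds_ratio,
                    "or_mm_ci_low": ors[0].ci_low,
                    "or_mm_ci_high": ors[0].ci_high,
                    "or_mM": ors[1].odds_ratio,
                    "or_mM_ci_low": ors[1].ci_low,
                    "or_mM_ci_high": ors[1].ci_high,
                    "hwe_p_controls": hwe_test(
                        t.ctrl_mm, t.ctrl_mM, t.ctrl_MM, method=self.hwe_method
                    ),
                }
            )
        frame = pd.DataFrame(rows)
        frame["allelic_p_adj"] = bh_adjust(frame["allelic_p"].to_numpy())
        frame["genotypic_p_adj"] = bh_adjust(frame["genotypic_p"].to_numpy())
        frame["significant"] = frame["allelic_p_adj"] < self.alpha
        return VerificationResults(
            frame=frame, alpha=self.alpha, genotypic_ors=geno_details
        )


@dataclass
class VerificationResults:
    """Per-SNP association report in the style of a verification table."""

    frame: pd.DataFrame
    alpha: float
    genotypic_ors: dict[str, list[OddsRatio]]

    @property
    def significant(self) -> list[str]:
        return self.frame.loc[self.frame["significant"], "snp_id"].tolist()

    def summary(self) -> str:
        lines = [
            "Verification-stage association",
            f"  SNPs tested: {len(self.frame)}   "
            f"significant (allelic BH p < {self.alpha:g}): {len(self.significant)}",
            f"  {'snp':<12} {'MA':<3} {'MAF ctl':<8} {'MAF case':<9} "
            f"{'OR (95% CI)':<20} {'p_adj':<9} {'geno test':<9} {'geno p_adj':<10}",
        ]
        for _, r in self.frame.iterrows():
            ci = f"{r.allelic_or:.2f} ({r.allelic_ci_low:.2f}-{r.allelic_ci_high:.2f})"
            star = "*" if r.significant else " "
            lines.append(
                f" {star}{r.snp_id:<12} {r.minor_allele:<3} {r.maf_controls:<8.3f} "
                f"{r.maf_cases:<9.3f} {ci:<20} {r.allelic_p_adj:<9.3g} "
                f"{r.genotype_test:<9} {r.genotypic_p_adj:<10.3g}"
            )
        return "\n".join(lines)


def verify_snps(
    tables: Sequence[GenotypeCountTable], alpha_adj: float = 0.05, **kwargs
) -> VerificationResults:
    """Functional wrapper: run the full verification report on count tables."""
    return VerificationStudy(tables, alpha=alpha_adj, **kwargs).fit()
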
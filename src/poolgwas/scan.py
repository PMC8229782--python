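"""Stage-1 association scan on pooled two-channel intensities.

The relative allele signal (RAS) of a probe in a pool, A/(A+B), estimates the
pool's minor-allele frequency.  The scan compares per-probe RAS between case
pools and control pools with an unequal-variance (Welch) t-test, applies a
step-down Holm family-wise correction over all probes, and summarises residual
stratification with the genomic inflation factor

    lambda = median(chi2_1(1 - p)) / median(chi2_1),

where chi2_1 denotes the 1-df chi-square quantile function (null median
~0.4549).  Pool-level quality control replaces visual inspection of the first
two principal components with a robust median/MAD distance rule.

``PooledAlleleScan`` is the model object; ``fit()`` returns
``PooledScanResults`` carrying the per-probe table, the QC report, lambda and
plotting helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._util import sort_by_position

__all__ = [
    "PoolIntensityMatrix",
    "QCReport",
    "PooledAlleleScan",
    "PooledScanResults",
    "compute_ras",
    "welch_test",
    "holm_adjust",
    "genomic_lambda",
    "pca_pool_qc",
    "run_scan",
]

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # ~0.4549


class ScanError(ValueError):
    pass


@dataclass
class PoolIntensityMatrix:
    """Two-channel signal matrices for pools x probes with metadata.

    ``pools``: pool_id, group ("case"/"control"), sex.
    ``probes``: probe_id, chrom, pos (1-based), optionally allele columns.
    ``A``/``B``: non-negative signal matrices of shape (n_pools, n_probes);
    channel A carries the minor (A-labelled) allele.
    """

    pools: pd.DataFrame
    probes: pd.DataFrame
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.shape != self.B.shape:
            raise ScanError("A and B must have the same shape")
        if self.A.shape != (len(self.pools), len(self.probes)):
            raise ScanError("signal shape inconsistent with pool/probe tables")
        if np.nanmin(self.A) < 0 or np.nanmin(self.B) < 0:
            raise ScanError("signal intensities must be non-negative")
        if (self.probes["pos"] < 1).any():
            raise ScanError("probe positions are 1-based and must be >= 1")

    @property
    def is_case(self) -> np.ndarray:
        return (self.pools["group"] == "case").to_numpy()


@dataclass
class QCReport:
    """Per-pool PCA coordinates, robust distances and outlier flags."""

    table: pd.DataFrame  # pool_id, group, pc1, pc2, distance, flagged
    mad_threshold: float

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "pool_id"].tolist()


def compute_ras(A, B):
    """Relative allele signal A/(A+B), elementwise; NaN where A+B == 0.

    Satisfies RAS(A, B) + RAS(B, A) = 1 wherever defined.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.nanmin(A) < 0 or np.nanmin(B) < 0:
        raise ScanError("signal intensities must be non-negative")
    total = A + B
    with np.errstate(invalid="ignore", divide="ignore"):
        ras = np.where(total > 0, A / np.where(total > 0, total, 1.0), np.nan)
    return ras if ras.shape else float(ras)


def welch_test(ras_case, ras_control, axis: int = 0):
    """Unequal-variance t-test with Satterthwaite df, two-sided p.

    Operates columnwise on matrices (pools along ``axis``); NaN cells are
    ignored per column.  Columns with fewer than two usable pools in either
    group yield NaN.  Degenerate conventions: zero variance in both groups
    with equal means -> (t=0, p=1); with unequal means -> (t=+/-inf, p=0).
    """
    x = np.asarray(ras_case, dtype=float)
    y = np.asarray(ras_control, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if axis == 1:
        x, y = x.T, y.T
    n1 = np.sum(~np.isnan(x), axis=0).astype(float)
    n2 = np.sum(~np.isnan(y), axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(x, axis=0), np.nanmean(y, axis=0)
        v1 = np.nanvar(x, axis=0, ddof=1)
        v2 = np.nanvar(y, axis=0, ddof=1)
    usable = (n1 >= 2) & (n2 >= 2)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    both_flat = usable & (se2 == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(both_flat, np.where(m1 == m2, 0.0, np.sign(m1 - m2) * np.inf), t)
        df = np.where(both_flat, n1 + n2 - 2, df)
        p = np.where(both_flat, np.where(m1 == m2, 1.0, 0.0), p)
    t = np.where(usable, t, np.nan)
    df = np.where(usable, df, np.nan)
    p = np.where(usable, p, np.nan)
    if np.ndim(ras_case) == 1:
        return float(t[0]), float(df[0]), float(p[0])
    return t, df, p


def holm_adjust(p) -> np.ndarray:
    """Step-down Holm adjustment; output order matches input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ScanError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="holm")[1]
    return out


def genomic_lambda(p) -> float:
    """Genomic inflation factor from a vector of association p-values."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ScanError("cannot compute lambda from an empty p-value vector")
    if (p <= 0).any() or (p > 1).any():
        raise ScanError("p-values must lie in (0, 1]")
    med = np.median(stats.chi2.isf(p, 1))
    if med == 0.0:  # e.g. every p == 1 (all-identical intensities)
        warnings.warn("degenerate p-value distribution; lambda undefined", RuntimeWarning)
        return float("nan")
    return float(med / CHI2_1_MEDIAN)


def pca_pool_qc(
    ras: np.ndarray,
    pools: pd.DataFrame,
    mad_threshold: float = 6.0,
) -> QCReport:
    """Flag outlying pools on the first two principal components of RAS.

    Probes missing in any pool are excluded from the PCA input.  Each
    component is converted to a modified z-score, 0.6745 * (x - median)/MAD,
    and pools whose Euclidean norm over (z1, z2) exceeds ``mad_threshold``
    are flagged.  A component with zero MAD contributes zero for pools at the
    median and +inf otherwise.
    """
    ras = np.asarray(ras, dtype=float)
    n_pools = ras.shape[0]
    if n_pools < 3:
        raise ScanError("PCA QC needs at least 3 pools")
    complete = ~np.isnan(ras).any(axis=0)
    X = ras[:, complete]
    if X.shape[1] < 2:
        raise ScanError("fewer than 2 complete probes for PCA QC")
    pcs = PCA(n_components=2, svd_solver="full").fit_transform(X - X.mean(axis=0))
    z = np.empty_like(pcs)
    for k in range(2):
        med = np.median(pcs[:, k])
        mad = np.median(np.abs(pcs[:, k] - med))
        dev = pcs[:, k] - med
        if mad == 0:
            z[:, k] = np.where(dev == 0, 0.0, np.inf)
        else:
            z[:, k] = 0.6745 * dev / mad
    dist = np.hypot(z[:, 0], z[:, 1])
    table = pd.DataFrame(
        {
            "pool_id": pools["pool_id"].to_numpy(),
            "group": pools["group"].to_numpy(),
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "distance": dist,
            "flagged": dist > mad_threshold,
        }
    )
    return QCReport(table=table, mad_threshold=mad_threshold)


class PooledAlleleScan:
    """Model object for the pooled-intensity association scan.

    Parameters
    ----------
    data : PoolIntensityMatrix
        Pooled signals with pool and probe metadata.
    mad_threshold : float
        Robust-distance cutoff for the PCA pool QC (``inf`` disables QC).
    """

    def __init__(self, data: PoolIntensityMatrix, mad_threshold: float = 6.0):
        self.data = data
        self.mad_threshold = float(mad_threshold)

    def fit(self) -> "PooledScanResults":
        d = self.data
        ras = compute_ras(d.A, d.B)
        qc = pca_pool_qc(ras, d.pools, self.mad_threshold)
        keep = ~qc.table["flagged"].to_numpy()
        is_case = d.is_case
        if (keep & is_case).sum() < 2 or (keep & ~is_case).sum() < 2:
            raise ScanError("fewer than 2 pools per group after QC")
        r_case = ras[keep & is_case]
        r_ctrl = ras[keep & ~is_case]
        t, df, p = welch_test(r_case, r_ctrl)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = pd.DataFrame(
                {
                    "probe_id": d.probes["probe_id"].to_numpy(),
                    "chrom": d.probes["chrom"].to_numpy(),
                    "pos": d.probes["pos"].to_numpy(),
                    "ras_case_mean": np.nanmean(r_case, axis=0),
                    "ras_control_mean": np.nanmean(r_ctrl, axis=0),
                    "t": t,
                    "df": df,
                    "p": p,
                    "n_case_pools": np.sum(~np.isnan(r_case), axis=0),
                    "n_control_pools": np.sum(~np.isnan(r_ctrl), axis=0),
                }
            )
        table["p_holm"] = holm_adjust(table["p"].to_numpy())
        table = sort_by_position(table)
        valid_p = table["p"].to_numpy()
        valid_p = valid_p[~np.isnan(valid_p)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lam = genomic_lambda(np.clip(valid_p, 1e-300, 1.0)) if valid_p.size else float("nan")
        return PooledScanResults(table=table, qc=qc, lambda_gc=lam)


@dataclass
class PooledScanResults:
    """Per-probe scan statistics, pool QC report and inflation factor."""

    table: pd.DataFrame
    qc: QCReport
    lambda_gc: float

    def summary(self) -> str:
        n_sig = int((self.table["p_holm"] < 0.05).sum())
        lines = [
            "Pooled-DNA association scan",
            f"  probes tested:        {len(self.table)}",
            f"  pools flagged by QC:  {len(self.qc.flagged)} {self.qc.flagged}",
            f"  genomic inflation:    lambda = {self.lambda_gc:.3f}",
            f"  Holm-significant:     {n_sig} probes (p_holm < 0.05)",
            "  top probes:",
        ]
        top = self.table.nsmallest(5, "p")
        for _, r in top.iterrows():
            lines.append(
                f"    {r.probe_id:<20} {r.chrom}:{int(r.pos):<10} "
                f"p={r.p:.3g} p_holm={r.p_holm:.3g}"
            )
        return "\n".join(lines)

    def qq_table(self) -> pd.DataFrame:
        """Observed vs expected -log10 p for a Q-Q plot."""
        p = np.sort(self.table["p"].dropna().to_numpy())
        n = p.size
        return pd.DataFrame(
            {
                "expected": -np.log10((np.arange(n) + 0.5) / n),
                "observed": -np.log10(np.clip(p, 1e-300, 1.0)),
            }
        )

    def plot_qq(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        qq = self.qq_table()
        ax.scatter(qq["expected"], qq["observed"], s=4, color="black")
        lim = float(qq["expected"].max()) if len(qq) else 1.0
        ax.plot([0, lim], [0, lim], color="red", lw=1)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        ax.set_title(f"lambda = {self.lambda_gc:.3f}")
        return ax

    def plot_manhattan(self, ax=None, sig_line: float | None = 5e-3):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(self.table.groupby("chrom", sort=False)):
            x = grp["pos"].to_numpy() + offset
            y = -np.log10(np.clip(grp["p"].to_numpy(), 1e-300, 1.0))
            ax.scatter(x, y, s=3, color=["steelblue", "darkorange"][i % 2])
            ticks.append(offset + grp["pos"].max() / 2)
            labels.append(str(chrom))
            offset += grp["pos"].max() + 1
        if sig_line:
            ax.axhline(-np.log10(sig_line), color="red", lw=0.8, ls="--")
        ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
        ax.set_ylabel("-log10 p")
        return ax


def run_scan(
    data: PoolIntensityMatrix, mad_threshold: float = 6.0
) -> PooledScanResults:
    """Functional wrapper: fit the scan model on a pooled intensity matrix."""
    return PooledAlleleScan(data, mad_threshold=mad_threshold).fit()
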
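"""Outlier handling and standardization front end of the PCA-LDA pipeline.

Gross single-well artifacts are common in qPCR ratio data and wreck both PCA
and LDA, so before any multivariate step the pipeline (i) screens the genes
carrying the major part of the raw-scale variance, (ii) runs the generalized
extreme studentized deviate (ESD, Rosner) test per screened gene at a strict
significance level, (iii) blanks the few globally most extreme flagged cells,
(iv) fills the resulting empty cells with the mean of the same gene within
the same experimental group, and (v) standardizes every gene column to mean 0
and unit variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ExpressionDataset

__all__ = [
    "PreprocessConfig",
    "EsdResult",
    "FlaggedCell",
    "OutlierReport",
    "StandardizedMatrix",
    "esd_test",
    "detect_and_remove",
    "impute_group_means",
    "standardize",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Front-end tuning knobs.

    ``esd_alpha`` is the two-sided significance level of the ESD test;
    ``max_outliers_total`` caps how many cells are blanked across the whole
    matrix (the two globally biggest by default); ``esd_max_k_per_gene`` is
    the per-column upper bound on outliers the ESD procedure may declare;
    ``variance_screen_fraction`` selects the top fraction of genes by
    raw-scale variance share as the screened set.
    """

    esd_alpha: float = 0.001
    max_outliers_total: int = 2
    esd_max_k_per_gene: int = 3
    variance_screen_fraction: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.esd_alpha < 1.0:
            raise ValueError(f"esd_alpha must be in (0, 1), got {self.esd_alpha}")
        if self.max_outliers_total < 0:
            raise ValueError("max_outliers_total must be >= 0")
        if self.esd_max_k_per_gene < 1:
            raise ValueError("esd_max_k_per_gene must be >= 1")
        if not 0.0 < self.variance_screen_fraction <= 1.0:
            raise ValueError("variance_screen_fraction must be in (0, 1]")


@dataclass(frozen=True)
class EsdResult:
    """One iteration of the generalized ESD procedure."""

    index: int  # position in the input vector
    statistic: float  # R_i = max |x - mean| / sd at this iteration
    critical_value: float  # lambda_i
    is_outlier: bool


@dataclass(frozen=True)
class FlaggedCell:
    sample_id: str
    gene: str
    value: float
    statistic: float
    critical_value: float


@dataclass
class OutlierReport:
    """All ESD-flagged cells and the subset actually removed."""

    flagged: list[FlaggedCell] = field(default_factory=list)
    removed: list[FlaggedCell] = field(default_factory=list)
    screened_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def row(c: FlaggedCell) -> dict:
            return {
                "sample_id": c.sample_id, "gene": c.gene, "value": c.value,
                "statistic": c.statistic, "critical_value": c.critical_value,
            }

        return {
            "screened_genes": list(self.screened_genes),
            "flagged": [row(c) for c in self.flagged],
            "removed": [row(c) for c in self.removed],
        }


@dataclass
class StandardizedMatrix:
    """Column-standardized matrix with the means/stds needed to invert it.

    Standard deviations use the population (n) denominator.  Constant raw
    columns map to all-zero z-columns with their std recorded as 0.
    """

    z: pd.DataFrame
    column_means: pd.Series
    column_stds: pd.Series

    def inverse(self) -> pd.DataFrame:
        """Map z-scores back to the raw scale (constant columns restore the mean)."""
        return self.z * self.column_stds + self.column_means


def esd_test(values, alpha: float = 0.001, max_k: int = 3) -> list[EsdResult]:
    """Generalized ESD (Rosner) test for up to ``max_k`` outliers.

    Iteratively computes R_i = max|x - mean|/sd over the remaining points,
    drops the most extreme point, and compares each R_i with the two-sided
    t-based critical value lambda_i at level ``alpha``.  The declared outlier
    count is the largest i with R_i > lambda_i; every earlier removal is then
    an outlier too (the procedure is robust to masking).  A zero sample
    standard deviation at any iteration stops the search.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"ESD test needs at least 4 values, got {n}")
    if max_k >= n / 2:
        raise ValueError(f"max_k must be < n/2 (got max_k={max_k}, n={n})")

    remaining = list(range(n))
    rows: list[tuple[int, float, float]] = []
    for i in range(1, max_k + 1):
        sub = x[remaining]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - mean)
        j = int(np.argmax(dev))  # ties: smallest position
        r_i = dev[j] / sd
        m = n - i + 1  # points entering this iteration
        p = 1.0 - alpha / (2.0 * m)
        df = m - 2
        t = stats.t.ppf(p, df)
        lam = (m - 1) * t / math.sqrt((df + t * t) * m)
        rows.append((remaining[j], float(r_i), float(lam)))
        remaining.pop(j)

    n_out = 0
    for i, (_, r_i, lam) in enumerate(rows, start=1):
        if r_i > lam:
            n_out = i
    return [
        EsdResult(idx, r_i, lam, i <= n_out)
        for i, (idx, r_i, lam) in enumerate(rows, start=1)
    ]


def _screened_genes(values: pd.DataFrame, fraction: float) -> list[str]:
    # "Major part of the variance": top `fraction` of genes ranked by their
    # raw-scale variance share, ties broken by column order.
    variances = values.var(axis=0, ddof=1, skipna=True)
    n_screen = math.ceil(fraction * values.shape[1])
    order = np.lexsort((np.arange(values.shape[1]), -variances.to_numpy()))
    return [values.columns[i] for i in order[:n_screen]]


def detect_and_remove(
    ds: ExpressionDataset, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionDataset, OutlierReport]:
    """Blank the globally most extreme ESD-flagged cells.

    The ESD test runs per screened gene column (NaN cells excluded); among
    all flagged cells across genes, the ``max_outliers_total`` with the
    largest ESD statistics are set to NaN.  Ties in the statistic are broken
    by (gene position, sample position) ascending for reproducibility.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    report = OutlierReport(screened_genes=_screened_genes(ds.values, cfg.variance_screen_fraction))

    gene_pos = {g: i for i, g in enumerate(ds.gene_names)}
    sample_pos = {s: i for i, s in enumerate(ds.sample_ids)}
    for gene in report.screened_genes:
        col = ds.values[gene]
        mask = col.notna().to_numpy()
        vals = col.to_numpy()[mask]
        samples = np.asarray(ds.sample_ids)[mask]
        if vals.size < 4:
            continue
        max_k = min(cfg.esd_max_k_per_gene, (vals.size - 1) // 2)
        if max_k < 1:
            continue
        for res in esd_test(vals, alpha=cfg.esd_alpha, max_k=max_k):
            if res.is_outlier:
                report.flagged.append(
                    FlaggedCell(
                        sample_id=str(samples[res.index]),
                        gene=gene,
                        value=float(vals[res.index]),
                        statistic=res.statistic,
                        critical_value=res.critical_value,
                    )
                )

    report.flagged.sort(
        key=lambda c: (-c.statistic, gene_pos[c.gene], sample_pos[c.sample_id])
    )
    report.removed = report.flagged[: cfg.max_outliers_total]

    out = ds.copy()
    for c in report.removed:
        out.values.loc[c.sample_id, c.gene] = np.nan
    return out, report


def impute_group_means(ds: ExpressionDataset) -> ExpressionDataset:
    """Fill each empty cell with the mean of its gene within its group."""
    out = ds.copy()
    empties = np.argwhere(out.values.isna().to_numpy())
    for r, c in empties:
        sid = out.sample_ids[r]
        gene = out.gene_names[c]
        group = out.groups[sid]
        peers = out.values.loc[out.samples_in(group), gene]
        fill = peers.mean(skipna=True)
        if np.isnan(fill):
            raise ValueError(
                f"cannot impute: group {group!r}, gene {gene!r} has no observed values"
            )
        out.values.iloc[r, c] = fill
    return out


def standardize(ds: ExpressionDataset) -> StandardizedMatrix:
    """Scale every gene column to mean 0 and unit (population) variance."""
    if ds.values.isna().any().any():
        raise ValueError("standardize requires a matrix with no empty cells")
    means = ds.values.mean(axis=0)
    stds = ds.values.std(axis=0, ddof=0)
    safe = stds.replace(0.0, 1.0)  # constant columns -> all zeros
    z = (ds.values - means) / safe
    return StandardizedMatrix(z=z, column_means=means, column_stds=stds)


def preprocess(
    ds: ExpressionDataset, cfg: PreprocessConfig | None = None
) -> tuple[StandardizedMatrix, OutlierReport]:
    """Run the whole front end: ESD removal, group-mean imputation, scaling."""
    blanked, report = detect_and_remove(ds, cfg)
    return standardize(impute_group_means(blanked)), report
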
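"""Count filtering, differential-expression tables and DEG calling.

The differential-expression engine itself (normalization, Wald tests,
shrinkage) is upstream of this package: its result tables — gene, log2 fold
change (LFC), LFC standard error, p-value, BH-adjusted p-value (FDR) — are
consumed as input.  This module applies the gene-level count filters, the
two-stage DEG criterion (FDR < 0.05 *and* |LFC| above the mean |LFC| of
non-significant genes), and summarizes responses over gene cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import normalize_name

__all__ = [
    "DEFAULT_DE_COLUMNS",
    "CohortSummary",
    "filter_counts",
    "load_de_table",
    "deg_classify",
    "summarize_cohort",
    "zero_sum_check",
]

DEFAULT_DE_COLUMNS: dict[str, str] = {
    "gene": "gene",
    "lfc": "log2FoldChange",
    "lfc_se": "lfcSE",
    "pvalue": "pvalue",
    "fdr": "padj",
}


@dataclass(frozen=True)
class CohortSummary:
    """Response summary of one gene cohort."""

    cohort_id: str
    n: int
    mu_abs_lfc: float
    sigma_abs_lfc: float
    sem: float
    n_deg: int
    frac_deg: float


def filter_counts(matrix: pd.DataFrame, min_count: int = 5,
                  max_low_samples: int = 3, min_mean: float = 10.0) -> pd.DataFrame:
    """Remove lowly-counted genes from a genes × samples count matrix.

    A gene is removed iff it has fewer than *min_count* counts in strictly
    more than *max_low_samples* samples, or its mean count is below
    *min_mean*.  Use ``max_low_samples=3`` for a single-batch design and 6
    when count matrices from two designs are merged.  Row order of the
    retained genes is preserved.
    """
    if matrix.empty:
        raise ValueError("count matrix is empty")
    if (matrix.values < 0).any():
        raise ValueError("count matrix has negative entries")
    low = (matrix < min_count).sum(axis=1) > max_low_samples
    small_mean = matrix.mean(axis=1) < min_mean
    return matrix.loc[~(low | small_mean)]


def load_de_table(path, condition: str, timepoint: float,
                  columns: Mapping[str, str] | None = None,
                  sep: str | None = None) -> pd.DataFrame:
    """Load a differential-expression result table into the tidy response form.

    Returns columns ``gene, lfc, lfc_se, pvalue, fdr, condition, timepoint``.
    Missing adjusted p-values are preserved as NaN.  *sep* None sniffs comma
    vs tab from the first line.
    """
    cols = {**DEFAULT_DE_COLUMNS, **(columns or {})}
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    missing = {v for v in cols.values()} - set(df.columns)
    if missing:
        raise ValueError(f"DE table {path} is missing columns {sorted(missing)}")
    out = pd.DataFrame({
        "gene": df[cols["gene"]].map(normalize_name),
        "lfc": pd.to_numeric(df[cols["lfc"]], errors="coerce"),
        "lfc_se": pd.to_numeric(df[cols["lfc_se"]], errors="coerce"),
        "pvalue": pd.to_numeric(df[cols["pvalue"]], errors="coerce"),
        "fdr": pd.to_numeric(df[cols["fdr"]], errors="coerce"),
    })
    bad = out.index[out["lfc"].isna() & df[cols["lfc"]].notna()]
    if len(bad):
        raise ValueError(f"non-numeric LFC in row {bad[0] + 1} of {path}")
    dup = out["gene"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate gene id {out.loc[dup, 'gene'].iloc[0]!r} in {path}")
    out["condition"] = condition
    out["timepoint"] = timepoint
    return out


def deg_classify(responses: pd.DataFrame, fdr_threshold: float = 0.05
                 ) -> tuple[float, pd.DataFrame]:
    """Two-stage DEG call for one condition/timepoint.

    The |LFC| threshold is the mean |LFC| over genes with FDR above
    *fdr_threshold* (genes with missing FDR excluded).  A gene is a DEG iff
    FDR < *fdr_threshold* and |LFC| strictly above the threshold — removing
    statistically significant genes with negligible fold change.  Returns the
    threshold and a copy of *responses* with an ``is_deg`` column.
    """
    fdr = responses["fdr"]
    background = responses.loc[fdr.notna() & (fdr > fdr_threshold), "lfc"].abs()
    if background.empty:
        raise ValueError("no genes with FDR above the threshold; |LFC| cut undefined")
    threshold = float(background.mean())
    out = responses.copy()
    out["is_deg"] = (fdr.notna() & (fdr < fdr_threshold)
                     & (out["lfc"].abs() > threshold))
    return threshold, out


def summarize_cohort(responses: pd.DataFrame, gene_set: Sequence[str],
                     cohort_id: str = "cohort") -> CohortSummary:
    """μ|LFC|, σ|LFC|, SEM and DEG content of a gene cohort.

    *gene_set* may repeat genes (with-replacement cohorts); duplicates count
    with multiplicity.  A singleton cohort has σ and SEM 0 by convention.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    genes = [normalize_name(g) for g in gene_set]
    indexed = responses.set_index("gene") if "gene" in responses.columns else responses
    missing = set(genes) - set(indexed.index)
    if missing:
        raise KeyError(f"genes missing from responses: {sorted(missing)[:5]}")
    sub = indexed.loc[genes]
    abs_lfc = sub["lfc"].abs().to_numpy(float)
    n = len(abs_lfc)
    sigma = float(np.std(abs_lfc, ddof=1)) if n > 1 else 0.0
    n_deg = int(sub["is_deg"].sum()) if "is_deg" in sub.columns else 0
    return CohortSummary(
        cohort_id=cohort_id,
        n=n,
        mu_abs_lfc=float(abs_lfc.mean()),
        sigma_abs_lfc=sigma,
        sem=sigma / np.sqrt(n),
        n_deg=n_deg,
        frac_deg=n_deg / n,
    )


def zero_sum_check(responses: pd.DataFrame, tolerance: float = 1e-6
                   ) -> tuple[bool, float]:
    """Mean signed LFC of a full condition and whether it is ~0.

    Median-of-ratios normalization with a zero-centered LFC prior forces the
    genome-wide mean LFC towards 0; a large mean flags a mis-normalized table.
    """
    mean_lfc = float(responses["lfc"].mean())
    return abs(mean_lfc) <= tolerance, mean_lfc
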
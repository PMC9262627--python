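"""Ensemble cohort sampling over regulatory-logic attributes.

The ensemble approach suppresses local-topology idiosyncrasies when relating
a cohort-mean attribute (the regulatory bias |b| or the input-TF count K_TF)
to the cohort-mean response μ|LFC|: genes are drawn *with replacement* into
fixed-size cohorts (default 10 genes) whose achieved attribute mean must land
within half a grid step of a target grid point; up to a cap of cohorts
(default 25000 per point) is collected and the response curve averages
μ|LFC| over the cohorts of each point.  A conditional variant holds one
attribute's mean fixed while the other spans the grid — disentangling |b|
from K_TF, which are strongly correlated in real regulatory networks — and a
bootstrap control draws equal-size cohorts within each K_TF class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSet",
    "sample_cohorts",
    "conditional_cohorts",
    "bootstrap_equal_size",
    "response_curve",
]

DEFAULT_GRID = np.round(np.arange(0.0, 5.25, 0.25), 10)
DEFAULT_COHORT_SIZE = 10
DEFAULT_MAX_COHORTS = 25000
DEFAULT_DRAW_BUDGET = 1_000_000


@dataclass
class CohortSet:
    """Cohorts grouped by grid point.

    ``by_point`` maps a grid value to an (n_cohorts, size) integer array of
    positions into ``genes`` (with-replacement draws repeat positions).
    """

    genes: np.ndarray                       # gene names, positional index
    attribute: str
    size: int
    grid_step: float
    by_point: dict[float, np.ndarray] = field(default_factory=dict)

    def n_cohorts(self, point: float) -> int:
        return len(self.by_point.get(point, ()))

    def cohort_genes(self, point: float) -> list[list[str]]:
        return [list(self.genes[idx]) for idx in self.by_point[point]]

    def to_frame(self) -> pd.DataFrame:
        """Audit dump: one row per (grid point, cohort, gene)."""
        rows = []
        for gp, cohorts in self.by_point.items():
            for ci, idx in enumerate(cohorts):
                for g in self.genes[idx]:
                    rows.append((gp, ci, g))
        return pd.DataFrame(rows, columns=["grid_point", "cohort_id", "gene"])


def _eligible(profiles: pd.DataFrame, min_ktf: int) -> pd.DataFrame:
    out = profiles[profiles["k_tf"] >= min_ktf]
    if out.empty:
        raise ValueError("no genes satisfy the K_TF restriction")
    return out


def sample_cohorts(profiles: pd.DataFrame, attribute: str = "b",
                   grid: np.ndarray | None = None,
                   size: int = DEFAULT_COHORT_SIZE,
                   max_cohorts_per_point: int = DEFAULT_MAX_COHORTS,
                   draw_budget: int = DEFAULT_DRAW_BUDGET,
                   min_ktf: int = 1,
                   seed: int | None = None) -> CohortSet:
    """Rejection-sample fixed-size cohorts onto an attribute-mean grid.

    Cohorts of *size* genes are drawn with replacement from genes with
    K_TF ≥ *min_ktf*; a draw is assigned to the nearest grid point if its
    achieved attribute mean lies within half a grid step, else rejected.
    Sampling stops when every point holds *max_cohorts_per_point* cohorts or
    the draw budget is spent.  Grid points left empty are omitted with a
    warning.  Fully reproducible from *seed*.
    """
    if attribute not in ("b", "k_tf"):
        raise ValueError("attribute must be 'b' or 'k_tf'")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    step = float(np.min(np.diff(np.sort(grid)))) if len(grid) > 1 else 0.5
    elig = _eligible(profiles, min_ktf)
    values = elig[attribute].to_numpy(float)
    genes = elig.index.to_numpy()
    rng = np.random.default_rng(seed)

    by_point: dict[float, list[np.ndarray]] = {float(g): [] for g in grid}
    counts = {float(g): 0 for g in grid}
    drawn = 0
    batch = 20000
    while drawn < draw_budget and any(c < max_cohorts_per_point for c in counts.values()):
        nb = min(batch, draw_budget - drawn)
        idx = rng.integers(0, len(genes), size=(nb, size))
        drawn += nb
        means = values[idx].mean(axis=1)
        gi = np.abs(means[:, None] - grid[None, :]).argmin(axis=1)
        nearest = grid[gi]
        ok = np.abs(means - nearest) <= step / 2
        for gp in map(float, grid):
            room = max_cohorts_per_point - counts[gp]
            if room <= 0:
                continue
            sel = ok & (nearest == gp)
            if sel.any():
                take = idx[sel][:room]
                by_point[gp].append(take)
                counts[gp] += len(take)

    out: dict[float, np.ndarray] = {}
    for gp in map(float, grid):
        if counts[gp] == 0:
            logger.warning("grid point %.3g: no cohorts accepted; omitted", gp)
        else:
            out[gp] = np.vstack(by_point[gp])
    return CohortSet(genes=genes, attribute=attribute, size=size,
                     grid_step=step, by_point=out)


def conditional_cohorts(profiles: pd.DataFrame, fixed: str, fixed_value: float,
                        varying: str | None = None,
                        grid: np.ndarray | None = None,
                        size: int = DEFAULT_COHORT_SIZE,
                        max_cohorts_per_point: int = DEFAULT_MAX_COHORTS,
                        draw_budget: int = DEFAULT_DRAW_BUDGET,
                        min_ktf: int = 1,
                        seed: int | None = None) -> CohortSet:
    """Cohorts whose *fixed* attribute mean is pinned while *varying* spans the grid.

    The fixed constraint accepts achieved means within half a grid step of
    *fixed_value*; the varying attribute is binned to the grid exactly as in
    :func:`sample_cohorts`.  Infeasible grid points are omitted with a
    warning.
    """
    if fixed not in ("b", "k_tf"):
        raise ValueError("fixed must be 'b' or 'k_tf'")
    if varying is None:
        varying = "k_tf" if fixed == "b" else "b"
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, float)
    step = float(np.min(np.diff(np.sort(grid)))) if len(grid) > 1 else 0.5
    elig = _eligible(profiles, min_ktf)
    fixed_vals = elig[fixed].to_numpy(float)
    vary_vals = elig[varying].to_numpy(float)
    genes = elig.index.to_numpy()
    rng = np.random.default_rng(seed)

    by_point: dict[float, list[np.ndarray]] = {float(g): [] for g in grid}
    counts = {float(g): 0 for g in grid}
    drawn = 0
    batch = 20000
    while drawn < draw_budget and any(c < max_cohorts_per_point for c in counts.values()):
        nb = min(batch, draw_budget - drawn)
        idx = rng.integers(0, len(genes), size=(nb, size))
        drawn += nb
        fmeans = fixed_vals[idx].mean(axis=1)
        ok_fixed = np.abs(fmeans - fixed_value) <= step / 2
        if not ok_fixed.any():
            continue
        idx = idx[ok_fixed]
        vmeans = vary_vals[idx].mean(axis=1)
        gi = np.abs(vmeans[:, None] - grid[None, :]).argmin(axis=1)
        nearest = grid[gi]
        ok = np.abs(vmeans - nearest) <= step / 2
        for gp in map(float, grid):
            room = max_cohorts_per_point - counts[gp]
            if room <= 0:
                continue
            sel = ok & (nearest == gp)
            if sel.any():
                take = idx[sel][:room]
                by_point[gp].append(take)
                counts[gp] += len(take)

    out: dict[float, np.ndarray] = {}
    for gp in map(float, grid):
        if counts[gp] == 0:
            logger.warning("conditional grid point %.3g (fixed %s=%.3g): "
                           "no cohorts; omitted", gp, fixed, fixed_value)
        else:
            out[gp] = np.vstack(by_point[gp])
    return CohortSet(genes=genes, attribute=varying, size=size,
                     grid_step=step, by_point=out)


def bootstrap_equal_size(profiles: pd.DataFrame, responses: pd.DataFrame,
                         n_cohorts: int = 10000,
                         cohort_size: int | None = None,
                         ktf_values: list[int] | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Equal-size bootstrap control for the μ|LFC|-vs-K_TF relationship.

    K_TF classes differ widely in size; to rule out cohort-size artefacts,
    *n_cohorts* subsamples of *cohort_size* genes (default: the size of the
    smallest class used) are drawn without replacement within every class and
    the mean and SEM of the cohort μ|LFC| are reported per class.  A class
    smaller than the cohort size falls back to with-replacement sampling and
    is flagged in the output.
    """
    rng = np.random.default_rng(seed)
    resp = responses.set_index("gene") if "gene" in responses.columns else responses
    abs_lfc = resp["lfc"].abs()
    merged = profiles.join(abs_lfc.rename("abs_lfc"), how="inner")
    if ktf_values is None:
        ktf_values = sorted(merged["k_tf"].unique())
    if cohort_size is None:
        cohort_size = int(min(
            (merged["k_tf"] == k).sum() for k in ktf_values
            if (merged["k_tf"] == k).sum() > 0))
    rows = []
    for k in ktf_values:
        vals = merged.loc[merged["k_tf"] == k, "abs_lfc"].to_numpy(float)
        if len(vals) == 0:
            continue
        with_replacement = len(vals) < cohort_size
        if with_replacement:
            logger.warning("K_TF=%d class (%d genes) smaller than cohort size %d; "
                           "sampling with replacement", k, len(vals), cohort_size)
            idx = rng.integers(0, len(vals), size=(n_cohorts, cohort_size))
            mus = vals[idx].mean(axis=1)
        else:
            mus = np.empty(n_cohorts)
            for i in range(n_cohorts):
                mus[i] = vals[rng.choice(len(vals), cohort_size, replace=False)].mean()
        sem = float(np.std(mus, ddof=1) / np.sqrt(len(mus))) if len(mus) > 1 else 0.0
        rows.append({"k_tf": k, "n_genes": len(vals), "cohort_size": cohort_size,
                     "mu_abs_lfc": float(mus.mean()), "sem": sem,
                     "full_class_mu": float(vals.mean()),
                     "with_replacement": with_replacement})
    return pd.DataFrame(rows)


def response_curve(cohorts: CohortSet, responses: pd.DataFrame) -> pd.DataFrame:
    """Average cohort μ|LFC| at each grid point of a :class:`CohortSet`.

    y is the mean over cohorts of the cohort-mean |LFC|; y_sem its SEM across
    cohorts.  Cohorts containing a gene missing from *responses* are dropped
    with a logged count.
    """
    resp = responses.set_index("gene") if "gene" in responses.columns else responses
    abs_lfc = resp["lfc"].abs()
    lookup = abs_lfc.reindex(cohorts.genes).to_numpy(float)
    rows = []
    n_dropped = 0
    for gp, idx in sorted(cohorts.by_point.items()):
        vals = lookup[idx]                      # (n_cohorts, size)
        good = ~np.isnan(vals).any(axis=1)
        n_dropped += int((~good).sum())
        vals = vals[good]
        if len(vals) == 0:
            continue
        mus = vals.mean(axis=1)
        sem = float(np.std(mus, ddof=1) / np.sqrt(len(mus))) if len(mus) > 1 else 0.0
        rows.append({"x": gp, "y": float(mus.mean()), "y_sem": sem,
                     "n_cohorts": len(mus)})
    if n_dropped:
        logger.warning("response_curve: dropped %d cohorts with genes missing "
                       "from responses", n_dropped)
    return pd.DataFrame(rows)
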
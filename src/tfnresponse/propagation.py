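"""Input→output signal propagation along the regulatory network.

Pairs genes separated by a minimum directed path length L in the TFN and
regresses the output gene's |LFC| on the input gene's |LFC|.  If a shift in a
global regulator propagates through the network, directly linked pairs
(L = 1) should correlate while the correlation decays quickly with L.  Only
*absolute* LFCs are compared (the sign of the downstream effect depends on
the unknown details of each promoter).  A rank-sorted re-pairing of the same
values gives the maximal correlation attainable from the two marginal
distributions (rearrangement inequality) — an upper bound against which the
observed fit is judged.  The module also tests whether a gene's position
inside a 3-gene operon changes its relationship to the shared input TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import TFNGraph, UnitAnnotation
from .regression import McOLSResults, ancova_compare, mc_ols

logger = logging.getLogger(__name__)

__all__ = [
    "PairedResponses",
    "pair_responses",
    "max_correlation_bound",
    "position_effect_test",
]


@dataclass
class PairedResponses:
    """|LFC| pairs of (input gene, output gene) at one minimum path length."""

    L: int
    pairs: pd.DataFrame          # input_gene, output_gene, input_abs_lfc, output_abs_lfc
    n_dropped: int = 0
    condition: str | None = None
    timepoint: float | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def x(self) -> np.ndarray:
        return self.pairs["input_abs_lfc"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.pairs["output_abs_lfc"].to_numpy(float)

    def fit(self, seed: int | None = None) -> McOLSResults:
        """Plain OLS of output |LFC| on input |LFC| (points carry no SEM)."""
        return mc_ols(self.x, self.y, m=1, seed=seed)


def pair_responses(path_pairs: pd.DataFrame, responses: pd.DataFrame, L: int,
                   ktf_filter: int | None = None,
                   profiles: pd.DataFrame | None = None) -> PairedResponses:
    """Join minimum-path-length pairs with the |LFC| of both genes.

    *path_pairs* is the output of :func:`~tfnresponse.network.min_path_lengths`;
    *responses* one condition/timepoint.  Pairs in which either gene lacks a
    response are dropped (counted).  *ktf_filter* restricts output genes to
    one K_TF class (requires *profiles*).
    """
    sub = path_pairs[path_pairs["L"] == L]
    if ktf_filter is not None:
        if profiles is None:
            raise ValueError("ktf_filter requires the regulatory profiles")
        keep = set(profiles.index[profiles["k_tf"] == ktf_filter])
        sub = sub[sub["output_gene"].isin(keep)]
    resp = responses.set_index("gene") if "gene" in responses.columns else responses
    abs_lfc = resp["lfc"].abs()
    df = sub.copy()
    df["input_abs_lfc"] = abs_lfc.reindex(df["input_gene"].to_numpy()).to_numpy()
    df["output_abs_lfc"] = abs_lfc.reindex(df["output_gene"].to_numpy()).to_numpy()
    n0 = len(df)
    df = df.dropna(subset=["input_abs_lfc", "output_abs_lfc"]).reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("pair_responses L=%d: dropped %d pairs lacking responses", L, n_dropped)
    cond = resp["condition"].iloc[0] if "condition" in resp.columns and len(resp) else None
    tp = resp["timepoint"].iloc[0] if "timepoint" in resp.columns and len(resp) else None
    cols = ["input_gene", "output_gene", "input_abs_lfc", "output_abs_lfc"]
    return PairedResponses(L=L, pairs=df[cols], n_dropped=n_dropped,
                           condition=cond, timepoint=tp)


def max_correlation_bound(paired: PairedResponses, seed: int | None = None) -> McOLSResults:
    """Best fit after rank-sorting the pair values to maximize correlation.

    Input and output values are independently sorted ascending and re-paired
    rank to rank; by the rearrangement inequality this maximizes the sample
    correlation over all re-pairings, bounding what any pairing of the same
    marginals could achieve.
    """
    if len(paired) < 3:
        raise ValueError("at least 3 pairs are required")
    x = np.sort(paired.x)
    y = np.sort(paired.y)
    return mc_ols(x, y, m=1, seed=seed)


def position_effect_test(annotations: dict[str, UnitAnnotation], graph: TFNGraph,
                         responses: pd.DataFrame, operon_size: int = 3
                         ) -> dict:
    """Does within-operon gene position modulate the input-TF relationship?

    For operons of exactly *operon_size* members whose members share their
    input TFs, builds (input-TF |LFC|, member |LFC|) pairs separately for
    each position, fits a line per position, and compares the position lines
    pairwise by ANCOVA (equal slope / equal intercept at the 10% level).
    With a single qualifying operon the fits are still computed but the
    ANCOVA is skipped with a warning.
    """
    resp = responses.set_index("gene") if "gene" in responses.columns else responses
    abs_lfc = resp["lfc"].abs()

    per_position: dict[int, list[tuple[float, float]]] = {
        p: [] for p in range(1, operon_size + 1)}
    n_units = 0
    for unit in annotations.values():
        if len(unit.members) != operon_size:
            continue
        input_sets = [frozenset(tf for tf, _ in graph.in_inputs(g)) for g in unit.members]
        shared = input_sets[0]
        if not shared or any(s != shared for s in input_sets):
            continue
        used = False
        for tf in shared:
            if tf not in abs_lfc.index:
                continue
            x = float(abs_lfc.loc[tf])
            for pos, g in enumerate(unit.members, start=1):
                if g in abs_lfc.index:
                    per_position[pos].append((x, float(abs_lfc.loc[g])))
                    used = True
        n_units += used
    if n_units == 0:
        raise ValueError(f"no {operon_size}-gene operons with shared inputs and responses")

    fits = {}
    for pos, pts in per_position.items():
        if len(pts) >= 3:
            x, y = np.array(pts).T
            if np.ptp(x) > 0:
                fits[pos] = mc_ols(x, y, m=1, seed=0)

    comparisons = {}
    if n_units < 2:
        logger.warning("position_effect_test: single qualifying operon; ANCOVA skipped")
    else:
        positions = sorted(fits)
        for i, p1 in enumerate(positions):
            for p2 in positions[i + 1:]:
                a = np.array(per_position[p1]).T
                b = np.array(per_position[p2]).T
                comparisons[(p1, p2)] = ancova_compare((a[0], a[1]), (b[0], b[1]))
    return {"n_operons": n_units, "fits": fits, "ancova": comparisons,
            "pairs": per_position}
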
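"""Synthetic regulatory networks and staged RNAP-shift response simulation.

Generates signed TF networks with operon structure (heavy-tailed TF
out-degrees, categorical operon sizes) and simulates the two-stage response
model of a global RNA polymerase (RNAP) concentration shift:

* short term — every gene's log2 fold change follows the RNAP shift scaled
  by a gene-specific sensitivity, ``lfc_short(i) = s_i · log2(rho) + noise``;
* mid term — by the time input-TF *protein* levels have shifted, those
  shifts propagate one edge further,
  ``lfc_mid(i) = lfc_short(i) + w · Σ_j r_ji · lfc_short(j) + noise``
  over the gene's input TFs j, so a gene whose inputs are biased (activators
  and repressors do not cancel; bias b = |Σ r| > 0) responds more strongly
  than a balanced one;
* prior — a small-noise baseline before the RNAP change.

Emitted interaction/annotation tables use exactly the dialect consumed by
:mod:`tfnresponse.network`, and DE-style tables (replicate-mean LFC, SEM,
t-test p, BH-adjusted p) the dialect of :mod:`tfnresponse.de`, so the whole
pipeline is testable with no external data.  Timepoint labels 60/125/180 min
tag the prior/short/mid stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import network as net
from .network import InteractionRecord, TFNGraph, UnitAnnotation

__all__ = [
    "NetworkSpec",
    "SimParams",
    "TIMEPOINTS",
    "generate_network",
    "simulate_shift",
    "emit_de_table",
    "emit_rnap_timeseries",
    "run_scenario",
    "ScenarioResult",
]

#: Stage → timepoint label in minutes (prior / short-term / mid-term).
TIMEPOINTS = {"lfc_prior": 60.0, "lfc_short": 125.0, "lfc_mid": 180.0}


@dataclass(frozen=True)
class NetworkSpec:
    """Shape of a synthetic signed TF network.

    TF out-degrees follow a heavy-tailed (Zipf) law with tail exponent
    *out_degree_exponent*; targets are operons/TUs (sizes from
    *operon_size_probs* over 1..5) or TF-coding genes, so TF→TF edges exist
    and paths of length ≥ 2 occur.  Each interaction is activating with
    probability *frac_activating*, else repressing.
    """

    n_genes: int = 4000
    n_tfs: int = 300
    mean_in_degree: float = 1.5
    out_degree_exponent: float = 2.0
    frac_activating: float = 0.5
    operon_size_probs: tuple[float, ...] = (0.55, 0.20, 0.12, 0.08, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs cannot exceed n_genes")
        if not np.isclose(sum(self.operon_size_probs), 1.0):
            raise ValueError("operon_size_probs must sum to 1")
        if self.mean_in_degree > self.n_tfs:
            raise ValueError("mean in-degree cannot exceed the number of TFs")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the staged RNAP-shift response simulation.

    ``rnap_fold`` is the shifted/control RNAP concentration ratio rho (< 1
    for a dilution).  ``sens_sd`` sets the spread of the lognormal (mean-1)
    per-gene sensitivity s_i.  ``w`` is the propagation weight of input-TF
    short-term shifts onto their outputs at mid-term; ``w = 0`` switches the
    network influence off.  ``center_lfc`` subtracts each stage's gene-mean
    LFC, mimicking the zero-sum convention of median-of-ratios normalization.
    """

    rnap_fold: float = 0.5
    sens_sd: float = 0.3
    w: float = 0.4
    sigma_prior: float = 0.05
    sigma_short: float = 0.2
    sigma_mid: float = 0.2
    n_rep: int = 3
    sigma_rep: float = 0.2
    center_lfc: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rnap_fold <= 0:
            raise ValueError("rnap_fold must be positive")
        if min(self.sigma_prior, self.sigma_short, self.sigma_mid,
               self.sigma_rep) < 0 or self.w < 0:
            raise ValueError("noise levels and w must be non-negative")
        if self.n_rep < 2:
            raise ValueError("n_rep must be at least 2")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(spec: NetworkSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a signed TF network; return (interaction table, annotation table).

    Both frames use the external dialects
    (``regulator/target/target_kind/effect`` with '+'/'-' tokens and
    ``unit_id/unit_kind/gene/position``), byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    tf_genes = genes[:spec.n_tfs]
    other = genes[spec.n_tfs:]

    # partition non-TF genes into operons/TUs
    sizes = []
    remaining = len(other)
    while remaining > 0:
        s = int(rng.choice(len(spec.operon_size_probs), p=spec.operon_size_probs)) + 1
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    units: list[tuple[str, list[str]]] = []
    pos = 0
    for ui, s in enumerate(sizes, start=1):
        units.append((f"op{ui:04d}", other[pos:pos + s]))
        pos += s

    # target pool: every unit plus the TF-coding genes themselves
    pool: list[tuple[str, str, int]] = []          # (target name, kind, fan-out)
    for uid, members in units:
        if len(members) == 1:
            pool.append((members[0], "gene", 1))
        else:
            pool.append((uid, "operon", len(members)))
    for tf in tf_genes:
        pool.append((tf, "tf", 1))
    fanout = np.array([f for _, _, f in pool], float)
    mean_fanout = fanout.mean()

    # number of interaction records so the gene-level mean in-degree ~ target
    n_records = int(round(spec.n_genes * spec.mean_in_degree / mean_fanout))
    weights = rng.zipf(spec.out_degree_exponent, size=spec.n_tfs).astype(float)
    per_tf = rng.multinomial(n_records, weights / weights.sum())
    per_tf = np.minimum(per_tf, len(pool))

    rows = []
    for ti, tf in enumerate(tf_genes):
        k = int(per_tf[ti])
        if k == 0:
            continue
        chosen = rng.choice(len(pool), size=k, replace=False)
        signs = rng.random(k) < spec.frac_activating
        for ci, act in zip(chosen, signs):
            tgt, kind, _ = pool[ci]
            rows.append((tf, tgt, kind, "+" if act else "-"))
    interactions = pd.DataFrame(rows, columns=["regulator", "target",
                                               "target_kind", "effect"])

    ann_rows = []
    for uid, members in units:
        if len(members) > 1:
            for p, g in enumerate(members, start=1):
                ann_rows.append((uid, "operon", g, p))
    annotations = pd.DataFrame(ann_rows, columns=["unit_id", "unit_kind",
                                                  "gene", "position"])
    return interactions, annotations


def simulate_shift(graph: TFNGraph, params: SimParams,
                   genes: list[str] | None = None) -> pd.DataFrame:
    """Simulate per-gene true LFCs at the prior/short/mid stages.

    *genes* is the full gene universe (defaults to the graph's nodes); genes
    without inputs respond to the RNAP shift only.
    """
    rng = np.random.default_rng(params.seed)
    if genes is None:
        genes = sorted(graph.nodes)
    genes = [net.normalize_name(g) for g in genes]
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    # lognormal sensitivity with mean 1 and sd ~ sens_sd
    sln = np.sqrt(np.log1p(params.sens_sd ** 2))
    s = rng.lognormal(mean=-sln ** 2 / 2, sigma=sln, size=n)

    shift = np.log2(params.rnap_fold)
    lfc_short = s * shift + rng.normal(0, params.sigma_short, n)

    prop = np.zeros(n)
    for u, v, r in graph.edges():
        if v in idx and u in idx and r != 0:
            prop[idx[v]] += r * lfc_short[idx[u]]
    lfc_mid = lfc_short + params.w * prop + rng.normal(0, params.sigma_mid, n)
    lfc_prior = rng.normal(0, params.sigma_prior, n)

    out = pd.DataFrame({"lfc_prior": lfc_prior, "lfc_short": lfc_short,
                        "lfc_mid": lfc_mid}, index=pd.Index(genes, name="gene"))
    if params.center_lfc:
        out = out - out.mean(axis=0)
    return out


def emit_de_table(true_responses: pd.DataFrame, stage: str, params: SimParams,
                  condition: str = "synthetic", seed: int | None = None
                  ) -> pd.DataFrame:
    """Turn one stage's true LFCs into a DE-style result table.

    Each gene gets ``n_rep`` replicate observations (true LFC plus
    Normal(0, sigma_rep) noise); the reported LFC is the replicate mean, the
    SE the replicate SEM, the p-value a t-statistic mean/SEM at
    ``n_rep − 1`` df, and the adjusted p-value the Benjamini–Hochberg FDR
    across genes.  Columns follow the DE-table dialect.
    """
    if stage not in TIMEPOINTS:
        raise ValueError(f"stage must be one of {sorted(TIMEPOINTS)}")
    rng = np.random.default_rng(params.seed + 1 if seed is None else seed)
    truth = true_responses[stage].to_numpy(float)
    n = len(truth)
    reps = truth[:, None] + rng.normal(0, params.sigma_rep, (n, params.n_rep))
    lfc = reps.mean(axis=1)
    se = reps.std(axis=1, ddof=1) / np.sqrt(params.n_rep)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.inf * np.sign(lfc))
    p = 2 * stats.t.sf(np.abs(t), df=params.n_rep - 1)
    p = np.where(np.isfinite(t), p, np.where(lfc == 0, 1.0, 0.0))
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": true_responses.index,
        "log2FoldChange": lfc,
        "lfcSE": se,
        "pvalue": p,
        "padj": padj,
    })


def emit_rnap_timeseries(a: float, c: float, t0: float, k: float, sem: float,
                         timepoints, seed: int | None = None) -> pd.DataFrame:
    """Noisy logistic RNAP-abundance time series with per-point SEM.

    Emulates a flow-cytometry mean-reporter-signal curve sampled every few
    minutes: logistic values a + (c − a)/(1 + exp(−k(t − t0))) plus
    Normal(0, sem) noise, with the stated SEM attached — ready for
    :class:`~tfnresponse.regression.SigmoidModel`.
    """
    t = np.asarray(timepoints, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly ascending")
    rng = np.random.default_rng(seed)
    y = a + (c - a) / (1.0 + np.exp(-k * (t - t0))) + rng.normal(0, sem, len(t))
    return pd.DataFrame({"t": t, "y": y, "y_sem": np.full(len(t), float(sem))})


@dataclass
class ScenarioResult:
    """Everything one synthetic scenario produces, ready for the pipeline."""

    interactions: pd.DataFrame
    annotations: pd.DataFrame
    graph: TFNGraph
    units: dict[str, UnitAnnotation]
    genes: list[str]
    profiles: pd.DataFrame
    true_responses: pd.DataFrame
    de_tables: dict[float, pd.DataFrame]          # timepoint → DE table


def run_scenario(spec: NetworkSpec, params: SimParams) -> ScenarioResult:
    """Generate a network, simulate the shift, and emit DE tables per stage.

    The interaction/annotation frames go through the same parsing and
    operon-expansion code paths as external data.
    """
    interactions, annotations = generate_network(spec)
    records = net.records_from_frame(interactions)
    units = net.annotations_from_frame(annotations) if len(annotations) else {}
    graph = net.expand_to_gene_graph(records, units)
    genes = _gene_names(spec.n_genes)
    profiles = net.regulatory_profile(graph, genes)
    true = simulate_shift(graph, params, genes=genes)
    de_tables = {}
    for stage, tp in TIMEPOINTS.items():
        tbl = emit_de_table(true, stage, params,
                            seed=params.seed * 8 + int(tp))
        tbl["condition"] = "synthetic"
        tbl["timepoint"] = tp
        de_tables[tp] = tbl.rename(columns={"log2FoldChange": "lfc",
                                            "lfcSE": "lfc_se",
                                            "padj": "fdr"})
    return ScenarioResult(interactions=interactions, annotations=annotations,
                          graph=graph, units=units, genes=genes,
                          profiles=profiles, true_responses=true,
                          de_tables=de_tables)
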
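"""Signed regulation network from an ensemble of fitted parameter sets.

Each interaction parameter (entries of the interaction matrix T, and the
maternal influences m) is examined across the ensemble: if it is strictly
positive in at least a threshold fraction of the best-fit sets (default 90%),
an activation edge is added to the network; strictly negative with the same
consistency yields an inhibition edge.  Exact zeros count toward neither
sign.  Because the fitted profiles are unit-normalized, edge signs are
meaningful but absolute regulatory strengths are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import networkx as nx
import numpy as np
import pandas as pd

from . import gene_circuit as gc
from .estimation import Ensemble

DEFAULT_THRESHOLD = 0.9


class NetworkInferenceError(ValueError):
    pass


def _param_values(source) -> tuple[list[gc.GeneCircuitParams], tuple[str, ...], str]:
    if isinstance(source, Ensemble):
        return source.param_sets(), source.gene_names, source.maternal_name
    sets = list(source)
    if not sets:
        raise NetworkInferenceError("empty ensemble")
    return sets, sets[0].gene_names, "maternal"


def sign_consistency(source, maternal_name: str | None = None) -> pd.DataFrame:
    """Fractions of strictly positive / negative / zero values per
    interaction parameter (T entries and maternal influences m).

    ``source`` is an :class:`~nemagrn.estimation.Ensemble` or a sequence of
    parameter sets.  Fractions sum to 1 for each parameter.
    """
    sets, gene_names, mat = _param_values(source)
    if maternal_name is not None:
        mat = maternal_name
    n = len(gene_names)
    rows = []
    ids = [("T", i, j) for i in range(n) for j in range(n)] + \
          [("m", i) for i in range(n)]
    N = len(sets)
    for pid in ids:
        values = np.array([p.scalar(pid) for p in sets])
        rows.append({
            "parameter": gc.parameter_label(pid, gene_names, mat),
            "block": pid[0],
            "source": gene_names[pid[2]] if pid[0] == "T" else mat,
            "target": gene_names[pid[1]],
            "frac_positive": float(np.sum(values > 0) / N),
            "frac_negative": float(np.sum(values < 0) / N),
            "frac_zero": float(np.sum(values == 0) / N),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if N > 1 else 0.0,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str  # "activation" | "inhibition"
    consistency: float
    mean: float
    sd: float


@dataclass(frozen=True)
class RegulationNetwork:
    """Signed directed edges passing the sign-consistency threshold."""

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    threshold: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.edges],
                            columns=["source", "target", "sign", "consistency",
                                     "mean", "sd"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, consistency=e.consistency,
                       mean=e.mean, sd=e.sd)
        return g

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def infer_edges(source, threshold: float = DEFAULT_THRESHOLD,
                maternal_name: str | None = None) -> RegulationNetwork:
    """Build the signed network from ensemble sign consistencies.

    An activation edge is added where the positive fraction is >= threshold,
    an inhibition edge where the negative fraction is >= threshold; all other
    parameters contribute no edge.  Self-edges (diagonal of T) are allowed.
    """
    if not 0.5 < threshold <= 1.0:
        raise NetworkInferenceError("threshold must lie in (0.5, 1]")
    table = sign_consistency(source, maternal_name)
    sets, gene_names, mat = _param_values(source)
    if maternal_name is not None:
        mat = maternal_name
    edges = []
    for _, row in table.iterrows():
        if row["frac_positive"] >= threshold:
            sign, cons = "activation", row["frac_positive"]
        elif row["frac_negative"] >= threshold:
            sign, cons = "inhibition", row["frac_negative"]
        else:
            continue
        edges.append(Edge(row["source"], row["target"], sign, float(cons),
                          float(row["mean"]), float(row["sd"])))
    nodes = tuple(gene_names) + (mat,)
    return RegulationNetwork(nodes, tuple(edges), threshold)


def parameter_statistics(source) -> pd.DataFrame:
    """Sample mean and standard deviation (n-1 denominator) of every scalar
    parameter across the ensemble, in long scatter-plot-ready format."""
    sets, gene_names, mat = _param_values(source)
    if len(sets) < 2:
        raise NetworkInferenceError("statistics need an ensemble of >= 2 runs")
    n = len(gene_names)
    rows = []
    for pid in gc.parameter_ids(n, gc.SIMPLIFIED):
        values = np.array([p.scalar(pid) for p in sets])
        rows.append({"parameter": gc.parameter_label(pid, gene_names, mat),
                     "block": pid[0], "mean": float(values.mean()),
                     "sd": float(values.std(ddof=1))})
    return pd.DataFrame(rows)
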
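"""Thresholded correlation network of baseline covariates and outcomes.

Edges connect variable pairs whose (Spearman by default) correlation
exceeds the threshold in absolute value; nodes carry a class (baseline or
outcome) and an importance weight — baselines from the counterfactual
variable-importance table summed across outcomes, outcomes by their degree
in the thresholded graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


def correlation_matrix(df: pd.DataFrame, variables, method: str = "spearman") -> pd.DataFrame:
    """Symmetric correlation matrix with unit diagonal.

    A constant variable's correlations are undefined and set to 0 with a
    warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    variables = list(variables)
    sub = df[variables].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 complete records")
    corr = sub.corr(method=method)
    constant = [v for v in variables if sub[v].nunique() <= 1]
    if constant:
        warnings.warn(f"constant variable(s) {constant}; correlations set to 0")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class CorrelationNetwork:
    graph: nx.Graph
    threshold: float

    def edges_dataframe(self) -> pd.DataFrame:
        rows = [
            {"var_a": a, "var_b": b, "r": d["r"], "edge_class": d["edge_class"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "edge_class"])

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_network(
    matrix: pd.DataFrame,
    threshold: float = 0.3,
    node_classes: dict[str, str] | None = None,
    importance: pd.DataFrame | None = None,
) -> CorrelationNetwork:
    """Graph with an edge for every |r| strictly above the threshold.

    ``node_classes`` maps variable → 'baseline' | 'outcome'; ``importance``
    is an (outcome × covariate) table of normalized importances whose
    column sums weight the baseline nodes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    node_classes = node_classes or {}
    g = nx.Graph(threshold=threshold)
    variables = list(matrix.columns)
    for v in variables:
        g.add_node(v, node_class=node_classes.get(v, "baseline"))
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            r = float(matrix.loc[a, b])
            if abs(r) > threshold:
                ca, cb = sorted((g.nodes[a]["node_class"], g.nodes[b]["node_class"]))
                g.add_edge(a, b, r=r, edge_class=f"{ca}-{cb}")
    for v in variables:
        if g.nodes[v]["node_class"] == "outcome":
            g.nodes[v]["importance"] = float(g.degree(v))
        elif importance is not None and v in importance.columns:
            g.nodes[v]["importance"] = float(importance[v].sum())
        else:
            g.nodes[v]["importance"] = 0.0
    return CorrelationNetwork(graph=g, threshold=threshold)
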
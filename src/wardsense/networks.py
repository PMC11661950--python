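"""Daily weighted interaction graphs and node metrics.

One undirected graph per calendar day: nodes are the participants whose badge
was active that day, and a pair is connected when its summed interaction
duration exceeds 10 minutes, with edge weight the common logarithm of that
total (in minutes).  Two node metrics are computed per day:

* eigenvector centrality — the i-th component of the Perron vector x of the
  weighted adjacency A (Ax = lambda x with lambda the largest eigenvalue),
  normalised to unit Euclidean norm;
* weighted clustering coefficient — the geometric-mean triangle intensity

      c_i = 1 / (deg_i (deg_i - 1)) * sum_{j,k} (w'_ij w'_ik w'_jk)^(1/3)

  over ordered neighbour pairs, with weights normalised by the maximum edge
  weight in that day's graph (w'_ij = w_ij / max w), so c_i lies in [0, 1]
  and is invariant to rescaling all raw weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from wardsense.errors import ComputationError, ValidationError

DEFAULT_MIN_EDGE_MINUTES = 10.0


@dataclass
class DailyGraph:
    """Weighted undirected participant graph for one day.

    graph: networkx.Graph whose edges carry ``minutes`` (raw summed duration)
    and ``weight`` (log10 minutes).  Node order for matrix views is the
    sorted participant list.
    """

    day: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def adjacency(self) -> np.ndarray:
        """Weighted adjacency matrix in node order (log10-minute weights)."""
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, weight="weight")

    def normalized_adjacency(self) -> np.ndarray:
        """Weights divided by the day's maximum weight; zeros when edgeless."""
        a = self.adjacency()
        m = a.max()
        return a / m if m > 0 else a

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (self.day, a, b, d["minutes"], d["weight"])
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["day", "a", "b", "minutes", "weight"])


def build_daily_graph(
    events: pd.DataFrame,
    active_participants: list[str],
    day: str | None = None,
    min_edge_minutes: float = DEFAULT_MIN_EDGE_MINUTES,
) -> DailyGraph:
    """Build the weighted graph for one day from that day's events.

    Nodes are all badge-active participants (isolates included).  An edge is
    added when the pair's summed event duration strictly exceeds
    ``min_edge_minutes``; its weight is log10 of the total in minutes.
    """
    g = nx.Graph()
    g.add_nodes_from(active_participants)
    if day is None:
        day = str(events["day"].iloc[0]) if len(events) else ""
    if len(events):
        active = set(active_participants)
        stray = (set(events["a"]) | set(events["b"])) - active
        if stray:
            raise ValidationError(f"event participant(s) not badge-active on {day}: {sorted(stray)}")
        totals = events.groupby(["a", "b"])["duration_s"].sum() / 60.0
        for (a, b), minutes in totals.items():
            if minutes > min_edge_minutes:
                g.add_edge(a, b, minutes=float(minutes), weight=float(np.log10(minutes)))
    return DailyGraph(day=day, graph=g)


def eigenvector_centrality(
    dg: DailyGraph, tol: float = 1e-10, max_iter: int = 1000, dense_cutoff: int = 64
) -> dict[str, float]:
    """Unit-norm Perron vector of the weighted adjacency; isolates get 0.

    Graphs up to ``dense_cutoff`` nodes (every ward-sized graph) use a dense
    eigendecomposition, which is exact and immune to the slow mixing of power
    iteration on near-degenerate spectra; larger graphs use power iteration
    from a uniform positive start with the dense route as a fallback when the
    iteration has not converged (for instance on disconnected graphs whose
    leading eigenvalue is attained by more than one component).
    """
    nodes = dg.nodes
    a = dg.adjacency()
    n = a.shape[0]
    if n == 0:
        return {}
    if not a.any():
        return {v: 0.0 for v in nodes}

    converged = False
    if n > dense_cutoff:
        x = np.ones(n) / np.sqrt(n)
        for _ in range(max_iter):
            y = a @ x
            norm = np.linalg.norm(y)
            if norm == 0:
                break
            y /= norm
            if np.linalg.norm(y - x) < tol:
                x, converged = y, True
                break
            x = y
    if not converged:
        try:
            vals, vecs = np.linalg.eigh(a)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise ComputationError(f"centrality failed on day {dg.day}: {err}") from err
        x = vecs[:, np.argmax(vals)]
    if x.sum() < 0:
        x = -x
    x = np.clip(x, 0.0, None)
    norm = np.linalg.norm(x)
    if norm == 0:  # pragma: no cover - Perron vector of a nonneg matrix
        raise ComputationError(f"degenerate principal eigenvector on day {dg.day}")
    x /= norm
    deg = (a > 0).sum(axis=1)
    x[deg == 0] = 0.0
    return dict(zip(nodes, x.astype(float)))


def clustering_coefficients(dg: DailyGraph) -> dict[str, float]:
    """Weighted clustering per node, max-normalised geometric triangle mean.

    Nodes with degree below 2 get 0.  Computed via the cube-root adjacency:
    the i-th diagonal entry of (W'^(1/3))^3 enumerates ordered neighbour
    pairs (j, k) with the full triangle product.
    """
    nodes = dg.nodes
    if not nodes:
        return {}
    w = dg.normalized_adjacency()
    c3 = np.cbrt(w)
    num = np.diagonal(c3 @ c3 @ c3).copy()
    deg = (w > 0).sum(axis=1)
    denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return dict(zip(nodes, np.clip(c, 0.0, 1.0).astype(float)))


def node_metrics(dg: DailyGraph) -> pd.DataFrame:
    """Tidy per-node metric table for one daily graph."""
    cent = eigenvector_centrality(dg)
    clus = clustering_coefficients(dg)
    deg = dict(nx.degree(dg.graph))
    return pd.DataFrame(
        {
            "participant": dg.nodes,
            "day": dg.day,
            "eigenvector_centrality": [cent[v] for v in dg.nodes],
            "clustering": [clus[v] for v in dg.nodes],
            "degree": [deg[v] for v in dg.nodes],
        }
    )


def daily_graphs_from_events(
    events: pd.DataFrame,
    active: pd.DataFrame,
    min_edge_minutes: float = DEFAULT_MIN_EDGE_MINUTES,
    omit_staff: bool = False,
    roster: pd.DataFrame | None = None,
) -> list[DailyGraph]:
    """One graph per day with badge activity.

    With ``omit_staff`` the graphs are rebuilt over patients only (events with
    a staff member involved are dropped), the robustness variant of the main
    analysis; ``roster`` is then required.
    """
    if omit_staff:
        if roster is None:
            raise ValidationError("omit_staff requires a roster")
        patients = set(roster.loc[roster["role"] == "patient", "participant"])
        events = events[events["a"].isin(patients) & events["b"].isin(patients)]
        active = active[active["participant"].isin(patients)]
    graphs = []
    for day, act_day in active.groupby("day", sort=True):
        ev_day = events[events["day"] == day] if len(events) else events
        graphs.append(
            build_daily_graph(
                ev_day, act_day["participant"].tolist(), day=day, min_edge_minutes=min_edge_minutes
            )
        )
    return graphs


def metrics_table(graphs: list[DailyGraph]) -> pd.DataFrame:
    """Concatenated node metrics across days."""
    if not graphs:
        return pd.DataFrame(
            columns=["participant", "day", "eigenvector_centrality", "clustering", "degree"]
        )
    return pd.concat([node_metrics(g) for g in graphs], ignore_index=True)
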
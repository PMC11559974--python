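"""Transport networks from settled-particle flow maps.

Each settled particle contributes exactly one transition from its spawn
cell to its settlement cell — the flow map.  Intermediate cells visited
along the trajectory are deliberately discarded.  Normalizing each spawn
cell's outgoing transition counts gives a directed, weighted, row-stochastic
network that approximates a Markov chain on the hexagonal bins.

Particles settling in cells from which no retained particle spawned are
deleted (iterated to a fixed point, since each deletion can empty a spawn
cell) so that every node keeps at least one out-link and the transition
matrix stays singly stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dispersal import SETTLED, ParticleCohort
from .hexgrid import HexGrid


@dataclass
class FlowMap:
    """One (spawn_cell, settle_cell) pair per surviving particle."""

    pairs: pd.DataFrame  # columns: particle_id, spawn_cell, settle_cell
    case: str | None = None

    def __post_init__(self):
        need = {"particle_id", "spawn_cell", "settle_cell"}
        if not need.issubset(self.pairs.columns):
            raise ValueError(f"flow map needs columns {sorted(need)}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def spawn_cells(self) -> set:
        return set(self.pairs["spawn_cell"].unique())

    @property
    def settle_cells(self) -> set:
        return set(self.pairs["settle_cell"].unique())

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, case=None) -> "FlowMap":
        return cls(pairs=pd.read_csv(path), case=case)


def build_flow_map(cohort: ParticleCohort, grid: HexGrid, case: str | None = None) -> FlowMap:
    """Reduce a settlement-resolved cohort to its flow map."""
    if cohort.settle_lon is None:
        raise ValueError("cohort settlement is unresolved")
    settled = np.flatnonzero(cohort.status == SETTLED)
    spawn = grid.cell(cohort.spawn_lon[settled], cohort.spawn_lat[settled])
    settle = grid.cell(cohort.settle_lon[settled], cohort.settle_lat[settled])
    df = pd.DataFrame(
        {"particle_id": settled, "spawn_cell": spawn, "settle_cell": settle}
    )
    return FlowMap(pairs=df, case=case or cohort.case)


def prune_to_closed(flow_map: FlowMap) -> FlowMap:
    """Delete pairs whose settle cell nobody spawns in, to a fixed point.

    One pass is insufficient: deleting pairs can empty a spawn cell, whose
    settlers must then be deleted too.  On return the settle-cell set is a
    subset of the spawn-cell set (possibly both empty).
    """
    if len(flow_map) == 0:
        raise ValueError("empty flow map")
    df = flow_map.pairs
    while True:
        spawned = set(df["spawn_cell"].unique())
        keep = df["settle_cell"].isin(spawned)
        if keep.all():
            break
        df = df[keep]
        if len(df) == 0:
            warnings.warn("pruning removed every particle; empty flow map")
            break
    return FlowMap(pairs=df.reset_index(drop=True), case=flow_map.case)


@dataclass
class TransportNetwork:
    """Directed weighted network on hexagonal cells.

    Integer transition counts are the stored truth; link probabilities
    (count / row total) are derived on demand.  Every node has out-links
    and rows sum to one, so the weight matrix is row-stochastic.
    """

    nodes: np.ndarray  # sorted cell ids
    counts: pd.DataFrame  # columns: src, dst, count
    case: str | None = None
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._index is None:
            self._index = {int(c): i for i, c in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_particles(self) -> int:
        return int(self.counts["count"].sum())

    def out_totals(self) -> pd.Series:
        return self.counts.groupby("src")["count"].sum()

    def edges(self) -> pd.DataFrame:
        """Edge list with derived probabilities (src, dst, count, probability)."""
        df = self.counts.copy()
        tot = df.groupby("src")["count"].transform("sum")
        df["probability"] = df["count"] / tot
        return df

    def transition_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(nodes, dense row-stochastic matrix W) with W[i, j] = P(i -> j)."""
        W = np.zeros((self.n_nodes, self.n_nodes))
        e = self.edges()
        W[
            [self._index[int(s)] for s in e["src"]],
            [self._index[int(d)] for d in e["dst"]],
        ] = e["probability"].to_numpy()
        return self.nodes, W

    # -- I/O ---------------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(int(c) for c in self.nodes)
        for row in self.edges().itertuples():
            g.add_edge(int(row.src), int(row.dst),
                       weight=float(row.probability), count=int(row.count))
        return g

    def write_pajek(self, path) -> None:
        nx.write_pajek(self.to_networkx(), path)

    def write_tsv(self, path) -> None:
        self.edges().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, case=None) -> "TransportNetwork":
        df = pd.read_csv(path, sep="\t")
        counts = df[["src", "dst", "count"]].copy()
        nodes = np.array(sorted(set(counts["src"])), dtype=np.int64)
        return cls(nodes=nodes, counts=counts, case=case)


def to_network(flow_map: FlowMap, case: str | None = None) -> TransportNetwork:
    """Aggregate a pruned flow map into a transport network.

    Raises on un-pruned input (a settle cell without spawners would leave a
    node with no out-links, breaking row-stochasticity).
    """
    df = flow_map.pairs
    if len(df) == 0:
        raise ValueError("cannot build a network from an empty flow map")
    spawned = set(df["spawn_cell"].unique())
    dangling = set(df["settle_cell"].unique()) - spawned
    if dangling:
        raise ValueError(
            f"flow map is not closed ({len(dangling)} settle cells never spawn); "
            "apply prune_to_closed first"
        )
    counts = (
        df.groupby(["spawn_cell", "settle_cell"], sort=True)
        .size()
        .reset_index(name="count")
        .rename(columns={"spawn_cell": "src", "settle_cell": "dst"})
    )
    nodes = np.array(sorted(spawned), dtype=np.int64)
    return TransportNetwork(nodes=nodes, counts=counts, case=case or flow_map.case)
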
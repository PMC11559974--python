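"""Community quality metrics for transport-network partitions.

Per community the module reports:

* mixing parameter M — how uniformly particles spread from each member bin
  to the other bins of the community (1 = perfectly even spreading,
  0 = deterministic routing), operationalized as the mean over member
  nodes of the base-2 entropy of the within-community renormalized
  transition distribution divided by log2(community size);
* coherence ratio rho — fraction of particles spawned in the community
  that settled in it (retention; outward border strength);
* fortress ratio F — fraction of particles settled in the community that
  also spawned in it (self-recruitment; inward border strength);
* a classification into sink / source / permeable / impermeable from the
  joint magnitudes of rho and F.

Also provided: bin-weighted global averages, the community-level
connectivity matrix (row-stochastic; its diagonal is the coherence ratio
by construction), and boundary persistence of bins over a partition
ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hexgrid import HexGrid
from .mapeq import Partition
from .transportnet import FlowMap, TransportNetwork

_EPS = 1e-9  # float guard so printed 2-decimal ratios compare as intended


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds: source/sink when |rho - F| >= delta;
    impermeable (permeable) when both >= (both <) the high cutoff h."""

    delta: float = 0.05
    h: float = 0.95

    def __post_init__(self):
        if not 0 < self.delta < 1 or not 0 < self.h < 1:
            raise ValueError("thresholds must be in (0, 1)")


def classify(rho: float, F: float, config: ClassifierConfig = ClassifierConfig()) -> str:
    """Label a community from its coherence and fortress ratios.

    Precedence: sink if rho - F >= delta (high retention, settlers mostly
    external); source if F - rho >= delta; else impermeable if both ratios
    >= h, permeable if both < h, otherwise unclassified.
    """
    if not (0 <= rho <= 1 and 0 <= F <= 1):
        raise ValueError("ratios must be in [0, 1]")
    if rho - F >= config.delta - _EPS:
        return "sink"
    if F - rho >= config.delta - _EPS:
        return "source"
    if min(rho, F) >= config.h - _EPS:
        return "impermeable"
    if max(rho, F) < config.h:
        return "permeable"
    return "unclassified"


def _counts(flow_map: FlowMap, partition: Partition):
    """Spawn/settle community arrays for every flow-map pair."""
    comm = partition.as_dict()
    try:
        spawn = np.array([comm[int(c)] for c in flow_map.pairs["spawn_cell"]])
        settle = np.array([comm[int(c)] for c in flow_map.pairs["settle_cell"]])
    except KeyError as err:
        raise ValueError(f"flow-map cell {err} has no community assignment") from None
    return spawn, settle


def coherence(flow_map: FlowMap, partition: Partition, community: int) -> float:
    """Fraction of the community's spawned particles that settled in it."""
    spawn, settle = _counts(flow_map, partition)
    mine = spawn == community
    if not mine.any():
        raise ValueError(f"community {community} spawns no particles")
    return float((mine & (settle == community)).sum() / mine.sum())


def fortress(flow_map: FlowMap, partition: Partition, community: int) -> float:
    """Fraction of the community's settled particles that spawned in it."""
    spawn, settle = _counts(flow_map, partition)
    mine = settle == community
    if not mine.any():
        warnings.warn(f"community {community} receives no settlers; fortress undefined")
        return float("nan")
    return float((mine & (spawn == community)).sum() / mine.sum())


def mixing(network: TransportNetwork, partition: Partition, community: int) -> float:
    """Mean normalized within-community spreading entropy of member nodes.

    For each member node the outgoing flow to community members (self-loops
    included) is renormalized to a distribution; its base-2 entropy over
    log2(n_c) averages to the mixing parameter.  Uniform spreading to every
    member gives 1; deterministic routing gives 0.  Singleton communities
    return 1 by convention.  Nodes with no internal outflow contribute 0.
    """
    members = set(int(c) for c in partition.members(community))
    if not members:
        raise ValueError(f"community {community} is empty")
    n_c = len(members)
    if n_c == 1:
        return 1.0
    edges = network.counts
    internal = edges[
        edges["src"].isin(members) & edges["dst"].isin(members)
    ]
    by_src = {src: grp["count"].to_numpy(dtype=float) for src, grp in internal.groupby("src")}
    hmax = np.log2(n_c)
    total = 0.0
    for node in members:
        w = by_src.get(node)
        if w is None or w.sum() == 0:
            continue
        q = w / w.sum()
        h = -(q * np.log2(q)).sum()
        total += h / hmax
    return float(total / n_c)


def community_quality(
    flow_map: FlowMap,
    network: TransportNetwork,
    partition: Partition,
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Per-community table: n_bins, mixing, coherence, fortress, label."""
    spawn, settle = _counts(flow_map, partition)
    rows = []
    for m in sorted(np.unique(partition.labels)):
        n_bins = int((partition.labels == m).sum())
        sp = spawn == m
        se = settle == m
        rho = float((sp & se).sum() / sp.sum()) if sp.any() else np.nan
        if se.any():
            F = float((sp & se).sum() / se.sum())
        else:
            warnings.warn(f"community {m} receives no settlers; fortress undefined")
            F = np.nan
        M = mixing(network, partition, m)
        label = classify(rho, F, config) if np.isfinite(rho) and np.isfinite(F) else "unclassified"
        rows.append(
            {"community": int(m), "n_bins": n_bins, "mixing": M,
             "coherence": rho, "fortress": F, "classification": label}
        )
    return pd.DataFrame(rows)


def global_quality(quality: pd.DataFrame) -> tuple[float, float, float]:
    """Bin-count-weighted global (mixing, coherence, fortress)."""
    w = quality["n_bins"].to_numpy(dtype=float)
    w = w / w.sum()
    return (
        float((w * quality["mixing"]).sum()),
        float((w * quality["coherence"]).sum()),
        float((w * quality["fortress"]).sum()),
    )


def connectivity_matrix(flow_map: FlowMap, partition: Partition) -> pd.DataFrame:
    """Community-to-community transition proportions.

    Rows are spawn communities, columns settlement communities; each row is
    the distribution of where that community's particles settled, so the
    matrix is row-stochastic and its diagonal equals the coherence ratio.
    """
    spawn, settle = _counts(flow_map, partition)
    comms = sorted(np.unique(partition.labels))
    k = len(comms)
    cidx = {m: i for i, m in enumerate(comms)}
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, ([cidx[m] for m in spawn], [cidx[m] for m in settle]), 1)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        mat = counts / totals
    return pd.DataFrame(mat, index=comms, columns=comms)


def boundary_bins(grid: HexGrid, partition: Partition) -> np.ndarray:
    """Boolean mask over partition.nodes: bin adjacent to another community.

    A bin is a boundary bin if at least one of its grid neighbors belongs
    to the network and to a different community; neighbors outside the
    network (land, unoccupied) do not count.
    """
    comm = partition.as_dict()
    nbrs = grid.neighbors_array(partition.nodes)
    out = np.zeros(len(partition.nodes), dtype=bool)
    for i, (c, row) in enumerate(zip(partition.nodes, nbrs)):
        mine = comm[int(c)]
        out[i] = any(
            comm.get(int(nb), mine) != mine for nb in row
        )
    return out


def boundary_persistence(grid: HexGrid, ensemble: list[Partition]) -> pd.DataFrame:
    """Fraction of ensemble partitions in which each bin is a boundary bin."""
    if not ensemble:
        raise ValueError("empty partition ensemble")
    ref = set(int(c) for c in ensemble[0].nodes)
    for part in ensemble[1:]:
        if set(int(c) for c in part.nodes) != ref:
            raise ValueError("ensemble partitions cover different cell sets")
    nodes = ensemble[0].nodes
    frac = np.zeros(len(nodes))
    for part in ensemble:
        order = {int(c): i for i, c in enumerate(part.nodes)}
        mask = boundary_bins(grid, part)
        frac += mask[[order[int(c)] for c in nodes]]
    frac /= len(ensemble)
    return pd.DataFrame({"cell_id": nodes, "persistence": frac})
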
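"""Graph-based assembly analysis of co-assembly trajectories.

Peptides are nodes; two peptides are connected when they share at least
five backbone hydrogen bonds or at least two hydrophobic sidechain
contacts.  Connected components are classified each frame as free
monomers, disordered oligomers, beta-sheets (an open ladder of
hydrogen-bonded strands) or beta-barrels (the ladder closed into a
cycle), giving the free/oligomer/fibril kinetics curves and the
barrel-to-sheet transition events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from catchsim.dmd_engine import CGSystem, Frame, Trajectory

__all__ = [
    "ConnectivityGraph",
    "ClusterReport",
    "pairwise_links",
    "connectivity_graph",
    "clusters",
    "classify_cluster",
    "kinetics_timeseries",
    "write_edge_list",
    "hbond_halftime",
    "HB_MIN",
    "PHOB_MIN",
    "SHEET_MIN",
]


def write_edge_list(cg: "ConnectivityGraph", path) -> None:
    """Export a frame's peptide connectivity as a plain edge-list file."""
    with open(path, "w") as fh:
        fh.write(f"# time={cg.time} n_peptides={cg.n_peptides}\n")
        fh.write("# p q n_hbonds n_hydrophobic\n")
        for p, q, data in cg.graph.edges(data=True):
            fh.write(f"{p} {q} {data.get('n_hbonds', 0)} "
                     f"{data.get('n_hydrophobic', 0)}\n")


def hbond_halftime(series: "pd.DataFrame") -> float:
    """Time at which the hydrogen-bond count first reaches half its final
    value; infinity when no bonds formed.

    Accepts either an engine sample table (column ``n_hbonds``) or a
    kinetics series (column ``total_hbonds``).
    """
    col = "n_hbonds" if "n_hbonds" in series else "total_hbonds"
    counts = series[col].to_numpy()
    times = series["time"].to_numpy()
    if len(counts) == 0 or counts[-1] < 1:
        return float("inf")
    target = 0.5 * counts[-1]
    return float(times[int(np.argmax(counts >= target))])

#: Connection rule: at least five hydrogen bonds ...
HB_MIN = 5
#: ... or at least two hydrophobic interactions between a peptide pair
PHOB_MIN = 2
#: Minimum strands for an ordered ladder to count as a beta-sheet
SHEET_MIN = 4


@dataclass
class ConnectivityGraph:
    """Peptide-level connectivity of one frame."""

    graph: nx.Graph
    time: float

    @property
    def n_peptides(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class ClusterReport:
    """Cluster census and kinetics series of a trajectory.

    ``series`` has one row per frame with peptide counts in each state
    (free / oligomeric / fibrillar) plus matching cluster counts and the
    total hydrogen-bond number; ``transitions`` lists (time, members,
    from_class, to_class) whenever a persistent cluster changes class.
    """

    frames: list[dict]
    series: pd.DataFrame
    transitions: list[tuple[float, frozenset, str, str]]

    def final_classes(self) -> dict[frozenset, str]:
        last = self.frames[-1]
        return {frozenset(c["members"]): c["class"] for c in last["clusters"]}


def pairwise_links(
    frame: Frame, system: CGSystem, max_phob_range: float | None = None,
    box: float | None = None,
) -> dict[tuple[int, int], tuple[int, int]]:
    """Per peptide pair: (number of H-bonds, number of hydrophobic contacts).

    H-bonds come from the frame's registry; a hydrophobic contact is a pair
    of hydrophobic-class sidechain beads within their square-well range.
    """
    links: dict[tuple[int, int], list[int]] = {}

    def bump(p, q, slot):
        if p == q:
            return
        key = (p, q) if p < q else (q, p)
        entry = links.setdefault(key, [0, 0])
        entry[slot] += 1

    pep = system.pep
    for nh, co in frame.hbond_pairs(system):
        bump(int(pep[nh]), int(pep[co]), 0)

    phob = np.nonzero(system.hydrophobic)[0]
    if len(phob):
        coords = frame.positions[phob]
        if box is not None:
            tree = cKDTree(np.mod(coords, box), boxsize=box)
        else:
            tree = cKDTree(coords)
        # query at the widest hydrophobic well, then check each pair
        ranges = system.lam2[np.ix_(
            system.btype[phob], system.btype[phob])]
        if max_phob_range is not None:
            rmax = max_phob_range
        elif ranges.size:
            rmax = float(np.sqrt(ranges.max()))
        else:
            rmax = 0.0
        for a, b in tree.query_pairs(rmax):
            i, j = int(phob[a]), int(phob[b])
            if pep[i] == pep[j]:
                continue
            l2 = system.lam2[system.btype[i], system.btype[j]]
            if l2 <= 0.0:
                continue
            d = coords[a] - coords[b]
            if box is not None:
                d -= box * np.round(d / box)
            if float(d @ d) < l2:
                bump(int(pep[i]), int(pep[j]), 1)

    return {k: (v[0], v[1]) for k, v in links.items()}


def connectivity_graph(
    frame: Frame, system: CGSystem,
    hb_min: int = HB_MIN, phob_min: int = PHOB_MIN,
    box: float | None = None,
) -> ConnectivityGraph:
    """Peptide graph with an edge wherever the connection rule holds."""
    g = nx.Graph()
    g.add_nodes_from(range(system.n_peptides))
    for (p, q), (nhb, nph) in pairwise_links(frame, system, box=box).items():
        if nhb >= hb_min or nph >= phob_min:
            g.add_edge(p, q, n_hbonds=nhb, n_hydrophobic=nph)
        else:
            # keep sub-threshold annotations available to the classifier
            g.add_node(p)
            g.add_node(q)
    return ConnectivityGraph(graph=g, time=frame.time)


def clusters(cg: ConnectivityGraph) -> list[set[int]]:
    """Connected components of the peptide graph."""
    return [set(c) for c in nx.connected_components(cg.graph)]


def classify_cluster(
    component: set[int], cg: ConnectivityGraph,
    hb_min: int = HB_MIN, sheet_min: int = SHEET_MIN,
) -> str:
    """Classify one connected component.

    The strand-adjacency subgraph keeps only edges backed by at least
    ``hb_min`` hydrogen bonds.  A single cycle through all members is a
    beta-barrel; a single path spanning at least ``sheet_min`` members is a
    beta-sheet; anything else (including hydrophobically glued groups) is
    an oligomer.  Singletons are free.
    """
    if len(component) == 1:
        return "free"
    sub = nx.Graph()
    sub.add_nodes_from(component)
    for p, q, data in cg.graph.edges(component, data=True):
        if p in component and q in component and \
                data.get("n_hbonds", 0) >= hb_min:
            sub.add_edge(p, q)
    degrees = [d for _, d in sub.degree()]
    n = len(component)
    m = sub.number_of_edges()
    if n >= 3 and m == n and all(d == 2 for d in degrees) \
            and nx.is_connected(sub):
        return "beta_barrel"
    if m == n - 1 and nx.is_connected(sub) and max(degrees, default=0) <= 2 \
            and n >= sheet_min:
        return "beta_sheet"
    return "oligomer"


def _cluster_identity(prev: list[frozenset], members: frozenset) -> int | None:
    """Index of the previous-frame cluster sharing >50% of either side."""
    for k, old in enumerate(prev):
        inter = len(old & members)
        if inter > 0.5 * len(old) or inter > 0.5 * len(members):
            return k
    return None


def kinetics_timeseries(
    trajectory: Trajectory,
    hb_min: int = HB_MIN,
    phob_min: int = PHOB_MIN,
    sheet_min: int = SHEET_MIN,
    periodic: bool = True,
) -> ClusterReport:
    """Free-peptide depletion, oligomerization and fibrillization series.

    Fibrillar peptides are members of beta_sheet or beta_barrel clusters.
    Class-change transitions are logged for clusters identified across
    consecutive frames by >50% member overlap.
    """
    if not trajectory.frames:
        raise ValueError("trajectory has no sampled frames")
    system = trajectory.system
    box = trajectory.box_length if periodic else None
    n = system.n_peptides

    rows = []
    frames_out: list[dict] = []
    transitions: list[tuple[float, frozenset, str, str]] = []
    prev_members: list[frozenset] = []
    prev_classes: list[str] = []

    for frame in trajectory.frames:
        cg = connectivity_graph(frame, system, hb_min, phob_min, box=box)
        comps = clusters(cg)
        cls = [classify_cluster(c, cg, hb_min, sheet_min) for c in comps]

        n_free = sum(len(c) for c, k in zip(comps, cls) if k == "free")
        n_fib = sum(len(c) for c, k in zip(comps, cls)
                    if k in ("beta_sheet", "beta_barrel"))
        n_olig = n - n_free - n_fib
        total_hb = len(frame.hbond_pairs(system))

        members_now = [frozenset(c) for c in comps]
        for mem, k in zip(members_now, cls):
            if len(mem) == 1:
                continue
            prev_idx = _cluster_identity(prev_members, mem)
            if prev_idx is not None and prev_classes[prev_idx] != k \
                    and len(prev_members[prev_idx]) > 1:
                transitions.append(
                    (frame.time, mem, prev_classes[prev_idx], k))
        prev_members = members_now
        prev_classes = cls

        rows.append({
            "time": frame.time,
            "n_free": n_free,
            "n_oligomeric": n_olig,
            "n_fibrillar": n_fib,
            "clusters_free": sum(1 for k in cls if k == "free"),
            "clusters_oligomer": sum(1 for k in cls if k == "oligomer"),
            "clusters_fibrillar": sum(1 for k in cls
                                      if k in ("beta_sheet", "beta_barrel")),
            "total_hbonds": total_hb,
        })
        frames_out.append({
            "time": frame.time,
            "clusters": [
                {"members": sorted(c), "size": len(c), "class": k}
                for c, k in zip(comps, cls)
            ],
        })

    return ClusterReport(
        frames=frames_out,
        series=pd.DataFrame(rows),
        transitions=transitions,
    )
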
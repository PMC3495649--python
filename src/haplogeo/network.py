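"""Statistical-parsimony haplotype networks and hierarchical clade nesting.

Network construction
--------------------
Haplotypes are connected by single mutational steps, inserting unobserved
intermediate nodes where observed haplotypes are more than one step apart.
When the coded sites are mutually compatible (every pair of sites passes
the four-gamete test — true for both packaged fixtures and for all
infinite-sites simulations), the network is the maximum-parsimony tree
built by perfect-phylogeny construction, which shares inferred
intermediates between branches and attains the parsimony bound of one step
per mutation.  For incompatible data the builder falls back to connecting
haplotype pairs in ascending distance order (Kruskal style), recording
equally short alternative connections as ambiguities.

Pairs farther apart than the 95% parsimony connection limit are not
connected; the result is then a forest of subnetworks.

Nesting
-------
Nested clades are agglomerated tips-inward: each terminal node unites with
its interior neighbour to form a 1-step clade, leftover adjacent nodes
unite with each other, and stranded nodes join the adjacent clade with the
lowest total observed frequency (deterministic tie-breaks).  The procedure
repeats on the clade graph to give 2-step clades and so on up to the total
cladogram.  Inferred-intermediate-only units are retained as clades; they
are excluded from geographic testing (no observations) but counted in the
nesting design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import Dataset

__all__ = [
    "parsimony_connection_limit", "build_parsimony_network",
    "HaplotypeNetwork", "Clade", "NestedDesign", "nest_clades",
]


def parsimony_probability(j: int, length: int) -> float:
    """Probability that a path of ``j`` observed steps over ``length`` sites
    involves no superimposed (multiple-hit) changes.

    Birthday-type approximation to the statistical-parsimony calculus:
    successive changes fall on 2*length mutational opportunities (site x
    lineage), so P_j = prod_{i=1}^{j-1} (1 - i / (2*length)).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    p = 1.0
    for i in range(1, j):
        p *= 1.0 - i / (2.0 * length)
    return p


def parsimony_connection_limit(length: int, confidence: float = 0.95) -> int:
    """Largest number of steps connectable at the given parsimony confidence."""
    j = 1
    while parsimony_probability(j + 1, length) > confidence:
        j += 1
    return j


@dataclass
class HaplotypeNetwork:
    """A parsimony network: observed haplotypes plus inferred intermediates.

    ``graph`` nodes carry attributes ``observed`` (bool) and ``frequency``
    (total gene copies; 0 for inferred nodes).  Every edge spans exactly one
    mutational step.  ``ambiguous_edges`` lists equally parsimonious
    alternative connections that were not used for the backbone.
    """

    graph: nx.Graph
    connection_limit: int
    ambiguous_edges: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    @property
    def total_steps(self) -> int:
        return self.graph.number_of_edges()

    def observed_nodes(self) -> list[str]:
        return [n for n, a in self.graph.nodes(data=True) if a["observed"]]

    def to_dot(self) -> str:
        lines = ["graph haplotypes {"]
        for n, a in self.graph.nodes(data=True):
            shape = "circle" if a["observed"] else "point"
            lines.append(f'  "{n}" [shape={shape}, label="{n}", '
                         f'width={0.3 + 0.05 * a["frequency"]:.2f}];')
        for u, v in self.graph.edges():
            lines.append(f'  "{u}" -- "{v}";')
        for u, v, d in self.ambiguous_edges:
            lines.append(f'  "{u}" -- "{v}" [style=dotted, label="{d}"];')
        lines.append("}")
        return "\n".join(lines)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def _pseudo_sites(dataset: Dataset, haps: list[str], root: str):
    """Binary split per non-root state per coded site, as frozen carrier sets."""
    hs = dataset.haplotypes
    rows = {h: hs.state_matrix[hs.index(h)] for h in haps}
    sites = []
    for j in range(hs.n_polymorphic_sites):
        root_state = rows[root][j]
        for state in sorted({rows[h][j] for h in haps} - {root_state}):
            carriers = frozenset(h for h in haps if rows[h][j] == state)
            sites.append((j, state, carriers))
    return sites


def _is_laminar(sets) -> bool:
    sets = list(sets)
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            a, b = sets[i], sets[j]
            if a & b and not (a <= b or b <= a):
                return False
    return True


def _build_perfect_phylogeny(graph, dataset, haps, freq):
    root = max(haps, key=lambda h: (freq.get(h, 0), -dataset.haplotypes.index(h)))
    sites = _pseudo_sites(dataset, haps, root)
    carrier_sets = {c for _, _, c in sites}
    if not _is_laminar(carrier_sets):
        return False
    hs = dataset.haplotypes
    ordered = sorted(carrier_sets,
                     key=lambda c: (-len(c), min(hs.index(h) for h in c)))
    parent: dict[frozenset, frozenset | None] = {}
    for c in ordered:
        parent[c] = None
        for cand in ordered:
            if cand is c or len(cand) <= len(c):
                continue
            if c < cand and (parent[c] is None or cand < parent[c] or
                             len(cand) < len(parent[c])):
                parent[c] = cand
    # minimal containing set per haplotype = its node
    node_of_hap = {}
    for h in haps:
        containing = [c for c in carrier_sets if h in c]
        node_of_hap[h] = min(containing, key=len) if containing else None
    name_of: dict[frozenset | None, str] = {None: root}
    observed_at = {v: k for k, v in node_of_hap.items() if v is not None}
    mv = 0
    for c in ordered:
        if c in observed_at:
            name_of[c] = observed_at[c]
        else:
            mv += 1
            name_of[c] = f"mv{mv}"
    for name in {name_of[c] for c in ordered} | {root}:
        graph.add_node(name, observed=name in freq, frequency=freq.get(name, 0))
    for c in ordered:
        muts = sorted((j, s) for j, s, cc in sites if cc == c)
        chain = [name_of[parent[c]]]
        for extra in range(len(muts) - 1):
            mv += 1
            graph.add_node(f"mv{mv}", observed=False, frequency=0)
            chain.append(f"mv{mv}")
        chain.append(name_of[c])
        for u, v, (j, s) in zip(chain[:-1], chain[1:], muts):
            graph.add_edge(u, v, site=j, state=s)
    return True


def _build_kruskal(graph, dataset, haps, freq, dist, limit, ambiguous):
    hs = dataset.haplotypes
    for h in haps:
        graph.add_node(h, observed=True, frequency=freq.get(h, 0))
    idx = {h: hs.index(h) for h in haps}
    pairs = [(h1, h2, int(dist[idx[h1], idx[h2]]))
             for i, h1 in enumerate(haps) for h2 in haps[i + 1:]]
    # ascending distance; ties favour the higher-frequency hub, then id order
    pairs.sort(key=lambda p: (p[2], -max(freq.get(p[0], 0), freq.get(p[1], 0)),
                              idx[p[0]], idx[p[1]]))
    comp = {h: h for h in haps}

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    mv = sum(1 for n in graph if str(n).startswith("mv"))
    for h1, h2, d in pairs:
        if d > limit:
            continue
        if find(h1) == find(h2):
            if d <= 2:
                ambiguous.append((h1, h2, d))
            continue
        comp[find(h1)] = find(h2)
        chain = [h1]
        for _ in range(d - 1):
            mv += 1
            graph.add_node(f"mv{mv}", observed=False, frequency=0)
            chain.append(f"mv{mv}")
        chain.append(h2)
        for u, v in zip(chain[:-1], chain[1:]):
            graph.add_edge(u, v)


def build_parsimony_network(dataset: Dataset,
                            connection_limit: int | None = None) -> HaplotypeNetwork:
    """Build the statistical-parsimony network for a dataset.

    Haplotype pairs farther apart than the connection limit fall into
    separate subnetworks.  Within each connectable component a perfect
    phylogeny is attempted first; homoplasic components use the ascending-
    distance fallback.
    """
    hs = dataset.haplotypes
    if connection_limit is None:
        connection_limit = parsimony_connection_limit(hs.effective_length)
    freq = dataset.total_counts()
    dist = hs.distance_matrix()

    # components under the connection limit
    conn = nx.Graph()
    conn.add_nodes_from(hs.haplotype_ids)
    for i, h1 in enumerate(hs.haplotype_ids):
        for h2 in hs.haplotype_ids[i + 1:]:
            if dist[hs.index(h1), hs.index(h2)] <= connection_limit:
                conn.add_edge(h1, h2)

    graph = nx.Graph()
    ambiguous: list[tuple[str, str, int]] = []
    for component in nx.connected_components(conn):
        haps = sorted(component, key=hs.index)
        if len(haps) == 1:
            graph.add_node(haps[0], observed=True, frequency=freq.get(haps[0], 0))
            continue
        sub = nx.Graph()
        if not _build_perfect_phylogeny(sub, dataset, haps, freq):
            sub = nx.Graph()
            _build_kruskal(sub, dataset, haps, freq, dist,
                           connection_limit, ambiguous)
        # merge, renaming inferred nodes to keep them globally unique
        offset = sum(1 for n in graph if str(n).startswith("mv"))
        mapping = {n: (f"mv{offset + int(str(n)[2:])}"
                       if str(n).startswith("mv") else n) for n in sub}
        graph = nx.union(graph, nx.relabel_nodes(sub, mapping))
    return HaplotypeNetwork(graph, connection_limit, ambiguous)


# ---------------------------------------------------------------------------
# Nesting
# ---------------------------------------------------------------------------

@dataclass
class Clade:
    label: str
    level: int
    members: list[str]                 # network node names (all levels flattened)
    observed_haplotypes: list[str]
    is_tip: bool = False

    @property
    def frequency_label(self) -> str:
        return f"{self.label}[{','.join(self.observed_haplotypes) or '-'}]"


@dataclass
class NestedDesign:
    """Clade hierarchy: levels[0] is the 1-step partition, the last level is
    the total cladogram (a single clade)."""

    levels: list[list[Clade]]
    network: HaplotypeNetwork

    def n_clades(self, level: int, observed_only: bool = False) -> int:
        clades = self.levels[level - 1]
        if observed_only:
            return sum(1 for c in clades if c.observed_haplotypes)
        return len(clades)

    def clades(self, level: int) -> list[Clade]:
        return self.levels[level - 1]

    def clade_containing(self, hap: str, level: int) -> Clade:
        for c in self.levels[level - 1]:
            if hap in c.observed_haplotypes:
                return c
        raise KeyError(hap)

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _one_nesting_pass(units: dict[str, set[str]], adj: nx.Graph,
                      unit_freq: dict[str, float], order: dict[str, int]):
    """Group the current units into next-level groups (lists of unit names)."""
    unnested = set(units)
    groups: list[set[str]] = []
    stranded_order: list[str] = []
    while unnested:
        sub_deg = {u: sum(1 for v in adj.neighbors(u) if v in unnested)
                   for u in unnested}
        tips = sorted((u for u in unnested if sub_deg[u] <= 1),
                      key=lambda u: order[u])
        progressed = False
        seeds: dict[str, set[str]] = {}
        paired: set[str] = set()
        for u in tips:
            nbrs = [v for v in adj.neighbors(u) if v in unnested and v not in paired]
            if not nbrs:
                continue
            v = min(nbrs, key=lambda x: order[x])
            if sub_deg[v] <= 1:      # tip-tip pair
                if u in paired:
                    continue
                seeds.setdefault(v, {v}).add(u)
                paired.update({u, v})
            else:                    # tip joins its interior neighbour
                seeds.setdefault(v, {v}).add(u)
                paired.add(u)
            progressed = True
        for members in seeds.values():
            groups.append(members)
            unnested -= members
        if not progressed:
            stranded_order = sorted(unnested, key=lambda u: order[u])
            break
    # stranded units: join the adjacent group with the lowest total observed
    # frequency; isolated units with no connected group stand alone
    for u in stranded_order:
        candidates = []
        for gi, g in enumerate(groups):
            if any(adj.has_edge(u, v) for v in g):
                total = sum(unit_freq[v] for v in g)
                candidates.append((total, min(order[v] for v in g), gi))
        if candidates:
            groups[min(candidates)[2]].add(u)
        else:
            groups.append({u})
    return groups


def nest_clades(network: HaplotypeNetwork, dataset: Dataset) -> NestedDesign:
    """Agglomerate the network into nested 1-step, 2-step, ... clades."""
    g = network.graph
    if nx.number_connected_components(g) != 1:
        raise ValueError("nesting requires a connected network")
    hs = dataset.haplotypes
    freq = dataset.total_counts()

    def hap_order(name: str) -> int:
        return hs.index(name) if name in freq else 10_000 + int(str(name)[2:])

    # level-0 units: network nodes
    units = {n: {n} for n in g.nodes()}
    unit_freq = {n: float(freq.get(n, 0)) for n in g.nodes()}
    order = {n: hap_order(n) for n in g.nodes()}
    adj = g.copy()

    levels: list[list[Clade]] = []
    level = 0
    while len(units) > 1:
        level += 1
        groups = _one_nesting_pass(units, adj, unit_freq, order)
        # materialize clades
        new_units: dict[str, set[str]] = {}
        clades: list[Clade] = []
        named = []
        for g_members in groups:
            members = sorted(set().union(*(units[u] for u in g_members)))
            observed = sorted((m for m in members if m in freq), key=hs.index)
            named.append((min(order[u] for u in g_members), members, observed))
        named.sort(key=lambda t: t[0])
        for i, (_, members, observed) in enumerate(named, start=1):
            clades.append(Clade(f"{level}-{i}", level, members, observed))
        # next-level adjacency
        new_adj = nx.Graph()
        member_to_clade = {}
        for c in clades:
            new_units[c.label] = set(c.members)
            new_adj.add_node(c.label)
            for m in c.members:
                member_to_clade[m] = c.label
        for u, v in g.edges():
            cu, cv = member_to_clade[u], member_to_clade[v]
            if cu != cv:
                new_adj.add_edge(cu, cv)
        for c in clades:
            c.is_tip = new_adj.degree(c.label) <= 1
        levels.append(clades)
        units = new_units
        unit_freq = {c.label: sum(freq.get(m, 0) for m in c.members)
                     for c in clades}
        order = {c.label: min(hap_order(m) for m in c.members) for c in clades}
        adj = new_adj
    return NestedDesign(levels, network)
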
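"""Statistical-parsimony haplotype networks with a 95% connection limit.

Two haplotypes are joined when the number of mutational steps between them
does not exceed the largest step count ``j_max`` whose *parsimony
probability* — the probability that a connection of that length is free of
multiple hits at any site — stays at or above the connection limit
(default 95%).  Haplotype clusters that cannot be joined under the limit
form independent networks; a candidate taxon whose haplotypes occupy only
components free of other populations satisfies the mtDNA line of evidence.

The parsimony probability is computed under a neutral finite-sites model:
over the divergence separating the pair, every site accumulates hits as a
Poisson process with common per-site mean ``m``, and hits move among the
four nucleotide states symmetrically (Jukes-Cantor type), so a site shows
a difference with probability d(m) = (3/4)(1 - exp(-4m/3)).  ``m`` is
estimated from the observed fraction of differing sites x = j/L by
inverting d(m) (the standard multiple-hit correction).  A connection is
parsimonious when the j observed differences are each the product of a
single substitution, so the inferred path carries no hidden extra steps;
because sites are independent the probability factorizes over the
differing sites:

    P_j = [ m e^(-m) / d(m) ]^j

where m e^(-m)/d(m) is P(exactly one hit | the site differs).  Hidden
multiple hits at sites observed *identical* leave the inferred path
between the two haplotypes intact and are not counted against the
connection.  The full probability table is exposed so the resulting
``j_max`` can be audited; the exact estimator inside historical
statistical-parsimony software is undocumented, so small step-limit
discrepancies against it are possible and the table makes them visible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

import networkx as nx
import numpy as np

from .alignments_io import HaplotypeSet, missing_states

__all__ = [
    "parsimony_probability",
    "connection_limit",
    "ConnectionLimit",
    "NetworkPartition",
    "build_networks",
    "is_independent_network",
    "step_distance",
]


def parsimony_probability(j: int, L: int) -> float:
    """Probability that a ``j``-step connection over ``L`` sites is
    non-homoplastic (no site hit more than once).

    ``j = 0`` returns 1 by convention; ``j > L`` is an error.  The result
    is non-increasing in ``j`` and non-decreasing in ``L``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if j < 0 or j > L:
        raise ValueError(f"j={j} outside [0, L={L}]")
    if j == 0:
        return 1.0
    x = j / L
    if x >= 0.75:
        # multiple-hit correction diverges: saturation, parsimony hopeless
        return 0.0
    m = -0.75 * np.log1p(-4.0 * x / 3.0)  # estimated hits per site
    d = 0.75 * -np.expm1(-4.0 * m / 3.0)  # P(site differs) == x by construction
    log_p = j * (np.log(m) - m - np.log(d))
    return float(min(np.exp(log_p), 1.0))


@dataclass(frozen=True)
class ConnectionLimit:
    """Maximum mutational steps justified at significance level alpha.

    ``probabilities[j]`` is the parsimony probability of a j-step
    connection; ``j_max`` is the largest j with probability >= 1 - alpha.
    The table runs up to the first failing j so the cut-off is auditable.
    """

    L: int
    alpha: float = 0.05
    j_max: int = 0
    probabilities: Mapping = field(default_factory=dict)
    marker_name: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "marker": self.marker_name,
            "L": self.L,
            "alpha": self.alpha,
            "j_max": self.j_max,
            "probabilities": {int(k): round(v, 6)
                              for k, v in self.probabilities.items()},
        }


@lru_cache(maxsize=256)
def _limit_core(L: int, alpha: float):
    threshold = 1.0 - alpha
    probs = {0: 1.0}
    j_max = 0
    for j in range(1, L + 1):
        p = parsimony_probability(j, L)
        probs[j] = p
        if p < threshold:
            break
        j_max = j
    return j_max, tuple(probs.items())


def connection_limit(L: int, alpha: float = 0.05,
                     marker_name: Optional[str] = None) -> ConnectionLimit:
    """Compute the connection limit for an ``L``-site alignment."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    j_max, probs = _limit_core(int(L), float(alpha))
    return ConnectionLimit(L=int(L), alpha=float(alpha), j_max=j_max,
                           probabilities=dict(probs), marker_name=marker_name)


def step_distance(a: str, b: str, gap_as_state: bool = False) -> int:
    """Mutational steps between haplotypes: Hamming distance over sites
    comparable (non-missing) in both, consistent with the collapse policy."""
    missing = missing_states(gap_as_state)
    return sum(1 for x, y in zip(a, b)
               if x != y and x not in missing and y not in missing)


@dataclass(frozen=True)
class NetworkPartition:
    """Partition of a haplotype set into independent parsimony networks.

    ``components`` holds tuples of haplotype indices (into
    ``haplotype_set.haplotypes``), largest first; ``edges`` the within-limit
    haplotype pairs annotated with step counts (steps - 1 is the number of
    interlying unsampled intermediates).
    """

    haplotype_set: HaplotypeSet
    limit: ConnectionLimit
    components: tuple
    edges: tuple  # of (i, j, steps)
    component_populations: tuple = ()  # parallel frozensets, if metadata given

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_of(self, hap_index: int) -> int:
        for c, comp in enumerate(self.components):
            if hap_index in comp:
                return c
        raise KeyError(hap_index)

    def to_dict(self) -> dict:
        return {
            "marker": self.haplotype_set.marker_name,
            "j_max": self.limit.j_max,
            "n_components": self.n_components,
            "components": [
                {
                    "haplotypes": list(comp),
                    "samples": sorted(
                        s for i in comp for s in self.haplotype_set.members[i]),
                    "populations": sorted(self.component_populations[c])
                    if self.component_populations else None,
                }
                for c, comp in enumerate(self.components)
            ],
            "edges": [{"a": i, "b": j, "steps": s} for i, j, s in self.edges],
        }


def build_networks(hs: HaplotypeSet, limit: ConnectionLimit,
                   sample_to_pop: Optional[Mapping] = None,
                   gap_as_state: bool = False) -> NetworkPartition:
    """Join haplotype pairs within ``limit.j_max`` steps and return the
    connected components (independent networks)."""
    g = nx.Graph()
    g.add_nodes_from(range(hs.n_haplotypes))
    edges = []
    for i, j in itertools.combinations(range(hs.n_haplotypes), 2):
        steps = step_distance(hs.haplotypes[i], hs.haplotypes[j], gap_as_state)
        if steps <= limit.j_max:
            g.add_edge(i, j, steps=steps)
            edges.append((i, j, steps))
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    comp_pops = ()
    if sample_to_pop is not None:
        comp_pops = tuple(
            frozenset(sample_to_pop[s] for i in comp for s in hs.members[i])
            for comp in comps
        )
    return NetworkPartition(
        haplotype_set=hs, limit=limit, components=tuple(comps),
        edges=tuple(edges), component_populations=comp_pops,
    )


def is_independent_network(partition: NetworkPartition,
                           candidate,
                           sample_to_pop: Mapping) -> bool:
    """True iff every haplotype carried by the candidate's samples lies in
    components containing no other population's samples.

    ``candidate`` is a population label or an iterable of labels (a clade).
    Exclusivity, not single-component connectivity, is the criterion: a
    candidate split across two components that are both free of other
    populations still qualifies.
    """
    cand = {candidate} if isinstance(candidate, str) else set(candidate)
    known = set(sample_to_pop.values())
    unknown = cand - known
    if unknown:
        raise KeyError(f"population(s) not in metadata: {sorted(unknown)}")
    hs = partition.haplotype_set
    seen = False
    for comp in partition.components:
        pops = {sample_to_pop[s] for i in comp for s in hs.members[i]}
        if pops & cand:
            seen = True
            if pops - cand:
                return False
    if not seen:
        raise KeyError(f"candidate {sorted(cand)} has no samples in partition")
    return True
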
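"""Uncorrected p-distances, group summaries, barcoding-threshold checks.

The p-distance between two aligned sequences is the fraction of differing
sites among the sites comparable in both (pairwise deletion of missing
data), with no substitution-model correction.  Group summaries give the
min/mean/max pairwise distance within each population and between each
pair of populations (or clades), mirroring how divergences are reported in
barcoding and taxonomic studies.  A simple UPGMA cut of the mean
between-population distances provides a guide grouping when no tree is
supplied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .alignments_io import MarkerAlignment
from .errors import UndefinedDistanceError

_BASE_CODES = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    """Map to integer codes; anything outside A/C/G/T becomes -1 (missing)."""
    return np.array([_BASE_CODES.get(c, -1) for c in seq], dtype=np.int8)


def p_distance(a: str, b: str, deletion: str = "pairwise") -> float:
    """Uncorrected p-distance between two equal-length sequences.

    Sites where either sequence has missing data (gap, N, ambiguity) are
    excluded.  ``deletion`` is accepted for interface symmetry with
    :func:`distance_matrix`; for a single pair the two policies coincide.
    """
    if deletion not in {"pairwise", "complete-against-matrix"}:
        raise ValueError(f"unknown deletion policy {deletion!r}")
    if len(a) != len(b):
        raise ValueError("sequences must have equal lengths")
    ca, cb = _encode(a.upper()), _encode(b.upper())
    ok = (ca >= 0) & (cb >= 0)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("zero comparable sites between pair")
    return float((ca[ok] != cb[ok]).sum()) / n


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise p-distances (fractions in [0, 1])."""

    marker_name: str
    samples: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.samples), len(self.samples)):
            raise ValueError("matrix shape does not match sample count")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("nonzero diagonal")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("entries outside [0, 1]")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.samples.index(a), self.samples.index(b)
        return float(self.values[ia, ib])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def distance_matrix(aln: MarkerAlignment,
                    deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs p-distance.

    ``complete-against-matrix`` first drops every column with missing data
    in *any* sequence, then compares complete columns only.
    """
    codes = np.stack([_encode(s) for s in aln.sequences])
    if deletion == "complete-against-matrix":
        keep = (codes >= 0).all(axis=0)
        if not keep.any():
            raise UndefinedDistanceError("no complete columns in alignment")
        codes = codes[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion!r}")
    n = codes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                raise UndefinedDistanceError(
                    f"zero comparable sites: {aln.samples[i]} vs {aln.samples[j]}"
                )
            d[i, j] = d[j, i] = (codes[i, ok] != codes[j, ok]).sum() / m
    return DistanceMatrix(aln.marker_name, tuple(aln.samples), d)


@dataclass(frozen=True)
class GroupStats:
    """min/mean/max of a set of pairwise distances (stored as fractions)."""

    min: float
    max: float
    mean: float
    n_pairs: int

    def __post_init__(self):
        if not (self.min - 1e-12 <= self.mean <= self.max + 1e-12):
            raise ValueError("requires min <= mean <= max")

    def as_percent(self, decimals: int = 1) -> dict:
        return {
            "min_pct": round(100 * self.min, decimals),
            "max_pct": round(100 * self.max, decimals),
            "mean_pct": round(100 * self.mean, decimals),
            "n_pairs": self.n_pairs,
        }


def _stats(vals: list) -> Optional[GroupStats]:
    if not vals:
        return None
    a = np.asarray(vals, dtype=float)
    return GroupStats(float(a.min()), float(a.max()), float(a.mean()), len(vals))


@dataclass(frozen=True)
class DistanceSummary:
    """Per-population and per-pair distance summaries, plus optional
    clade-level (pooled population) summaries."""

    marker_name: str
    within: Mapping          # population -> GroupStats | None (singletons)
    between: Mapping         # (popA, popB) sorted tuple -> GroupStats
    group_within: Mapping = field(default_factory=dict)   # clade -> GroupStats|None
    group_between: Mapping = field(default_factory=dict)  # (cladeA, cladeB) -> GroupStats

    def to_dict(self, decimals: int = 1) -> dict:
        def fmt(m):
            return {
                "|".join(k) if isinstance(k, tuple) else k:
                (v.as_percent(decimals) if v is not None else None)
                for k, v in m.items()
            }
        return {
            "marker": self.marker_name,
            "within_population": fmt(self.within),
            "between_populations": fmt(self.between),
            "within_group": fmt(self.group_within),
            "between_groups": fmt(self.group_between),
        }


def group_distance_summary(dm: DistanceMatrix,
                           sample_to_pop: Mapping,
                           grouping: Optional[Mapping] = None) -> DistanceSummary:
    """Summarize within- and between-population p-distances.

    ``grouping`` (population -> clade label) adds pooled clade-level
    records; the clade-pair maximum is by construction the max over all
    cross-clade sample pairs.  Singleton populations get a ``None`` within
    record (absent, not zero).
    """
    missing = [s for s in dm.samples if s not in sample_to_pop]
    if missing:
        raise KeyError(f"samples without population: {missing}")
    pops = sorted({sample_to_pop[s] for s in dm.samples})
    idx_of_pop = {
        p: [i for i, s in enumerate(dm.samples) if sample_to_pop[s] == p]
        for p in pops
    }

    def pairs_within(indices):
        return [dm.values[i, j] for i, j in itertools.combinations(indices, 2)]

    def pairs_between(ia, ib):
        return [dm.values[i, j] for i in ia for j in ib]

    within = {p: _stats(pairs_within(idx_of_pop[p])) for p in pops}
    between = {
        (a, b): _stats(pairs_between(idx_of_pop[a], idx_of_pop[b]))
        for a, b in itertools.combinations(pops, 2)
    }

    group_within: dict = {}
    group_between: dict = {}
    if grouping is not None:
        clades = sorted({grouping[p] for p in pops})
        idx_of_clade = {
            c: [i for p in pops if grouping[p] == c for i in idx_of_pop[p]]
            for c in clades
        }
        group_within = {c: _stats(pairs_within(idx_of_clade[c])) for c in clades}
        group_between = {
            (a, b): _stats(pairs_between(idx_of_clade[a], idx_of_clade[b]))
            for a, b in itertools.combinations(clades, 2)
        }
    return DistanceSummary(dm.marker_name, within, between,
                           group_within, group_between)


@dataclass(frozen=True)
class ThresholdReport:
    """Comparison of pairwise divergence maxima against a barcoding
    threshold (in percent); the boundary is inclusive ("meets")."""

    marker_name: str
    threshold_percent: float
    comparisons: tuple  # of dicts: pair, max_percent, min_percent, relation

    def to_dict(self) -> dict:
        return {
            "marker": self.marker_name,
            "threshold_percent": self.threshold_percent,
            "comparisons": list(self.comparisons),
        }


def threshold_comparison(summary: DistanceSummary,
                         threshold_percent: float,
                         level: str = "auto") -> ThresholdReport:
    """Compare each pair's maximum p-distance with a percent threshold.

    ``level``: ``"group"`` uses clade pairs, ``"population"`` population
    pairs, ``"auto"`` prefers clade pairs when present.
    """
    if level == "auto":
        level = "group" if summary.group_between else "population"
    records = summary.group_between if level == "group" else summary.between
    comps = []
    for pair, st in sorted(records.items()):
        if st is None:
            continue
        max_pct = 100 * st.max
        relation = ("meets-or-exceeds"
                    if max_pct >= threshold_percent - 1e-9 else "below")
        comps.append({
            "pair": "|".join(pair),
            "max_percent": round(max_pct, 1),
            "min_percent": round(100 * st.min, 1),
            "relation": relation,
        })
    return ThresholdReport(summary.marker_name, threshold_percent, tuple(comps))


def upgma_grouping(dm: DistanceMatrix,
                   sample_to_pop: Mapping,
                   k: int) -> dict:
    """Average-linkage agglomeration of populations, cut at ``k`` groups.

    Starts from the mean between-population p-distance and merges the
    closest pair until ``k`` clusters remain; equidistant candidates are
    broken lexicographically (first by sorted member tuple).  Returns
    population -> group label, labels being the '+'-joined sorted members.
    """
    summary = group_distance_summary(dm, sample_to_pop)
    pops = sorted(summary.within.keys())
    if k < 1 or k > len(pops):
        raise ValueError(f"k={k} outside [1, {len(pops)}]")
    sizes = {p: sum(1 for s in dm.samples if sample_to_pop[s] == p) for p in pops}
    clusters = {(p,): sizes[p] for p in pops}  # member tuple -> #samples
    # sample-count weighting keeps every cluster-cluster distance equal to
    # the mean over all cross-cluster sample pairs (true UPGMA)
    dist = {}
    for (a, b), st in summary.between.items():
        dist[((a,), (b,))] = st.mean

    def get_d(c1, c2):
        key = (c1, c2) if (c1, c2) in dist else (c2, c1)
        return dist[key]

    while len(clusters) > k:
        names = sorted(clusters)
        best = min(
            ((get_d(c1, c2), c1, c2)
             for i, c1 in enumerate(names) for c2 in names[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, c1, c2 = best
        merged = tuple(sorted(c1 + c2))
        n1, n2 = clusters.pop(c1), clusters.pop(c2)
        for other in list(clusters):
            d_new = (n1 * get_d(c1, other) + n2 * get_d(c2, other)) / (n1 + n2)
            dist[(merged, other)] = d_new
        clusters[merged] = n1 + n2

    out = {}
    for members in clusters:
        label = "+".join(members)
        for p in members:
            out[p] = label
    return out
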
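"""Candidate designation and species/subspecies rank assignment.

Implements the lines-of-evidence scheme for integrative delimitation of
allopatric candidate taxa:

1. *mtDNA line* — the candidate's haplotypes form independent
   statistical-parsimony network components (no component shared with
   another candidate) on the configured mitochondrial marker.
2. *nDNA line* — the candidate shares no nuclear haplotype with any other
   candidate AND is set apart by at least ``min_nuclear_substitutions``
   fixed substitutions (a single private substitution is treated as too
   slight to count, unless the threshold is lowered to 1).
3. *morphology line* — at least one fixed, non-graded diagnostic character
   against the comparison group.

A candidate meeting two or more lines against its sisters ranks as a
species; exactly one line, subspecies; none, not distinct.  Candidates are
first pooled into guide-grouping clades and the clades evaluated against
each other, then members are evaluated within each clade.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignments_io import HaplotypeSet, MarkerAlignment, missing_states
from .morphology import MorphMatrix, fixed_diagnostic_characters
from .parsimony_network import NetworkPartition, is_independent_network


@dataclass(frozen=True)
class CandidateTaxon:
    """A candidate species: one or more populations inside a guide clade."""

    name: str
    populations: frozenset
    clade: str

    def __post_init__(self):
        if not self.populations:
            raise ValueError(f"candidate {self.name}: empty population set")


@dataclass(frozen=True)
class EvidenceConfig:
    """Knobs encoding the taxonomic-judgment calls of the scheme."""

    mtdna_marker: str = "cytb"
    nuclear_markers: tuple = ("Rag2",)
    min_nuclear_substitutions: int = 2
    exclude_graded_characters: bool = True
    morphology_scope: str = "clade"   # "clade" or "all"
    quantitative_rule: str = "range"  # or "amadon"


@dataclass(frozen=True)
class EvidenceProfile:
    candidate: str
    mtdna_line: Optional[bool]
    ndna_line: Optional[bool]
    morphology_line: Optional[bool]
    detail: Mapping = field(default_factory=dict)

    @property
    def n_lines(self) -> int:
        return sum(1 for b in (self.mtdna_line, self.ndna_line,
                               self.morphology_line) if b)

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "mtdna_line": self.mtdna_line,
            "ndna_line": self.ndna_line,
            "morphology_line": self.morphology_line,
            "n_lines": self.n_lines,
            "detail": dict(self.detail),
        }


def designate_candidate(molecular_distinct: bool,
                        relevant_character: bool,
                        sympatric_no_admixture: Optional[bool] = None,
                        admixture: bool = False,
                        slight_differences_only: bool = False) -> str:
    """Classify a candidate as UCS, CCS or DCL.

    ``sympatric_no_admixture=None`` means the sympatry criterion does not
    apply (allopatric, e.g. insular, candidates).  A deeply divergent
    lineage with admixture — or whose only distinctions are explicitly
    judged slight — is a deep conspecific lineage (DCL); molecular
    distinctness plus a taxonomically relevant character (or sympatry
    without admixture) confirms the candidate (CCS); molecular evidence
    alone leaves it unconfirmed (UCS).
    """
    if admixture and sympatric_no_admixture:
        raise ValueError("admixture contradicts sympatric_no_admixture")
    if admixture:
        return "DCL"
    if not molecular_distinct:
        raise ValueError("a candidate species requires molecular distinctness "
                         "or evidence of admixture")
    if relevant_character or bool(sympatric_no_admixture):
        return "CCS"
    if slight_differences_only:
        return "DCL"
    return "UCS"


def shared_haplotypes(hs: HaplotypeSet, samples_a: set, samples_b: set) -> list:
    """Haplotype indices carried by samples of both groups."""
    out = []
    for i, grp in enumerate(hs.members):
        g = set(grp)
        if g & samples_a and g & samples_b:
            out.append(i)
    return out


def fixed_substitutions(aln: MarkerAlignment, samples_a: set,
                        samples_b: set) -> int:
    """Columns whose observed states are disjoint between the two groups."""
    missing = missing_states()
    idx_a = [k for k, s in enumerate(aln.samples) if s in samples_a]
    idx_b = [k for k, s in enumerate(aln.samples) if s in samples_b]
    n = 0
    for col in zip(*aln.sequences):
        sa = {col[k] for k in idx_a} - missing
        sb = {col[k] for k in idx_b} - missing
        if sa and sb and not (sa & sb):
            n += 1
    return n


def evaluate_lines(candidate: CandidateTaxon,
                   others: Sequence,
                   mtdna_partition: NetworkPartition,
                   nuclear_alignments: Mapping,
                   morphology: Optional[MorphMatrix],
                   sample_to_pop: Mapping,
                   config: EvidenceConfig = EvidenceConfig()) -> EvidenceProfile:
    """Evaluate the three lines for one candidate against ``others``.

    ``nuclear_alignments`` maps marker name -> MarkerAlignment; the markers
    named in ``config.nuclear_markers`` must be present.  ``others`` are the
    comparison candidates (the other clades at clade scope, the siblings
    within a clade).  The nDNA substitution count is summed over the
    configured markers against the pooled other candidates.
    """
    detail: dict = {}
    cand_pops = set(candidate.populations)
    other_pops = set().union(*(set(o.populations) for o in others)) if others \
        else set()

    # (1) mtDNA: component exclusivity on the configured marker
    mt = is_independent_network(mtdna_partition, cand_pops, sample_to_pop)
    detail["mtdna"] = {
        "marker": config.mtdna_marker,
        "independent_networks": mt,
        "j_max": mtdna_partition.limit.j_max,
    }

    # (2) nDNA: no shared haplotypes, enough fixed substitutions
    missing_markers = [m for m in config.nuclear_markers
                       if m not in nuclear_alignments]
    if missing_markers:
        raise KeyError(
            f"nuclear marker(s) {missing_markers} required by the evidence "
            f"configuration are not among {sorted(nuclear_alignments)}")
    samples_cand = {s for s, p in sample_to_pop.items() if p in cand_pops}
    samples_other = {s for s, p in sample_to_pop.items() if p in other_pops}
    from .alignments_io import collapse_haplotypes
    shared: dict = {}
    subs = 0
    for mname in config.nuclear_markers:
        aln = nuclear_alignments[mname]
        hs = collapse_haplotypes(aln)
        shared[mname] = shared_haplotypes(hs, samples_cand, samples_other)
        subs += fixed_substitutions(aln, samples_cand, samples_other)
    no_shared = not any(shared.values())
    nd = bool(others) and no_shared and subs >= config.min_nuclear_substitutions
    detail["ndna"] = {
        "markers": list(config.nuclear_markers),
        "shared_haplotypes": {k: v for k, v in shared.items()},
        "fixed_substitutions": subs,
        "min_required": config.min_nuclear_substitutions,
    }

    # (3) morphology: a fixed non-graded character against every other
    morph: Optional[bool] = None
    if morphology is not None and others:
        per_other = {}
        for o in others:
            rep = fixed_diagnostic_characters(
                morphology, cand_pops, set(o.populations),
                include_graded=not config.exclude_graded_characters,
                quantitative=config.quantitative_rule,
            )
            per_other[o.name] = rep.diagnostic_characters()
        morph = all(bool(v) for v in per_other.values())
        detail["morphology"] = {"diagnostic_characters": per_other}

    return EvidenceProfile(candidate.name, mt, nd, morph, detail)


@dataclass(frozen=True)
class RankAssignment:
    """Hierarchical outcome: species, their member candidates and ranks."""

    species: tuple        # of (species label, tuple of member candidate names)
    ranks: Mapping        # candidate name -> species/subspecies/not-distinct
    rationale: Mapping    # candidate name -> list of strings

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_subspecies(self) -> int:
        return sum(1 for r in self.ranks.values() if r == "subspecies")

    def to_dict(self) -> dict:
        return {
            "species": [{"label": lab, "members": list(mem)}
                        for lab, mem in self.species],
            "ranks": dict(self.ranks),
            "rationale": {k: list(v) for k, v in self.rationale.items()},
        }


def assign_ranks(candidates: Sequence,
                 clade_profiles: Mapping,
                 candidate_profiles: Mapping) -> RankAssignment:
    """Assign ranks hierarchically from clade- and candidate-level profiles.

    ``clade_profiles`` maps clade label -> EvidenceProfile of the pooled
    clade against the other clades; ``candidate_profiles`` maps candidate
    name -> EvidenceProfile against its within-clade siblings.  A clade
    qualifying for >= 2 lines is a species; its members rank subspecies
    (exactly one line against the siblings), species (two or more, the
    strict-application split), or not-distinct (none; synonymized with the
    siblings).  Singleton clades take their clade-level rank directly.
    """
    by_clade: dict = {}
    seen = set()
    for c in candidates:
        if c.populations & seen:
            raise ValueError(f"candidate populations overlap at {c.name}")
        seen |= c.populations
        by_clade.setdefault(c.clade, []).append(c)

    species: list = []
    ranks: dict = {}
    rationale: dict = {c.name: [] for c in candidates}

    species_clades = []
    weak_clades = []
    for clade in sorted(by_clade):
        prof = clade_profiles[clade]
        (species_clades if prof.n_lines >= 2 else weak_clades).append(clade)
        for c in by_clade[clade]:
            rationale[c.name].append(
                f"clade {clade}: {prof.n_lines} line(s) of evidence vs other "
                f"clades -> {'species' if prof.n_lines >= 2 else 'below species'}"
            )

    def resolve_members(members):
        """Within one species-level group, rank members by sibling profiles."""
        if len(members) == 1:
            ranks[members[0].name] = "species"
            rationale[members[0].name].append("single member: species rank")
            return [members[0].name], []
        core, elevated = [], []
        for c in sorted(members, key=lambda c: c.name):
            n = candidate_profiles[c.name].n_lines
            if n >= 2:
                elevated.append(c.name)
                ranks[c.name] = "species"
                rationale[c.name].append(
                    f"{n} lines vs siblings -> elevated to species")
            elif n == 1:
                core.append(c.name)
                ranks[c.name] = "subspecies"
                rationale[c.name].append("1 line vs siblings -> subspecies")
            else:
                core.append(c.name)
                ranks[c.name] = "not-distinct"
                rationale[c.name].append(
                    "0 lines vs siblings -> not distinct from siblings")
        return core, elevated

    for clade in species_clades:
        core, elevated = resolve_members(by_clade[clade])
        if core:
            # a single remaining core member is the species itself
            if len(core) == 1:
                ranks[core[0]] = "species"
            species.append((f"sp-{clade}", tuple(core)))
        for name in elevated:
            species.append((f"sp-{name}", (name,)))

    if weak_clades:
        # clades not species-distinct from each other collapse into one
        # species; their members still rank within it by sibling evidence
        members = [c for clade in weak_clades for c in by_clade[clade]]
        core, elevated = resolve_members(members)
        if core:
            if len(core) == 1:
                ranks[core[0]] = "species"
            species.append(("sp-" + "+".join(sorted(weak_clades)), tuple(core)))
        for name in elevated:
            species.append((f"sp-{name}", (name,)))

    # a subspecies only makes sense alongside a sister subspecies
    for lab, mem in species:
        sub = [m for m in mem if ranks[m] == "subspecies"]
        if len(sub) == 1 and len(mem) == 1:
            ranks[sub[0]] = "species"
    return RankAssignment(tuple(species), ranks, rationale)
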
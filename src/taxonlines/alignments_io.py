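"""Reading, validation and haplotype collapsing of per-marker alignments.

A *marker alignment* is one pre-aligned locus (e.g. cyt b, Rag2) over the
DNA alphabet plus gaps, ``N`` and IUPAC ambiguity codes.  Sample metadata
maps every sequence to an island population.  Haplotype collapsing merges
sequences that are identical (``strict``) or compatible once missing data
are treated as wildcards (``missing-as-wildcard``), which is how
statistical-parsimony network software groups sequences before network
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, MetadataError

#: Unambiguous nucleotide states.
BASES = frozenset("ACGT")

#: IUPAC ambiguity codes, N and '?' — treated as missing observations.
AMBIGUOUS = frozenset("RYSWKMBDHVN?")

GAP = "-"


def missing_states(gap_as_state: bool = False) -> frozenset:
    """Characters treated as missing data.

    Gaps count as missing by default; with ``gap_as_state`` the gap is kept
    as a fifth character state (both conventions are in common use).
    """
    return AMBIGUOUS if gap_as_state else AMBIGUOUS | {GAP}


@dataclass(frozen=True)
class MarkerAlignment:
    """One aligned locus: parallel tuples of sample IDs and sequences."""

    marker_name: str
    samples: tuple
    sequences: tuple
    coding: bool = False

    def __post_init__(self):
        if not self.samples:
            raise AlignmentError(f"{self.marker_name}: empty alignment")
        if len(self.samples) != len(self.sequences):
            raise AlignmentError(
                f"{self.marker_name}: {len(self.samples)} ids vs "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise AlignmentError(f"{self.marker_name}: duplicate sample IDs {dupes}")
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.marker_name}: unequal sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError(f"{self.marker_name}: zero-length sequences")
        allowed = BASES | AMBIGUOUS | {GAP}
        for sid, s in zip(self.samples, seqs):
            bad = set(s) - allowed
            if bad:
                raise AlignmentError(
                    f"{self.marker_name}/{sid}: invalid characters {sorted(bad)}"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequences[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sequence_of(self, sample_id: str) -> str:
        try:
            return self.sequences[self.samples.index(sample_id)]
        except ValueError:
            raise KeyError(sample_id) from None

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.samples, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    population: str
    voucher: Optional[str] = None
    sex: Optional[str] = None  # male / female / unknown

    def __post_init__(self):
        if self.sex is not None and self.sex not in {"male", "female", "unknown"}:
            raise MetadataError(
                f"{self.sample_id}: sex must be male/female/unknown, got {self.sex!r}"
            )


def read_metadata(csv_path) -> dict:
    """Read the ``sample_id,population,voucher,sex`` table into a dict."""
    df = pd.read_csv(csv_path, dtype=str).fillna("")
    required = {"sample_id", "population"}
    if not required <= set(df.columns):
        raise MetadataError(
            f"metadata must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out = {}
    for _, row in df.iterrows():
        sid = row["sample_id"].strip()
        if sid in out:
            raise MetadataError(f"duplicate metadata row for sample {sid!r}")
        out[sid] = SampleMetadata(
            sample_id=sid,
            population=row["population"].strip(),
            voucher=(row.get("voucher") or None) or None,
            sex=(row.get("sex") or None) or None,
        )
    if not out:
        raise MetadataError("metadata table is empty")
    return out


def write_metadata(metadata: Mapping, csv_path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "population": m.population,
            "voucher": m.voucher or "",
            "sex": m.sex or "",
        }
        for m in metadata.values()
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def population_map(metadata: Mapping) -> dict:
    """sample_id -> population label."""
    return {sid: m.population for sid, m in metadata.items()}


def read_alignment(fasta_path, metadata_path, marker: str,
                   coding: bool = False) -> MarkerAlignment:
    """Read a FASTA alignment and check every record against the metadata.

    Raises :class:`AlignmentError` for unequal lengths / empty input and
    :class:`MetadataError` if a record has no metadata row.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"{marker}: no records in {fasta_path}")
    aln = MarkerAlignment(
        marker_name=marker,
        samples=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
        coding=coding,
    )
    meta = read_metadata(metadata_path)
    missing = [s for s in aln.samples if s not in meta]
    if missing:
        raise MetadataError(f"{marker}: no metadata for samples {missing}")
    return aln


@dataclass(frozen=True)
class HaplotypeSet:
    """Distinct sequence variants and the samples carrying each.

    ``haplotypes[i]`` is the representative sequence of haplotype *i*;
    under the wildcard policy it is the consensus of the merged members
    with missing positions filled by any observed base.
    """

    marker_name: str
    haplotypes: tuple
    members: tuple  # tuple of tuples of sample IDs, parallel to haplotypes

    def __post_init__(self):
        all_samples = [s for grp in self.members for s in grp]
        if len(all_samples) != len(set(all_samples)):
            raise AlignmentError("haplotype member sets overlap")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def sample_ids(self) -> frozenset:
        return frozenset(s for grp in self.members for s in grp)

    def members_of(self, index: int) -> tuple:
        return self.members[index]

    def haplotype_of(self, sample_id: str) -> int:
        for i, grp in enumerate(self.members):
            if sample_id in grp:
                return i
        raise KeyError(sample_id)


def _compatible(a: str, b: str, missing: frozenset) -> bool:
    return all(x == y or x in missing or y in missing for x, y in zip(a, b))


def collapse_haplotypes(aln: MarkerAlignment,
                        policy: str = "missing-as-wildcard",
                        gap_as_state: bool = False) -> HaplotypeSet:
    """Collapse identical (or missing-compatible) sequences into haplotypes.

    ``strict``
        sequences share a haplotype iff identical character by character.
    ``missing-as-wildcard``
        N / ambiguity codes (and gaps unless ``gap_as_state``) match any
        base; sequences are merged greedily in input order onto the first
        compatible representative, whose missing positions are refined with
        newly observed bases.  The greedy merge is order-dependent, which is
        the documented tie-break.
    """
    if policy not in {"strict", "missing-as-wildcard"}:
        raise ValueError(f"unknown collapse policy {policy!r}")
    if policy == "strict":
        groups: dict = {}
        for sid, seq in zip(aln.samples, aln.sequences):
            groups.setdefault(seq, []).append(sid)
        return HaplotypeSet(
            marker_name=aln.marker_name,
            haplotypes=tuple(groups.keys()),
            members=tuple(tuple(v) for v in groups.values()),
        )

    missing = missing_states(gap_as_state)
    reps: list = []     # list of list-of-chars representatives
    members: list = []
    for sid, seq in zip(aln.samples, aln.sequences):
        for rep, grp in zip(reps, members):
            if _compatible("".join(rep), seq, missing):
                grp.append(sid)
                for i, c in enumerate(seq):  # refine missing rep positions
                    if rep[i] in missing and c not in missing:
                        rep[i] = c
                break
        else:
            reps.append(list(seq))
            members.append([sid])
    return HaplotypeSet(
        marker_name=aln.marker_name,
        haplotypes=tuple("".join(r) for r in reps),
        members=tuple(tuple(g) for g in members),
    )


def count_variable_sites(aln: MarkerAlignment, gap_as_state: bool = False) -> int:
    """Number of columns with >= 2 distinct observed (non-missing) states."""
    missing = missing_states(gap_as_state)
    n = 0
    for col in zip(*aln.sequences):
        states = {c for c in col if c not in missing}
        if len(states) >= 2:
            n += 1
    return n
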
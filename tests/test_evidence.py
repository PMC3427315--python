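"""Candidate designation, lines of evidence and rank assignment."""

import itertools

import pytest

from taxonlines import (CandidateTaxon, EvidenceConfig, EvidenceProfile,
                        assign_ranks, build_networks, collapse_haplotypes,
                        connection_limit, designate_candidate, evaluate_lines)
from taxonlines.evidence_engine import fixed_substitutions, shared_haplotypes
from conftest import make_alignment


class TestDesignation:
    def test_distinct_with_character_is_confirmed(self):
        assert designate_candidate(True, True) == "CCS"

    def test_molecular_only_is_unconfirmed(self):
        assert designate_candidate(True, False) == "UCS"

    def test_admixture_is_deep_conspecific_lineage(self):
        assert designate_candidate(True, False, admixture=True) == "DCL"

    def test_explicitly_slight_differences_demote(self):
        assert designate_candidate(True, False,
                                   slight_differences_only=True) == "DCL"

    def test_sympatry_without_admixture_confirms(self):
        assert designate_candidate(True, False,
                                   sympatric_no_admixture=True) == "CCS"

    def test_contradictory_flags(self):
        with pytest.raises(ValueError):
            designate_candidate(True, False, sympatric_no_admixture=True,
                                admixture=True)

    def test_no_evidence_at_all(self):
        with pytest.raises(ValueError):
            designate_candidate(False, False)


def _nuclear_case():
    """Rag2-style alignment: one substitution private to population A."""
    base = "A" * 613
    mutant = "G" + base[1:]
    seqs = [mutant, mutant, base, base, base, base]
    ids = ["A1", "A2", "B1", "B2", "C1", "C2"]
    pops = dict(zip(ids, ["A", "A", "B", "B", "C", "C"]))
    return make_alignment(seqs, marker="Rag2", ids=ids), pops


class TestNuclearHelpers:
    def test_private_haplotype_not_shared(self):
        aln, pops = _nuclear_case()
        hs = collapse_haplotypes(aln)
        a = {s for s, p in pops.items() if p == "A"}
        rest = set(pops) - a
        assert shared_haplotypes(hs, a, rest) == []
        assert shared_haplotypes(hs, {"B1", "B2"}, rest - {"B1", "B2"}) != []

    def test_fixed_substitution_count(self):
        aln, pops = _nuclear_case()
        a = {s for s, p in pops.items() if p == "A"}
        assert fixed_substitutions(aln, a, set(pops) - a) == 1


def _mtdna_partition():
    """Three populations, far apart; A split into two close haplotypes."""
    base = "A" * 400
    seqs = {
        "A1": base,
        "A2": base[:-1] + "G",
        "B1": "C" * 40 + base[40:],
        "B2": "C" * 40 + base[40:-1] + "G",
        "C1": base[:100] + "G" * 40 + base[140:],
        "C2": base[:100] + "G" * 40 + base[140:],
    }
    pops = {k: k[0] for k in seqs}
    aln = make_alignment(list(seqs.values()), marker="cytb",
                         ids=list(seqs.keys()))
    hs = collapse_haplotypes(aln)
    part = build_networks(hs, connection_limit(400), pops)
    return part, pops


class TestEvaluateLines:
    def _candidates(self):
        return {p: CandidateTaxon(p, frozenset({p}), "X" if p in "AB" else "Y")
                for p in "ABC"}

    def test_anjouan_like_profile(self):
        # independent network, private nuclear haplotype one step away,
        # no morphology supplied: lines (True, False, None) by default
        part, pops = _mtdna_partition()
        aln, npops = _nuclear_case()
        cands = self._candidates()
        prof = evaluate_lines(cands["A"], [cands["B"], cands["C"]], part,
                              {"Rag2": aln}, None, pops)
        assert prof.mtdna_line is True
        assert prof.ndna_line is False          # 1 substitution < default 2
        assert prof.detail["ndna"]["fixed_substitutions"] == 1
        assert prof.n_lines == 1

    def test_lower_nuclear_threshold_flips_the_line(self):
        part, pops = _mtdna_partition()
        aln, _ = _nuclear_case()
        cands = self._candidates()
        cfg = EvidenceConfig(min_nuclear_substitutions=1)
        prof = evaluate_lines(cands["A"], [cands["B"], cands["C"]], part,
                              {"Rag2": aln}, None, pops, cfg)
        assert prof.ndna_line is True

    def test_shared_nuclear_haplotype_blocks_the_line(self):
        part, pops = _mtdna_partition()
        aln, _ = _nuclear_case()
        cands = self._candidates()
        cfg = EvidenceConfig(min_nuclear_substitutions=1)
        prof = evaluate_lines(cands["B"], [cands["A"], cands["C"]], part,
                              {"Rag2": aln}, None, pops, cfg)
        assert prof.ndna_line is False

    def test_missing_configured_marker_named_in_error(self):
        part, pops = _mtdna_partition()
        cands = self._candidates()
        with pytest.raises(KeyError, match="Rag2"):
            evaluate_lines(cands["A"], [cands["B"]], part, {}, None, pops)


def profile(name, mt, nd, mo):
    return EvidenceProfile(name, mt, nd, mo)


def comoro_profiles(anjouan_nd=False):
    clade_profiles = {
        "AM": profile("AM", True, False, True),
        "GM": profile("GM", True, False, True),
    }
    cand_profiles = {
        "Anjouan": profile("Anjouan", True, anjouan_nd, False),
        "Mayotte": profile("Mayotte", True, False, False),
        "GrandComoro": profile("GrandComoro", True, False, False),
        "Moheli": profile("Moheli", True, False, False),
    }
    candidates = [
        CandidateTaxon("Anjouan", frozenset({"Anjouan"}), "AM"),
        CandidateTaxon("Mayotte", frozenset({"Mayotte"}), "AM"),
        CandidateTaxon("GrandComoro", frozenset({"GrandComoro"}), "GM"),
        CandidateTaxon("Moheli", frozenset({"Moheli"}), "GM"),
    ]
    return candidates, clade_profiles, cand_profiles


RANK_ORDER = {"not-distinct": 0, "subspecies": 1, "species": 2}


class TestAssignRanks:
    def test_two_species_each_with_two_subspecies(self):
        cands, cp, pp = comoro_profiles()
        res = assign_ranks(cands, cp, pp)
        assert res.n_species == 2
        assert res.n_subspecies == 4
        assert all(r == "subspecies" for r in res.ranks.values())

    def test_strict_nuclear_reading_elevates_one_candidate(self):
        cands, cp, pp = comoro_profiles(anjouan_nd=True)
        res = assign_ranks(cands, cp, pp)
        assert res.ranks["Anjouan"] == "species"
        assert res.n_species == 3
        # the orphaned sibling is a monotypic species, not a subspecies
        assert res.ranks["Mayotte"] == "species"
        assert res.ranks["GrandComoro"] == "subspecies"

    def test_no_lines_anywhere_collapses_to_single_species(self):
        cands, cp, pp = comoro_profiles()
        cp = {k: profile(k, False, False, False) for k in cp}
        pp = {k: profile(k, False, False, False) for k in pp}
        res = assign_ranks(cands, cp, pp)
        assert res.n_species == 1
        assert res.n_subspecies == 0

    def test_within_clade_pair_with_two_lines_each_splits_fully(self):
        cands, cp, pp = comoro_profiles()
        pp["Anjouan"] = profile("Anjouan", True, False, True)
        pp["Mayotte"] = profile("Mayotte", True, False, True)
        res = assign_ranks(cands, cp, pp)
        assert res.n_species >= 3
        assert res.ranks["Anjouan"] == "species"
        assert res.ranks["Mayotte"] == "species"

    def test_overlapping_candidate_populations_rejected(self):
        cands, cp, pp = comoro_profiles()
        bad = cands + [CandidateTaxon("dup", frozenset({"Anjouan"}), "AM")]
        pp["dup"] = profile("dup", True, False, False)
        with pytest.raises(ValueError):
            assign_ranks(bad, cp, pp)

    def test_each_subspecies_belongs_to_exactly_one_species(self):
        cands, cp, pp = comoro_profiles()
        res = assign_ranks(cands, cp, pp)
        seen = [m for _, members in res.species for m in members]
        assert sorted(seen) == sorted(set(seen))

    def test_adding_a_line_never_lowers_any_rank(self):
        cands, cp, pp = comoro_profiles()
        base = assign_ranks(cands, cp, pp)
        for name in pp:
            for attr in ("mtdna_line", "ndna_line", "morphology_line"):
                p = pp[name]
                if getattr(p, attr):
                    continue
                boosted = dict(pp)
                boosted[name] = EvidenceProfile(
                    p.candidate,
                    True if attr == "mtdna_line" else p.mtdna_line,
                    True if attr == "ndna_line" else p.ndna_line,
                    True if attr == "morphology_line" else p.morphology_line)
                res = assign_ranks(cands, cp, boosted)
                assert (RANK_ORDER[res.ranks[name]]
                        >= RANK_ORDER[base.ranks[name]])

    def test_deterministic_and_order_invariant(self):
        cands, cp, pp = comoro_profiles()
        r1 = assign_ranks(cands, cp, pp)
        r2 = assign_ranks(list(reversed(cands)), cp, pp)
        assert r1.ranks == r2.ranks
        assert sorted(r1.species) == sorted(r2.species)
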
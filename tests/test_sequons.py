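"""Sequon scanning, putative glycopeptide calling, redundancy collapse."""

import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

from venomglyco.sequons import (
    GlycoSite,
    PeptideIdentification,
    ProteinRecord,
    call_putative_glycopeptides,
    collapse_redundancy,
    find_sequons,
    site_ratio,
)


def prot(seq, pid="P1", **kw):
    return ProteinRecord(pid, seq, **kw)


def brute_force_sequons(seq):
    """Independent oracle: regex over every tripeptide window."""
    return sorted(
        i + 1 for i in range(len(seq) - 2)
        if re.fullmatch(r"N[^P][ST]", seq[i:i + 3])
    )


class TestFindSequons:
    def test_simple_nxt(self):
        hits = find_sequons(prot("AANGTK"))
        assert [(h.position, h.motif) for h in hits] == [(3, "NXT")]

    def test_proline_excluded(self):
        assert find_sequons(prot("AANPTK")) == []

    def test_adjacent_sequons(self):
        hits = find_sequons(prot("NGSNGT"))
        assert [(h.position, h.motif) for h in hits] == [(1, "NXS"), (4, "NXT")]

    def test_noncanonical_flagged_not_countable(self):
        hits = find_sequons(prot("AANGCAATGNAA"), include_noncanonical=True)
        canonical = [h for h in hits if h.canonical]
        flagged = [h for h in hits if not h.canonical]
        assert canonical == []
        assert {(h.position, h.noncanonical_flag) for h in flagged} == {
            (3, "NXC"), (10, "reverse-S/TXN"),
        }

    @given(st.text(alphabet="ANPSTGKLR", min_size=3, max_size=200))
    def test_agrees_with_brute_force(self, seq):
        hits = find_sequons(prot(seq))
        assert [h.position for h in hits] == brute_force_sequons(seq)
        for h in hits:
            assert seq[h.position - 1] == "N"
            assert seq[h.position] != "P"
            assert seq[h.position + 1] in "ST"


def ident(sample, rep, pep, deam, pid="P1", start=1, fraction="dF1"):
    return PeptideIdentification(
        sample_id=sample, replicate=rep, fraction=fraction, peptide=pep,
        deamidation_positions=deam, protein_mappings=((pid, start),),
    )


class TestCallPutative:
    PROT = {"P1": prot("AANGTKAANPTKAANAAK")}

    def test_two_replicates_is_putative(self):
        part = call_putative_glycopeptides(
            [ident("s", 1, "AANGTK", (3,)), ident("s", 2, "AANGTK", (3,))], self.PROT
        )
        assert [e["peptide"] for e in part.putative_glyco] == ["AANGTK"]
        assert part.putative_glyco[0]["sites"] == (("P1", 3),)

    def test_single_replicate_excluded(self):
        part = call_putative_glycopeptides([ident("s", 1, "AANGTK", (3,))], self.PROT)
        assert part.putative_glyco == []
        assert part.deamidated_only[0]["reason"] == "insufficient_replicates"

    def test_proline_sequon_is_deamidated_only(self):
        recs = [ident("s", r, "AANPTK", (3,), start=7) for r in (1, 2, 3)]
        part = call_putative_glycopeptides(recs, self.PROT)
        assert part.putative_glyco == []
        assert part.deamidated_only[0]["reason"] == "no_canonical_sequon_at_deamidated_site"

    def test_truncated_sequon_validated_in_protein_context(self):
        # peptide ends at the sequon Asn; S/T lies beyond the tryptic boundary
        p = {"P1": prot("AAKGGNVTAAK")}
        recs = [ident("s", r, "GGN", (3,), start=4) for r in (1, 2)]
        part = call_putative_glycopeptides(recs, p)
        assert part.putative_glyco[0]["sites"] == (("P1", 6),)

    def test_nonmodified_partition(self):
        part = call_putative_glycopeptides([ident("s", 1, "AANGTK", ())], self.PROT)
        assert part.putative_glyco == part.deamidated_only == []
        assert len(part.nonmodified) == 1

    def test_unmappable_peptide_warned(self):
        part = call_putative_glycopeptides(
            [ident("s", 1, "WWWWWW", ()), ident("s", 1, "NGTAAA", (1,), pid="PX")],
            self.PROT,
        )
        assert any(w["reason"] == "unmappable_peptide" for w in part.warnings)
        assert not part.putative_glyco

    def test_fractions_pooled_for_replicate_count(self):
        recs = [
            ident("s", 1, "AANGTK", (3,), fraction="dF1"),
            ident("s", 2, "AANGTK", (3,), fraction="dF3"),
        ]
        assert call_putative_glycopeptides(recs, self.PROT).putative_glyco

    @given(st.integers(1, 4))
    def test_monotone_in_min_replicates(self, k):
        recs = [
            ident("s", r, "AANGTK", (3,)) for r in (1, 2, 3)
        ] + [ident("s", 1, "AANAAK", (3,), start=13)]
        lo = call_putative_glycopeptides(recs, self.PROT, min_replicates=k)
        hi = call_putative_glycopeptides(recs, self.PROT, min_replicates=k + 1)
        assert {e["peptide"] for e in hi.putative_glyco} <= {
            e["peptide"] for e in lo.putative_glyco
        }


def putative_entry(sample, pep, sites):
    return {"sample_id": sample, "peptide": pep, "sites": tuple(sites),
            "deamidation_positions": (1,), "n_replicates": 2,
            "replicates": (1, 2), "protein_mappings": (), "reason": "putative_glyco"}


def brute_force_collapse(peptides_sites):
    """All-pairs substring oracle within one sample."""
    kept = []
    for pep, sites in peptides_sites:
        if not any(
            pep != q and pep in q and set(sites) & set(qs)
            for q, qs in peptides_sites
        ):
            kept.append(pep)
    return sorted(set(kept))


class TestCollapse:
    PROT = {"P1": prot("PEPTIDENGTKAAANGSK")}

    def test_subset_peptide_removed(self):
        entries = [
            putative_entry("s", "PEPTIDENGTK", [("P1", 8)]),
            putative_entry("s", "TIDENGTK", [("P1", 8)]),
        ]
        reps, sites = collapse_redundancy(entries, self.PROT)
        assert [e["peptide"] for e in reps] == ["PEPTIDENGTK"]
        assert [(s.protein_id, s.position, s.motif) for s in sites] == [("P1", 8, "NXT")]

    def test_different_sites_both_kept(self):
        entries = [
            putative_entry("s", "PEPTIDENGTK", [("P1", 8)]),
            putative_entry("s", "AAANGSK", [("P1", 15)]),
        ]
        reps, sites = collapse_redundancy(entries, self.PROT)
        assert len(reps) == 2 and len(sites) == 2

    def test_identity(self):
        entries = [putative_entry("s", "AAANGSK", [("P1", 15)])]
        reps, sites = collapse_redundancy(entries, self.PROT)
        assert [e["peptide"] for e in reps] == ["AAANGSK"]

    def test_idempotent_and_order_independent(self):
        entries = [
            putative_entry("s", "PEPTIDENGTK", [("P1", 8)]),
            putative_entry("s", "TIDENGTK", [("P1", 8)]),
            putative_entry("s", "AAANGSK", [("P1", 15)]),
        ]
        reps1, sites1 = collapse_redundancy(entries, self.PROT)
        reps2, sites2 = collapse_redundancy(entries[::-1], self.PROT)
        assert [e["peptide"] for e in reps1] == [e["peptide"] for e in reps2]
        assert sites1 == sites2
        reps3, sites3 = collapse_redundancy(reps1, self.PROT)
        assert [e["peptide"] for e in reps3] == [e["peptide"] for e in reps1]

    def test_every_site_is_canonical_sequon(self, zero_noise_bundle):
        from venomglyco.io import peptide_identifications

        b = zero_noise_bundle
        part = call_putative_glycopeptides(
            peptide_identifications(b.deglyco_table), b.proteins
        )
        _, sites = collapse_redundancy(part.putative_glyco, b.proteins)
        for s in sites:
            assert s.position in {
                h.position for h in find_sequons(b.proteins[s.protein_id])
            }

    @given(
        st.lists(
            st.sampled_from(
                ["PEPTIDENGTK", "TIDENGTK", "IDENGTK", "DENGTK", "AAANGSK", "ANGSK"]
            ),
            min_size=1, max_size=6, unique=True,
        )
    )
    def test_matches_brute_force_oracle(self, peps):
        site_of = {
            "PEPTIDENGTK": ("P1", 8), "TIDENGTK": ("P1", 8), "IDENGTK": ("P1", 8),
            "DENGTK": ("P1", 8), "AAANGSK": ("P1", 15), "ANGSK": ("P1", 15),
        }
        entries = [putative_entry("s", p, [site_of[p]]) for p in peps]
        reps, _ = collapse_redundancy(entries, self.PROT)
        assert sorted(e["peptide"] for e in reps) == brute_force_collapse(
            [(p, [site_of[p]]) for p in peps]
        )


class TestSiteRatio:
    def test_simple_percentages(self):
        sites = [GlycoSite("P1", i, "NXT", "s") for i in (1, 4, 7, 10, 13, 16, 19, 22, 25, 28)]
        peps = [putative_entry("s", f"PEP{i}", [("P1", i)]) for i in range(20)]
        assert site_ratio(sites, peps) == pytest.approx(50.0)
        assert site_ratio(sites[:1], peps[:1]) == pytest.approx(100.0)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            site_ratio([], [])
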
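"""Intact glycopeptide assembly, occupancy and distribution summaries."""

import pandas as pd
import pytest

from venomglyco.assembly import (
    assemble,
    class_distribution,
    expected_vs_identified,
    glycopeptide_neutral_mass,
    o_acetyl_fraction,
)
from venomglyco.glycans import parse_composition
from venomglyco.sequons import GlycoSite, ProteinRecord

MAN5 = "(Hex)2 + (Man)3(GlcNAc)2"
B43 = "(Hex)2 (HexNAc)2 (Deoxyhexose)1 (NeuAc)2 + (Man)3(GlcNAc)2"

PROTEINS = {
    "SVMP_1": ProteinRecord(
        "SVMP_1", "AANGTKPEPTIDENVSKAAAWK", toxin_class="SVMP",
        domain_annotations=(("pro", 1, 8), ("catalytic", 9, 22)),
    ),
    "SVSP_1": ProteinRecord("SVSP_1", "GGWDENGSKAAK", toxin_class="SVSP"),
}


def row(sample="s1", backbone="AANGTK", pid="SVMP_1", site=3, comp=MAN5, score=10.0,
        mass=None, acetyl=0):
    if mass is None:
        mass = glycopeptide_neutral_mass(
            backbone, parse_composition(comp, acetyl_count=acetyl)
        )
    return {"sample_id": sample, "backbone": backbone, "protein_id": pid, "site": site,
            "composition": comp, "acetyl_count": acetyl, "neutral_mass": mass,
            "score": score}


class TestAssemble:
    def test_dedup_keeps_best_score(self):
        table = pd.DataFrame([row(score=10.0), row(score=40.0)])
        res = assemble(table, PROTEINS)
        assert len(res.records) == 1
        assert res.records[0].score == 40.0

    def test_combinatorial_counts(self):
        rows = []
        for backbone, pid, site in [
            ("AANGTK", "SVMP_1", 3), ("PEPTIDENVSK", "SVMP_1", 14), ("GGWDENGSK", "SVSP_1", 6)
        ]:
            for comp in (MAN5, B43):
                rows.append(row(backbone=backbone, pid=pid, site=site, comp=comp))
        res = assemble(pd.DataFrame(rows), PROTEINS)
        counts = res.per_sample_counts().iloc[0]
        assert counts["n_glycopeptides"] == 6
        assert counts["n_backbones"] == 3
        assert counts["n_compositions"] == 2

    def test_no_sequon_backbone_rejected(self):
        table = pd.DataFrame([row(backbone="AAAWK", site=19)])
        res = assemble(table, PROTEINS)
        assert not res.records
        assert res.rejected[0]["reason"] == "site_not_canonical_sequon"

    def test_unparseable_composition_rejected(self):
        table = pd.DataFrame([row(comp="(Fru)3", mass=1.0)])
        res = assemble(table, PROTEINS)
        assert "unparseable_composition" in res.rejected[0]["reason"]

    def test_mass_validation_catches_1da_corruption(self):
        good = row()
        bad = row(backbone="PEPTIDENVSK", site=14)
        bad["neutral_mass"] += 1.0
        res = assemble(pd.DataFrame([good, bad]), PROTEINS, validate_mass_tol=0.02)
        assert len(res.records) == 1
        assert res.rejected[0]["reason"] == "neutral_mass_mismatch"

    def test_counts_ordering_invariant(self, default_bundle):
        """n_sites <= n_backbones <= n_glycopeptides for every sample."""
        b = default_bundle
        res = assemble(b.intact_table, b.proteins, b.glycan_db)
        counts = res.per_sample_counts()
        assert (counts["n_sites"] <= counts["n_backbones"]).all()
        assert (counts["n_backbones"] <= counts["n_glycopeptides"]).all()


class TestExpectedVsIdentified:
    def _sites(self, positions, sample="s1"):
        return [GlycoSite("SVMP_1", p, "NXT", sample) for p in positions]

    def test_identical_sets_full_recovery(self):
        recs = assemble(pd.DataFrame([row(), row(backbone="PEPTIDENVSK", site=14)]),
                        PROTEINS).records
        out = expected_vs_identified(self._sites([3, 14]), recs)
        assert out["pct_identified"].iloc[0] == pytest.approx(100.0)

    def test_half_recovery(self):
        recs = assemble(pd.DataFrame([row()]), PROTEINS).records
        out = expected_vs_identified(self._sites([3, 14]), recs)
        assert out["pct_identified"].iloc[0] == pytest.approx(50.0)
        assert out["n_only_intact"].iloc[0] == 0

    def test_empty_expected_is_error(self):
        with pytest.raises(ValueError):
            expected_vs_identified({"s1": set()}, [])


class TestClassDistribution:
    def _records(self):
        rows = (
            [row(backbone="AANGTK", pid="SVMP_1", site=3, comp=c) for c in (MAN5, B43)]
            + [row(backbone="PEPTIDENVSK", pid="SVMP_1", site=14, comp=MAN5)]
            + [row(backbone="GGWDENGSK", pid="SVSP_1", site=6, comp=c) for c in (MAN5, B43)]
        )
        return assemble(pd.DataFrame(rows), PROTEINS).records

    def test_toxin_class_split(self):
        table = class_distribution(self._records(), PROTEINS, facet="toxin_class")
        assert table.loc["s1", "SVMP"] == 3
        assert table.loc["s1", "SVSP"] == 2

    def test_svmp_domain_facet(self):
        table = class_distribution(self._records(), PROTEINS, facet="svmp_domain")
        assert table.loc["s1", "pro"] == 2          # site 3
        assert table.loc["s1", "catalytic"] == 1    # site 14
        assert table.loc["s1", "unannotated"] == 2  # SVSP record, no domain

    def test_motif_facet(self):
        table = class_distribution(self._records(), PROTEINS, facet="motif")
        assert table.loc["s1", "NXT"] == 2
        assert table.loc["s1", "NXS"] == 3

    def test_rows_sum_to_totals(self):
        recs = self._records()
        table = class_distribution(recs, PROTEINS, facet="toxin_class")
        assert table.sum(axis=1).iloc[0] == len(
            {(r.backbone, r.composition_key) for r in recs}
        )


class TestOAcetyl:
    def test_fractions(self):
        rows = []
        backbones = ["AANGTK", "PEPTIDENVSK"]
        sites = [3, 14]
        for i in range(2):
            rows.append(row(backbone=backbones[i], site=sites[i], comp=B43, acetyl=1))
        for i in range(2):
            rows.append(row(backbone=backbones[i], site=sites[i], comp=MAN5))
        recs = assemble(pd.DataFrame(rows), PROTEINS).records
        assert o_acetyl_fraction(recs)["s1"] == pytest.approx(50.0)

    def test_zero_acetylated(self):
        recs = assemble(pd.DataFrame([row()]), PROTEINS).records
        assert o_acetyl_fraction(recs)["s1"] == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            o_acetyl_fraction([])


class TestNeutralMass:
    def test_glycine_plus_empty_glycan(self):
        from venomglyco.glycans import GlycanComposition

        assert glycopeptide_neutral_mass("G", GlycanComposition({})) == pytest.approx(
            75.03203, abs=1e-4
        )

    def test_acetyl_difference(self):
        comp = parse_composition(B43)
        d = glycopeptide_neutral_mass("AANGTK", comp.with_acetyl(1)) - \
            glycopeptide_neutral_mass("AANGTK", comp)
        assert d == pytest.approx(42.0106, abs=1e-4)

    def test_unknown_residue_error(self):
        from venomglyco.glycans import GlycanComposition

        with pytest.raises(ValueError):
            glycopeptide_neutral_mass("AXZ1", GlycanComposition({}))
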
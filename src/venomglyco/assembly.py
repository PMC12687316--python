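"""Intact glycopeptide assembly and occupancy/distribution summaries.

The counting unit is the N-glycopeptide: a unique (peptide backbone, glycan
composition) pair per sample.  Charge states, retention times and replicate
spectra are collapsed; the best (highest) search score is retained on
deduplication.  Search scores are carried opaquely — no rescoring.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from pyteomics import mass as _pmass

from .glycans import GlycanComposition, composition_mass, format_composition, parse_composition
from .sequons import GlycoSite, ProteinRecord, canonical_sequon_positions

__all__ = [
    "IntactGlycopeptide",
    "AssemblyResult",
    "assemble",
    "expected_vs_identified",
    "class_distribution",
    "o_acetyl_fraction",
    "glycopeptide_neutral_mass",
    "peptide_mass",
    "occupancy_summary",
]

# Fixed Cys carbamidomethylation (+57.02146) is common in these workflows;
# off by default, switchable where peptide masses are computed.
CARBAMIDOMETHYL = 57.02146


def peptide_mass(backbone: str, carbamidomethyl: bool = False) -> float:
    """Monoisotopic peptide mass (residue sum + water), standard residues."""
    try:
        m = _pmass.fast_mass(backbone)
    except Exception as exc:
        raise ValueError(f"unknown residue in backbone {backbone!r}") from exc
    if carbamidomethyl:
        m += CARBAMIDOMETHYL * backbone.count("C")
    return m


def glycopeptide_neutral_mass(
    backbone: str, comp: GlycanComposition, carbamidomethyl: bool = False
) -> float:
    """Neutral monoisotopic mass of an intact glycopeptide.

    Peptide mass plus the glycan residue-sum (the glycosidic bond to Asn
    displaces the water the free glycan would carry) plus acetyl increments.
    """
    return peptide_mass(backbone, carbamidomethyl) + composition_mass(comp, as_free_glycan=False)


@dataclass(frozen=True)
class IntactGlycopeptide:
    sample_id: str
    backbone: str
    protein_id: str
    site: int  # 1-based Asn position in the protein
    composition: GlycanComposition
    neutral_mass: float
    score: float = 0.0

    @property
    def composition_key(self) -> str:
        """Composition identity string; acetyl variants kept distinct."""
        base = format_composition(self.composition)
        if self.composition.acetyl_count:
            return f"{base} [+{self.composition.acetyl_count}Ac]"
        return base


@dataclass
class AssemblyResult:
    records: list[IntactGlycopeptide]
    rejected: list[dict]

    def per_sample_counts(self, acetyl_distinct: bool = True) -> pd.DataFrame:
        """Per-sample tallies: glycopeptides, backbones, sites, compositions."""
        rows = []
        for sample in sorted({r.sample_id for r in self.records}):
            recs = [r for r in self.records if r.sample_id == sample]
            comp_keys = {
                r.composition_key if acetyl_distinct else format_composition(r.composition)
                for r in recs
            }
            rows.append(
                {
                    "sample_id": sample,
                    "n_glycopeptides": len({(r.backbone, r.composition_key) for r in recs}),
                    "n_backbones": len({r.backbone for r in recs}),
                    "n_sites": len({(r.protein_id, r.site) for r in recs}),
                    "n_compositions": len(comp_keys),
                }
            )
        return pd.DataFrame(rows)


def assemble(
    intact_table: pd.DataFrame,
    proteins: dict[str, ProteinRecord],
    glycan_db: pd.DataFrame | None = None,
    validate_mass_tol: float | None = None,
) -> AssemblyResult:
    """Build deduplicated intact-glycopeptide records from a search table.

    Expected columns: sample_id, backbone, protein_id, site, composition,
    neutral_mass, score, optional acetyl_count.  Rows with unparseable
    compositions, unmappable backbones, or sites that are not canonical
    sequons are rejected with a reason.  Duplicates on
    (sample, backbone, site, composition) keep the best score.

    With ``validate_mass_tol`` set (Da), rows whose reported neutral mass
    disagrees with backbone + glycan arithmetic beyond the tolerance are
    rejected — this catches corrupted or mis-assigned masses.
    """
    db_ids: dict[GlycanComposition, str] = {}
    if glycan_db is not None:
        for _, row in glycan_db.iterrows():
            try:
                db_ids[parse_composition(row["composition"])] = str(row["id"])
            except Exception:
                continue

    best: dict[tuple, IntactGlycopeptide] = {}
    rejected: list[dict] = []
    sequon_cache: dict[str, set[int]] = {}
    for idx, row in intact_table.iterrows():
        reason = None
        comp = None
        try:
            comp = parse_composition(
                str(row["composition"]), acetyl_count=int(row.get("acetyl_count", 0) or 0)
            )
        except Exception as exc:
            reason = f"unparseable_composition: {exc}"
        pid = str(row["protein_id"])
        site = int(row["site"])
        backbone = str(row["backbone"])
        if reason is None:
            prot = proteins.get(pid)
            if prot is None or backbone not in prot.sequence:
                reason = "unmappable_backbone"
            else:
                if pid not in sequon_cache:
                    sequon_cache[pid] = canonical_sequon_positions(prot)
                starts = []
                at = prot.sequence.find(backbone)
                while at != -1:
                    starts.append(at + 1)
                    at = prot.sequence.find(backbone, at + 1)
                if site not in sequon_cache[pid]:
                    reason = "site_not_canonical_sequon"
                elif not any(s <= site < s + len(backbone) for s in starts):
                    reason = "site_outside_backbone"
        if reason is None and validate_mass_tol is not None:
            expected = glycopeptide_neutral_mass(backbone, comp)
            if abs(float(row["neutral_mass"]) - expected) > validate_mass_tol:
                reason = "neutral_mass_mismatch"
        if reason is not None:
            rejected.append({"row": idx, "reason": reason})
            continue
        if comp in db_ids and comp.id is None:
            comp = GlycanComposition(
                dict(comp.counts), comp.acetyl_count, dict(comp.core), id=db_ids[comp]
            )
        rec = IntactGlycopeptide(
            sample_id=str(row["sample_id"]),
            backbone=backbone,
            protein_id=pid,
            site=site,
            composition=comp,
            neutral_mass=float(row["neutral_mass"]),
            score=float(row.get("score", 0.0) or 0.0),
        )
        key = (rec.sample_id, rec.backbone, rec.protein_id, rec.site, rec.composition_key)
        if key not in best or rec.score > best[key].score:
            best[key] = rec
    return AssemblyResult(records=[best[k] for k in sorted(best)], rejected=rejected)


def expected_vs_identified(
    expected_sites: dict[str, set[tuple[str, int]]] | list[GlycoSite],
    records: list[IntactGlycopeptide],
) -> pd.DataFrame:
    """Per-sample fraction of expected sites recovered in the intact analysis.

    Expected sites come from the de-glyco stage; identified sites from intact
    records.  Sites seen only intact are reported separately, never counted
    in the recovery fraction.
    """
    if not isinstance(expected_sites, dict):
        exp: dict[str, set[tuple[str, int]]] = defaultdict(set)
        for s in expected_sites:
            exp[s.sample_id].add((s.protein_id, s.position))
        expected_sites = dict(exp)
    ident: dict[str, set[tuple[str, int]]] = defaultdict(set)
    for r in records:
        ident[r.sample_id].add((r.protein_id, r.site))
    rows = []
    for sample in sorted(expected_sites):
        expected = expected_sites[sample]
        if not expected:
            raise ValueError(f"empty expected site set for sample {sample!r}")
        found = ident.get(sample, set())
        rows.append(
            {
                "sample_id": sample,
                "n_expected": len(expected),
                "n_identified_of_expected": len(expected & found),
                "pct_identified": 100.0 * len(expected & found) / len(expected),
                "n_only_intact": len(found - expected),
            }
        )
    return pd.DataFrame(rows)


def class_distribution(
    records: list[IntactGlycopeptide],
    proteins: dict[str, ProteinRecord],
    facet: str = "toxin_class",
    unit: str = "glycopeptides",
) -> pd.DataFrame:
    """Contingency table of glycopeptides (or sites) per facet level per sample.

    ``facet``: toxin_class, svmp_domain, or motif.  Records whose annotation
    is missing are tallied under "unannotated".
    """
    if facet not in ("toxin_class", "svmp_domain", "motif"):
        raise ValueError(f"unknown facet: {facet!r}")
    if unit not in ("glycopeptides", "sites"):
        raise ValueError(f"unknown unit: {unit!r}")

    def level(rec: IntactGlycopeptide) -> str:
        prot = proteins.get(rec.protein_id)
        if prot is None:
            return "unannotated"
        if facet == "toxin_class":
            return prot.toxin_class or "unannotated"
        if facet == "svmp_domain":
            return prot.domain_at(rec.site) or "unannotated"
        seq = prot.sequence
        return f"NX{seq[rec.site + 1]}" if rec.site + 1 < len(seq) else "unannotated"

    tally: dict[tuple[str, str], set] = defaultdict(set)
    for r in records:
        unit_key = (
            (r.backbone, r.composition_key) if unit == "glycopeptides" else (r.protein_id, r.site)
        )
        tally[(r.sample_id, level(r))].add(unit_key)
    samples = sorted({s for s, _ in tally})
    levels = sorted({lv for _, lv in tally})
    table = pd.DataFrame(
        [[len(tally.get((s, lv), ())) for lv in levels] for s in samples],
        index=pd.Index(samples, name="sample_id"),
        columns=levels,
    )
    return table


def o_acetyl_fraction(records: list[IntactGlycopeptide]) -> pd.Series:
    """Per-sample percentage of glycopeptides carrying >= 1 O-acetyl on NeuAc."""
    if not records:
        raise ValueError("o_acetyl_fraction undefined for an empty record set")
    by_sample: dict[str, list[IntactGlycopeptide]] = defaultdict(list)
    for r in records:
        by_sample[r.sample_id].append(r)
    return pd.Series(
        {
            s: 100.0 * sum(r.composition.acetyl_count >= 1 for r in recs) / len(recs)
            for s, recs in sorted(by_sample.items())
        },
        name="pct_o_acetylated",
    )


def occupancy_summary(
    expected_sites, records: list[IntactGlycopeptide], acetyl_distinct: bool = True
) -> pd.DataFrame:
    """Combined per-sample counts plus expected-vs-identified recovery."""
    counts = AssemblyResult(records, []).per_sample_counts(acetyl_distinct)
    evi = expected_vs_identified(expected_sites, records)
    return counts.merge(evi, on="sample_id", how="outer")
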
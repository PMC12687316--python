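"""Sequon scanning, putative glycopeptide calling, and redundancy collapse.

PNGase F release of an N-glycan converts the carrier Asn to Asp (+0.984 Da
deamidation).  A peptide observed deamidated in at least two replicates, with
the deamidated Asn sitting in a canonical N-glycosylation sequon
(N-X-S/T, X != Pro) of its parent protein, is called a putative (formerly)
N-glycosylated peptide.  Deamidation is a spontaneous modification too, so
deamidated peptides failing the sequon test are kept as a separate class.

Tryptic and semitryptic cleavage can truncate a sequon at the peptide
C-terminus (the S/T falling beyond the cut), so sequon membership is always
evaluated in the parent protein's coordinates, never on the bare peptide.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

__all__ = [
    "ProteinRecord",
    "SequonHit",
    "PeptideIdentification",
    "GlycoSite",
    "PutativePartition",
    "find_sequons",
    "call_putative_glycopeptides",
    "collapse_redundancy",
    "site_ratio",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

TOXIN_CLASSES = (
    "SVMP", "SVSP", "LAAO", "CTL", "PLA2", "5'-Nase",
    "APase", "PDE", "PLB", "HYA", "CRISP", "other",
)
SVMP_DOMAINS = ("pro", "catalytic", "disintegrin", "Cys-rich")


@dataclass(frozen=True)
class ProteinRecord:
    """A venom protein with toxin-class and (for SVMPs) domain annotation.

    Positions are 1-based inclusive on the full precursor sequence as given
    in the FASTA (signal/pro regions included).
    """

    protein_id: str
    sequence: str
    toxin_class: str = "other"
    domain_annotations: tuple = ()  # (label, start, end), 1-based inclusive

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.protein_id}: non-canonical residues {sorted(bad)}")
        spans = sorted((int(s), int(e)) for _, s, e in self.domain_annotations)
        for (s, e) in spans:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"{self.protein_id}: domain [{s},{e}] outside sequence")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.protein_id}: overlapping domain annotations")

    def domain_at(self, position: int) -> str | None:
        for label, s, e in self.domain_annotations:
            if int(s) <= position <= int(e):
                return label
        return None


@dataclass(frozen=True)
class SequonHit:
    protein_id: str
    position: int  # 1-based Asn index
    motif: str  # "NXS" or "NXT" for canonical hits
    noncanonical_flag: str | None = None  # "NXC", "NXV", or "reverse-S/TXN"

    @property
    def canonical(self) -> bool:
        return self.noncanonical_flag is None


@dataclass(frozen=True)
class PeptideIdentification:
    """One replicate-level peptide observation from a de-glyco search table."""

    sample_id: str
    replicate: int
    fraction: str
    peptide: str
    deamidation_positions: tuple[int, ...] = ()  # peptide-local, 1-based, on N
    protein_mappings: tuple[tuple[str, int], ...] = ()  # (protein_id, start 1-based)
    missed_cleavages: int = 0
    other_modifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for p in self.deamidation_positions:
            if not (1 <= p <= len(self.peptide)):
                raise ValueError(f"deamidation position {p} outside peptide {self.peptide!r}")
            if self.peptide[p - 1] != "N":
                raise ValueError(
                    f"deamidation position {p} is {self.peptide[p - 1]!r}, not N, in {self.peptide!r}"
                )


@dataclass(frozen=True)
class GlycoSite:
    protein_id: str
    position: int  # 1-based Asn index in the protein
    motif: str
    sample_id: str
    supporting_peptides: frozenset[str] = frozenset()


@dataclass
class PutativePartition:
    """Exhaustive, disjoint partition of (sample, peptide, deamidation-state) groups."""

    putative_glyco: list[dict] = field(default_factory=list)
    deamidated_only: list[dict] = field(default_factory=list)
    nonmodified: list[dict] = field(default_factory=list)
    warnings: list[dict] = field(default_factory=list)


def find_sequons(protein: ProteinRecord, include_noncanonical: bool = False) -> list[SequonHit]:
    """Scan a protein for N-glycosylation sequons.

    Canonical rule: Asn at i, residue i+1 != Pro, residue i+2 in {S, T}.
    With ``include_noncanonical``, NXC/NXV (same X != P window) and the
    reverse motif S/T-X-N are returned flagged; flagged hits are never
    counted as glycosylation sites downstream.
    """
    seq = protein.sequence
    hits: list[SequonHit] = []
    for i in range(len(seq) - 2):
        a, x, c = seq[i], seq[i + 1], seq[i + 2]
        if a == "N" and x != "P":
            if c in "ST":
                hits.append(SequonHit(protein.protein_id, i + 1, f"NX{c}"))
            elif include_noncanonical and c in "CV":
                hits.append(SequonHit(protein.protein_id, i + 1, f"NX{c}", f"NX{c}"))
        if include_noncanonical and a in "ST" and c == "N" and x != "P":
            hits.append(SequonHit(protein.protein_id, i + 3, f"{a}XN", "reverse-S/TXN"))
    hits.sort(key=lambda h: (h.position, h.noncanonical_flag is not None, h.motif))
    return hits


def canonical_sequon_positions(protein: ProteinRecord) -> set[int]:
    return {h.position for h in find_sequons(protein) if h.canonical}


def _map_peptide(pep: str, protein: ProteinRecord, start: int) -> bool:
    return protein.sequence[start - 1 : start - 1 + len(pep)] == pep


def call_putative_glycopeptides(
    ids: list[PeptideIdentification],
    proteins: dict[str, ProteinRecord],
    min_replicates: int = 2,
) -> PutativePartition:
    """Partition identifications into putative glyco / deamidated-only / nonmodified.

    Replicates are counted per (sample, peptide sequence, deamidated-site set)
    with fractions pooled.  A group enters ``putative_glyco`` when it was seen
    deamidated in >= ``min_replicates`` distinct replicates and at least one
    deamidated Asn falls on a canonical sequon of a mapped protein (evaluated
    in protein coordinates so C-terminally truncated sequons still count).
    Deamidated groups failing either test go to ``deamidated_only`` with a
    reason code; groups without deamidation go to ``nonmodified``.
    Unmappable peptides are excluded with a warning record.
    """
    groups: dict[tuple, list[PeptideIdentification]] = defaultdict(list)
    for rec in ids:
        groups[(rec.sample_id, rec.peptide, tuple(sorted(rec.deamidation_positions)))].append(rec)

    out = PutativePartition()
    for (sample, pep, deam), recs in sorted(groups.items()):
        replicates = sorted({r.replicate for r in recs})
        mappings: list[tuple[str, int]] = []
        unmapped: list[tuple[str, int]] = []
        for pid, start in sorted({m for r in recs for m in r.protein_mappings}):
            prot = proteins.get(pid)
            if prot is None or not _map_peptide(pep, prot, start):
                unmapped.append((pid, start))
            else:
                mappings.append((pid, start))
        for pid, start in unmapped:
            out.warnings.append(
                {"sample_id": sample, "peptide": pep, "protein_id": pid, "start": start,
                 "reason": "unmappable_peptide"}
            )
        entry = {
            "sample_id": sample,
            "peptide": pep,
            "deamidation_positions": deam,
            "n_replicates": len(replicates),
            "replicates": tuple(replicates),
            "protein_mappings": tuple(mappings),
        }
        if not deam:
            entry["reason"] = "no_deamidation"
            out.nonmodified.append(entry)
            continue
        if not mappings:
            entry["reason"] = "unmappable_peptide"
            out.warnings.append(dict(entry))
            continue
        # Deamidated Asn positions that land on canonical sequons, per protein.
        site_hits: list[tuple[str, int]] = []
        for pid, start in mappings:
            sequon_pos = canonical_sequon_positions(proteins[pid])
            for p in deam:
                prot_pos = start + p - 1
                if prot_pos in sequon_pos:
                    site_hits.append((pid, prot_pos))
        if not site_hits:
            entry["reason"] = "no_canonical_sequon_at_deamidated_site"
            out.deamidated_only.append(entry)
        elif len(replicates) < min_replicates:
            entry["reason"] = "insufficient_replicates"
            out.deamidated_only.append(entry)
        else:
            entry["reason"] = "putative_glyco"
            entry["sites"] = tuple(sorted(set(site_hits)))
            out.putative_glyco.append(entry)
    return out


def collapse_redundancy(
    putative: list[dict], proteins: dict[str, ProteinRecord]
) -> tuple[list[dict], list[GlycoSite]]:
    """Remove subset peptides (exact-substring, same site) and emit nonredundant sites.

    Within each sample, a putative peptide whose sequence is an exact
    substring of another retained peptide covering at least one common
    glycosylation site is dropped; the remaining representatives are mapped
    to (protein, position) sites.  Set semantics: the result is invariant
    under input order and duplication.
    """
    by_sample: dict[str, dict[str, dict]] = defaultdict(dict)
    for entry in putative:
        by_sample[entry["sample_id"]].setdefault(entry["peptide"], entry)

    representatives: list[dict] = []
    site_support: dict[tuple[str, str, int], set[str]] = defaultdict(set)
    for sample in sorted(by_sample):
        entries = by_sample[sample]
        peptides = sorted(entries, key=lambda p: (-len(p), p))  # longest first
        kept: list[str] = []
        for pep in peptides:
            redundant = False
            for longer in kept:
                if pep != longer and pep in longer and (
                    set(entries[pep]["sites"]) & set(entries[longer]["sites"])
                ):
                    redundant = True
                    break
            if not redundant:
                kept.append(pep)
        for pep in sorted(kept):
            representatives.append(entries[pep])
            for pid, pos in entries[pep]["sites"]:
                site_support[(sample, pid, pos)].add(pep)

    sites = []
    for (sample, pid, pos) in sorted(site_support):
        seq = proteins[pid].sequence
        motif = f"NX{seq[pos + 1]}"
        sites.append(
            GlycoSite(pid, pos, motif, sample, frozenset(site_support[(sample, pid, pos)]))
        )
    return representatives, sites


def site_ratio(sites: list[GlycoSite], putative: list[dict]) -> float:
    """Nonredundant sites as a percentage of putative glycopeptides.

    Peptides mapping to several proteins count once; each distinct
    (sample, protein, position) site counts once.
    """
    n_pep = len({(e["sample_id"], e["peptide"]) for e in putative})
    if n_pep == 0:
        raise ValueError("site_ratio undefined for an empty putative peptide set")
    n_sites = len({(s.sample_id, s.protein_id, s.position) for s in sites})
    return 100.0 * n_sites / n_pep
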
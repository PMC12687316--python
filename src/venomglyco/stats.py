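"""Microheterogeneity ratios, sialylation distributions, composition frequencies.

The heterogeneity ratio divides the number of glycoforms — unique
(site, composition) pairs — by the number of occupied sites.  A site carrying
three different glycans contributes 3 to the numerator and 1 to the
denominator, so the ratio reads as "glycoforms per glycosite" and is >= 1
whenever every counted site carries at least one composition.  An
alternative numerator (distinct compositions per group, which can fall below
the site count) is computed alongside for audit.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import pandas as pd

from .assembly import IntactGlycopeptide
from .glycans import classify, format_composition, neuac_count
from .sequons import ProteinRecord

__all__ = [
    "heterogeneity",
    "sialylation_distribution",
    "composition_frequency",
]


def _group_of(rec: IntactGlycopeptide, proteins: dict[str, ProteinRecord], grouping: str) -> str | None:
    if grouping == "global":
        return "global"
    prot = proteins.get(rec.protein_id)
    if prot is None:
        return None
    if grouping == "toxin_class":
        return prot.toxin_class
    if grouping == "svmp_domain":
        if prot.toxin_class != "SVMP":
            return None
        return prot.domain_at(rec.site)
    raise ValueError(f"unknown grouping: {grouping!r}")


def heterogeneity(
    records: list[IntactGlycopeptide],
    proteins: dict[str, ProteinRecord],
    grouping: str = "global",
    numerator: str = "glycoforms",
) -> pd.DataFrame:
    """Per-sample, per-group heterogeneity ratios.

    ``numerator="glycoforms"`` counts unique (protein, site, composition)
    pairs; ``"compositions"`` counts distinct compositions in the group.
    Groups with zero sites are omitted.  Set semantics throughout: duplicated
    records never change a ratio.
    """
    if numerator not in ("glycoforms", "compositions"):
        raise ValueError(f"unknown numerator: {numerator!r}")
    glycoforms: dict[tuple[str, str], set] = defaultdict(set)
    comps: dict[tuple[str, str], set] = defaultdict(set)
    sites: dict[tuple[str, str], set] = defaultdict(set)
    for r in records:
        g = _group_of(r, proteins, grouping)
        if g is None:
            continue
        key = (r.sample_id, g)
        glycoforms[key].add((r.protein_id, r.site, r.composition_key))
        comps[key].add(r.composition_key)
        sites[key].add((r.protein_id, r.site))
    rows = []
    for key in sorted(sites):
        n_sites = len(sites[key])
        n_num = len(glycoforms[key]) if numerator == "glycoforms" else len(comps[key])
        rows.append(
            {
                "sample_id": key[0],
                "group": key[1],
                "n_glycoforms": len(glycoforms[key]),
                "n_compositions": len(comps[key]),
                "n_sites": n_sites,
                "ratio": round(n_num / n_sites, 2),
            }
        )
    return pd.DataFrame(rows)


_SIA_BINS = ("0", "1", "2", "3", ">=4")


def _sia_bin(n: int) -> str:
    return str(n) if n < 4 else ">=4"


def sialylation_distribution(
    records: list[IntactGlycopeptide],
    proteins: dict[str, ProteinRecord],
    grouping: str = "toxin_class",
    hybrid_complex_only: bool = True,
    include_nonsialylated: bool = True,
) -> pd.DataFrame:
    """Proportion of glycopeptides per NeuAc-count bin, per sample and group.

    Bins {0, 1, 2, 3, >=4}; each row sums to 1.  With
    ``hybrid_complex_only`` (default) high-mannose records are excluded from
    the denominators; ``include_nonsialylated=False`` additionally drops the
    0 bin, reproducing the figure-style binning restricted to sialylated
    chains.  Empty groups are omitted.
    """
    counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for r in records:
        g = _group_of(r, proteins, grouping)
        if g is None:
            continue
        if hybrid_complex_only and classify(r.composition).type_label != "hybrid/complex":
            continue
        n = neuac_count(r.composition)
        if n == 0 and not include_nonsialylated:
            continue
        counts[(r.sample_id, g)][_sia_bin(n)] += 1
    bins = _SIA_BINS if include_nonsialylated else _SIA_BINS[1:]
    rows = []
    for key in sorted(counts):
        total = sum(counts[key].values())
        row = {"sample_id": key[0], "group": key[1]}
        row.update({b: counts[key].get(b, 0) / total for b in bins})
        rows.append(row)
    return pd.DataFrame(rows)


def composition_frequency(
    records: list[IntactGlycopeptide],
    proteins: dict[str, ProteinRecord] | None = None,
    grouping: str = "global",
    top: int | None = None,
) -> pd.DataFrame:
    """Identification counts per composition, ranked (word-cloud data, tabular).

    Ties broken lexicographically by canonical composition string.  The
    composition's database id is carried when resolved.
    """
    proteins = proteins or {}
    counts: dict[tuple[str, str], Counter] = defaultdict(Counter)
    ids: dict[str, str] = {}
    for r in records:
        g = _group_of(r, proteins, grouping) if grouping != "global" else "global"
        if g is None:
            continue
        key = format_composition(r.composition)
        counts[(r.sample_id, g)][key] += 1
        if r.composition.id:
            ids[key] = r.composition.id
    rows = []
    for (sample, g) in sorted(counts):
        ranked = sorted(counts[(sample, g)].items(), key=lambda kv: (-kv[1], kv[0]))
        if top is not None:
            ranked = ranked[:top]
        for rank, (comp, n) in enumerate(ranked, start=1):
            rows.append(
                {
                    "sample_id": sample,
                    "group": g,
                    "rank": rank,
                    "composition": comp,
                    "composition_id": ids.get(comp, ""),
                    "count": n,
                }
            )
    return pd.DataFrame(rows)
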
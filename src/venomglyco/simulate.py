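"""Synthetic venom glycoproteome generator with known ground truth.

Emulates the data structure of a bottom-up N-glycoproteomics study of seven
related venoms: a small toxin proteome (SVMPs with domain structure, SVSPs,
LAAO, lectins, PLA2s), planted N-glycosylation sequons, tryptic digestion
with missed/semitryptic cleavage noise, replicate-structured de-glycosylated
identification tables carrying deamidation marks, intact glycopeptide tables
drawing glycan compositions from group-structured repertoires, and MS/MS
spectra carrying the diagnostic oxonium ions the composition implies.

The seven samples fall into three groups of sizes {3, 2, 2}, mirroring the
phylogenetic structure of the Bothrops venoms the generator emulates
(Jararaca complex / cotiara+fonsecai / jararacussu+moojeni); group-specific
glycan repertoires make the groups recoverable by clustering.

Everything is driven by one integer seed; identical seeds give
byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import glycopeptide_neutral_mass
from .glycans import (
    GlycanComposition,
    diagnostic_ions,
    format_composition,
    neuac_count,
    parse_composition,
)
from .sequons import ProteinRecord, find_sequons
from .spectra import Spectrum, write_mgf

__all__ = [
    "SimulationConfig",
    "SimulationBundle",
    "simulate",
    "spectra_for",
    "planted_feature_matrix",
    "digest",
    "DEFAULT_SAMPLES",
    "GLYCAN_CATALOGUE",
]

DEFAULT_SAMPLES = (
    "B_alcatraz", "B_insularis", "B_jararaca",  # group 0: Jararaca complex
    "B_cotiara", "B_fonsecai",                   # group 1
    "B_jararacussu", "B_moojeni",                # group 2
)

# Composition catalogue.  A1/A2 are the two high-mannose structures (Man5,
# Man6) conserved across the venoms; B-series ids echo the naming scheme of
# group-specific sialylated compositions.  The remaining entries are
# generated hybrid/complex compositions covering 0-4 NeuAc and optional
# fucosylation.
_CORE = " + (Man)3(GlcNAc)2"
GLYCAN_CATALOGUE: dict[str, str] = {
    "A1": "(Hex)2" + _CORE,  # Man5
    "A2": "(Hex)3" + _CORE,  # Man6
    "B11": "(Hex)2 (HexNAc)2 (Deoxyhexose)1 (NeuAc)4" + _CORE,
    "B22": "(Hex)2 (HexNAc)2 (NeuAc)3" + _CORE,
    "B32": "(Hex)3 (HexNAc)3 (Deoxyhexose)1 (NeuAc)3" + _CORE,
    "B43": "(Hex)2 (HexNAc)2 (Deoxyhexose)1 (NeuAc)2" + _CORE,
}
for _i, (_hex, _hexnac, _dhex, _sia) in enumerate(
    [
        (1, 1, 0, 0), (2, 2, 0, 0), (2, 2, 1, 0), (3, 3, 1, 0),
        (1, 1, 0, 1), (2, 2, 0, 1), (2, 2, 1, 1), (3, 2, 0, 1),
        (1, 2, 1, 2), (2, 3, 0, 2), (3, 3, 1, 2), (2, 2, 0, 2),
        (2, 3, 1, 3), (3, 3, 0, 3), (3, 4, 1, 3), (1, 2, 0, 3),
        (3, 4, 0, 4), (3, 3, 1, 4), (2, 3, 1, 4), (4, 4, 1, 4),
        (2, 4, 0, 2), (4, 3, 1, 1), (1, 3, 1, 1), (4, 4, 0, 3),
    ]
):
    _parts = [f"(Hex){_hex}", f"(HexNAc){_hexnac}"]
    if _dhex:
        _parts.append(f"(Deoxyhexose){_dhex}")
    if _sia:
        _parts.append(f"(NeuAc){_sia}")
    GLYCAN_CATALOGUE[f"G{_i + 1:02d}"] = " ".join(_parts) + _CORE

_PROTEIN_LENGTHS = {"SVMP": 420, "SVSP": 260, "LAAO": 500, "CTL": 150, "PLA2": 140}
_SVMP_DOMAINS = (("pro", 1, 170), ("catalytic", 171, 320), ("disintegrin", 321, 360),
                 ("Cys-rich", 361, 420))
# Residues used for random sequence fill: no K/R (cleavage control), no N
# (sequon control), P kept out to keep the cleavage rule simple to reason about.
_FILL = "ACDEFGHILMQSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator.  Probabilities in [0,1]; seed fixes everything."""

    sample_names: tuple[str, ...] = DEFAULT_SAMPLES
    group_sizes: tuple[int, ...] = (3, 2, 2)
    proteins_per_class: tuple[tuple[str, int], ...] = (
        ("SVMP", 4), ("SVSP", 3), ("LAAO", 2), ("CTL", 2), ("PLA2", 2)
    )
    sequons_per_protein: int = 4
    site_occupancy: float = 0.85       # sequon glycosylated at all
    intact_detection: float = 0.55     # occupied site seen in the intact tables
    compositions_per_site_mean: float = 2.6
    compositions_per_site_exact: int | None = None
    within_group_overlap: float = 0.9
    between_group_overlap: float = 0.2
    acetylation_p: float = 0.15
    deamidation_fp_rate: float = 0.05
    replicate_dropout: float = 0.2
    # 0.3 + 0.3 redundant variants per site put the nonredundant-site to
    # putative-peptide ratio in the 52-77% range typical of bottom-up data
    missed_cleavage_rate: float = 0.3
    semitryptic_rate: float = 0.3
    ppm_noise: float = 3.0
    n_replicates: int = 3
    fractions: tuple[str, ...] = ("dF1", "dF2", "dF3")
    dimer_groups: tuple[int, ...] = (0, 1)  # groups whose NeuAc>=2 glycans carry dimer antennae
    catalogue_group_specific: int = 8      # group-exclusive compositions per group
    catalogue_shared: int = 4              # compositions shared by all groups (incl. A1/A2)
    site_pool_size: int = 5                # preferred compositions per (group, site)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != len(self.sample_names):
            raise ValueError("group sizes must sum to the number of samples")
        if not self.sample_names or not self.proteins_per_class:
            raise ValueError("need at least one sample and one protein")
        for name in ("site_occupancy", "intact_detection", "within_group_overlap",
                     "between_group_overlap", "acetylation_p", "deamidation_fp_rate",
                     "replicate_dropout", "missed_cleavage_rate", "semitryptic_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def group_of(self, sample: str) -> int:
        idx = self.sample_names.index(sample)
        cum = 0
        for g, size in enumerate(self.group_sizes):
            cum += size
            if idx < cum:
                return g
        raise ValueError(sample)


def zero_noise_config(k: int = 3, seed: int = 0, **overrides) -> SimulationConfig:
    """Noise-free configuration: every planted site is occupied, detected, and
    carries exactly ``k`` compositions; no dropout, no false deamidation."""
    kw = dict(
        site_occupancy=1.0, intact_detection=1.0, compositions_per_site_exact=k,
        deamidation_fp_rate=0.0, replicate_dropout=0.0, missed_cleavage_rate=0.0,
        semitryptic_rate=0.0, ppm_noise=0.0, within_group_overlap=1.0, seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def digest(sequence: str, missed_cleavages: int = 0) -> list[tuple[str, int]]:
    """Tryptic digest: cleave after K/R unless the next residue is P.

    Returns (peptide, start) with 1-based starts; with ``missed_cleavages``
    also emits peptides spanning up to that many uncut sites.
    """
    cuts = [0]
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    segments = [
        (sequence[cuts[i]:cuts[i + 1]], cuts[i] + 1) for i in range(len(cuts) - 1)
    ]
    out = list(segments)
    for mc in range(1, missed_cleavages + 1):
        for i in range(len(segments) - mc):
            pep = "".join(s for s, _ in segments[i:i + mc + 1])
            out.append((pep, segments[i][1]))
    return out


def spectra_for(
    comp: GlycanComposition,
    base_peaks: list[tuple[float, float]],
    rng: np.random.Generator,
    ppm_noise: float = 0.0,
    dimer: bool = False,
    spectrum_id: str = "synthetic",
    precursor_mz: float = 1000.0,
    precursor_charge: int = 2,
) -> Spectrum:
    """A synthetic MS/MS spectrum carrying the composition's diagnostic ions.

    NeuAc oxonium ions appear for any sialylated composition; the full
    dimer series only when a NeuAc-NeuAc antenna is planted (``dimer``);
    the O-acetyl pair when the composition is acetylated.  Mass error is a
    signed uniform draw with magnitude in [0.5, 1.0] x ``ppm_noise``, so a
    3 ppm setting lands every ion inside a 10 ppm window and outside 1 ppm.
    """
    ions: list[float] = []
    if neuac_count(comp) >= 1:
        ions += [diagnostic_ions("neuac", 0), diagnostic_ions("neuac", 1)]
    if dimer and neuac_count(comp) >= 2:
        ions += [diagnostic_ions("neuac_dimer", k) for k in (0, 1, 2)]
    if comp.acetyl_count >= 1:
        ions += [diagnostic_ions("acetyl_neuac", 0), diagnostic_ions("acetyl_neuac", 1)]
    peaks = list(base_peaks)
    for mz in ions:
        if ppm_noise > 0:
            eps = rng.uniform(0.5 * ppm_noise, ppm_noise) * rng.choice([-1.0, 1.0])
            mz = mz * (1.0 + eps * 1e-6)
        peaks.append((mz, float(rng.uniform(1e3, 1e5))))
    return Spectrum(spectrum_id, precursor_mz, precursor_charge, tuple(peaks))


def planted_feature_matrix(
    rng: np.random.Generator,
    group_sizes: tuple[int, ...] = (3, 2, 2),
    n_features_per_group: int = 100,
    within_overlap: float = 0.9,
    between_overlap: float = 0.2,
    sample_names: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Binary matrix with a planted group structure.

    Each group owns a pool of features; a sample carries its own group's
    features with probability ``within_overlap`` and other groups' features
    with probability ``between_overlap``.  Returns (matrix, true labels).
    """
    n = sum(group_sizes)
    names = sample_names or tuple(f"S{i + 1}" for i in range(n))
    labels: dict[str, int] = {}
    i = 0
    for g, size in enumerate(group_sizes):
        for _ in range(size):
            labels[names[i]] = g
            i += 1
    n_feat = n_features_per_group * len(group_sizes)
    feat_group = np.repeat(np.arange(len(group_sizes)), n_features_per_group)
    rows = []
    for s in names:
        p = np.where(feat_group == labels[s], within_overlap, between_overlap)
        rows.append((rng.random(n_feat) < p).astype(int))
    mat = pd.DataFrame(
        rows, index=pd.Index(names, name="sample_id"),
        columns=[f"f{j}" for j in range(n_feat)],
    )
    keep = mat.columns[mat.sum(axis=0) > 0]
    return mat[keep], labels


@dataclass
class SimulationBundle:
    config: SimulationConfig
    proteins: dict[str, ProteinRecord]
    annotations: pd.DataFrame
    deglyco_table: pd.DataFrame
    intact_table: pd.DataFrame
    glycan_db: pd.DataFrame
    spectra: list[Spectrum]
    ground_truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "proteins.fasta", "w") as fh:
            for pid in sorted(self.proteins):
                fh.write(f">{pid}\n{self.proteins[pid].sequence}\n")
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        self.deglyco_table.to_csv(outdir / "deglyco_identifications.tsv", sep="\t", index=False)
        self.intact_table.to_csv(outdir / "intact_glycopeptides.tsv", sep="\t", index=False)
        self.glycan_db.to_csv(outdir / "glycan_db.tsv", sep="\t", index=False)
        write_mgf(self.spectra, outdir / "spectra.mgf")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)


def _make_protein(rng: np.random.Generator, pid: str, toxin_class: str,
                  n_sequons: int) -> tuple[ProteinRecord, list[int]]:
    """Random protein built from tryptic segments with planted sequons."""
    length = _PROTEIN_LENGTHS.get(toxin_class, 200)
    n_segments = max(4, length // 18)
    seg_lens = rng.integers(8, 28, size=n_segments)
    residues: list[str] = []
    seg_bounds: list[tuple[int, int]] = []  # 0-based [start, end) excluding the K/R
    pos = 0
    for L in seg_lens:
        body = [
            _FILL[j] for j in rng.integers(0, len(_FILL), size=int(L))
        ]
        residues.extend(body)
        residues.append("K" if rng.random() < 0.5 else "R")
        seg_bounds.append((pos, pos + int(L)))
        pos += int(L) + 1
    # plant sequons in distinct segments, fully interior so the base tryptic
    # peptide always contains the complete N-X-S/T window
    domains = _SVMP_DOMAINS if toxin_class == "SVMP" else ()
    eligible = [
        i for i, (s, e) in enumerate(seg_bounds)
        if e - s >= 6 and not any(
            lab == "disintegrin" and lab_s - 1 <= s <= lab_e for lab, lab_s, lab_e in domains
        )
    ]
    chosen = rng.choice(eligible, size=min(n_sequons, len(eligible)), replace=False)
    sites: list[int] = []
    for i in sorted(int(c) for c in chosen):
        s, e = seg_bounds[i]
        p = int(rng.integers(s + 1, e - 3))  # 0-based Asn index, window interior
        residues[p] = "N"
        residues[p + 1] = _FILL[int(rng.integers(0, len(_FILL)))]
        residues[p + 2] = "S" if rng.random() < 0.5 else "T"
        sites.append(p + 1)  # 1-based
    seq = "".join(residues)
    length = len(seq)
    dom = ()
    if toxin_class == "SVMP":
        dom = tuple(
            (lab, s, min(e, length)) for lab, s, e in _SVMP_DOMAINS if s <= length
        )
    return ProteinRecord(pid, seq, toxin_class, dom), sites


def _build_repertoires(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[int, tuple[list[str], np.ndarray]]:
    """Per-group composition-id repertoires with a shared core and rank weights.

    The shared slice always contains the two high-mannose ids (A1, A2); the
    named B-series ids are distributed one per group so reports carry
    recognizable ids; the rest of each group's slice comes from the
    generated catalogue.  Draw probabilities fall off as 1/rank, with the
    group's B-series composition dominant and A1 second — mirroring the
    strong reuse of a few glycans across many sites seen in real venoms.
    """
    ids = list(GLYCAN_CATALOGUE)
    shared = ["A1", "A2"]
    extra_shared = [i for i in ids if i.startswith("G")][: max(0, cfg.catalogue_shared - 2)]
    shared += extra_shared
    b_series = [i for i in ids if i.startswith("B")]
    pool = [i for i in ids if i.startswith("G") and i not in shared]
    rng.shuffle(pool)
    n_groups = len(cfg.group_sizes)
    reps: dict[int, tuple[list[str], np.ndarray]] = {}
    take = 0
    for g in range(n_groups):
        specific = [b_series[g % len(b_series)]] if b_series else []
        need = max(0, cfg.catalogue_group_specific - len(specific))
        specific += pool[take:take + need]
        take += need
        rest = sorted(set(shared[1:] + specific[1:]))
        rng.shuffle(rest)
        ordered = ([specific[0]] if specific else []) + ["A1"] + [
            r for r in rest if r != "A1"
        ]
        w = 1.0 / (1.0 + np.arange(len(ordered)))
        reps[g] = (ordered, w / w.sum())
    return reps


def simulate(config: SimulationConfig | None = None) -> SimulationBundle:
    """Generate a complete synthetic study bundle with ground truth."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- proteome -----------------------------------------------------------
    proteins: dict[str, ProteinRecord] = {}
    planted_sites: dict[str, list[int]] = {}
    ann_rows = []
    for cls, n in cfg.proteins_per_class:
        for j in range(n):
            pid = f"{cls}_{j + 1}"
            prot, sites = _make_protein(rng, pid, cls, cfg.sequons_per_protein)
            proteins[pid] = prot
            planted_sites[pid] = sites
            ann_rows.append({"protein_id": pid, "toxin_class": cls,
                             "domain": "", "start": "", "end": ""})
            for lab, s, e in prot.domain_annotations:
                ann_rows.append({"protein_id": pid, "toxin_class": cls,
                                 "domain": lab, "start": s, "end": e})
    annotations = pd.DataFrame(ann_rows)

    # sanity: planted sequons must be canonical sequons of their protein
    for pid, sites in planted_sites.items():
        canon = {h.position for h in find_sequons(proteins[pid])}
        assert set(sites) <= canon

    # base tryptic peptide covering each planted site
    site_peptide: dict[tuple[str, int], tuple[str, int]] = {}
    for pid, sites in planted_sites.items():
        peps = digest(proteins[pid].sequence)
        for pos in sites:
            for pep, start in peps:
                if start <= pos < start + len(pep):
                    site_peptide[(pid, pos)] = (pep, start)
                    break

    repertoires = _build_repertoires(cfg, rng)
    glycan_db = pd.DataFrame(
        [
            {
                "id": gid,
                "composition": comp,
                "class": "high-mannose" if gid.startswith("A") else "hybrid/complex",
            }
            for gid, comp in sorted(GLYCAN_CATALOGUE.items())
        ]
    )

    all_sites = sorted(site_peptide)

    # Preferred compositions per (group, site), shared by the group's samples:
    # a site tends to carry the same few glycans in related venoms.
    site_pools: dict[tuple[int, tuple[str, int]], tuple[list[str], np.ndarray]] = {}
    for g in range(len(cfg.group_sizes)):
        ordered, w = repertoires[g]
        for site in all_sites:
            m = min(cfg.site_pool_size, len(ordered))
            idx = [int(i) for i in rng.choice(len(ordered), size=m, replace=False, p=w)]
            pw = np.asarray([w[i] for i in idx])
            site_pools[(g, site)] = ([ordered[i] for i in idx], pw / pw.sum())

    occupied: dict[str, list] = {}
    detected: dict[str, list] = {}
    site_glycoforms: dict[str, dict[str, list[str]]] = {}
    glyco_peptides: dict[str, list[str]] = {}
    deglyco_rows = []
    intact_rows = []
    spectra: list[Spectrum] = []

    for sample in cfg.sample_names:
        g = cfg.group_of(sample)
        rep_order, _ = repertoires[g]
        sample_keep = {
            gid for gid in rep_order if rng.random() < cfg.within_group_overlap
        } or {rep_order[0]}
        occ = [site for site in all_sites if rng.random() < cfg.site_occupancy]
        det = [site for site in occ if rng.random() < cfg.intact_detection]
        occupied[sample] = [list(s) for s in occ]
        detected[sample] = [list(s) for s in det]
        gforms: dict[str, list[str]] = {}
        sample_glyco_peps: set[str] = set()

        # --- de-glyco identification rows (3 replicates x fractions) --------
        for (pid, pos) in occ:
            pep, start = site_peptide[(pid, pos)]
            variants = [(pep, start)]
            if rng.random() < cfg.missed_cleavage_rate:
                for mpep, mstart in digest(proteins[pid].sequence, missed_cleavages=1):
                    if mstart <= pos < mstart + len(mpep) and len(mpep) > len(pep):
                        variants.append((mpep, mstart))
                        break
            if rng.random() < cfg.semitryptic_rate and pos - start >= 3:
                trunc = int(rng.integers(start + 1, pos - 1))
                variants.append((proteins[pid].sequence[trunc - 1: start - 1 + len(pep)], trunc))
            for vpep, vstart in variants:
                local = pos - vstart + 1
                mc = sum(
                    1 for i_ in range(len(vpep) - 1)
                    if vpep[i_] in "KR" and vpep[i_ + 1] != "P"
                )
                for r in range(1, cfg.n_replicates + 1):
                    if rng.random() < cfg.replicate_dropout:
                        continue
                    frac = cfg.fractions[int(rng.integers(0, len(cfg.fractions)))]
                    deglyco_rows.append(
                        {"sample_id": sample, "replicate": r, "fraction": frac,
                         "peptide": vpep, "deamidation_positions": str(local),
                         "protein_id": pid, "start": vstart, "missed_cleavages": mc}
                    )
                sample_glyco_peps.add(vpep)

        # nonmodified background peptides + deamidation false positives
        for pid in sorted(proteins):
            peps = [
                (p, s) for p, s in digest(proteins[pid].sequence)
                if 6 <= len(p) <= 30 and s not in
                {st for (qid, _), (_, st) in site_peptide.items() if qid == pid}
            ]
            picks = [peps[int(i)] for i in rng.choice(len(peps), size=min(4, len(peps)),
                                                      replace=False)] if peps else []
            for pep, start in picks:
                deam = ""
                n_local = [i + 1 for i, aa in enumerate(pep) if aa == "N"]
                # false-positive deamidation outside canonical sequons
                if n_local and rng.random() < cfg.deamidation_fp_rate:
                    deam = str(n_local[0])
                for r in range(1, cfg.n_replicates + 1):
                    if rng.random() < cfg.replicate_dropout:
                        continue
                    frac = cfg.fractions[int(rng.integers(0, len(cfg.fractions)))]
                    deglyco_rows.append(
                        {"sample_id": sample, "replicate": r, "fraction": frac,
                         "peptide": pep, "deamidation_positions": deam,
                         "protein_id": pid, "start": start, "missed_cleavages": 0}
                    )

        glyco_peptides[sample] = sorted(sample_glyco_peps)

        # --- intact glycopeptide rows ---------------------------------------
        for (pid, pos) in det:
            pep, _ = site_peptide[(pid, pos)]
            if cfg.compositions_per_site_exact is not None:
                k = cfg.compositions_per_site_exact
            else:
                k = 1 + int(rng.poisson(max(cfg.compositions_per_site_mean - 1.0, 0.0)))
            pool_ids, pool_w = site_pools[(g, (pid, pos))]
            avail = [i for i, gid in enumerate(pool_ids) if gid in sample_keep]
            if not avail:
                avail = list(range(len(pool_ids)))
            aw = pool_w[avail] / pool_w[avail].sum()
            k = min(k, len(avail))
            chosen = sorted(
                pool_ids[avail[int(i)]]
                for i in rng.choice(len(avail), size=k, replace=False, p=aw)
            )
            forms = []
            for gid in chosen:
                comp = parse_composition(GLYCAN_CATALOGUE[gid], id=gid)
                if neuac_count(comp) >= 1 and rng.random() < cfg.acetylation_p:
                    comp = comp.with_acetyl(1)
                nm = glycopeptide_neutral_mass(pep, comp)
                intact_rows.append(
                    {"sample_id": sample, "backbone": pep, "protein_id": pid,
                     "site": pos, "composition": format_composition(comp),
                     "acetyl_count": comp.acetyl_count,
                     "neutral_mass": round(nm, 5),
                     "score": round(float(rng.uniform(20, 100)), 3)}
                )
                forms.append(
                    format_composition(comp)
                    + (f" [+{comp.acetyl_count}Ac]" if comp.acetyl_count else "")
                )
                dimer = g in cfg.dimer_groups
                spec = spectra_for(
                    comp,
                    base_peaks=[(204.0867, 5e3), (366.1395, 4e3),
                                (float(rng.uniform(700, 1700)), 1e4)],
                    rng=rng, ppm_noise=cfg.ppm_noise, dimer=dimer,
                    spectrum_id=f"{sample}|{pid}|{pos}|{gid}"
                                + (f"+{comp.acetyl_count}Ac" if comp.acetyl_count else ""),
                    precursor_mz=round(nm / 2 + 1.00728, 4),
                )
                spectra.append(spec)
            gforms[f"{pid}:{pos}"] = forms
        site_glycoforms[sample] = gforms

    ground_truth = {
        "group_labels": {s: cfg.group_of(s) for s in cfg.sample_names},
        "planted_sites": {pid: sites for pid, sites in sorted(planted_sites.items())},
        "occupied_sites": occupied,
        "detected_sites": detected,
        "site_glycoforms": site_glycoforms,
        "glyco_peptides": glyco_peptides,
    }
    return SimulationBundle(
        config=cfg,
        proteins=proteins,
        annotations=annotations,
        deglyco_table=pd.DataFrame(deglyco_rows),
        intact_table=pd.DataFrame(intact_rows),
        glycan_db=glycan_db,
        spectra=spectra,
        ground_truth=ground_truth,
    )
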
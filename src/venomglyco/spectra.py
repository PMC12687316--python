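"""MS/MS diagnostic-ion matching and antenna signature flags.

Oxonium ions are glycan B-type fragments whose presence in an HCD spectrum
reports monosaccharide content independently of the peptide backbone.  Two
signatures matter here: the sialic-acid dimer series (m/z 583.198 and its
one- and two-water-loss companions 565.188 / 547.177), evidence of a
NeuAc-NeuAc antenna terminus, and the O-acetyl-NeuAc pair 334.113 / 316.103.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from pyteomics import mgf as _mgf

from .glycans import diagnostic_ions

__all__ = [
    "Spectrum",
    "IonMatch",
    "match_diagnostic_ions",
    "flag_antenna_signatures",
    "dimer_series",
    "acetyl_pair",
    "read_mgf",
    "write_mgf",
]


@dataclass(frozen=True)
class Spectrum:
    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity), sorted by m/z

    def __post_init__(self) -> None:
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise ValueError("negative peak intensity")
        object.__setattr__(self, "peaks", pk)


@dataclass(frozen=True)
class IonMatch:
    label: str
    theoretical_mz: float
    observed_mz: float
    ppm_error: float
    intensity: float


def dimer_series() -> list[tuple[str, float]]:
    """The NeuAc-dimer oxonium series: parent and two successive water losses."""
    return [
        (f"neuac_dimer-{k}H2O" if k else "neuac_dimer", diagnostic_ions("neuac_dimer", k))
        for k in (0, 1, 2)
    ]


def acetyl_pair() -> list[tuple[str, float]]:
    """The O-acetyl-NeuAc diagnostic pair (334.113 and its water loss 316.103)."""
    return [
        ("acetyl_neuac", diagnostic_ions("acetyl_neuac", 0)),
        ("acetyl_neuac-H2O", diagnostic_ions("acetyl_neuac", 1)),
    ]


def match_diagnostic_ions(
    spec: Spectrum,
    ions: list[tuple[str, float]],
    tol_ppm: float = 10.0,
    min_intensity: float = 0.0,
) -> list[IonMatch]:
    """Match theoretical ions against a peak list at a ppm tolerance.

    For each theoretical ion the nearest-m/z peak within ``m * tol_ppm * 1e-6``
    is reported; when two peaks are equidistant the more intense wins.
    Misses are omitted.  An empty spectrum yields an empty result.
    """
    if not ions:
        raise ValueError("no theoretical ions supplied")
    mzs = [m for m, _ in spec.peaks]
    out: list[IonMatch] = []
    for label, theo in ions:
        if not spec.peaks:
            continue
        tol = theo * tol_ppm * 1e-6
        lo = bisect.bisect_left(mzs, theo - tol)
        hi = bisect.bisect_right(mzs, theo + tol)
        candidates = [
            (abs(m - theo), -i, m, i)
            for m, i in spec.peaks[lo:hi]
            if i >= min_intensity
        ]
        if not candidates:
            continue
        _, _, m, i = min(candidates)
        out.append(IonMatch(label, theo, m, (m - theo) / theo * 1e6, i))
    return out


def flag_antenna_signatures(
    spec: Spectrum,
    tol_ppm: float = 10.0,
    min_series_members: int = 3,
    min_intensity: float = 0.0,
) -> dict[str, bool]:
    """Flag NeuAc-dimer and O-acetyl-NeuAc evidence in one spectrum.

    The dimer flag requires ``min_series_members`` of the three series ions
    (default: all three, the full dehydration ladder); the acetyl flag
    requires both members of the 334/316 pair.
    """
    dimer = match_diagnostic_ions(spec, dimer_series(), tol_ppm, min_intensity)
    acetyl = match_diagnostic_ions(spec, acetyl_pair(), tol_ppm, min_intensity)
    return {
        "dimer_series_present": len(dimer) >= min_series_members,
        "acetyl_neuac_present": len(acetyl) == 2,
    }


def read_mgf(path) -> list[Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params.get("charge", [1])[0])
            spectra.append(
                Spectrum(
                    spectrum_id=str(params.get("title", f"spectrum_{len(spectra)}")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks=tuple(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist())),
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path) -> None:
    entries = [
        {
            "m/z array": [m for m, _ in s.peaks],
            "intensity array": [i for _, i in s.peaks],
            "params": {
                "title": s.spectrum_id,
                "pepmass": s.precursor_mz,
                "charge": s.precursor_charge,
            },
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")
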
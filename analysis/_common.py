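"""Shared configuration for the numbered analysis drivers.

Every driver regenerates the same synthetic study bundle (seed 17, default
study conditions) in memory, runs one pipeline stage, prints what it found,
and writes its tables under results/.  Bulky raw files (the full bundle with
spectra) go under scratch/, regenerated on demand.
"""

from pathlib import Path

from venomglyco.assembly import assemble
from venomglyco.io import peptide_identifications
from venomglyco.sequons import call_putative_glycopeptides, collapse_redundancy
from venomglyco.simulate import SimulationConfig, simulate

SEED = 17
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_bundle():
    return simulate(SimulationConfig(seed=SEED))


def run_deglyco_stage(bundle):
    part = call_putative_glycopeptides(
        peptide_identifications(bundle.deglyco_table), bundle.proteins
    )
    reps, sites = collapse_redundancy(part.putative_glyco, bundle.proteins)
    return part, reps, sites


def get_records(bundle):
    return assemble(bundle.intact_table, bundle.proteins, bundle.glycan_db).records


def outpath(name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS / name
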
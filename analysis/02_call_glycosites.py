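"""Call putative formerly N-glycosylated peptides and nonredundant glycosites.

Applies the deamidation + canonical-sequon + two-replicate rule, collapses
substring-redundant peptides, and reports how many nonredundant sites the
putative peptides reduce to (the site/peptide ratio).
"""

import pandas as pd

from _common import get_bundle, outpath, run_deglyco_stage
from venomglyco.sequons import site_ratio


def main():
    bundle = get_bundle()
    part, reps, sites = run_deglyco_stage(bundle)

    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "protein_id": s.protein_id,
             "position": s.position, "motif": s.motif,
             "n_supporting_peptides": len(s.supporting_peptides)}
            for s in sites
        ]
    ).to_csv(outpath("02_glycosites.tsv"), sep="\t", index=False)

    counts = pd.DataFrame(
        [
            {"partition": name, "n_groups": len(entries)}
            for name, entries in [
                ("putative_glyco", part.putative_glyco),
                ("deamidated_only", part.deamidated_only),
                ("nonmodified", part.nonmodified),
            ]
        ]
    )
    counts.to_csv(outpath("02_partition_summary.tsv"), sep="\t", index=False)

    ratio = site_ratio(sites, part.putative_glyco)
    print(counts.to_string(index=False))
    print(f"{len(sites)} nonredundant glycosites from "
          f"{len(part.putative_glyco)} putative peptides "
          f"(site/peptide ratio {ratio:.1f}%)")


if __name__ == "__main__":
    main()
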
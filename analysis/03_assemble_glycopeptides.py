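"""Assemble intact glycopeptides; tally counts, site recovery and O-acetylation.

Deduplicates the intact search table into (backbone, composition) records,
compares sites identified intact against the sites expected from the
de-glyco stage, and measures the O-acetylated fraction per venom.
"""

from _common import get_bundle, get_records, outpath, run_deglyco_stage
from venomglyco.assembly import AssemblyResult, expected_vs_identified, o_acetyl_fraction


def main():
    bundle = get_bundle()
    _, _, sites = run_deglyco_stage(bundle)
    records = get_records(bundle)

    counts = AssemblyResult(records, []).per_sample_counts()
    counts.to_csv(outpath("03_per_sample_counts.tsv"), sep="\t", index=False)

    evi = expected_vs_identified(sites, records)
    evi.to_csv(outpath("03_expected_vs_identified.tsv"), sep="\t", index=False)

    oac = o_acetyl_fraction(records)
    oac.rename_axis("sample_id").reset_index().to_csv(
        outpath("03_o_acetyl_fraction.tsv"), sep="\t", index=False
    )

    print(counts.to_string(index=False))
    pooled = 100.0 * evi["n_identified_of_expected"].sum() / evi["n_expected"].sum()
    print(f"expected-site recovery: {evi['pct_identified'].min():.0f}-"
          f"{evi['pct_identified'].max():.0f}% per venom (pooled {pooled:.1f}%)")
    print(f"O-acetylated fraction: {oac.min():.1f}-{oac.max():.1f}% per venom")


if __name__ == "__main__":
    main()
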
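"""Microheterogeneity ratios and sialylation profiles per venom and toxin class.

Glycoforms (site x composition pairs) per occupied site, globally, per toxin
class and per SVMP domain; NeuAc-count distributions of hybrid/complex
glycans; ranked composition frequencies.
"""

from _common import get_bundle, get_records, outpath
from venomglyco.stats import composition_frequency, heterogeneity, sialylation_distribution


def main():
    bundle = get_bundle()
    records = get_records(bundle)

    glob = heterogeneity(records, bundle.proteins, "global")
    glob.to_csv(outpath("05_heterogeneity_global.tsv"), sep="\t", index=False)
    by_class = heterogeneity(records, bundle.proteins, "toxin_class")
    by_class.to_csv(outpath("05_heterogeneity_toxin_class.tsv"), sep="\t", index=False)
    by_domain = heterogeneity(records, bundle.proteins, "svmp_domain")
    by_domain.to_csv(outpath("05_heterogeneity_svmp_domain.tsv"), sep="\t", index=False)

    sia = sialylation_distribution(records, bundle.proteins, "toxin_class")
    sia.to_csv(outpath("05_sialylation_distribution.tsv"), sep="\t", index=False)
    freq = composition_frequency(records, bundle.proteins, top=10)
    freq.to_csv(outpath("05_composition_frequency_top10.tsv"), sep="\t", index=False)

    pooled = glob["n_glycoforms"].sum() / glob["n_sites"].sum()
    print(glob.to_string(index=False))
    print(f"global heterogeneity: {glob['ratio'].min():.2f}-{glob['ratio'].max():.2f} "
          f"per venom (pooled {pooled:.2f} glycoforms per site)")
    print("most frequent composition ids per venom:",
          ", ".join(freq[freq["rank"] == 1]["composition_id"].unique()))


if __name__ == "__main__":
    main()
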
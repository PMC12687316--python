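# Methods

This package post-processes bottom-up N-glycoproteomics identifications of
snake-venom proteins and compares glyco-phenotypes across venoms. It
consumes the tabular outputs of upstream search engines (a MaxQuant-style
evidence table for de-N-glycosylated peptides, a GlycReSoft-style table for
intact glycopeptides) and does no spectral searching, rescoring or FDR
estimation of its own. All inputs it needs can be produced by its synthetic
generator, so every stage is testable against a known ground truth.

## Glycan model

Compositions are monosaccharide count vectors over Hex, HexNAc, Deoxyhexose
(Fuc) and NeuAc, written in bracket notation with the invariant
Man3GlcNAc2 core split off after a `+`:

    (Hex)2 (HexNAc)2 (Deoxyhexose)1 (NeuAc)4 + (Man)3(GlcNAc)2

Core Man counts as Hex and core GlcNAc as HexNAc for mass and counting; the
core segment is kept only for display and for recognising high-mannose
structures. No topology or linkage is inferred anywhere — "composition"
always means counts.

Monoisotopic residue masses (Da): Hex 162.05282, HexNAc 203.07937,
Deoxyhexose 146.05791, NeuAc 291.09542; water 18.010565, proton 1.00728,
O-acetyl (C2H2O) 42.010565, deamidation +0.984016. These reproduce the
diagnostic oxonium m/z values exactly: the NeuAc-dimer series
583.198 / 565.188 / 547.177 (successive water losses) and the
O-acetyl-NeuAc pair 334.113 / 316.103.

Classification is two-way: *high-mannose* iff total HexNAc == 2, no
Deoxyhexose, no NeuAc and total Hex >= 5 (Man5 and larger); everything else
is *hybrid/complex*, with fucosylation (dHex >= 1) and sialylation
(NeuAc >= 1) as independent flags. Hybrid and complex are not separated
because composition data cannot distinguish them reliably. O-acetylation is
a per-composition count bounded by the NeuAc count, not localised to a
specific sialic acid, matching how upstream engines report the +42 Da
increment.

## Glycosite calling from de-glycosylated peptides

PNGase F release converts the glycan-bearing Asn to Asp (+0.984 Da), so
deamidation is indirect evidence of former N-glycosylation — but it is also
a spontaneous artifact. The calling rule is therefore conjunctive: a
peptide group (sample x sequence x deamidated-site set) is *putative
formerly N-glycosylated* when (i) it was observed deamidated in at least 2
distinct replicates (fractions pooled before counting) and (ii) at least one
deamidated Asn falls on a canonical sequon N-X-S/T, X != Pro, evaluated in
the parent protein's coordinates. Protein-context evaluation matters because
tryptic/semitryptic cleavage can cut between the Asn and the S/T.
Noncanonical motifs (NXC, NXV, reverse S/T-X-N) are scanned and flagged but
never counted as sites. Deamidated groups failing either condition are kept
as `deamidated_only` with a reason code; the partition over groups is
exhaustive and disjoint.

Redundancy collapse removes, per sample, any peptide that is an exact
substring of a retained longer peptide covering at least one common site
(longest-first, set semantics — order- and duplication-invariant). The
survivors map to nonredundant sites keyed (protein, Asn position), and the
site/peptide ratio is reported as a percentage.

## Intact glycopeptide assembly

The counting unit is the *N-glycopeptide*: a unique (peptide backbone,
glycan composition) pair per sample; charge states and retention times are
ignored and the best search score is kept on deduplication. Rows with
unparseable compositions, backbones absent from the FASTA, or site positions
that are not canonical sequons are rejected with a reason. Optional neutral-
mass validation recomputes backbone + glycan arithmetic (standard amino-acid
monoisotopic residues via pyteomics; fixed Cys carbamidomethylation
switchable) and rejects rows off by more than a tolerance — this catches
1 Da mis-assignments planted in test tables. Acetyl variants count as
distinct compositions by default; both conventions are computable.

Expected-vs-identified site recovery divides the intact-stage site set by
the de-glyco-stage ("expected") site set per sample; sites seen only intact
are reported separately and never enter the fraction.

## Heterogeneity and distributions

The heterogeneity ratio divides unique glycoforms — (protein, site,
composition) pairs — by unique occupied sites, per sample and per group
(global, toxin class, SVMP domain). With this numerator the ratio is >= 1
and reads "glycoforms per glycosite". The alternative numerator (distinct
compositions in the group, which can fall below the site count) is computed
alongside under a flag; outputs report both. Sialylation distributions bin
NeuAc counts into {0, 1, 2, 3, >=4}; by default high-mannose records are
excluded and each row sums to 1; a switch additionally drops the 0 bin to
mirror sialylated-only displays. Composition frequencies are ranked with
lexicographic tie-break on the canonical string.

## Co-occurrence networks

Two compositions co-occur when both are identified at the same (protein,
position) site in a sample; each site contributes each unordered pair once
regardless of how many glycopeptides carry it. Edges observed at fewer than
3 sites are dropped (configurable). Networks are per sample; a pooled
variant exists behind a flag. Ego networks annotate neighbours with their
glycan class and degree; rendering beyond edge/node table export is out of
scope.

## Clustering and intersections

Samples are compared on binary presence/absence matrices of glycopeptides,
bare backbones, or neutral masses. Neutral masses are grouped across
samples by single-linkage chaining at 0.02 Da (configurable) — a tolerance
the upstream literature leaves unstated, so it is an explicit implementation
choice here. Clustering is complete-linkage over Euclidean distances (on
binary rows the squared distance is the count of differing features). The
agglomeration is written out explicitly so the tie-break is defined — on
equal heights the pair with lexicographically smallest member labels merges
first — and a test cross-checks merge heights against
`scipy.cluster.hierarchy.linkage`. Dendrograms export to Newick with branch
lengths equal to height differences. Exclusive intersections follow UpSet
semantics: for each nonempty sample subset, the number of features present
in exactly that subset; counts sum to the union size.

## Synthetic data generator

The generator emulates a seven-venom study with three phylogenetic groups
of sizes {3, 2, 2} (Jararaca complex / cotiara + fonsecai / jararacussu +
moojeni). Defaults, chosen as realistic study conditions:

- **Proteome**: 13 proteins (4 SVMP with pro/catalytic/disintegrin/Cys-rich
  domains, 3 SVSP, 2 LAAO, 2 CTL, 2 PLA2), built from tryptic segments
  (cleave after K/R, not before P) with 4 planted canonical sequons each,
  none in the disintegrin domain. Sequons sit fully inside one tryptic
  peptide so the base peptide always carries the complete motif.
- **Glycans**: a 30-entry catalogue containing the two high-mannose
  structures (ids A1 = Man5, A2 = Man6) and named sialylated ids (B11, B22,
  B32, B43) plus generated hybrid/complex compositions. Each group's
  repertoire is 12 ids (4 shared across groups, 8 group-specific) with
  1/rank draw weights — the group's B-series id dominant, A1 second — so a
  few glycans recur across many sites, as in real venoms. Each (group,
  site) keeps a preferred pool of 5 compositions shared by the group's
  samples.
- **Rates**: site occupancy 0.85; intact-stage detection 0.55 (the midpoint
  of the 40–67% recovery range such studies report); compositions per site
  1 + Poisson(1.6), mean 2.6; acetylation of sialylated glycoforms 0.15;
  replicate dropout 0.2 (three technical replicates then share ~50% of
  identifications); deamidation false positives 0.05; missed-cleavage and
  semitryptic variant rates 0.3 each, which puts the nonredundant-site to
  putative-peptide ratio in the 52–77% range typical of bottom-up data;
  spectra carry 3 ppm mass error drawn with magnitude in [0.5, 1.0] x the
  setting, so planted ions match at 10 ppm and never at 1 ppm.
- **Spectra**: each intact record gets an MS/MS spectrum with the oxonium
  ions its composition implies; the NeuAc-dimer antenna (and hence the
  583/565/547 series) is planted only in groups 0 and 1, not in the
  jararacussu/moojeni group.

A single integer seed drives everything; identical seeds give byte-identical
bundles. The zero-noise configuration (all rates 0, occupancy and detection
1, exactly k compositions per site) makes every stage's output equal its
planted ground truth, which the test suite asserts end to end: recovered
putative peptides, sites and glycoforms are set-equal to the plant and the
global heterogeneity ratio equals k exactly.

What the generator does **not** emulate: intensity/abundance models,
retention time, chimeric spectra, decoys and FDR, protein-inference
ambiguity beyond exact substring sharing, sequence variation between the
venoms (all samples share one FASTA), and real glycan biosynthetic
constraints beyond the composition catalogue. Passing tests therefore
demonstrate correctness of the analysis logic under controlled conditions,
not search-engine performance on real spectra.

## Scale, determinism and known limitations

Default problem sizes (13 proteins, ~50 sites, ~400–500 intact records,
7 samples) were chosen so the full pipeline runs in seconds and statistical
checks over 20 seeds run in well under a minute; they are a deliberate
scale-down of a real study (which had 129–328 glycopeptides per venom).
One consequence is visible in the clustering stage: with per-sample site
detection at 0.55, presence/absence noise is large relative to the
group-repertoire signal at this scale, and the full pipeline recovers the
planted {3,2,2} partition in roughly two-thirds of seeds (the planted
feature-matrix control at within/between overlaps 0.9/0.2, where overlap is
controlled directly, recovers it in ~100%). Driver
`analysis/07_clustering_intersections.py` prints both rates. This mirrors
the real trade-off: cross-sample clustering of binary glyco-features is
robust only when feature counts are large relative to detection noise.

Numerical conventions: masses to 1e-6 Da determinism; ppm windows are
symmetric multiplicative intervals; ratios rounded to 2 decimals in reports
only; all positions 1-based inclusive; TSVs tab-delimited UTF-8 with header
rows. Empty inputs raise explicit errors wherever a statistic would be
undefined (site ratio, O-acetyl fraction, expected-site recovery, clustering
with fewer than two samples).
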
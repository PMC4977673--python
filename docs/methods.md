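# Methods

## Site model and evidence classes

A candidate N-glycosylation site is an Asn in an N-X-S/T sequon. The
scanner reports every match (overlaps included) in ascending position;
by default X ≠ Pro, reflecting oligosaccharyltransferase preference and
the behaviour of standard sequon predictors, with `allow_proline_X=True`
available for the literal N-X-S/T reading (sites that exist only under
that flag carry a `proline_x` provenance marker). A sequon whose +2
residue would fall past the C-terminus is not a sequon; there is no
wrapping and no ambiguity-code handling — the parser rejects anything
outside the 20 standard residues up front.

Classification is presence-based: one covering peptide bearing the
+203.0794 Da GlcNAc remnant on the site's Asn validates the site. The
remnant is what Endo H leaves behind; it is modelled purely as a mass
delta, with no glycan structure. An optional `min_tagged_spectra`
threshold (default 1) emulates stricter re-validation filters by
requiring a minimum number of tagged spectra, applied to validated sites
only. Evidence rows carrying a remnant on a residue that is not a sequon
Asn are logged as inconsistent and excluded. The three classes are
disjoint and exhaustive by construction, and adding evidence can only
promote a site (non-covered → covered, covered → validated), never demote
it.

Sites in non-secreted proteins are retained and flagged rather than
dropped; filtering on secretion is an upstream decision.

## Digestion and masses

Trypsin cleaves after K/R except before P (Mascot-style, no keratin
exceptions). Peptides are enumerated for 0..`max_missed` missed cleavages
with 1-based inclusive coordinates; zero-missed peptides tile the protein
exactly, which is the invariant the evidence mapper relies on. Masses are
monoisotopic throughout (a 10 ppm-class precursor tolerance implies
monoisotopic bookkeeping): residue masses and water come from pyteomics,
modification deltas are GlcNAc remnant 203.0794, carbamidomethyl 57.0215
(fixed on Cys), oxidation 15.9949 (variable on Met). N-terminal Met is
not treated specially: inputs are mature, signal-cleaved proteins.
Coverage is interval containment of the site position, boundary-inclusive.

## Motif statistics

Windows are 13 characters over positions −6..+6, centre rendered `n`,
termini padded with `-`. In motif patterns a residue letter is literal
and never matches a pad (a constrained position must exist in the
protein), while `.` is a don't-care that accepts pads — so a motif like
`......n.T....` matches a site three residues from the C-terminus, but
`......nGT....` requires the Gly to be present. Dataset percent is
100·matches/n_windows; the background is the set of *all* Asn-centred
windows over the background proteins, which makes the background percent
of `n.T` approximate the proteome's Thr frequency — the natural null for
a position-specific statistic. Display rounding is one decimal
(109/151 → 72.2). Binomial enrichment p-values are optional output; a
small greedy motif-x-style search is provided for exploration but feeds
no reported number.

The chemical-class profile classifies flanking residues as Hydrophobic
(A,V,L,I,M), Aromatic (F,Y,W), Polar uncharged (S,T,N,C,Q), Acidic (D,E),
Basic (K,R,H) or Unique (G,P); positions 0 and +2 are excluded (fixed by
the sequon) and pads are excluded from denominators, so class frequencies
sum to 1 at every plotted position.

## Conservation

The homolog set, its alignment, and any E-value gate (recorded as
metadata) are inputs. The query site maps to the alignment column holding
its Asn by degapped-prefix counting; a homolog conserves the site when it
has an Asn within ±`window_tol` columns (default 0, strict column
identity) whose degapped context is an intact sequon. The tolerant mode
exists because alignment gaps shift sequons in primary-sequence
coordinates even when the glycan sits at a similar position in the fold;
nearest qualifying Asn wins, ties prefer the smaller displacement, then
upstream. Percentages are over non-query rows, rendered to one decimal.
Conservation is invariant under inserting all-gap columns, and the
verdict set is monotone in `window_tol`.

## Glycan profiling

Compositions are Hex_nHexNAc_2-style (labels never claim Man vs Galf —
they are isobaric). Two mass routes are implemented from one element
table: the site-count route (free-glycan elemental composition plus one
CH2 per methylation site, sites = 5h + 5k − 2(h + k − 1)) and the
permethylated-residue shortcut (Hex 204.0999, HexNAc 245.1263, end
correction C2H6O 46.0419); they are algebraically equivalent and serve as
mutual checks (< 1e−6 Da over Hex0..20 × HexNAc2..6). Ions are singly
charged [M+Na]+ (the standard species for permethylated glycans in MALDI
positive reflector mode); the adduct mass is the Na+ cation,
22.98922 Da. Assignment takes the nearest theoretical composition within
a 0.2 Da default tolerance (MALDI-TOF reflector scale), breaking exact
ties toward the smaller total residue count; it is per-peak, hence
order-independent and idempotent. The composition space is capped at
Hex20 by default, comfortably above the largest high-mannose structures
reported for *Aspergillus* (~18 Hex). Hex distributions are
intensity-weighted proportions per condition, summing to 1, with the
modal Hex count flagged.

## Secretome summaries

Detection is spectrum count > 0 (no threshold is published for the
emulated design). Venn regions are exact-membership counts, so the
2^k − 1 regions sum to the number of detected proteins. CAZy family
proportions normalise each class to 100 % and aggregate families below
2 % (boundary-inclusive: exactly 2 % is shown) into "other" in the
display frame only; the machine-readable frame keeps every family. Two
weightings are available: summed spectrum counts (default) and detected
protein counts. An optional total-sum scaling per condition emulates
spectral-count "quantitative value" normalisation; the exact commercial
formula is unpublished, so plain total-sum scaling is used and labelled
as such. Top-protein rankings break ties by protein id so the output is
independent of input order.

## Synthetic-data generator

The generator emulates the targeted study design: a secretome of 265
proteins (default) of 200–800 residues, ~60 % carrying a CAZy family
label, observed across three conditions (glucose, SCB, xylan), with
high-mannose glycan pools dominated by Hex5HexNAc2 and traces up to
Hex18.

* **Sequences** are uniform over the 20 residues; every accidental
  N-·-S/T triplet is removed by replacing the Asn (replacements are drawn
  from an alphabet without N/S/T/P, so fixing cannot create new sequons
  and one pass terminates). Sequons are then planted by substitution at
  non-overlapping slots (every third position), with the per-slot
  probability set so the expected count matches `sequon_density` per 100
  residues; densities infeasible for the length range are rejected. The
  emitted sequon set therefore *equals* the planted set, which is what
  makes density and occupancy recovery exact binomial questions.
  NXT:NXS is planted 1:1; X is drawn from the no-N/S/T/P alphabet.
* **Occupancy** is a property of the site: each planted sequon is drawn
  occupied once (Bernoulli(`occupancy`)) at generation time, and every
  covering observed peptide of an occupied site is tagged. This matches
  both boundary behaviours (coverage = occupancy = 1 ⇒ all validated) and
  makes the validated fraction of covered sites an unbiased estimator of
  occupancy.
* **Evidence**: zero-missed tryptic peptides are observed independently
  with probability `coverage`; an observed peptide becomes its one-missed
  extension with probability `missed_cleavage_rate`. The simulator
  digests with `min_length=1` and no upper bound so that full coverage
  guarantees every sequon is covered; the 5–60 residue observability
  window typical of LC–MS/MS remains available as `digest()` arguments
  but would break that guarantee, so it is not the simulator default.
  Spectrum counts are Poisson–gamma (negative-binomial-like) per
  condition around a lognormal per-protein abundance, shifted by +1 so
  observed peptides have at least one spectrum.
* **Homolog families**: each homolog retains each query sequon with
  probability `homolog_retention` (a destroyed sequon is an Asn→Asp
  substitution); other positions diverge by substitution (rate 0.1) and
  deletion (`indel_rate`), and short homolog-specific insertions become
  gap columns in the other rows. Retained sequon triplets are never
  mutated, deleted or split by an insertion, so the planted retention
  draws are exactly recoverable by the conservation module at
  `window_tol=0`.
* **Glycan peaks**: one peak per nonzero composition and condition at the
  theoretical sodiated m/z plus Gaussian error (`mass_error_sd`, default
  0.05 Da), intensity proportional to the planted weight with
  multiplicative lognormal noise.
* **The 151-window preset** reproduces the published dataset-matches
  column of the motif report: 42 N-X-S and 109 N-X-T windows, the latter
  containing exactly 19 NGT, 12 NTT and 14 NST; the unconstrained N-X-T
  block draws X outside {G,T,S,P} so the fixed tallies stay exact, and
  all other positions are filled uniformly from a fixed internal seed.
  Windows are treated as unique sites (no duplicates from repeated
  observations of one site).

Randomness uses one master seed with per-stage numpy `SeedSequence`
substreams, so each stage is individually reproducible and a fixed seed
yields byte-identical outputs.

What the generator does **not** emulate: real amino-acid composition
(background is uniform, so background motif percentages are flat), true
spectral scoring and FDR, semi-tryptic or chymotryptic contamination,
retention times, isotope envelopes, glycan isomers/topology, or
correlated evolution among homologs. Passing tests therefore demonstrate
correctness of the pipeline's logic and estimators under a controlled
model — not that any particular biological dataset would yield the same
numbers.

## Problem sizes and tolerances in the checks

The test suite and `scripts/acceptance.py` use: ~10,000 simulated sites
for the partition check; ≥ 500 covered sites for occupancy recovery,
judged against the exact (Clopper–Pearson-style) central 99 % binomial
interval around 0.7; 1,000 random proteins for digestion invariants;
200 families × 20 homologs for retention recovery (three standard
errors around 0.9); 1,000 noisy peaks at 0.05 Da for assignment accuracy
(≥ 99 %). These sizes keep every check well-powered while running in
seconds.

## Known limitations

* Background motif percentages depend entirely on the supplied background
  proteins; no attempt is made to reproduce any published background
  column, which derived from an unreleased protein set.
* The optional minimum-tagged-spectra filter is a coarse stand-in for
  site-localization scoring (Ascore-style); it applies to validated
  sites only.
* Overlapping sequons in which one is retained and the other destroyed
  can interact in the homolog simulator; the generator itself never
  plants overlapping sequons, so this affects only hand-built inputs.
* `conservation` consumes alignments as given; alignment quality is the
  caller's responsibility.
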
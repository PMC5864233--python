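# Methods

## The analysis this package implements

Microbial rhodopsins are seven-transmembrane (7-TM) photoproteins that
bind retinal through a conserved lysine in the seventh helix. Two small
sets of residues, read in a fixed reference numbering, predict their
function: positions 97/101/108 (bacteriorhodopsin 85/89/96) form the
ion-pumping motif — DTE and DTD are proton pumps, NDQ sodium pumps, NTQ
chloride pumps, with abundant environmental variants such as DTT and DTQ
functionally unassigned — and position 105 (bacteriorhodopsin 93) is the
spectral-tuning residue: Q absorbs blue light, L/M/I green, and T (the
dominant deep-water variant) has no established absorption. Variants are
reported with the combined "PUMP-TUNING" shorthand (DTE-Q, DTT-T, …).

The pipeline takes translated gene sequences from a metagenomic
catalogue and:

1. **screens** candidates, requiring 7 called TM segments and a lysine
   homologous to the reference retinal-binding site, located inside the
   seventh segment;
2. **annotates** survivors by global alignment to the reference frame,
   reading the four motif residues and classifying pump and tuning
   function from the rule tables;
3. **dereplicates** sequences at an identity threshold (default 95 %);
4. **profiles abundance** as copies per genome — gene coverage divided
   by the mean coverage of ten universal single-copy genes (COG0012,
   COG0016, COG0018, COG0172, COG0215, COG0495, COG0525, COG0533,
   COG0541, COG0552) — aggregated by depth, taxon label, motif label or
   named gene set, and **expression** as the percentage of non-rRNA
   transcriptome reads mapping to rhodopsins.

## Reference frame and coordinate conventions

The bundled reference is the canonical green-absorbing proteorhodopsin
eBAC31A08 (249 aa), whose own motif is DTE-L with the retinal lysine at
position 231. All quoted positions are 1-based in this sequence; the
bacteriorhodopsin frame is derived by the constant −12 offset at the
motif sites and offered for reporting only. Internally all intervals
are 0-based half-open; output tables report 1-based inclusive
positions.

Motif positions are transferred per sequence by pairwise global
alignment (Needleman–Wunsch/Gotoh, BLOSUM62, gap open 11 / extend 1; a
gap of length k costs 11 + (k−1)). A multiple alignment would add
nothing for single-position transfer and is harder to verify; the
pairwise aligner is checked against an independent recursive DP oracle
in the test suite. Ties among co-optimal moves are resolved diagonal >
up (gap in query) > left, and gap-open > gap-extend, so outputs are
byte-stable. Alignments below 25 % identity (identical columns over the
shorter length) are refused as unalignable: position transfer between
non-homologues is meaningless. Records missing any of the four sites
(fragments) are flagged incomplete and excluded from motif summaries.

## TM calling

Membrane topology is called from the Kyte–Doolittle hydropathy profile:
per-residue mean over a centred window (truncated at the termini, X
scoring 0), maximal runs at or above a threshold, runs separated by
fewer than `merge_gap` positions merged, runs shorter than
`min_tm_length` discarded. Defaults — window 11, threshold 0.8,
min_tm_length 10, merge_gap 3 — were calibrated once on the reference
so that it yields exactly seven segments with K231 inside the seventh.
The textbook window of 19 and threshold of 1.6 are tuned to proteins
with long loops; proteorhodopsin's inter-helix loops are short enough
that a 19-residue window smooths them away entirely. Two consequences
are worth knowing: the hydrophobic N-terminal signal-anchor stretch is
counted as the first "TM" segment, and the weakly hydrophobic helix 2
region is not separately resolved — the criterion is "seven hydrophobic
segments with the retinal lysine in the last", which is what the screen
needs, not a structural helix assignment. The retinal lysine is located
by homology (alignment to the reference), not by scanning the seventh
segment for any lysine; membership in the seventh segment allows ±2
residues of slack because window smoothing blurs segment edges.
Sequences over 20 % X, or shorter than one window, fail as ambiguous.
All four caller parameters are exposed in the run config and CLI.

## Dereplication

Greedy longest-first, first-fit clustering (CD-HIT style): each
sequence joins the first representative it matches at ≥ threshold, else
founds a cluster; representatives are therefore mutually < threshold.
Identity is identical columns of the optimal global alignment divided
by the shorter sequence length — a convention tolerant of the gene
fragments real catalogues contain (a perfect fragment has identity 1).
An alignment-length denominator is available; only under that
denominator is the length-ratio skip (pairs whose length ratio is below
the threshold cannot reach it) sound, so the shortcut is enabled only
there. No k-mer prefilter: at desk scale (≤10⁴ sequences) all-vs-
representative alignment is affordable.

## Abundance and expression estimators

Copies per genome = Σ coverage of the gene set ÷ arithmetic mean of the
sample's ten USCG coverages (the mean USCG coverage estimates genome
equivalents; a median option exists for robustness). Genes absent from
a sample's table count as coverage zero — absence from an assembled
catalogue is evidence of absence. Category profiles are
coverage-weighted sums over member genes, hence additive and invariant
to rescaling all coverages in a sample. Depth grouping is by exact
depth value (fixed sampling depths; no binning). Transcript fraction is
100 × rhodopsin reads / total non-rRNA reads.

## The synthetic-data generator

The generator replaces the original survey's catalogue with inputs
whose truth is planted, so every estimator can be tested against known
values.

**Opsins** are mutated copies of the reference: the four motif residues
are planted, the retinal lysine and a ±3 flank are frozen, and the
number of substitutions is set by the identity target (realised
identity within ±0.03; targets span 0.3–1.0). Substitutions inside
reference TM segments are drawn from the hydrophobic alphabet
{A,F,I,L,M,V,W} and loop substitutions from a hydrophilic alphabet
{D,E,G,H,K,N,P,Q,R,S,T,Y}, so the hydropathy topology is preserved in
distribution. Because segment edges can still erode at low identity,
the generator verifies each product against the screen and the
annotator and re-draws from the same seeded stream on failure
(generate-and-verify); planted truth therefore holds by construction
and outputs remain deterministic per seed. **Decoys** come in three
classes exercising each screen failure: `six_tm` (seventh segment
erased with hydrophilic residues, lysine kept), `no_lysine` (K231→A),
and `soluble` (random sequence over an alphabet whose hydropathy can
never reach the threshold).

**Coverage tables** plant copies per genome per gene per sample; USCG
rows are drawn around a mean coverage of 500, a deep-coverage-
metagenome regime in which a single-sample Poisson estimate of a
0.7-copies-per-genome gene has ≈4 % median relative error. Noise models:
none (exact inversion by the estimator), Poisson on expected coverages,
or mean-one lognormal (σ = 0.2). **Transcript tables** draw rhodopsin
read counts as Binomial(total, fraction/100) or deterministic rounding.

The bundled survey (`make_bundle`, CLI `simulate`) composes these into
a depth-stratified study: seven metagenome depths from 25 to 1000 m
with total rhodopsin copy numbers falling 0.70 → 0.15 per genome, a
SAR11-dominated taxon allocation (60.9 % of copies, apportioned by
largest remainder so planted fractions are recovered exactly), a motif
palette dominated by DTE-Q in shallow water and DTT-T at depth, a
retinal-biosynthesis gene set (blh, crtB, crtI, crtY, diox1) with
surface-high and flat profiles, and transcript fractions of 0.02 % at
15 m decaying to 0.001 % below 500 m.

What the generator deliberately does not emulate: real sequence
evolution (substitutions are uniform within alphabet classes, no
indels, no rate heterogeneity), HMM search scores, chimeras or
frameshifts, taxonomy (labels are assigned, not evolved), and the
coverage noise structure of any real catalogue. Passing tests
demonstrate that the estimators invert the stated generative model —
not that screening counts or motif frequencies from a real survey would
be reproduced, which depend on catalogue content and TM-caller choice.

## Numerical and degenerate-input choices

* Alignment tie-breaks and gap cost convention as above; scores are
  exact floats of integer matrix entries, so comparisons are exact.
* Identity targets are quantised to whole substitution counts; the
  ±0.03 tolerance absorbs the rounding.
* An empty TM segment list is a valid call; the lysine-membership check
  then fails with its own reason rather than erroring.
* Zero total copies in a sample makes relative abundances NaN
  (undefined), never zero.
* Classification functions are total: any unknown or missing residue
  maps to "unknown", never an error; rule tables are user-extensible
  mappings.
* Noise draws that would produce a non-positive USCG coverage are
  floored at 1 to keep the normalisation denominator defined (at the
  default coverage this is effectively unreachable).

## Problem sizes

Default verification sizes were chosen to give tight Monte-Carlo
evidence at interactive runtimes: 200 + 200 sequences for screen
sensitivity/specificity, 500 planted motifs across identities
0.6/0.75/0.9, 500 random pairs against the alignment oracle, 100
planted clustering instances of 20 sequences (length 80, within-group
identity ≥ 0.975, between-group ≪ 0.8), and 100 Poisson replicates for
the abundance error. `scripts/acceptance.py` re-runs all of these from
scratch under one seed.

## Known limitations

* Hydropathy-only TM calling is cruder than profile- or ML-based
  topology predictors; counts of passing sequences on real data are
  method-dependent.
* The rule tables cover only variants with established functional
  assignments; everything else is "unknown" by design.
* The greedy clustering is order-dependent (longest-first, documented
  tie-breaks); it matches the planted truth on separated instances but
  is not a globally optimal partition.
* Per-sequence pairwise transfer can in principle disagree with an MSA
  column assignment for highly diverged queries; the 25 % identity
  floor bounds, but does not eliminate, this risk.
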
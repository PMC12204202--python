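# Methods

## Detection model

The pipeline treats a genome as an ordered list of genes per replicon
(1-based inclusive coordinates, GFF3 convention) and a set of Pfam domain
hits per protein. Detection proceeds in four stages.

**Role assignment.** Each gene's hits passing the E-value threshold
(`evalue_max`, default 1e-5 — hmmscan runs in this domain rarely need a
stricter cut, and the value is configurable) are mapped through the role
catalog. Two roles are composite: *tolB* requires the β-propeller hit
(PF07676); a propeller-only gene is reported `tolB_like` and excluded from
the minimal complement, because propeller-only proteins include many
TolB-unrelated enzymes and outer-membrane-protein relatives. *tbdt*
requires both the β-barrel (PF00593) and the plug (PF07715) by default
(`require_plug`), since plug-less barrels are ambiguous. Genes whose hits
span several role families are flagged ambiguous and resolved by best
bitscore, ties by lexicographic accession — a deterministic stand-in for
the case-by-case structural inspection such conflicts really deserve.

**Locus detection.** Two role-bearing genes are proximal when they share a
replicon, their rank distance is at most `max_intervening + 1` genes
(default `max_intervening` = 3) and the intergenic gap is at most
`max_gap_bp` (default 5000). Loci are the connected components of this
relation — equivalently, the transitive closure of the pairwise predicate,
which is what the test oracle computes naively. The defaults absorb small
insertions while keeping an *E. coli*-style operon intact; both knobs are
exposed, and widening either is monotone (loci can only merge, the tol-pal
status can only be promoted along absent → partial → split → complete).
Strand is recorded but ignored for proximity: curated loci in this family
of systems mix orientations across taxa. Replicons are treated as linear;
an optional circular mode closes the rank adjacency.

**Classification.** A genome is tol-pal *complete* when one locus carries
the minimal complement {motor_pentamer, motor_dimer, transducer, tolB,
pal}; *split* when only a union of two or more loci does (each contributing
at least one complement role, searched genome-wide with no maximum
separation); *partial* when some but not all complement roles exist
genome-wide; otherwise *absent*. The Ton call is genome-wide with no
proximity requirement — transducer (not claimed as TolA), TBDT, and the
motor pair each anywhere — because *tonB* genuinely co-occurs only
infrequently with its motor. Partial genomes therefore feed the Ton call
rather than being silently dropped.

**Identity.** The transducer inside the complement-satisfying locus (or
split union) is TolA; one TolA per genome is enforced, and when a complete
locus contains several transducers the call is flagged and the one nearest
*tolB* in rank wins. All other transducers are TonB candidates; the
representative TonB is the first candidate (replicon order, then start)
whose secondary-structure profile shows a TMH with room for a non-empty
domain II ahead of the 100-residue C-terminal domain. CpoB is reported
separately: *present* genome-wide, and *directly adjacent* when within
`adjacency_rank` (default 1, i.e. an immediate neighbor) of a complement
gene — adjacency is deliberately distinct from locus membership.

## Architecture model

Domain I is the predicted TMH. Domain II is `[tmh_end+1, L-100]`; domain
III is the final 100 residues, by residue count even where the real fold
boundary differs. When `tmh_end + 1 > L - 100` the record is flagged with
an empty domain II and excluded from cohort statistics; no TMH is ever
guessed for a transducer that lacks one. Composition metrics are exact
arithmetic: `helix_pct` counts H states in the three-state prediction,
`proline_pct` counts P residues in the amino-acid sequence (proline is a
minimal proxy for PPII-helix content, which three-state predictors cannot
call; PPII propensity, when supplied, is summarized separately as the
fraction of domain II residues at or above `ppii_cutoff`, default 0.5).

The motor box is detected as the first run of ≥ `min_strand` (3)
consecutive E states beginning within the first `motor_box_window` (75)
residues of domain II, flanked on both sides by ≥ `min_coil_flank` (3) coil
states. The motif is defined in the literature only as "a β-strand in the
disordered region after the TMH", so all three knobs are explicit
parameters swept in the tests, not claims about any published criterion.

Composition classes use a dominance ratio `comp_ratio` (2) and a floor
`comp_floor` (10%): α-dominant when helix ≥ 2× proline and ≥ 10%,
proline-dominant symmetrically, disordered when both are below the floor,
mixed otherwise. The lipobox fallback (`[LIV][ASTVI][GAS]C` within residues
10–40) exists so synthetic tests need no external predictor; an external
signal-peptide call always takes precedence.

## Statistics

Median for even n is the midpoint of the two central order statistics;
quartiles are Tukey's inclusive hinges (each half contains the median
element) — common spreadsheet/statistics defaults, stated here because
conventions differ. Pearson correlation requires n ≥ 3 and nonzero variance
in both margins; species missing a TonB representative are dropped from the
paired correlation, not imputed. The Mann–Whitney U test is two-sided
throughout: exact (null distribution of U enumerated) when n₁·n₂ ≤ 400 and
the pooled sample has no ties, tie-corrected normal approximation with
continuity correction otherwise. Reported percentages are rounded half-up
to integers with the raw fraction retained. No multiple-testing correction
is applied.

## What the synthetic data emulates — and what it does not

The genome generator plants contiguous clusters with the correct Pfam
accessions among decoy genes (intergenic gaps uniform in 20–200 bp, genes
150–450 codons, ~20% of decoys carrying an off-catalog accession), with
distal clusters separated by `split_offset` (10) decoy genes so they can
never satisfy the default rank predicate. The profile generator places
exactly the requested number of H states and prolines in domain II
(count-exact, so composition assertions carry zero tolerance) and, on
request, a strand of `min_strand + 1` E states with coil flanks inside the
detection window. The cohort generator draws paired domain II lengths
through a Gaussian copula with ρ = 0.28 and clipped lognormal marginals
with medians 192 (TolA II, range 110–335) and 113 (TonB II, range 40–245),
for 70 species — the conditions of the curated study cohort.

Passing at zero noise shows the logic is implemented correctly, not that it
is robust to real annotation noise: real genomes have frame-shifted or
fragmented genes, partial Pfam hits near the E-value threshold, ambiguous
paralogs, misassembled contigs splitting loci, and secondary-structure
predictions that disagree with each other. The generator models none of
these; the configurable thresholds exist precisely because real data will
need them tuned against curated examples.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  spec + seed give byte-identical output files.
- ss2 parsing re-derives the state as the maximum-confidence state, ties
  broken by the fixed precedence H > E > C for determinism.
- hmmscan per-domain tables are parsed through Biopython's SearchIO
  (`hmmscan3-domtab`); envelope coordinates are converted to 1-based
  inclusive and Pfam accession versions stripped.
- When the final-100-residue domain III would reach into the TMH on a very
  short protein, its start is clipped to `tmh_end + 1` and the record
  flagged; such proteins need manual review.
- Acceptance-scale problem sizes: 200 random scatter genomes (≤ 50 genes)
  for the clustering oracle, 60 planted genomes across all five kinds plus
  combined tol-pal + Ton genomes, 100 profiles for composition/motor-box
  checks, 500 null replicates for p-value uniformity (run at n = 30 per
  group, where the normal-approximation p-value is continuous — exact
  p-values at small n are discrete and sub-uniform by construction, so a
  continuous KS check would be the wrong instrument there).

## Known limitations

- Six-frame translation is out of scope: the pipeline starts from gene
  calls, so unannotated genes are invisible to it.
- The role catalog ships only the Tol-Pal/Ton accessions; other transducer
  families (e.g. vWA-domain transducers) require adding their models to the
  catalog TSV.
- Flanking-gene synteny (*ybgC*, *ruvABC*, *queEC*, *slyD*) is not used for
  classification; only the complement roles are.
- Structure-based validation of ambiguous roles is replaced by the
  secondary-structure plausibility check (`is_full_transducer`); the
  pipeline does not reason about tertiary structure.
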
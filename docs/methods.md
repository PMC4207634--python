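# Methods

This note documents the models implemented in `lephox`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer would want
recorded. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## K-mer spectrum genome profiling

Reads are 2-bit packed and k-mers counted exactly by hashing (k ≤ 31
guard); canonical pooling of a k-mer with its reverse complement is on
by default because shotgun reads sample both strands. The multiplicity
histogram of a single-copy genome sequenced to base coverage C peaks
near the k-mer coverage C_k = C·(L−k+1)/L; k-mers carrying sequencing
errors accumulate at low multiplicity, repeats at high multiplicity.

`find_peak` returns the histogram's local maximum at multiplicity ≥
`min_multiplicity` (default 4, skipping the error ramp; no local
maximum above the floor is reported as an uninterpretable spectrum),
refined by 3-point quadratic interpolation for sub-integer resolution.
For a Poisson-like spectrum this interpolated mode sits about half a
unit below the mean multiplicity, so the full estimation chain
(`profile_reads`) refines coverage to the mean multiplicity of the
peak region [min_multiplicity, 2.5 × peak] and feeds the k-mer mass of
that same region, converted to base space by L/(L−k+1), into
genome_size = total_bases / C. Excluding the error ramp from both
numerator and denominator in this way is what keeps the estimator
unbiased in the presence of errors: with 0.5% per-base error only
(1−e)^17 ≈ 92% of genomic 17-mer copies are error-free, and an
estimator using raw sequenced bases over the peak coverage would be
biased upward by roughly that factor's inverse (≈ +9%). The acceptance
script measures a median relative error well under 1% at 1 Mb / 15× /
0.5% error over 10 seeds.

Not modelled: heterozygosity and repeat decomposition of the spectrum
(a second peak at C_k/2 or multiples of C_k would be mis-read as noise
or repeats), quality trimming (inputs are taken as provided), and any
assembly.

## Homeobox hunting

The homeodomain is modelled as a single gapless 60-column block.
Profile column scores are ln(((f_a + pc·bg_a)/(1+pc))/bg_a) with
pseudocount mass pc = 0.1 and the JTT equilibrium frequencies as
background. Contigs are translated in all six frames and scanned with
a sliding 60-residue window; windows containing stop codons or
ambiguous bases are voided. This replaces a translated-BLAST search
with an ungapped profile scan — adequate because the targets are
single-exon homeoboxes; spliced homeoboxes are out of scope and a hit
interrupted by an intron will simply be missed or truncated.

Significance uses an empirical null: 1000 random background windows
are scored once per profile (fixed calibration seed) and a Gumbel
distribution fitted; `evalue_like` = windows-scanned × Gumbel tail
probability. Only the ordering/threshold semantics of a BLAST E-value
are preserved, not its Karlin–Altschul calibration; since the null
scores are approximately normal and the Gumbel has a heavier right
tail, the extrapolated tail is conservative (false-positive estimates
err high). The search driver (`hunt_genome`) builds one profile per
reference class rather than pooling all classes: pooling divergent
classes dilutes every column and weakens true-member scores below the
deep-tail cutoff that a 1e-6 threshold implies on megabase scans.

Redundancy removal is greedy best-first: a hit overlapping a kept
higher-scoring hit on ≥50% of the shorter span is dropped. On cliques
of mutually overlapping hits this equals exhaustive maximum-weight
selection; on long staggered chains spanning disjoint sub-clusters it
can differ from the global maximum-weight set — the greedy behaviour
is the contract, matching the practice of dismissing redundant
scaffolds by best hit.

Classification assigns the class of the nearest reference by
p-distance over the 60-residue peptide, with ties broken toward the
larger class then lexicographically, 'unknown' beyond distance 0.6 or
when >10% of the peptide is ambiguous. Diagnostic residue flags are
evaluated on homeodomain numbering 1–60; serine at position 10 (S10)
is the Hox3 (zen/Shx) lineage diagnostic. Neighbor joining over a
p-distance matrix provides assignment support; ties in the Q-criterion
break lexicographically so output is deterministic, and the final
three-taxon star is solved in closed form.

The bundled reference panel (`gen_reference_panel`) is synthetic:
class archetypes are derived from the canonical Antp homeodomain
scaffold by seeded substitution at 30% of positions (S10 enforced in
the zen/Shx class only), three members per class at ~5% internal
divergence. Real surveys should substitute curated homeodomains; the
panel exists so detection and classification are testable with exact
ground truth.

## Conservation statistics

Columns with more than 50% missing data (gap '-' or 'X') are removed
before analysis; exactly 50% is kept. A conserved motif is a maximal
run of ≥3 columns in each of which some residue state is carried by at
least ⌈n/2⌉ of the n species in the alignment *and* by at least one
species on each side of a two-group deep-lineage partition. Species
with a gap at a column do not carry but stay in the denominator. The
sharing rule is applied per column (per residue); an alternative
whole-motif reading of lineage sharing would be laxer and is not
implemented. When several states qualify in one column the most
frequent (then alphabetical) is reported as consensus.

Invariant-site percentages are the fraction of columns with a single
residue state, reported rounded to the nearest integer, matching how
such percentages are conventionally printed. Divergence matrices
support p-distance, Poisson (−ln(1−p), +∞ flagged at saturation) and
a JTT maximum-likelihood distance: the published Jones–Taylor–Thornton
(1992) exchangeabilities and frequencies (shipped as a text data file)
define a reversible rate matrix scaled to one expected substitution
per site; the single time parameter is optimized by bounded 1-D search
on (1e-8, 50) with tolerance 1e-6, using the spectral decomposition of
the symmetrized rate matrix for fast P(t).

## Counting dN/dS

`ng86_pairwise` implements Nei–Gojobori (1986): per-codon synonymous
site counts are the fraction of the nine single-nucleotide changes
that preserve the amino acid, averaged over the two sequences;
observed differences are apportioned over all shortest mutational
pathways with equal weights, discarding pathways through stop codons
(all-blocked pairs fall back to all pathways). One deliberate
convention: changes creating stop codons count as non-synonymous
rather than being excluded from the site denominator, so that
N_sites + S_sites = 3 × codons compared holds exactly; this differs
from implementations that shrink the denominator and changes dN by
well under 1% on typical data. Proportions are corrected with
Jukes–Cantor d = −(3/4)ln(1−4p/3); ω = dN/dS is reported as undefined
(not infinite) when dS = 0 or either proportion saturates.

Group contrasts pool raw counts over all within-group pairs before
correction and ratio-taking, and bootstrap codon columns (default 200
replicates, seeded) for percentile intervals. The estimator is meant
for directional contrasts — strongly purifying vs relaxed groups — and
is consistent for ω ≤ 1 only when its assumptions hold (no
transition/transversion bias, low saturation); under a κ = 2 codon
model it under-estimates ω by roughly 20% at neutrality because
transitions are preferentially synonymous. Maximum-likelihood branch
and branch-site codon models are deliberately out of scope, and ML ω
values from such models are not comparable to these counting
estimates.

## Binding-site evolution

The engine evolves an 11-bp DNA core (configurable) against an energy
model scoring a 60-residue homeodomain/DNA complex, lower = more
stable. Each cycle proposes exactly one base change — position drawn
with weight 3.0 for the inner 9 positions vs 1.0 for the two flanks,
new base uniform over the three alternatives — rescores the complex,
and accepts if the energy is not worse (ties accepted). "Cycles" count
proposals, not acceptances. A configurable Metropolis temperature
(default 0 = greedy) covers the alternative reading in which worse
intermediates are occasionally kept. Four trajectories run per
invocation, one per homopolymer start (poly-A/C/G/T), with per-start
seeds derived as seed + start-index. Every evaluated (sequence,
energy) pair is archived, so good states visited but not kept as
templates still reach the consensus stage.

Consensus matrices pool the four archives, deduplicate by sequence
keeping each sequence's best energy, take the 50 lowest (ties broken
by sequence for determinism), and report per-position base
probabilities with information content 2 + Σ p·log₂p bits; export is
MEME-format text consumable by standard logo renderers. The
substitution scan scores all single-base substitutions of a fixed
start with the remaining positions held; for additive models its
position-wise argmin is the exact global optimum, making it both a
starting-bias control and an oracle.

The built-in `ContactPotentialModel` is a coarse additive residue–base
contact potential: a contact map links N-terminal-arm residues (2–8)
to the core edges and recognition-helix residues (47–57) to the
central major groove, with a 20×4 compatibility table encoding
textbook preferences (Asn/Gln→A, Arg/Lys→G, hydrophobics→T via the
thymine methyl, background 0.25). It exists to give the engine a
deterministic, enumerable default; it is not an atomic energy
function, and consensus motifs obtained with it should not be read as
binding-site predictions. Atomic backends plug in through
`ExternalEnergyModel`, a subprocess adapter calling
`command protein dna` and parsing a scalar; results that depend on
structure-based scoring (e.g. recovering the known ATTA core for Antp)
require such a backend and are validated here only through
model-independent invariants (greedy monotonicity, archive integrity,
planted-optimum recovery, scan/enumeration agreement).

## Synthetic data: what it does and does not emulate

The generators provide desk-scale stand-ins with exact ground truth.

- **Genomes/reads**: i.i.d. background bases at a requested GC
  fraction (default 0.40), planted proteins back-translated with
  uniform synonymous codon choice (recorded in the truth table),
  paired reads of length 101 at Normal(300, 30) insert, substitution
  errors only. Defaults mirror the regime of low-coverage insect
  genome surveys (6–17×, 101-bp paired reads); the acceptance runs use
  1 Mb genomes at 15× with 0.5% error so ten seeds complete in about a
  minute. No coverage bias, indels, heterozygosity or repeat
  structure — so passing tests show estimator correctness under the
  model, not robustness to real-genome repeat/heterozygosity spectra.
- **Codon alignments**: GY94-style Markov simulation on a newick tree,
  uniform codon frequencies over the 61 sense codons, κ = 2 default,
  per-branch ω, branch lengths in expected substitutions/codon (the
  rate matrix is rescaled per branch ω). No stop codons ever arise;
  no indels; no among-site rate variation.
- **Energy landscapes**: mismatch-count × penalty from a planted
  target, optional Gaussian noise drawn deterministically per sequence
  (seeded by a CRC of the sequence) so the model stays a pure
  function; unique global optimum at noise 0, verifiable by
  enumeration at core length ≤ 8.
- **Protein MSAs**: i.i.d. background residues per species, motif
  residues copied into carrier species. Background columns are redrawn
  until they fail the conservation rule, so the planted truth is
  exactly the set of detectable motifs — precision/recall 1.0 is the
  designed behaviour at background rate 0, and the tests verify the
  detector against an independent column-wise validator rather than
  only against the generator. Planted motifs whose carriers violate
  the half-of-species or both-lineages rule are planted but excluded
  from truth.

## Problem sizes and tolerances

Acceptance-scale runs use: 10 × (1 Mb, 15×, 0.5% error) genome-size
recoveries (median relative error ≤ 5% asserted; ≈ 0.3–0.4% observed);
a 100 kb genome with all ten homeodomain classes planted on both
strands (10/10 recall, exact coordinates, correct class) and 1 Mb
random-sequence scans for false hits (mean ≤ 2 per Mb asserted; 0
observed); 50-seed motif recovery; NG86 vs exhaustive pathway
enumeration on all sense-codon pairs with ≤ 2 differences; 100-seed
ω-ordering contrasts at 0.02 vs 1.0 over 500 codons (≥ 95 required);
and 100 seeded evolution runs at core length 8 against the enumerated
optimum (≥ 95 required; monotone best-energy paths in all runs). These
sizes keep the full suite and the acceptance script each within a few
minutes on a single CPU while leaving every assertion at the stated
tolerance.

## Known limitations

- The profile scan cannot find homeoboxes split across exons or
  contig boundaries, and reports absence only as absence of hits.
- The Gumbel E-value analogue is calibrated per profile on synthetic
  background; scores are not comparable across profiles with different
  column entropies except through their E-values.
- Counting dN/dS saturates quickly; beyond roughly one substitution
  per site the Jukes–Cantor correction and pathway averaging both
  degrade, and ω is reported undefined on saturation rather than
  extrapolated.
- The invariant-site and motif statistics treat the alignment as
  given; alignment errors propagate directly.
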
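# lephox

Tools for surveying homeobox genes in low-coverage draft genomes of
Lepidoptera and allied insects, with the molecular-evolution statistics
needed to characterise fast-evolving Hox-cluster paralogues such as the
ditrysian *Shx* (Special homeobox) genes — divergent tandem duplicates
of *zen*, the insect Hox3 gene repurposed for extra-embryonic tissue
specification.

The package covers five analysis stages, plus a synthetic-data module
that generates ground-truthed inputs for all of them:

1. **k-mer genome profiling** (`lephox.kmer`) — compute the k-mer
   multiplicity spectrum of shotgun reads, locate its coverage peak
   C<sub>k</sub>, convert to per-base coverage via
   C<sub>k</sub> = C·(L−k+1)/L for read length L, and estimate genome
   size as sequenced bases / C.
2. **homeobox hunting** (`lephox.hunt`) — six-frame sliding scan of
   contigs with 60-column homeodomain log-odds profiles, an empirical
   Gumbel E-value analogue, greedy redundancy removal, and orthology
   classification by p-distance to labelled references plus diagnostic
   residues (serine at homeodomain position 10 marks the Hox3/zen/Shx
   lineage). Includes neighbor joining for assignment support trees.
3. **conservation statistics** (`lephox.conservation`) — missing-data
   column filtering (>50% rule), conserved-motif detection (runs of ≥3
   columns whose residue state is carried by ≥ half the species and by
   both sides of a deep lineage partition), invariant-site percentages,
   and pairwise divergence under p, Poisson or JTT maximum-likelihood
   distances.
4. **selection contrasts** (`lephox.dnds`) — Nei–Gojobori (1986)
   counting estimates of dN and dS with equal-weight shortest-pathway
   apportionment and Jukes–Cantor correction, pooled over taxon groups
   with a codon-column bootstrap; ω = dN/dS ≪ 1 indicates purifying
   selection, larger ω relaxed constraint.
5. **binding-site evolution** (`lephox.evolve`) — cycles of single-base
   mutation and greedy selection of an 11-bp DNA core (elevated
   sampling of the inner 9 positions) against a pluggable protein–DNA
   energy model, from all four homopolymer starts; consensus
   base-probability matrices with information content are built from
   the 50 lowest-energy archived complexes, with a substitution-scan
   control for starting-point bias and a subprocess adapter for atomic
   scoring backends.

## Worked example

Plant a homeodomain on the reverse strand of a synthetic 500 kb genome,
sequence it to 15× with 0.5% base error, and run the first two stages:

```python
import numpy as np
from lephox import synthetic, kmer, hunt

panel = synthetic.gen_reference_panel(seed=0)          # labelled references
zen = next(r for r in panel if r[1] == "zen/Shx")
spec = synthetic.SyntheticGenomeSpec(
    length=500_000, seed=7,
    planted_genes=[("zen_planted", zen[2], 120_000, "-")],
)
contigs, truth = synthetic.gen_genome(spec)
genome = contigs["synthetic_contig_1"]
reads = synthetic.simulate_reads(
    genome, synthetic.ReadSimSpec(coverage=15, error_rate=0.005, seed=7))

codes = np.vstack([reads.r1, reads.r2])
print(kmer.profile_reads(codes, reads.true_total_bases, read_length=101, k=17))

for c in hunt.hunt_genome(contigs, panel, threshold_evalue=1e-6):
    h = c.hit
    print(f"{h.contig_id}:{h.start}-{h.end}({h.strand}) "
          f"class={c.assigned_class} S10={c.diagnostic_flags['S10']} "
          f"E={h.evalue_like:.2e}")
```

prints

```
{'k': 17, 'ck': 11.628, 'c': 13.817, 'total_bases': 6881012.365,
 'genome_size': 498028.0, 'input_bases': 7500058}
synthetic_contig_1:120000-120180(-) class=zen/Shx S10=True E=3.94e-13
```

The k-mer peak sits at multiplicity ≈ 11.6 rather than the nominal
15 × 85/101 ≈ 12.6 because sequencing errors spill genomic 17-mers
into the low-multiplicity error ramp; the peak-region estimator
excludes that ramp from both the coverage and the base count, so the
genome-size estimate lands within 0.4% of the true 500 kb. The scan
recovers the planted homeobox at its exact coordinates (0-based,
half-open, forward strand), on the correct strand, classified to the
zen/Shx class with the Hox3-diagnostic serine-10 flag set.

A command-line interface mirrors the library:
`lephox synth|kprof|hunt|conserve|dnds|evolve|scan --help`.

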
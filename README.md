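# cfdonor

Donor-derived cell-free DNA (dd-cfDNA) quantification **without a donor
genotype** — a "one-genome" maximum-likelihood estimator with an
identity-by-descent (IBD) hidden Markov extension for related
donor–recipient pairs, plus the two-genomes reference estimator and a
generative benchmark simulator.

## The problem

After a solid-organ or bone-marrow transplant, the fraction *d* of plasma
cell-free DNA that originates from the graft tracks graft health:
rejection and tissue injury release donor (or, in marrow transplants,
recipient) DNA into circulation. Genome-wide SNP differences between donor
and recipient genomes make *d* measurable from shotgun cfDNA sequencing —
but the conventional approach needs both genotypes, and the donor's is
often unavailable. `cfdonor` estimates *d* from three inputs only:

1. the recipient genotype at bi-allelic SNPs (VCF or TSV),
2. per-SNP cfDNA allele counts (TSV, e.g. derived from `samtools mpileup`),
3. population allele-frequency tables (one column per candidate population).

A genetic map (chrom, pos, rate, cumulative cM) is additionally needed for
the related-donor model.

## The model

For SNP *i* with alleles A/B and population allele-A frequency *f*, the
likelihood marginalizes the true recipient genotype (given the measured
one and genotyping error e_g ∈ [10⁻⁹, 10⁻³]), the donor genotype
(Hardy–Weinberg from the candidate population: f², 2f(1−f), (1−f)²), and
each read's true allele (sequencing error e_s ∈ [10⁻⁹, 10⁻²]):

    P(read = A | r, dd; d) = d · dose_A(dd)/2 + (1 − d) · dose_A(r)/2

with the per-SNP likelihood a product over reads, and the genome
log-likelihood a sum over independent SNPs. −log L is minimized with
bounded L-BFGS-B for every candidate population; the best population wins.

For related pairs, each haploid pair of the duo follows a two-state
(IBD / not-IBD) chain over ~2 cM genetic blocks. With m = 1 − log₂(P_IBD)
meioses separating a pair and Haldane crossover probability
θ = (1 − e^{−2l/100})/2 across l cM, the chain stays IBD with probability
y₁y₂, y₁ = (1−θ)^{m−2}, y₂ = (1−θ)² + θ², and enters IBD with probability
(1 − y₁y₂)/(2^{m−1} − 1), giving stationary IBD mass exactly P_IBD. Donor
genotype priors condition on the recipient genotype per IBD count (0: the
population prior; 1: one shared haploid; 2: identical genotypes), and the
forward algorithm integrates the four-state joint chain over the genome.
The fit then maximizes over (d, e_s, e_g, P_IBD^I, P_IBD^II), P_IBD ≤ 0.5.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## A worked example

`examples/02_sibling_donor_ibd.py` simulates a marrow-transplant-like
sample whose donor is a sibling (60% dd-cfDNA, 100K SNPs, 1.5× coverage)
and compares the naive and IBD-aware fits:

```
$ python examples/02_sibling_donor_ibd.py
simulated dd-cfDNA fraction      : 0.600
unrelated-model estimate (naive) : 0.325
IBD-aware estimate               : 0.594
estimated IBD probabilities      : 0.500, 0.452
```

The naive estimate recovers barely half the truth — donor molecules inside
IBD segments are indistinguishable from recipient ones — while the HMM
recovers the fraction within 0.006 and identifies both haploid pairs as
sibling-like (P_IBD ≈ 0.5). The other scripts in `examples/` cover the
unrelated fit, the two-genomes cross-check, benchmark sweeps, and the
plasma-vs-cellular chimerism divergence.

The same operations are scriptable from the shell:

```bash
cfdonor simulate --config sim.yaml -o data/
cfdonor blocks --map data/genetic_map.txt --snps data/genotypes.tsv -o blocks.tsv
cfdonor fit --genotypes data/genotypes.tsv --counts data/counts.tsv \
            --freqs data/frequencies.tsv --mode related \
            --map data/genetic_map.txt -o fit.json
```

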
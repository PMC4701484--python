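# radnet

Reference-free SNP discovery and linkage-disequilibrium analysis for
reduced-representation (ddRAD) sequencing of inbred polyploid panels, with a
downstream LD toolkit: background-LD estimation, LD-based placement of
unmapped markers on a genetic map, LD-decay fitting, confidence-interval
haplotype blocks with group classification, and marker/trait arithmetic
(PIC, broad-sense heritability, genome-wide significance thresholds).

## The problem and the approach

Allopolyploid crops such as oilseed rape carry large families of homeologous
and paralogous sequences.  Aligning short reads to a reference — or naively
clustering them without one — conflates two very different kinds of sequence
pair: the two **alleles** of one locus, and two **homeologous copies** at
different loci.  Calling a homeolog pair as a SNP produces a marker that is
"heterozygous" in nearly every line and poisons downstream genetics.

`radnet` implements a network-based, reference-free discovery path:

1. 90 bp paired-end reads are demultiplexed by exact inline barcode +
   restriction-site remnant match at both ends, trimmed to 80 + 80 nt, and
   collapsed into **tags** with per-line read counts.
2. Tags seen in only one line or with a single read are removed; survivors
   are linked into **networks** (connected components under ≤ 2 mismatches
   per read end), and low-count error tags are pruned with an error
   tolerance rate (ETR, default 0.03).
3. Within each 2–10-tag network, every tag pair is scored across the panel:
   `n_het` lines carry both tags, `n_hom_a` / `n_hom_b` carry only one.  The
   **relative heterozygosity**

   H_R = n_het / min(n_hom_a, n_hom_b)

   is near zero for true allelic pairs in an inbred panel and large for
   homeolog pairs, which are co-present in most lines.  Pairs with
   H_R < 0.20 are accepted (greedily, disjointly per network) and genotyped:
   only tag A → homozygous allele 1, only tag B → homozygous allele 2,
   both → heterozygous, neither → missing.

Downstream, inbred genotypes are haploidized and LD is the squared allele
correlation r² = D²/(p(1−p)q(1−q)).  The **background LD** is the
nearest-rank 99th percentile of r² among different-chromosome anchor pairs
(0.26 in the panel this toolkit was designed around; shipped as the default
constant).  Unmapped markers inherit the map position of their highest-r²
anchor when that r² exceeds the background.  LD decay is fitted with the
Hill–Weir drift expectation E(r²) as a function of C = ρ·d, and the decay
distance solves E(r²)(d) = background.  Haplotype blocks follow the D′
confidence-interval model (strong LD: 90% CI within [0.70, 1] with upper
bound ≥ 0.98; blocks need ≥ 95% strong-LD informative pairs; < 100 kb
removed), and per-group block sets are classified as group-specific, common,
or group-preferential (major-haplotype frequency difference > 0.40).

## Worked example

`examples/snp_discovery.py` simulates a 24-line panel with 80 allelic loci
and 15 homeolog families and runs the whole discovery path:

```
reads: 23937, assigned 23574, rejected 363 (imperfect barcode/remnant)
distinct tags: 6192
after removing single-read / single-line error tags: 386
networks of 2-10 tags: 89
allelic tag pairs (H_R < 0.20): 75, carrying 165 SNPs
genotype matrix: 24 lines x 75 markers
74/75 called pairs match planted loci; ...
```

Most raw tags are singleton sequencing-error derivatives and disappear at
the filtering step; the H_R discriminator then recovers almost all planted
allelic loci while rejecting the homeolog families, which present as
constitutive heterozygotes.  The other example scripts cover LD-based map
assignment (`ld_map_assignment.py`), decay fitting (`ld_decay.py`),
haplotype blocks and their group classification (`haplotype_blocks.py`),
and marker/trait arithmetic (`trait_summaries.py`); each prints the numbers
it computes together with a one-line interpretation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch on seeded simulations:
the full read-to-genotype pipeline on the reference panel (96 lines, 500
allelic loci, 100 homeolog families), background-LD estimation and LD-based
map assignment on a 189-line genotype simulation, the Hill–Weir decay fit
with its background crossing, and haplotype-block detection on planted
blocks.  It prints a run summary and writes the results manifest to the
`--out` path.
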
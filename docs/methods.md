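# Methods

## Homozygosity mapping

A genotype call is classified for ROH support as one of `HQ_HOM`, `HET`,
`LOW_QUALITY`, `MISSING`. `HQ_HOM` requires a homozygous (or hemizygous)
genotype with genotype quality ≥ `min_gq` (20), total read depth — the sum
of the allelic depths — ≥ `min_depth` (10), and called-allele depth over
total depth ≥ `min_allele_fraction` (0.9). "Total depth" and "called-allele
fraction" are the only readings of a depth/fraction pair that are
well-defined for homozygous calls, which is why the thresholds are defined
that way here. Any *called* heterozygote is `HET` regardless of quality
(an optional `het_min_gq` demotes weak heterozygotes to `LOW_QUALITY` for
noisy call sets); everything else is `LOW_QUALITY`.

A run of homozygosity is a maximal stretch of ≥ `min_run` (4) `HQ_HOM` SNVs
with no intervening `HET`. Two deliberate conventions:

* `LOW_QUALITY` and `MISSING` sites are transparent — they neither support
  nor break a run. The rule counts confident homozygotes and is broken only
  by evidence of heterozygosity.
* The interval spans the first to the last supporting SNV (half-open past
  the last SNV's base). No extension toward flanking heterozygotes: the
  reported segment is exactly the marker-supported one, reproducible from
  the call set alone. A corollary, relevant to testing: a variant lying in
  the unmarkered margin of a true autozygous segment is *outside* the
  detected run. This is a property of point-marker support, not an error.
* Indels never support runs (the rule is about SNVs) but remain in the
  record stream for prioritization.
* No maximum inter-SNV gap is imposed by default (`max_gap` is available);
  per-sample runs are *not* length-filtered.

The shared autozygome is the chromosome-wise interval intersection across
all affected samples' tracks, keeping pieces ≥ `min_shared_length` (1 Mb).
Intersection is commutative and associative; a shared piece's supporting-SNV
count is the minimum over its source intervals. Internally all coordinates
are 0-based half-open; 1-based coordinates exist only at the VCF/HGVS
boundary. Unsorted VCF input is an error by default (`allow_unsorted`
re-sorts) because silent re-sorting hides upstream problems.

## Recessive prioritization

Candidates are the variants called homozygous-alternate in every affected
member. Each filter appends a machine-readable reason; a candidate with no
reasons is retained, and the verdict list is sorted retained-first, then by
reason count and id. Because every filter is a pure predicate on one
candidate, the retained set is invariant under any ordering of filters or
candidates.

* `fails_segregation` — some affected member is not homozygous-alternate, a
  genotyped unaffected parent is not heterozygous, or an unaffected member
  is homozygous-alternate. A *missing* parental genotype is reported as
  `missing_parental_genotype` (excluding, but distinct from an observed
  segregation failure).
* `frequency_exceeds_cutoff` — any per-database allele frequency > 0.5%.
  Databases are tested independently, not pooled: the conservative choice
  when database sampling frames differ.
* `control_homozygote` — any homozygote among healthy controls. This is
  separate from the frequency rule because under a recessive model carrier
  heterozygotes are expected and tolerated; a single healthy homozygote is
  the decisive observation against causality.
* `outside_shared_roh` — position not inside any shared interval (binary
  search over the sorted half-open track).
* `phenotype_mismatch` — the annotation flag `phenotype_match = no`. This
  encodes clinical judgment (a gene's known disease association does not
  fit the patient phenotype); it is consumed as input, never computed.
* `benign_prediction_low_conservation` — conservation score below 2.0 *and*
  no in-silico tool giving a confidently damaging label. Equivocal labels
  ("possibly damaging") do not count as damaging, so they cannot rescue a
  poorly conserved variant; they also never exclude on their own. Variants
  without a conservation score never fire this rule.

The X scan returns variants outside the pseudoautosomal regions (hg19
PAR1/PAR2 by default, overridable for toy genomes) that are hemizygous-
or homozygous-alternate in every affected male, absent in unaffected males,
and pass the frequency filter. It applies only when all affected members
are male; otherwise it is skipped with a logged notice.

## Consequence prediction

The transcript model is a strand-aware exon structure over a supplied locus
sequence with transcript-space CDS bounds. For a deletion overlapping one
exon's interior or terminal bases, splicing is modelled as *preserved*: the
donor (or acceptor) shifts to recruit the adjacent base and the spliced
cDNA loses exactly the deleted exonic bases. This is the empirically
observed outcome for donor-adjacent single-base deletions, implemented as a
deterministic rule; splice-site strength is deliberately not modelled.
Deletions that are fully intronic return the unchanged cDNA with a notice;
deletions spanning a whole exon or several exons are unsupported errors.

Protein consequences compare the original CDS translation with the edited
molecule translated from the same CDS start through the 3'UTR. The first
divergent residue anchors the HGVS-like string; a deletion length divisible
by 3 is an in-frame deletion, otherwise a frameshift with
`stop_offset` = 1-based index of the first stop in the new frame, counting
the divergent residue as 1 (`not found` when the transcript ends first). A
frameshift whose first divergent codon is itself a stop is reported as
`stop_gained` (`p.X<pos>*`), which is why `frameshift` always implies
`stop_offset ≥ 2`. One-letter amino-acid codes with `fs*N` are used rather
than three-letter HGVS-strict, and only the standard nuclear code is
supported.

## The simulator

The pedigree is fixed: grandparental couple G1/G2, children C1/C2 married
to unrelated S1/S2, first cousins F and M (kinship 1/16), and two affected
sons II.1/II.2 (expected inbreeding coefficient F = 1/16, verified by path
counting in the pedigree code itself). Meioses draw crossover counts
Poisson(L_Mb × rate/100) with uniform positions and no interference on a
linear 1 cM/Mb map — the simplest model producing the correct autozygous
segment-length scale (~100/6 ≈ 17 cM for the six-meiosis loop). Founder
haplotypes are labelled, so autozygosity is exact bookkeeping: segments
where a child's two haplotypes carry the same founder label.

Default scale is desk-sized and chosen once: 2 chromosomes × 50 Mb,
5 markers/Mb, founder marker allele frequencies ~ Uniform(0.1, 0.5) so
markers are informative for descent. The planted loss-of-function variant
(emitted as a 1 bp deletion) sits at a fixed position on one grandparental
haplotype; a drop segregates in ≈ 1/256 of replicates, so the generator
resamples the whole drop until segregation (or flags a non-segregating
replicate when resampling is disabled). Decoys are placed uniformly
(length-weighted) inside the *realized* shared autozygous segments, riding
the founder haplotype that is IBD there — the only placement under which a
fixed annotation archetype is guaranteed to be shared homozygous, mirroring
how real decoy candidates arise. The three default archetypes: a control
homozygote carrier (with 16 database heterozygotes), a phenotype-mismatched
gene, and a benign-prediction/low-conservation variant (score 1.101).

Noise model: per-call depth ~ Poisson(30) (negative binomial if a
dispersion is set); allelic depths binomial around the true dosage with
per-read error 0.005; GQ ~ Normal(60, 15) clipped to [0, 99]; and with
probability 0.001 the *called* genotype is replaced by a different one
while the evidence fields keep their clean-looking values — the realistic
failure mode for hard-filtered exome calls, and the one that actually
stresses the pipeline (a miscalled heterozygote can split a run). All
randomness flows from one seed; fixed seed gives byte-identical output.

What the simulator does not emulate: linkage disequilibrium, demography,
exome capture bias, mapping artefacts, multi-nucleotide variants, and
pedigree errors. Passing tests therefore demonstrate correctness of the
mapping/filtering logic under idealized marker independence, not robustness
to real exome artefacts. Marker homozygosity-by-state, however, *is*
present (founder frequencies are high), so chance ROH and the resulting
reliance on the downstream filters are exercised realistically.

## Validation design

Every nontrivial algorithm is checked against an independent re-derivation:
the ROH caller against direct enumeration of candidate windows; the
consequence engine against a full-translation diff using a literal codon
table; autozygosity against the closed-form F = 1/16 (2000 simulated
children, agreement within 3 Monte-Carlo standard errors); the full
pipeline against the simulator's truth record (unique recovery of the
planted variant in ≥ 90% of 100 segregating replicates — measured ≈
95–100% across seeds at the default noise level). Problem sizes (1000
random chromosomes, 500 random deletions, 100 replicates) keep the complete
validation suite within a few CPU-minutes while leaving Monte-Carlo error
well below the asserted margins.

## Known limitations

* ROH calling is rule-based; no HMM/likelihood model, no genetic-map-aware
  lengths, no LD pruning. Dense common markers produce chance runs by
  design of the rule.
* The frequency cascade cannot validate intermediate funnel sizes against
  external data; only the four-variant endpoint is encoded.
* The donor-shift rule applies to deletions touching at most one exon;
  whole-exon and multi-exon events are out of scope.
* compound heterozygosity, CNVs and gVCF inputs are not modelled.
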
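# Methods

`roxevol` studies how the binding sites of chromatin-associated lncRNAs
(modeled on the *Drosophila* dosage-compensation RNAs roX1/roX2) can be
found across genomes and how they evolve. Because the real analyses need
dozens of fly genomes and deposited ChIRP-seq data, the package ships a
synthetic data generator whose planted truth plays the role of the real
signal; every statistical claim is then checked as a recovery problem with
known ground truth.

## The synthetic model

### Species set (`generate_species_set`)

Eight species (`sp0`–`sp7`) each carry one 20-kb scaffold holding a lncRNA
locus flanked by two protein-coding anchor genes (60 aa each, ≤2 kb from
the locus). The reference locus contains a fixed number of motif units
(consensus `GCTTGTGA`) folded into stem–loops: each unit's 3′ arm is the
reverse complement of its 5′ arm around a short loop. Orthologous loci
diverge from the reference by substitution only (no indels), at per-site
rates rising linearly from 0.0 to 0.06 across the clade; coding sequence
mutates only at third codon positions (synonymous-biased), non-coding
sequence uniformly. Substitution-only divergence keeps coordinate maps as
identity maps, so lift-over behavior can be tested separately from
alignment behavior. A species can be declared a *decoy*: its locus
sequence is scrambled (composition preserved, motifs destroyed) while its
anchors stay intact — the negative control for the ortholog search.

Rates and motif counts were fixed a priori when the generator was written:
0–6% spans "nearly identical" to "roughly the divergence at which an
8-mer expects ~0.5 substitutions", and the motif count (8) is enough for
cluster election to be non-trivial while fitting a 1.5-kb locus.

### Annotated scaffolds and PPTs (`generate_annotated_scaffold`)

Genes with alternating strands are tiled along a scaffold (30 genes; 300-bp
exons, two 600-bp introns, 700-bp intergenic gaps). Every intron receives
one polypyrimidine tract (PPT) on the transcribed strand: length 12–25,
each base pyrimidine with probability 0.9, ending 5–40 bp upstream of the
3′ splice site (the penalty-free zone of the PPT selector). Planting is
per-base Bernoulli, so a minority of tracts are weaker than the detector's
85% threshold — deliberate: the detector must cope with marginal tracts.

### ChIRP-style experiments (`generate_chirp_experiment`)

An annotated genome (chrX 300 kb, chr2 100 kb) receives planted peaks:
50 X-linked and 2 autosomal by default. Input coverage is flat Poisson;
each RNA's ChIRP track adds a triangular bump per peak scaled so the
1-kb window holding the peak reaches the planned 20-fold enrichment. 20%
of summits are placed 20–95 bp from a planted PPT midpoint (proximal set);
the rest are kept >100 bp from any PPT so the realized proximal fraction
matches the plan. Every summit receives a GA-repeat motif (`GAGAGAGAGA`)
whose orientation follows a per-feature bias (80% reverse in introns, 80%
forward in coding exons, measured against the host gene's strand).
Distinct summits are kept at least motif length + 2 apart so planted
motifs never overwrite each other. `feature_peaks` can force extra peaks
into introns/CDS for orientation studies, and `spacing_regime`
(even/random/clustered) controls summit placement for spacing analyses.

### Known limits of the generator

- No indels, so alignment gap handling is exercised only by unit oracles,
  not by the species set.
- Coverage bumps are triangular, not read-sampled; q-scores are drawn, not
  computed from coverage.
- One transcript per gene; alternative splicing enters only through
  deliberately overlapping toy annotations in tests.
- The homology floor on these loci (~50%) is higher than for natural
  sequences because the global aligner with small gap penalty aligns
  scrambled sequences of identical composition rather well; the floor is
  reported, not assumed.

## Analysis components

- **Ortholog search**: anchors are located by six-frame translation,
  exact 5-mer amino-acid seeding and ungapped BLOSUM62 extension; the
  synteny window between anchors (≤ max span) is scanned with a PWM built
  from the reference motif instances; a candidate needs ≥3 hits in a
  500-bp window (ties broken by hit count, then total score, then leftmost
  position) and a stem–loop score ≥6 at one hit. Accepted instances
  refine the PWM (counts accumulate; background re-estimated from searched
  windows) before the next species, walking the phylogeny by distance.
- **PWM p-values** are exact: per-column log-odds are rescaled by 100 and
  rounded to integers, the full score distribution under the background is
  built by dynamic programming, and the tail is clipped at 1. Default scan
  threshold p ≤ 1e-4.
- **Stem–loop score**: ungapped arms (2–20 nt, loop 3–50), Watson–Crick
  plus G·T wobble; score = pairs − mismatches; the 5′ arm must overlap the
  focus window. Threshold 6.0 ≈ a 7-bp helix with one mismatch.
- **Sequence identity**: global alignment (match +1, mismatch −1, linear
  gap −2), identity = matches / (matches + mismatches + gaps) × 100; the
  scrambled-sequence floor uses the same aligner on composition-preserving
  shuffles.
- **PPT selection**: tracts ≥9 nt, ≥85% C/T, ≤1 purine per 10 nt; raw
  score = #pyrimidines − 2×#purines; distance penalty 0 up to 40 bp from
  the 3′ splice site, then 0.02 per base (the offset convention is
  penalty = 0.02 × (d − 40) for d ≥ 40, so d = 40 itself is free); ties
  prefer the tract closer to the splice site, then the longer one.
- **Statistics**: two-sample KS with D from pooled ECDFs and p from the
  asymptotic Kolmogorov distribution at effective n = nm/(n+m); exact
  two-sided binomial by tail doubling; permutation nulls relocate summits
  uniformly within their chromosome. Spacing uses nearest-neighbour
  distances against a uniform null; the evenness score is the excess
  probability mass within ±25% of the perfect distance D* = L/n.

## Determinism

All randomness flows through `child_rng(seed, label)` =
`default_rng(SeedSequence([seed mod 2^31, crc32(label)]))`, so every
component draws from an independent, label-separated stream and any table
regenerates byte-identically from its seed. `run_pipeline` writes a
manifest with a config hash and per-output checksums; reruns are verified
byte-identical in the test suite.
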
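# Methods

## Problem setting and model

`shmscope` quantifies somatic hypermutation (SHM) in cloned, pre-aligned
antigen-receptor V-region cDNA when no assembled germline locus exists. The
core inferential move is to use clonal identity as a germline surrogate:
clones carrying an identical CDR3-J junction (at the nucleotide level,
within one individual) descend from one founder cell, so differences among
them arose somatically. Everything downstream — consensus building,
mutation calling, hotspot targeting, mutability indices, region and tissue
comparisons — is conditional on that grouping.

Alignment is an input contract, not a computation: sequences of one V
family must arrive aligned to a common column space with a region map
(FR1/CDR1/FR2/CDR2/FR3/CDR3/J/C intervals, 0-based half-open columns, plus
the frame offset of FR1's first codon position). Re-alignment would add an
uncontrolled degree of freedom to every downstream count.

## Clonal grouping and junction analysis

* Grouping key: `(family, CDR3-J nucleotide string, individual)`. The key
  is the ungapped concatenation of the CDR3 and J region columns; identity
  is exact string equality. Amino-acid identity is not accepted. The same
  junction in two individuals is treated as two events.
* `min_size` defaults to 2: only groups of ≥2 clones support a consensus.
* Germline V/J boundary inference scans columns 5'→3' (and 3'→5' for J)
  for cross-individual agreement: a non-gap base carried by ≥2 individuals
  is taken as germline. Extension ends at a run of ≥2 columns without
  agreement (`break_threshold`, configurable; 2 avoids terminating on a
  lone polymorphism). Columns carried by a single clone (e.g. private
  insertions) are skipped as alignment artifacts. If no break exists the
  boundary falls back to the region map's CDR3 start.

  Accuracy, measured on simulated same-V/same-J families of two
  individuals with known trim points: ~87% of boundaries within ±2 nt of
  truth. The ceiling is inherent: non-templated junction bases agree
  across individuals by chance (¼ per overlapping column), and the rule
  then legitimately but wrongly extends the "germline" segment. Families
  assembled from many founders, or founders using different J genes,
  degrade the estimate further — the method presumes the compared clones
  share germline V and J.
* Identity-based family assignment uses single-linkage clustering on
  pairwise ungapped V-segment identity (matches / columns where both are
  non-gap), defaulting to 85% (family) and 90% (subfamily). Single linkage
  is a mechanical approximation to the tree-cutting practice it replaces;
  it merges chains whose ends fall below the threshold.

## Consensus and mutation calling

* Consensus: per-column plurality over members; gap only when gaps are the
  strict majority; ties resolved to the earliest member in input order
  (logged). An IUPAC-ambiguity alternative was rejected because ambiguity
  codes would poison codon classification downstream.
* A call is any (member, column) with distinct non-gap member and
  consensus bases. Insertion columns (consensus gap) yield no calls;
  member-gap and insertion columns are excluded from that member's
  denominators. Counting against the consensus undercounts mutations the
  founder shares with a majority of descendants; with per-base rates ~0.02
  and ≥2 members this bias is small (measured: consensus equals the true
  founder at >99% of columns for 9-member groups), but it is a real floor.
* SYN/NSYN: the observed base is substituted alone into the consensus
  codon containing its column; translation uses the standard nuclear code;
  stop codons count as NSYN. The reading frame runs over the consensus'
  non-gap columns from `frame_offset`, so private insertions do not shift
  it. Columns before the frame start or in an incomplete terminal codon
  are UNDETERMINED: counted in totals, excluded from SYN/NSYN tallies.
  Classification is applied wherever a complete codon exists, including J
  and C columns; the FR/CDR summary tables use FR/CDR regions only.
* Tandem runs: maximal sets of ≥2 consecutive mutated alignment columns
  within one member; runs never span a gap column. Each mutated base keeps
  its own independent SYN/NSYN classification.

## Hotspot analysis

* Motifs: DGYW (target G at offset 1), WRCH (target C at offset 2), WA
  (target A at offset 1), TW (target T at offset 0); D=A/G/T, Y=C/T,
  W=A/T, R=A/G, H=A/C/T. Scanning is forward-strand only: each pair is its
  own reverse complement, so one strand covers both. Overlapping windows
  all count; target positions are deduplicated per class. Scanning runs on
  the ungapped consensus only — motifs created by a member's mutation are
  never counted — and positions map back to alignment columns.
* Strata: FR (FR1+FR2+FR3) and CDR (CDR1+CDR2+CDR3) nucleotide totals are
  consensus columns weighted by member coverage. Expected in-motif
  mutations split each class's observed total in proportion to nucleotide
  totals; the enrichment ratio is the in/out frequency ratio; χ² (df=1)
  compares observed with expected over {in, out}. Group-level one-tailed
  t-tests (in-motif > outside frequencies per group) accompany the table.
  Per-stratum expected values for FR and CDR rows are computed from these
  first principles; only the ALL/Outside construction is anchored to
  published counts.

## Summary statistics

* Pooled frequencies are always ratios of sums (Σ mutations / Σ
  nucleotides across groups), never means of per-group ratios; a
  regression test pins this distinction.
* Mutability index: MI_b = o_b / (O·n_b/N). Bias tests pair (G,C) and
  (A,T): the statistic sums (O−E)²/E over the pair's two bases and is
  referred to χ² on one degree of freedom — the construction that exactly
  reproduces the published p-values from the published counts, adopted
  here as the convention.
* Substitution spectrum: transitions are A↔G and C↔T; the C:A/G:T
  transversion class is tallied separately, matching the reporting
  convention of the source tables.
* All t-tests are unpaired, pooled-variance, one-tailed Student tests with
  the clonal group as observation unit (directions: CDR > FR;
  periphery > thymus). Zero-variance, equal-mean comparisons report
  p = 0.5. No multiple-testing correction is applied by default.
* CDR-vs-FR testing excludes CDR3 from the tested CDR frequency. Groups
  are defined by identical CDR3-J junctions, so within a group CDR3
  columns cannot exhibit mutations; leaving their structurally
  mutation-free denominators in the test biases it toward FR regardless of
  the truth (in null simulations the one-tailed p collected near 1; with
  the exclusion, null p-values are uniform — KS p ≈ 0.46 over 200
  replicates, type-I error 3% at α=0.05). Descriptive tables still count
  CDR3 as annotated. `include_cdr3=True` restores the naive comparison.

## The synthetic repertoire generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the emulated study conditions.

| parameter | default | meaning |
|---|---|---|
| `n_v_genes`, `n_j_genes` | 9, 6 | germline segment counts |
| `v_length_nt` | 300 | V gene length (fixed FR1 75 / CDR1 21 / FR2 51 / CDR2 21 nt; FR3 fills to a 9-nt CDR3 tail) |
| `family_identity` | 0.90 | target pairwise identity of germline segments |
| `n_founders` | 48 | founder rearrangements (clonal groups) |
| `members_min..max` | 2–9 | clone family sizes |
| `trim_max` | 6 | max exonuclease trim per cut end |
| `np_min..max` | 0–12 | junction N/P insert length (±2 nt frame adjustment) |
| `per_base_rate` | 0.02 | realized marginal mutation rate per eligible base |
| `gc_hotspot_multiplier` | 4.0 | DGYW/WRCH target weight |
| `at_hotspot_multiplier` | 2.0 | WA/TW target weight |
| `cdr_multiplier` | 2.0 | extra CDR1/CDR2 weight |
| `transition_bias` | 2.0 | transition:transversion odds per substitution |
| `tandem_prob` | 0.25 | chance a mutation event extends into a run |
| `tandem_max` | 4 | maximal run length |
| `insertion_prob` | 0.01 | per-member chance of an in-frame FR3 insertion (3 or 18 nt) |
| `n_individuals` | 2 | donors; founders assigned randomly |

Design choices that matter:

* Rearrangements are productive by construction: junction length is
  adjusted so the J segment stays in its design frame (total length is
  then a codon multiple), and junctions whose spanning codons contain a
  stop are resampled. P additions mirror untrimmed cut ends (≤2 nt);
  N bases are uniform.
* Position weights are computed against the founder sequence (motifs are
  not rescanned after each mutation), mirroring the analysis convention of
  consensus-only motifs.
* Weights are renormalized so the realized marginal rate equals
  `per_base_rate`, including the expected extra bases contributed by
  tandem extensions (factor 1 + `tandem_prob`·E[run length − 1]); without
  this, multipliers and tandems would silently inflate the rate and
  parameter-recovery checks would be biased by construction.
* Tandem run lengths follow the empirical 40:10:1 histogram for runs of
  2:3:4 bases, truncated at `tandem_max`; with `tandem_prob` 0.25 this
  yields ≈43% of mutated bases inside runs, matching the shark TcRα
  observation (≈42%).
* CDR3 and J columns are protected from mutation by default so clonal
  grouping truth is exactly recoverable (`protect_cdr3j=False` lifts
  this). In-frame insertions are placed at FR3 codon boundaries; placing
  them in CDR3 would corrupt the junction key of truth families. Insertion
  columns widen FR3, which is why region codon-divisibility is validated
  as a warning, not an error.
* Randomness: one seeded stream for the locus; each founder draws from a
  counter-keyed substream, so changing one founder's member count cannot
  shift another founder's draws. Outputs are byte-identical under a fixed
  seed. Founders whose junction collides with an existing same-family,
  same-individual founder are resampled (the analysis's own working
  assumption).

What the generator does **not** emulate, hence what passing tests do not
show about real data: selection (positive or negative) on mutated clones,
PCR/sequencing error, indel mutations beyond rare in-frame insertions,
position-dependent base composition of real V genes, allelic polymorphism
between individuals, and D segments (the emulated locus has none). The
dense WA/TW motif (half of all A/T bases are targets) also means the
default multipliers produce class-marginal G:C and A:T rates that are more
similar than in the real data, so synthetic mutability indices sit near 1.

## Numerical and degenerate-input conventions

* Coordinates are 0-based half-open internally; report tables print
  1-based columns. Percentages print to 2 decimals, per-nucleotide
  frequencies to 4, mutability indices to 2.
* Zero denominators: empty repertoires produce zero-total tables rather
  than errors; 0/0 tandem fractions are 0, not NaN; a zero outside-motif
  frequency reports an infinite enrichment ratio with a warning; MI with
  zero expected is NA. Non-finite values serialize as JSON null.
* Tissue classes: THY vs periphery (PBL, SPV, SPLEEN); unrecognized
  tissues parse as OTHER (warning) and are excluded from the tissue
  comparison. A tissue class with fewer than two contributing groups skips
  its test with a warning.
* Exit codes (CLI): 0 success, 1 invalid configuration or input, 2 no
  clonal group reaching the minimum size (reports still written, empty but
  valid).

## Problem sizes used in the checks

Desk-scale defaults keep the full suite around a minute of CPU: oracle
equivalence suites use 1000 random 200-mers (motifs), all 64×9 single
codon substitutions (effects) and 1000 random instances (tandems);
parameter recovery runs 20 seed-fixed replicates of 50 groups × 5 members;
null calibration runs 200 replicates of 30 groups × 4 members; junction
boundary recovery uses 100 simulated two-individual families. Recovery
bands: per-replicate mutation rate within 15% of 0.02; pooled G:C
enrichment ratio in [3.0, 5.0] for a true multiplier of 4.0 (the pooled
estimate sits near 3.2 — tandem spillover onto non-motif neighbours
dilutes observed/expected targeting, a property of the estimator, not a
bug); transition share within 5 points of the generative 50%.

## Known limitations

* Consensus-referenced counting cannot see mutations fixed in a majority
  of a clone; reported frequencies are lower bounds in that respect.
* CDR3 mutation frequencies are structurally underestimated (grouping
  conditions on junction identity), which is why the hypothesis test
  excludes CDR3 while descriptive tables keep it.
* Junction boundary inference is heuristic; its ±2 nt accuracy holds for
  few-founder, shared-V/J comparisons and degrades as junction diversity
  at shared columns grows.
* The paired (G,C)/(A,T) χ² convention and the single-linkage clustering
  are reverse-engineered/approximate conventions, documented as such.
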
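# Methods

This note documents the models, parameter choices and numerical conventions
behind `felsnp`, and what the synthetic-data generator does and does not
emulate.

## The discovery model

Variant discovery is read-versus-consensus: each aligned read is compared
base by base against a fixed reference, and a discrepancy becomes a
candidate variant only if it passes the Neighborhood Quality Standard (NQS)
and sits in a column whose depth does not exceed a cap. There is no
genotype-likelihood model, no realignment and no base-quality recalibration
— the method is designed for light (few-fold) Sanger coverage, where most
sites are seen in one or two reads and the principal enemy is base-calling
error, not genotyping uncertainty.

### NQS parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `center_min_q` | 23 | PHRED | error probability ≤ 5×10⁻³ at the discrepant base |
| `flank_min_q` | 15 | PHRED | the five bases each side must be trustworthy context |
| `flank_width` | 5 | bases | 11-base neighborhood |
| `min_flank_matches` | 9 | of 10 | tolerates one real flanking polymorphism |
| `max_depth` | 8 | reads | low coverage cap; see below |
| `max_dip_length` | 10 | bases | longer gaps are treated as structural, not DIPs |

The coverage cap value is a package choice, not a reconstruction: the
method's description fixes only that a *low* upper limit is applied. The
default of 8 is ≈ 2.5× the ~2.8-fold mean read redundancy of the study
design, high enough to keep nearly all ordinary columns (P(depth > 8) <
0.5% at mean 3) while discarding collapsed-repeat pileups.

Three rules the NQS description leaves open are resolved as follows and
covered by tests:

- **Gaps.** Any alignment gap intersecting the 11-base neighborhood
  disqualifies the center base. For DIP calling the two bases flanking the
  gap under test are qualified with *that* gap excluded: their neighborhood
  is the nearest five aligned bases on each side, which must come from the
  two alignment runs adjacent to the gap (so a second gap disqualifies).
- **Read ends.** A base whose neighborhood extends past either read end is
  never qualified. This also defines the "NQS bases" denominator of the SNP
  rate: qualified bases are counted per read and summed over reads, so a
  position covered twice contributes twice — rates are per trace base, not
  per genome position.
- **Reference N.** Reference-N columns, and columns within `flank_width` of
  an N-run, are excluded from calling entirely; a reference N never counts
  as a flank match. DIP calling applies the same coverage cap and N
  exclusions at the gap's anchor column, for consistency with the
  coverage-cap rationale.

Merging is alternate-allele-resolved: two different alternate bases at one
position are two sites. Per-cat totals therefore always sum to at least the
non-redundant total.

## The synthetic population

The generator is the package's study-conditions definition, not a tuning
knob. Defaults:

- **Individuals.** Six domestic breed cats (Pixel, Zeelie, Tipper, Scooter,
  Speedy, Cocoa), one wildcat (Nancy), one inbred cat (Cinnamon); Tipper
  and Scooter are male and carry a single X haplotype.
- **Shared polymorphism.** Segregating sites are placed as a Poisson process
  at density `domestic_het_rate / E[2p(1−p)]`, with population frequencies p
  drawn from Beta(0.5, 0.5) discretized to the attainable grid k/16,
  k = 1…15. Each individual draws alleles Bernoulli(p) per haplotype, so
  expected heterozygosity per domestic cat is exactly `domestic_het_rate`
  (default 1/600 per base). The symmetric Beta produces both singletons and
  common alleles, giving the informative-fraction estimator signal.
- **Inbred mosaic.** Cinnamon's genome alternates homozygous and
  heterozygous tracts via a two-state process with geometric tract lengths
  (homozygous mean 500 kb; the heterozygous mean follows from the 0.60
  stationary homozygous fraction). She is forced homozygous-reference
  outside heterozygous tracts and draws ordinary shared-site genotypes
  inside them — which yields exactly 1 SNP/600 bp inside het tracts and
  ~0.4/600 genome-wide with no extra private-site process. Because the
  realized fraction of a desk-scale genome is highly variable (a 10-Mb
  chromosome holds only ~12 tract cycles at these lengths), the mosaic is
  redrawn up to 300 times and the realization closest to the configured
  fraction kept (early stop within 0.025): the genome-wide fraction is a
  defining condition of the emulated genome, not an output.
- **Wildcat divergence.** Nancy participates in the shared polymorphism and
  additionally carries private homozygous-alternate sites at
  `wildcat_extra_rate` (default 1/900 per base, so that 1/600 + 1/900 =
  1/360, the scale of observed wildcat divergence). The observed wildcat
  *discovery* rate also depends on assembly composition, so the simulator
  promises only the ordering wildcat > domestic > inbred, not a specific
  observed rate.
- **DIPs.** Short (1–3 bp) insertion/deletion sites at 0.22× the shared SNP
  site density, the ratio of DIP to SNP totals in the emulated resource.
- **Geometry.** Variant sites keep ≥ 12 bp separation and ≥ 12 bp clearance
  from N-runs and chromosome ends, so no two truth variants share an NQS
  neighborhood. N-gap runs start at 10⁻⁵ per base with geometric mean
  length 500 bp.
- **Reads.** Fosmid paired ends: insert Normal(37 000, CV 0.08) — the model
  rejects CV ≥ 0.10 — read lengths Normal(700, 50) truncated to
  [100, 1000] bp, PHRED profile plateauing at q40 mid-read with logistic
  decay to q10 over ~30 bases at each end (Sanger-typical; no profile is
  prescribed anywhere, so this is a package choice). Substitution errors
  are injected per base at 10^(−q/10) and recorded on the read, so emitted
  reads are exactly reconstructable from reference + truth variants +
  recorded errors (a tested invariant).
- **Coverage.** Per-class defaults scale the study's per-cat read counts to
  a 2.5-Gb genome at 700 bp/read: domestic ~0.085×, wildcat ~0.38×, inbred
  ~2.29× — about 3.2× combined, the total redundancy of the emulated
  study. Tests that need "~3× total, evenly split" pass `coverage = 3/8`.
- **Consensus substitution.** `consensus_from=<name>` re-bases SNPs onto a
  random haplotype mosaic of one individual (swapping reference/alternate
  and flipping genotype codes), emulating an assembly dominated by that
  cat's reads — the mechanism that depresses the deep cat's apparent SNP
  rate. DIP re-basing is not modeled; the donor instead drops DIPs chosen
  for the consensus.

Seeding: one global seed fans out through SHA-256-derived 31-bit child
seeds keyed by stage, chromosome and individual, so adding or removing an
individual never perturbs the others' genomes or reads, and fixed seeds give
byte-identical output files.

### What the generator does not emulate

Chromatograms and trace artifacts, fosmid cloning bias, assembly errors
(reads are aligned to the true reference by construction — there is no
mapper, so calling is tested free of mismapping noise), linkage
disequilibrium along chromosomes (sites are independent), population
substructure among the breeds, and CpG or repeat-context mutation-rate
variation. Passing tests therefore demonstrate the correctness of the
calling/statistics machinery under the stated model, not robustness to
misalignment or to non-uniform genomes.

## Statistics conventions

- **bases-per-SNP** is round-half-up of non-N bases / SNP count, which
  reproduces all 63 published per-chromosome table cells; zero counts give
  an explicit undefined marker (`None` / `NA`).
- **Windows** tile [0, chromosome length) half-open; the final partial
  window is kept as a shorter window; windows with zero non-N bases are
  flagged undetermined and excluded from occupancy denominators unless
  `include_unmapped` is set.
- **Informative fraction** rounds to whole percent *before* extrapolating
  (88% × 964,285 → 849 k to the nearest thousand), matching the published
  arithmetic rather than the unrounded ratio.
- **Validation rates** keep the resource's own two denominator conventions:
  SNP mode drops low-quality amplimers (92/93 = 99%); DIP mode counts every
  record in amplicons including untested ones (43/45 = 96%).
- **Gap distance** for testability is measured from the variant position to
  the nearest N character, with contig termini treated as virtual gaps just
  outside the sequence; the ≥ 750-base bound is inclusive.
- **Panel selection** is one site per spacing window, nearest the window
  midpoint, ties to the smaller coordinate. Selections in adjacent windows
  can therefore be closer than the spacing; on uniformly occupied input the
  mean inter-selection gap is ≈ genome / selections (tested). A greedy
  minimum-distance variant is available via `method="greedy"`.
- **Homozygous-fraction recovery** uses a ratio estimator on 50-kb windows:
  1 − overall density / heterozygous-tract density, the latter taken from
  windows denser than 0.6× the 90th-percentile window density. Unlike
  binary window classification, mixed tract-boundary windows contribute in
  proportion to their heterozygous content, which keeps the bias well
  inside the ±0.05 recovery tolerance at 5-Mb scale. The estimator is
  biased downward when error-driven false positives add a uniform density
  floor (deep coverage with errors enabled); recovery tests use clean
  reads.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 1-Mb shared
fixtures for oracle and property checks, a 5-Mb single-chromosome
population at ~3× combined coverage for parameter recovery, and the default
5-Mb three-chromosome genome for the end-to-end determinism run. Genome-
scale counts (millions of SNPs, 100 k-SNP panels) are not reproduced at
these sizes; the tests instead verify the constructions that produce them
(exact oracle equivalences, zero false positives on clean reads, category
and panel accounting identities).

## Known limitations

- The SNP-rate denominator and the depth definition count only M-aligned
  bases; deletion-spanning reads do not add depth inside the deleted
  interval.
- Multi-allelic DIPs at one anchor are distinct sites; no normalization of
  equivalent indel representations is attempted (unnecessary here because
  simulated alignments are canonical by construction).
- `consensus_from` changes reference bases only at SNP sites; indel
  differences between the donor and the founder are not folded into the
  consensus.
- Validation on synthetic data scores against the truth catalog (an ideal,
  error-free assay); amplimer failure modes are represented only as record
  statuses.
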
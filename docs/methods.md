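# Methods

This note documents the models and procedures implemented in `tedyn`, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the underlying methodology left the design
open.

## Sequence primitives

**Global alignment.** Needleman–Wunsch with affine gaps (match +2, mismatch
−3, gap of length *L* costs 5 + 2*L*), computed by Biopython's C
`PairwiseAligner` behind the module surface. Of co-optimal alignments the
aligner's first traceback is returned, making output deterministic. `N` is
scored 0 against everything. The test suite checks optimality against an
independent hand-written Gotoh DP and, at tiny lengths, against full
alignment-path enumeration.

**Identity and coverage.** Identity = matches / residue–residue columns
(gap columns excluded; `N` never counts as a match). Coverage =
residue–residue columns / length of the **longer** sequence. The "aligned
over 80% of their length" criterion is ambiguous when lengths differ; using
the longer sequence is the conservative reading, and is recorded in report
metadata.

**K2P distance.** Over gap-free, non-`N` columns, with transition
proportion *P* and transversion proportion *Q*:
*K* = −½·ln((1 − 2*P* − *Q*)·√(1 − 2*Q*)). When 1 − 2*P* − *Q* ≤ 0 or
1 − 2*Q* ≤ 0 the distance is undefined and a saturation error is raised —
saturated elements are flagged and excluded from age histograms, never
silently dropped.

**Flank mapping.** BLASTn-style search is re-implemented as exact 13-mer
seeding (binary search over per-sequence sorted k-mer ids) + local
re-alignment of clustered seeds, both strands. Instead of a database-size
dependent E-value, hits require score ≥ 50 and identity ≥ 0.75 — a
deterministic, database-free criterion. Seed clusters need ≥ 3 exact
13-mers before extension: a genuine ≥ 75%-identity hit of a 500-bp query
yields ~12 expected seeds, while isolated random matches cannot reach the
score floor. k-mers occurring more than 50 times are skipped (miniature
repeat masking).

## Structural LTR annotation

The detector looks for the defining structure — two similar terminal
repeats at element-scale separation: k-mer self-matches are grouped by
exact separation *d* (substitution-only divergence preserves *d* exactly;
the detector therefore assumes no large internal indels between the LTRs),
runs of seeds are extended by ungapped X-drop comparison of the two repeat
copies, and candidates must satisfy LTR length 100–3000 bp, element length
1–15 kb and LTR identity ≥ 0.85. A 4–6 bp target-site duplication is
recorded when present, and is optional. Defaults mirror common structural
annotators in spirit; exact parity with any external tool is not claimed.

Filters applied to candidates, each with a recorded rejection reason:

* **non-coding** — no internal domain hit (domain tables are consumed as
  input, e.g. from an HMM scan; `tedyn` does not scan protein profiles);
* **single-hit** — the full element sequence has only one genomic 80/80
  match (itself): removes unreproducible singletons;
* **gap fraction** — > 10% `N` (assembly gaps), computed over the whole
  element (the internal-only alternative was considered; whole-element is
  recorded in output metadata);
* **tandem fraction** — > 50% of positions inside period ≤ 12 tandem runs
  of ≥ 24 bp (an autocorrelation criterion, dependency-free).

Superfamily classification uses the internal domain order on the coding
strand (majority strand of the domain hits; minus-strand hits are mirrored
first): INT before RT ⇒ Copia, RT before INT ⇒ Gypsy, otherwise
unclassified. Elements lacking any of GAG, PR, INT, RT, RH are tagged
`incomplete`. MITE copies are kept when their length is within consensus
± 20% (closed interval).

## Insertion dating

Divergence between the two LTRs of one element accrues on both copies, so
E[*K*] = 2·*r*·*T* and *T* = *K*/(2*r*), with *r* = 10⁻⁸
substitutions·site⁻¹·yr⁻¹ by default. A generation time (default 10 yr) is
carried as metadata only: the rate is per year, so generations do not enter
the formula. Pairs with fewer than 50 compared sites are flagged
`too_short` (the binomial noise floor on *K* at 50 sites is ~14%, making
such ages meaningless). Ages are linear in *K*, so halving *r* exactly
doubles every age.

## Family clustering

Elements from both genomes are compared all-vs-all on their full sequence
(LTRs + internal; the internal-only alternative is noted in the report
metadata). An edge requires identity **>** 0.80 over coverage **>** 0.80
(strict, per "higher than"/"more than"). Families are connected components
(single linkage) — the standard 80/80 family practice; no linkage beyond
the pairwise threshold is assumed. Pairs whose length ratio already
precludes 80% coverage are skipped exactly; a unit-cost edit-distance
screen (edlib) skips pairs estimated below 70% identity, a generous margin
so borderline pairs are still decided by the full affine alignment.
A cluster is *mixed* when it contains elements of both genomes.

## Orthologous-insertion classification

For each full-length element: extract 500-bp flanks (truncated at sequence
ends and flagged; an element touching the end has no locus), map both onto
the other genome, and accept the locus only when both flanks map
**unambiguously** — best hit ≥ 1.2× the runner-up score, identity ≥ 0.75,
coverage ≥ 0.5, at most 5 hits (TE-dense flanks are reported unmapped
rather than forced). Concordance requires same target sequence and strand,
preserved left/right order after strand normalisation, and inner-edge
distance < 25 kb (with 20 bp slop for slightly overlapping flank
alignments). The ambiguity filter reflects that only about half of real
insertions resolve to unique orthologous loci.

Classification of a concordant locus:

* inter-flank span ≤ 100 bp ⇒ **specific** — an empty orthologous site
  carries only the target-site footprint; 100 bp absorbs small indels
  (the methodology gives no number; this is the package's choice, flagged
  in outputs);
* else align the inter-flank region to the element: identity ≥ 0.8 and
  coverage ≥ 0.8 ⇒ **conserved**; otherwise **partially deleted or
  rearranged**.

Per category the report gives counts and the fraction of insertions
younger/older than the speciation time (default 5.88 Mya): specific
insertions are expected mostly younger, conserved mostly older.

## Cohort polymorphism

Deletion calls (consumed from VCF `SVTYPE=DEL` with a `SUPPORT` key, or a
Pindel-like TSV) are filtered to ≥ 20 supporting reads per cultivar and no
overlap with N-regions padded ± 1000 bp. A deletion overlaps a TE when the
overlap covers ≥ 80% of **either** interval (one-way rule, symmetric in its
arguments, inclusive at the boundary). An insertion is polymorphic iff at
least one cohort cultivar has a filtered overlapping deletion; presence is
inferred only from the absence of a deletion call (read-level evidence is
out of scope), an asymmetry stated in the output metadata. Size classes
{1–50, 51–500, 501–10 000, 10 001–50 000} bp are computed over unique
events (exact-span identity across cultivars; a merge slop is configurable,
default 0); larger events are reported separately.

## Structural-variant / TE association

Variants sized 20 bp – 25 kb (inclusive) are kept. Insertion-like variants
(insertion, repeat/tandem expansion) are tested against the TE annotation
of the genome that gained the sequence over that genome's span;
deletion-like variants against the genome that retains it. Coverage is
computed on the **merged** TE footprint — no double counting, and adding
annotation can only flag more variants (monotone). Variants of unknown type
pass through unflagged and are listed in the summary.

## The simulator

The generator emulates the statistical structure the analyses assume:

* an ancestral backbone (i.i.d. bases at GC 0.375) splits into two
  lineages 5.88 Mya apart; each lineage accrues substitutions under an
  **exact per-site K2P process** (transition rate α, transversion rate 2β,
  α/β = κ = 2, total rate *r* = 10⁻⁸) — the dating estimator is therefore
  correctly specified, and dating recovery tests measure estimator noise,
  not model mismatch;
* families carry a random LTR consensus (500 bp) and an internal region
  (2 kb) with GAG–PR–INT–RT–RH domains in Copia or Gypsy order; the domain
  coordinates are emitted as the domain-hit tables;
* insertions are planted with 5-bp target-site duplications at sites with
  guaranteed spacing; fates are: **conserved** (inserted before the split,
  present in both genomes), **specific** (after the split, one genome),
  **partially deleted** (shared, then 40–70% of the element deleted in one
  lineage). LTR copies mutate independently for the element's age, split
  between shared and lineage branches, so the expected inter-LTR distance
  is exactly 2·*r*·*T*. Default fate counts are 50 conserved, 50 + 50
  specific and 25 + 25 partially deleted on a 1.2-Mb backbone;
* cohorts: each insertion draws an allele frequency (default spectrum
  {1.0: 0.7, 0.9: 0.15, 0.5: 0.15}); a cultivar lacking the insertion emits
  a deletion call spanning it with support ~ Poisson(40). Spurious calls
  are planted at random positions with support ~ Poisson(8): caller false
  positives are characteristically low-support events, which is exactly
  what the ≥ 20-read threshold exists to remove — with ~30% of the genome
  in TEs, spurious calls indistinguishable from true ones (same support)
  would make any classifier's accuracy collapse, so distinguishability by
  support is part of the modelled noise;
* N-regions (assembly gaps) are planted midway between insertion sites;
* background small indels (geometric lengths, mean 3 bp) are **off by
  default** so ancestral coordinates stay exactly mappable; a 1% stress
  mode exercises the flank mapper under coordinate drift. Indels are
  restricted to the inter-element backbone, keeping the truth ledger exact.

Everything is drawn from a single seeded RNG stream; identical
configurations are byte-identical. The truth ledger records ages, fates,
families, per-genome coordinates and cohort presence, and a conservation-
of-mass check (final length = ancestral + inserted − deleted ± indels) is
asserted in tests.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: nested/fragmented insertions, solo-LTR formation
by unequal recombination, rate heterogeneity along the genome and CHH/CHG
context effects, segmental duplications, real assembly artefacts beyond N
runs, and read-level evidence (no FASTQ/BAM). Detector recall on real
genomes with nested repeats will be lower than on these clean simulations;
the orthology ambiguity filter will reject more loci in genuinely
repeat-dense flanks.

## Problem sizes and runtime

The bundled validation uses backbones of 0.4–1.2 Mb with 20–200 planted
elements, 10-cultivar cohorts and 100–200 dating replicates — sizes chosen
so the full suite and the acceptance script each run in minutes on one core
while keeping binomial error bars far smaller than every asserted margin.
All thresholds asserted in tests (15% median dating error, 95%/90%
category accuracy, 3σ pattern contrasts) come from the statistical design
of the corresponding experiment, not from observed outcomes.

## Known limitations

* The structural detector assumes substitution-dominated LTR divergence;
  long internal indels between the two LTRs break the exact-separation
  seeding (real annotators handle this with chained seeds).
* Dating ignores gene conversion between LTRs, which biases real ages down;
  nothing in the simulator models it.
* `specific` vs `partially_deleted` is decided by the 100-bp empty-site
  rule; a real locus with a large foreign insertion at the orthologous
  position would be called `partially_deleted_or_rearranged`, which is the
  intended reading of "rearranged".
* Cluster comparison uses full-element sequences; families whose members
  differ mainly by internal deletions may fail the coverage term and split.
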
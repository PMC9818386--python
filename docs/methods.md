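# Methods

## The prioritization model

`famprior` formalizes a family-based dominant-model prioritization of rare
non-coding variants.  The underlying assumptions are:

- **Dominance.** Carrying one alternate allele suffices; "carries" means
  alt-allele count ≥ 1, and hom/het are not distinguished anywhere in the
  funnel.
- **Complete penetrance within a family, by the time of follow-up.** A
  confirmed unaffected member who carries the variant falsifies
  segregation.  Because penetrance is age-dependent, an unaffected member
  more than `age_gap_years` (default 10, strict comparison of
  age-at-last-follow-up against the family's earliest diagnosis age)
  younger than the earliest case cannot be used as evidence and is
  demoted to "possible carrier", as are members with plasma-cell
  anomalies short of a case diagnosis and members with missing ages
  (absence of information never proves non-carriage).
- **Conservative treatment of missingness.** A missing genotype
  (including genotypes masked for read depth ≤ 10) in a case or
  non-carrier fails segregation; `missing_fails=False` switches to
  ignoring such members.
- **Per-family evaluation.** A variant is kept when it segregates in at
  least one family; families are never pooled, matching the family-private
  character of rare variants.

SMM is included in the case set by default (the cohort design enrolls SMM
as an MM precursor) even though narrower case definitions exist; the set
is a config value and the run reports which set was used.

## Thresholds and comparators

| parameter | default | comparator | note |
|---|---|---|---|
| gnomAD exome/genome AF | 0.001 | strict < | "rare" = MAF below 0.1% |
| local carrier fraction | 0.02 | inclusive ≤ | denominator = genotyped cohort samples when no external local set is supplied |
| read depth | > 10 | strict | genotypes at ≤ 10 reads are masked missing |
| CADD PHRED | 15 | inclusive ≥ | ≈ top 1.5% most deleterious |
| GERP | 2 | strict > | conservation composite |
| PhastCons (vertebrate) | 0.3 | inclusive ≥ | both conventions circulate; a `phastcons_strict` switch selects > |
| PhyloP (vertebrate) | 3.0 | inclusive ≥ | |
| context++ percentile | 90 | inclusive ≥ | significant miRNA site |
| mirSVR | −0.1 | strict < | predicted downregulation |
| ChromHMM summary | 20% of profiled lines | inclusive ≥ | states present recurrently |
| histone summary | 20% of profiled lines | strict > | |
| PWM relative score τ | 0.80 | inclusive ≥ | common JASPAR operating point |

The conservation composite is reported on 0–3 (0 is logically possible
even though descriptions of such scores often say "1–3"); every decision
rule only ever uses ≥ thresholds, so the distinction is cosmetic.

## Coordinates and variant footprints

Everything after ingestion is 0-based half-open; VCF positions are
converted at the boundary.  An SNV/MNV at 1-based p spans
[p−1, p−1+len(ref)).  Anchored indels exclude the shared anchor base: a
deletion spans exactly the deleted bases, an insertion is the zero-length
point after the anchor (overlap for insertions is point containment).
This makes promoter and miRNA-site overlap well-defined for indels.
Chromosome names are reconciled by stripping `chr`, never rejected.

## PWM scanning

Position frequency matrices are smoothed with a total pseudocount of 0.8
split by the uniform background (0.2 per base per column), normalized to
probabilities, and converted to log2-odds against background 0.25.  Every
placement on both strands is scored and mapped to the relative scale
(S − Smin)/(Smax − Smin); ties prefer the plus strand and the smaller
offset; windows containing N are unscannable at that offset; a degenerate
matrix with Smax = Smin scores 1.0 by convention.  A site is called at
relative score ≥ τ = 0.80.  For a variant, the alternate window is built
by splicing the alt allele into the ±10 bp reference context (indel
windows change length and are scanned fully); a PWM is **lost** when the
reference window carries a site and the alternate does not, **gained** in
the mirror case.  The scanner is strand-symmetric and ref/alt
anti-symmetric by construction, and both properties are asserted in tests
together with agreement with a brute-force enumerator.

## Shortlist rules

The 3′ rule is fully determined by the evidence layers: conservation
composite ≥ 2 ∧ overlapping miRNA site ∧ mirSVR < −0.1 ∧ gene-end context
(Segway `GE*` and Tx/TxWk among the summarized states).  The gene-end
requirement is a design choice — the evidence could be read as merely
descriptive — so it has its own off switch.

The 5′ rule is this package's crisp formalization of "positive scores on
the selected annotations": promoter ∧ CpG island ∧ conservation ≥ 2 ∧
non-empty recurrent-histone-mark summary, with unknown tri-states failing.
An additional active-chromatin requirement (TssA/TssAFlnk/TssBiv/EnhBiv/
Enh present) exists but is OFF by default: genuinely top promoter variants
can sit in repressed chromatin in the profiled cell-line panel, and
requiring activity would wrongly exclude them.  Every sub-criterion is
independently switchable and every decision records all evaluated flags,
so alternative rules remain auditable.

Context++ ≥ 90 is deliberately **not** part of the 3′ top rule: it is
reported per site, but sites with lower percentiles still count as
binding evidence.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
(scipy's survival function; exact-enumeration agreement to 1e-12 for all
backgrounds M ≤ 30 is part of the acceptance tests) and BH FDR across all
pathways tested (every pathway with K ≥ 1 inside the background is
tested; only pathways with hits are reported, and the report carries the
background size).  The background defaults to the union of the GMT's
genes and should be overridden with an explicit universe file when one is
available — FDR values are only comparable for a fixed, stated test
count.  The query set is the unique gene symbols of all funnel-surviving
variants; a gene with both a 5′ and a 3′ variant counts once.

## Synthetic data: what it emulates and what it does not

The generator plants a complete, self-consistent study: 14 families with
2–4 cases each (diagnosis ages 40–75), unaffected members within ten
years of the earliest diagnosis, one young unaffected member per family
(exercising the possible-carrier age rule), and one variant per plan —
planted 5′ tops (promoter + CpG + conservation ≥ 2 + recurrent histone
marks + a planted PWM whose consensus spans the variant, guaranteeing a
LOST call), planted 3′ tops (miRNA site at percentile 95, mirSVR −0.8,
Segway GE0, Tx-dominated chromatin), and one decoy per class constructed
to fail exactly one stage (AF 0.005; local fraction 0.05; one case at
depth 8; intronic category; one non-carrying case; CADD 12; GERP/PhyloP/
PhastCons all failing; outside the promoter track; no miRNA site; mirSVR
−0.05; repressed gene end).  Local-set frequencies are emitted as an
INFO field emulating a local collection much larger than the cohort —
with ~70 cohort samples a family-private variant already exceeds a 2%
cohort carrier fraction, which is exactly why the filter distinguishes an
external local set from the cohort fraction fallback.  The planted PWM
motif length is 4 so that a single mismatch scores (L−1)/L = 0.75 < τ on
a consensus-only matrix; windows are rejection-sampled so the motif
occurs exactly once in the reference window and never in the alternate.

Not emulated: linkage disequilibrium, recombination, realistic site
spectra, sequencing errors, multi-allelic sites in the cohort VCF, and
any correlation between annotation layers.  Passing the planted-truth
tests therefore demonstrates that the pipeline's logic routes each
evidence type correctly — not that the thresholds are well calibrated
for real WGS data.

All randomness flows from one `numpy` generator seeded by the config;
fixed seed gives byte-identical files (manifest paths are stored relative
to the study directory for this reason).

## Problem sizes used in the checks

The packaged worked example covers the 27 printed shortlist rows.  The
synthetic end-to-end checks run a 14-family cohort with 6 planted tops
and 11 decoy classes (unit tests use a 6-family study).  The segregation
predicate is verified against a brute-force oracle over the full
enumeration of families up to 5 members (3^m status × 3^m genotype-state
assignments), and the hypergeometric kernel against exact rational
enumeration for all (k, n, K, M) with M ≤ 30.

## Known limitations

- The 5′ top rule is one defensible formalization; the decision record
  exposes all flags so other rules can be audited, but only one default
  is shipped.
- The funnel counts and enrichment FDRs of any private cohort depend on
  inputs this package does not compute (caller-supplied scores, local-set
  frequencies, Reactome-scale backgrounds) and are not reproducible from
  the package alone.
- mirSVR is consumed per variant (minimum over supplied values), not per
  miRNA site; 3′ mechanisms beyond miRNA binding (stop-codon
  stabilization, cleavage sites) are out of scope.
- Annotation-only scores (EIGEN, Funseq2, FATHMM, ReMM, DeepSEA) are
  carried as passthrough fields and never used in decisions.
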
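# Methods

## Overview

`repairmut` models and analyses a reporter-episome mutagenesis assay: a
defined DNA lesion (T/G, hmU/G, U/G, ab/G mispair, or a single-strand
break) is carried on one strand of a circular shuttle vector; repair of the
lesion in human cells exposes single-stranded DNA that TpC-preferring
APOBEC cytidine deaminases attack, mutating the flanking reporter. The
package couples a mechanistic stochastic generator of such experiments with
the analysis pipeline that measures them, so that the pipeline's statistics
can be validated exactly against the generator's event log and its
calibrated rates.

## Coordinate and strand conventions

The reference top strand is the FASTA record as given, 5′→3′; the bottom
strand is its reverse complement, with bottom coordinate *j* pairing with
top coordinate *n − 1 − j*. All mutation records are reported in top-strand
readout: a bottom-strand substitution is complemented and remapped. The
episome is circular; all exposure-window arithmetic is modulo the length.
Internally coordinates are 0-based half-open; reports print 1-based
positions.

## The default episome and lesion catalog

The built-in reference (`episome.default_reference`) is a 5,000-bp
synthetic episome that mirrors the assay layout: promoter [100,160), supF
[160,245), mismatch (MM) region [245,298), an 8-bp bar code [306,314)
between the fixed flanks `GAGCTCTA`/`TACGTACG`, and backbone elsewhere.
The MM-region top strand is the assay's 53-bp MM1 duplex and the bar-code
flanks its fixed octamers; the promoter, supF and backbone
spans are deterministic *synthetic stand-ins* drawn once from a fixed RNG —
the analysis depends only on layout and base composition, not on the
biological sequences. The construction rewrites any chance extra occurrence
of a bar-code flank so extraction is unambiguous on the reference.

Top-strand base lesions sit on the two MM-region cytosines of the AatII
site (top coordinates 258 and 261), <50 bp from the cis 3′ end of the
reporter; bottom-strand lesions sit on the guanine partners (256, 259 on
the bottom strand template reading). Because exposure runs 5′ of the
lesion *on the lesion strand*, bottom-strand lesions face the long
(~5 kb) way around the circle to the reporter — reproducing the top/bottom
distance asymmetry without any extra mechanism.

## The generator

One repair event per mutated colony:

1. **Fate / template choice.** For T/G the G strand is chosen as repair
   template with probability `tg_template_choice` (default 0.75 — the
   assay's ~25% conversion); choosing the T strand converts the site to
   T/A. U/G and hmU/G restore with probability 0.99, ab/G with 1.0;
   non-restored base lesions read out as converted. SSB events have no
   base fate.
2. **Exposure.** Mechanism per condition: `ber_mmr` (U/G, hmU/G, ab/G,
   proximal SSB, random nicks) draws a geometric resection length with
   mean `exposure_len_mean` = 300 nt — the simplest memoryless choice
   consistent with a mutagenic reach ≪ 5 kb; `dloop` (T/G) exposes the
   whole episome, matching the distance-insensitive T/G effect; `ssbr`
   (distal SSB) is non-mutagenic at the lesion, and such conditions
   contribute only background random-nick events. The exposed window is
   the resected span's complement, expressed in template-strand
   coordinates.
3. **Deamination.** The per-event deamination count follows
   `cluster_size_pmf` (defaults P(1)=0.73, P(2)=0.17, P(3)=0.07,
   P(4)=0.03, i.e. P(≥2)=0.27, calibrated to the observed 25–30%
   clustered fraction). Deaminations are placed without replacement on
   distinct exposed template cytosines: each draw targets a TpC-context C
   with probability `p_five_prime_T` = 0.8, otherwise a non-TpC C. If the
   window exposed no C of the wanted class at all, any exposed C is used
   (logged); if the class pool was merely exhausted by earlier draws in
   the same event, that deamination is not realized. The alternative —
   always falling back to the other class — preserves the count but
   dilutes the realized TpC preference by ~1.3 percentage points, breaking
   3-SE parameter recovery at n = 10,000; the chosen rule keeps the
   preference exact conditional on availability at the cost of truncating
   a small fraction of multi-deamination events in short windows
   (realized P(≥2) ≈ 0.253 for geometric-window conditions; exact for
   D-loop events, whose pool is the whole episome). Outcomes per
   deaminated C: transition (C→T) with `p_transition` = 0.5, else C→G or
   C→A equally — the A-rule/abasic-bypass split that yields roughly equal
   transitions and transversions.
4. **Clone realization.** The mutant top strand is built by writing the
   lesion fate, mapping each deamination to top-strand readout, and
   installing a fresh random 8-bp bar code. A clone is **white** iff at
   least one substitution falls in promoter+supF — a deliberate
   simplification (no codon-level inactivation model), justified because
   >99% of undeleted white episomes carry a reporter mutation and the
   strong G bias of the spectrum is not an ascertainment artifact.
   Lesion-site base pairs and the bar-code slot are excluded as
   deamination targets (the former are fate, the latter unobservable).
5. **Colony screen.** Per transfection, the number of white-undeleted
   mutated colonies is Binomial(n, rate) with the condition's calibrated
   per-colony rate (T/G top 0.00107, hmU/G top 0.00182, U/G top 0.00726,
   ab/G top 0.0078, T/G bottom 0.0023, no-MM 0.00025; U/G bottom 0.0008,
   SSB near 0.0073, SSB far 0.0004 — the last three chosen to reflect the
   observed orderings where no calibration is available). Each mutated colony's
   event is re-drawn until it yields a white clone, so the realized
   white-undeleted frequency equals the calibrated rate by construction.
   Reporter-deleted white colonies are added so they form `deletion_rate`
   = 3% of whites (the deletion removes the entire supF span), and
   `indel_rate` = 5% of sequenced undeleted clones receive a 1–3 nt
   indel in the reporter.

Randomness: one master seed; each transfection uses an independent
substream derived by CRC-32 hashing of its identifier into a NumPy
`SeedSequence`, so datasets are reproducible and order-independent.

## The analysis pipeline

* **Triage.** Equal-length clones are `ok`; unequal-length clones are
  aligned with edlib, and a clone missing ≥ `deletion_span` = 50 reference
  bases (summed) inside promoter+supF+MM is `deleted`, otherwise
  `small_indel`. Substitutions are only ever called on the equal-length,
  gap-free path; alignment is triage-only. Indel clones are excluded from
  spectra but, like all white-undeleted colonies, still count in the
  mutation frequency.
* **Calling.** One record per mismatch, with 5′/3′ reference contexts;
  bar-code positions are skipped (designed randomness, not mutation);
  lesion positions are flagged `is_lesion_site` and excluded from all
  spectra — they are reported in the fate table instead, which avoids
  double-counting the introduced lesion as an induced mutation.
* **Dedup.** Clones within one transfection sharing bar code *and* the
  full mutation set are siblings of one transformation event and collapse
  to one; the same mutations under different bar codes are independent.
  Unreadable bar codes (mutated or duplicated flanks, ~0.5% of simulated
  clones) are kept without dedup and logged.
* **Fates.** Per lesion position: `restored` (reference base), `converted`
  (T readout on top for top-strand lesions, A for bottom), else `other`
  (expected ≈0; reported for completeness). Summaries pool per
  (lesion type, strand).
* **Spectra and contexts.** Per-base fractions of total induced mutations
  with per-alt-base splits; 12-class identity-and-fate tables per group;
  k=2 contexts per side and G-centred trinucleotides, each paired with the
  composition background of the reporter region (promoter+supF+MM) tallied
  over overlapping windows within each region. Mutations lacking the
  needed neighbor at a cassette edge are excluded from context tallies
  (counts reported).
* **Clusters.** A mutated clone is `clustered` iff it carries ≥2 induced
  mutations *within the sequenced cassette* (promoter+supF+MM; a regions
  filter exposes the whole-clone view). The restriction matters: white
  clones are ascertained by reporter hits, which enriches
  multi-deamination events; counted over the whole 5-kb episome the
  clustered fraction is ~33%, while over the cassette — the span the assay
  actually sequences — it is ~25%, matching the assay's cluster definition. No
  distance threshold is applied (a configurable span exists but defaults
  off).
* **Frequencies.** Percent white-undeleted per total screened; mean ± SEM
  over transfections (SEM is NaN for a single transfection); two-sided
  Fisher exact p by minimum-likelihood summation of hypergeometric
  probabilities in log space (relative tie tolerance 1e-12, underflow-safe
  for colony-scale margins); Bonferroni family = number of lesion-vs-
  control contrasts in the run (configurable).

## Problem sizes and validation

The test suite validates each stage on toy examples with hand-computed
expectations, on property checks (revcomp/readout involutions, fraction
tables summing to 1, Fisher p against an independent log-factorial
enumeration and scipy), and on simulator output, where calling must
reproduce the generator's event log *exactly*. Stochastic recoveries use
10,000 repair events for fate/context parameters and 20 transfections ×
50,000 colonies per condition for frequencies, all at 3-standard-error
tolerances; these sizes keep the whole suite under a minute while making
the 3-SE bands a few relative percent wide.

## What the generator does and does not emulate

It reproduces the assay's observable structure: calibrated per-colony
mutation frequencies, fate ratios, TpC/GpA context bias, strand and
distance asymmetry, cluster sizes, bar codes, deletions and small indels,
and 0 MM random-nick controls. It does **not** model biochemical kinetics,
codon-level supF inactivation, Sanger basecall noise, siRNA knockdowns
(only expressible as scalar rate multipliers), or chromatin/ChIP
observables. Passing tests therefore demonstrate the pipeline's
correctness and the mechanism's internal consistency at the calibrated
rates — not that real data were re-measured.

## Known limitations

* The white/blue call is positional, not functional; spectra conditioned
  on whiteness inherit a mild ascertainment tilt toward the reporter span.
* The printed MM-region G+C contents of the alternative MM duplexes do not
  pin down the span their authors used; composition utilities accept any
  configured span and make no claim of matching those figures.
* Realized multi-deamination counts in very short exposure windows are
  truncated by target availability (see above); quantities sensitive to
  this are measured on D-loop conditions or documented where they are not.
* The bottom-strand and SSB per-colony rates are ordering-faithful
  defaults, not printed values; they are configuration, not claims.
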
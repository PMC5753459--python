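# Methods

## Scope and units

The pipeline operates on single-nucleotide variant alleles only;
multi-allelic VCF records are split per alternate allele and anything
that is not a simple SNV (indels, MNVs, symbolic alleles) is counted
and dropped at ingestion — indel calling on flow-based chemistry is
unreliable enough that it is out of scope by design. Positions are
1-based throughout (VCF convention); BED input is converted at the
boundary. Chromosome names are compared with the `chr` prefix stripped
and case folded, so mixed-dialect inputs interoperate.

Two units appear in the analysis: *calls* (per caller, per sample) and
*loci* (distinct variant alleles pooled across samples and patients).
Concordance, inspection and strategy evaluation all operate on loci;
a per-sample classification precedes a per-locus collapse (below).

## Channel constructions

* **PM subtraction** matches the exact allele (chrom, pos, ref, alt):
  a different alternate allele at the same site in the normal is not
  evidence that the tumor allele is germline. A locus-level mode exists
  for sensitivity analysis. Subtraction deliberately consults only
  *called* normal variants, never normal pileups: an allele the normal
  caller missed leaks through, and catching that failure is the
  matched-normal inspection rule's job, not the subtractor's.
* **MG rescue** includes a MuTect candidate iff it is KEEP, or REJECT
  with a non-empty set of failure reasons wholly contained in the
  rescue flags (default `{nearby_gap_events}`). Subset semantics make
  multiple rescue flags compose predictably. `clustered_read_position`
  is accepted as a flag but off by default: on inspected amplicon data
  that category overlapped poorly with other channels and validated
  poorly.
* **VS filtering** rejects calls with somatic p-value strictly greater
  than 10⁻⁶; a call exactly at the threshold is retained. A missing
  p-value is an error naming the record.

## Annotation exclusions

Population membership (1KG, EVS) is presence/absence with no frequency
threshold — none is warranted for this filter's purpose. The functional
keep-set is {exonic, UTR3, UTR5, stopgain, splicing, ncRNA}; intronic,
intergenic and everything else ("other", e.g. upstream/downstream) is
excluded, since the retained classes are enumerated exhaustively.
Annotation lookup is allele-exact; there is no locus-level fallback
because population membership is allele-specific. Strict mode errors on
an unannotated call; lenient mode retains it with a counter.

## Inspection rules

The classifier replaces visual cues with quantitative proxies; every
threshold is a named parameter:

| parameter | default | meaning |
|---|---|---|
| `window_bp` | 10 | reference context half-width (centred window; one-sided was the open alternative, centred chosen) |
| `min_run` | 6 | homopolymer length that triggers triage |
| `exception_run_min` | 5 | shortest run relevant to slippage and the exception |
| `slippage_proximity_bp` | 2 | max gap between the variant and an alt-base run for the slippage footprint |
| `coupled_window_bp` | 15 | search window for coupled unidirectional calls |
| `heterogeneity_min_distinct` | 3 | distinct bases outside the run for the good-mapping exception |
| `min_alt_per_strand` | 1 | bidirectional-support requirement |
| `af_min` | 0.05 | minimum plausible tumor allele fraction |
| `af_precision_depth` | 200 | depth below which the AF estimate is flagged imprecise |
| `poor_map_max` | 0.5 | max fraction of poorly mapped supporting reads |
| `normal_af_max` | 0.05 | max allele fraction in the matched normal |

Precedence: homopolymer triage first — a run of at least `min_run`
in the window *and* (slippage footprint *or* coupled calls) — unless
the exception applies (longest triggering run no longer than `min_run`,
heterogeneous flanks, bidirectional support, AF ≥ `af_min`); then any
of the four disqualifying rules makes the call bad, with every
triggered reason recorded; otherwise valid. The low-depth note is
advisory only: the AF < 5% rule always applies, and depth below 200 is
annotated rather than used to suppress the rule — suppression would
silently pass unverifiable calls. "High coverage" is not enforced as a
separate validity requirement (no defensible number exists); it
surfaces only through the note. N bases break runs and never count
toward flank heterogeneity.

Classification is per (locus, sample); the per-locus verdict is
valid-if-valid-in-any-sample by default (mirroring review of all
carrying samples in one browser view), with a majority rule available.

## Concordance and inspection sampling

The caller × locus matrix stores each locus's *signature* (the channel
subset that called it). Strategy expressions (`&`, `|`, parentheses,
`any(k)`) are parsed by a small recursive-descent parser and evaluated
with set semantics; `any(k)` selects loci with signature size ≥ k.
The inspection set contains every multi-caller locus
(deterministically) plus at most 50 singleton loci per channel, sampled
uniformly from a named substream of the run seed so selection is
independent of simulation randomness.

## Evaluation

PPV = v/C and sensitivity = v/V with V the union-proxy denominator.
Extrapolation stratifies by full caller signature — the finest
partition consistent with assuming inspected rates transfer — and adds
`round(rate × n_uninspected)` per stratum, rounding half-up at the
stratum level so the v columns stay integers. A stratum with
uninspected loci and no inspected loci cannot arise under the intended
design; if user data produces one, the pooled singleton rate of that
channel (or the overall inspected rate) is substituted with a warning.
The standard error is the binomial √(p(1−p)/n), reported only when
n·min(p, 1−p) ≥ 5 with *n* the examined count — extrapolated counts
contribute no precision. Sensitivity SEs use the total inspected count
of the evaluation universe. Display rounding of the results table uses
the builtin (IEEE half-even) float rounding, the convention of the
pandas-style tabulation stack these tables target.

The evaluation surface is a model/results pair:
`StrategyPerformanceModel(matrix, valid_by_locus, inspected,
strategies).fit()` returns a results object with per-strategy
estimates, SEs, the extrapolation decomposition and a `summary()`
table; `strategy_row_from_counts` performs the same arithmetic when
the counts come from an external inspection campaign instead of the
built-in classifier.

## Synthetic studies

The generator emulates a deep targeted panel experiment end to end and
labels everything:

* **Reference**: 20 regions × 5 kb by default (a scaled-down target
  space; the full-size panel would be ~1 Mb), background sequence kept
  free of runs ≥ 4 so homopolymer structure is entirely planted: ~3
  runs/kb, lengths 4–9, flanked by mismatching bases so runs are
  maximal.
* **Study design**: 4 patients, 7 tumor samples (whole section plus
  core biopsies) and one matched normal each; 75 somatic variants per
  patient (300 total), allele fractions Beta(2,5) — the left-skewed
  spectrum produced by tumor heterogeneity and purity dilution; read
  depth negative binomial with mean 1400 (shape 8). Each variant is
  carried by each tumor sample with probability 0.8 (at least one
  forced).
* **Error mechanisms**: slippage artifacts placed 0–2 bp outside a
  planted run of ≥ 6 bases with alt equal to the run base and
  unidirectional support; strand-biased artifacts with every
  supporting read on one strand; low-AF noise with true AF in
  (0.005, 0.035); germline variants at AF ≈ 0.5, of which 40% leak
  (the normal-channel call is missed so subtraction fails); 25% of
  artifacts additionally get degraded mapping-quality fractions.
  Half the germline records are flagged as population-database members;
  20% of somatic and 30% of artifact loci are annotated
  intronic/intergenic so the annotation filters have work to do.
* **Caller profiles**: per-channel sensitivity (IR 0.80, PM 0.90,
  MG 0.60 with 30% rescuable and 10% unrescuable rejections, VS 0.92)
  and per-mechanism false-positive rates per Mb. IR and PM are
  TVC-linked: they share one latent uniform per artifact locus, so
  equal marginal rates give identical artifact sets — the mechanism
  behind their elevated pairwise concordance. VS attaches somatic
  p-values straddling 10⁻⁶ for artifacts (half retained by default)
  and well below it for true calls. Artifact rates are calibration
  knobs with no measured real-data counterpart; they were fixed once
  so that every mechanism exercises every downstream rule.

All randomness flows from one seed through named substreams per stage
(`reference`, `truth`, `evidence`, `calls`, `annotations`,
`inspection-set`), so stages regenerate independently and every output
is byte-reproducible.

What the generator does *not* model: read-level data (no FASTQ/BAM),
sequencing chemistry, FFPE damage, copy-number-driven AF distortion,
shared loci between patients, or correlation between caller detection
and allele fraction. Passing tests therefore demonstrate that the
pipeline's bookkeeping, rules and estimators behave as specified under
a faithful statistical caricature of the platform — not that the
inspection proxies reproduce human verdicts on real alignments.

## Expected-performance arithmetic

`expected_channel_performance` computes, from a configuration alone,
the PPV and sensitivity the pipeline should recover: expected valid
calls integrate the Beta AF prior against binomial read sampling around
the 5% validity threshold across carried samples; expected call counts
add per-mechanism artifact calls surviving the annotation (and VS
p-value) filters; the sensitivity denominator is the union proxy
1 − ∏(1 − s_c) over effective channel sensitivities. Recovery tests
compare pipeline estimates to these values at the 95% binomial
interval.

## Numerical and degenerate-input choices

Zero called loci make PPV undefined (error), zero valid loci make
sensitivity undefined (error). Empty call tables classify to empty
label tables. Duplicate channel names, unknown judgement tokens,
unparseable strategy expressions (with position), missing reference
context, and patient-mixed subtraction inputs all fail fast with typed
errors. Extrapolation rounding is half-up at the stratum level;
`round_half_up` is also used for percentage headlines. The VCF writer
emits no timestamps, keeping fixture and pipeline outputs
byte-identical across reruns.

## Known limitations

The slippage and poor-mapping criteria are inherently visual; the
proxies here are stated decisions, and no claim is made that they
reproduce expert judgements on real data. The sensitivity denominator
is a discovered-variant proxy, so reported sensitivities are upper
bounds relative to truly existing mutations. Per-caller extrapolated
valid counts depend on per-stratum inspected tallies; with few
inspected singletons the extrapolation is coarse (integer rounding at
stratum level). Specificity and NPV are not computed — the negative
domain of a targeted panel is unknown.
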
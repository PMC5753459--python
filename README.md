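# ionsom

Ensemble somatic SNV calling, artifact triage and strategy evaluation
for Ion Torrent-style deep targeted sequencing.

## The problem

Deep amplicon sequencing on flow-based platforms (Ion Torrent) is widely
used to survey somatic point mutations in tumor panels, but its error
profile — homopolymer length misestimation, alignment slippage at
amplicon boundaries, strand-biased artifacts — makes single-caller
output unreliable. A practical way to obtain high-confidence somatic
SNVs is to run several callers, filter the candidates, review the
survivors against the read evidence, and pick a caller-combination
strategy whose positive predictive value (PPV) and sensitivity suit the
study. `ionsom` implements that workflow end to end for four caller
channels:

* **IR** — Ion Reporter tumor–normal calls, ingested as-is;
* **PM** — the "Poor Man's" somatic detector: exact-allele subtraction
  of the matched normal's Torrent Variant Caller VCF from the tumor's;
* **MG** — MuTect with a rescue pass over its call-stats file:
  candidates rejected *only* for `nearby_gap_events` are recovered
  (gaps are implicit in amplicon data);
* **VS** — VarScan2 somatic calls kept only when the somatic p-value
  is at most 10⁻⁶.

Candidates present in the 1000 Genomes Project or the Exome Variant
Server are excluded, as are intronic/intergenic calls. The remaining
candidates are triaged by quantitative analogues of expert visual
inspection into **valid**, **bad** or **homopolymer**, with reason
codes (no bidirectional support; allele fraction < 5%; poorly mapped
supporting reads; > 5% in the matched normal; homopolymer slippage or
coupled unidirectional calls near a run of ≥ 6 bases).

## The evaluation model

For a strategy with called-locus set of size *C* containing *v* valid
loci, PPV = *v*/*C*. Sensitivity = *v*/*V*, where *V* is a proxy for
the true number of valid variants: the valid loci discovered by any
channel, extrapolated to uninspected loci by assuming the validity
rates observed among inspected loci hold in the uninspected ones
(stratified by caller signature). The binomial standard error
√(p(1−p)/n) is reported only when n·min(p, 1−p) ≥ 5, with *n* the
number of loci actually examined; otherwise `NA`. Strategies are
written in a small expression language over channel names:
`IR & PM`, `IR | PM`, `(IR | PM) & (MG | VS)`, `any(k)`.

Because no sequencing data is bundled, a first-class synthetic-data
module generates fully labelled studies — reference panel with
homopolymer runs, planted somatic variants with Beta(2,5) allele
fractions, artifact loci per mechanism, germline leakage, per-caller
sensitivity and false-positive profiles with shared TVC artifact draws
for IR and PM — so the whole pipeline can be exercised against known
ground truth.

## Worked example

```python
from ionsom import SimulationConfig, PipelineConfig, write_fixture, run_pipeline

write_fixture("study", SimulationConfig(seed=7))          # synthetic fixture
run = run_pipeline(PipelineConfig(fixture_dir="study",
                                  output_dir="study/out", seed=7))
print(run.results.to_frame())
```

prints (excerpt):

```
   name   C   v extrapolated  PPV PPV_SE  n_inspected  Sensitivity Sens_SE
     IR 209 175              0.84  0.026          209         0.75   0.024
     MG 147 128              0.87  0.028          147         0.55   0.028
     PM 264 211              0.80  0.025          264         0.90   0.017
     VS 263 217              0.83  0.023          263         0.93   0.015
IR & PM 189 155              0.82  0.028          189         0.66   0.027
 any(2) 283 232              0.82  0.023          283         0.99      NA
 any(3) 197 183              0.93  0.018          197         0.78   0.023
```

Reading the IR row: of 209 loci the IR channel called (after
annotation filtering), 175 were judged valid by the inspection rules,
a PPV of 0.84 ± 0.026; those 175 are 75% of the 234 valid loci found
by any channel (the *V* proxy). Requiring three concordant callers
(`any(3)`) raises PPV to 0.93 at the cost of sensitivity (0.78). The
`any(2)` sensitivity SE is `NA` because 283·min(0.99, 0.01) < 5.

The same run is available from the shell:

```sh
ionsom simulate --seed 7 --out study
ionsom run-all --config study.yaml        # or: --seed / --out overrides
```

plus per-stage subcommands (`call-pm`, `rescue-mg`, `filter-vs`,
`filter-annot`, `concord`, `classify`, `igv-batch`, `evaluate`) that
read and write plain TSV/VCF, and an IGV batch-script emitter for
blinded manual review.

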
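# circmir

Circulating small-RNA biomarker analysis for chemotherapy-treated breast
cancer: small-RNA read annotation and counting, count filtering and quantile
normalisation, negative-binomial differential abundance with FDR control, and
a leave-one-out cross-validated logistic miR-375/miR-122 relapse signature
with confusion-matrix and odds-ratio evaluation.

## The problem

Circulating miRNAs are stable in serum and can be profiled from a blood draw
taken before treatment, making them attractive minimally invasive markers of
chemotherapy response and metastatic relapse. A deep-sequencing study of this
kind produces, per patient, millions of small-RNA reads that must be
annotated by class (miRNA, tRNA, rRNA, scRNA, snRNA, snoRNA, ...), counted per
mature miRNA, normalised across unequal library depths, tested for
association with clinical covariates (relapse, pathologic complete response,
ER/PR/HER2 status, inflammatory disease, chemotherapy regimen), and finally
distilled into a small qPCR-portable signature whose diagnostic performance
can be cross-validated and then checked in an independent cohort.

`circmir` implements that workflow end to end as a library, together with a
synthetic-data generator that emulates the study conditions (42 patients, 11
relapses, serum read-class mixture, planted marker effects), so every stage
is exercised and tested without access to patient data.

## The statistics at the core

**Counts.** miRNA counts are modelled negative-binomial with a single common
dispersion φ: `Var(Y) = μ + φμ²`. φ is estimated by maximising the
conditional NB log-likelihood summed over genes on depth-equalised counts.

**Exact two-group test.** After scaling samples to the geometric-mean depth,
the two group sums are NB with sizes `n_g/φ`. Conditioning on their total,
the two-sided p-value is twice the smaller tail of the conditional
distribution (observed point included), capped at 1. As φ → 0 this reduces to
the conditional binomial test.

**Adjusted test.** The "multivariate" variant fits an NB log-linear model
(IRLS at fixed φ, log-library-size offsets) with the chemotherapy regimen as
an unordered factor and tests the group coefficient by a likelihood-ratio
χ²(1). Multiplicity is controlled by Benjamini–Hochberg step-up FDR.

**Signature.** A logistic regression on the log2 levels of miR-375 and/or
miR-122 (miR-16-normalised PCR levels, or normalised sequencing counts). The
probability cutoff is chosen to minimise the training misclassification
count; a sample is called "relapsed" when its predicted probability exceeds
the cutoff. Performance is evaluated by leave-one-out cross-validation
(model and cutoff refitted per fold) and reported as a 2×2 confusion table
with sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`, and the odds ratio
`(tp·tn)/(fn·fp)` with a Woolf 95% CI, which for a binary predictor equals
the unconditional-logistic-regression OR.

## Worked example

`examples/04_relapse_signature_loocv.py` simulates the cohort, normalises
counts, and cross-validates the three classifiers:

```
miR-375 alone        tp= 9 fn= 2 fp= 2 tn=29  sens  82%  spec  94%  OR 65.2
miR-122 alone        tp= 7 fn= 4 fp= 3 tn=28  sens  64%  spec  90%  OR 16.3
two-gene signature   tp=10 fn= 1 fp= 0 tn=31  sens  91%  spec 100%  OR 441.0
```

Each row is a 2×2 confusion table of predicted vs observed metastatic
relapse under LOOCV; the two-gene signature calls 10 of 11 true relapses
with no false positives on this seed, dominating either gene alone — the
qualitative pattern the signature is designed to show. The other example
scripts cover annotation composition (`01`), filtering/normalisation/
clustering (`02`), differential abundance (`03`, the planted miR-375 and
miR-122 emerge at FDR < 0.1 and no other gene does), and cross-platform PCR
validation (`05`).

A thin CLI wraps the same stages:

```
circmir simulate --seed 1 --outdir sim
circmir annotate sim/reads.fastq --reference sim/reference.fasta
circmir diff sim/counts.tsv --metadata sim/metadata.tsv --contrast relapse
circmir run-all --seed 1 --outdir run
```

## Layout

- `src/circmir/synth.py` — reference, read, cohort and mock-qPCR generators
- `src/circmir/annotate.py` — size selection, class assignment, counting
- `src/circmir/preprocess.py` — filters, quantile normalisation, ranking, clustering
- `src/circmir/diffabund.py` — NB exact test, NB-GLM LRT, dispersion, BH FDR
- `src/circmir/signature.py` — logistic signature, cutoff search, LOOCV
- `src/circmir/valstats.py` — confusion metrics, odds ratios, ΔCt, t-tests, correlations
- `src/circmir/io.py`, `pipeline.py`, `cli.py` — formats, the end-to-end run, the CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
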
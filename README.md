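# hlatag

Carrier inference for pharmacogenomically critical HLA alleles from
surrogate TaqMan assays, with full diagnostic-accuracy validation against
reference HLA typing.

## The problem

Four HLA class I alleles gate common drug-safety decisions: **HLA-A\*31:01**
and **HLA-B\*15:02** (carbamazepine/phenytoin severe skin reactions),
**HLA-B\*57:01** (abacavir hypersensitivity) and **HLA-B\*58:01**
(allopurinol SCAR risk).  Gold-standard HLA typing (NGS, PCR-SSOP, Luminex)
does not fit on the inexpensive multi-SNV TaqMan/OpenArray platforms that
clinical pharmacogenetics labs use for everything else.  The workaround is
*tag SNVs*: single-nucleotide variants in strong linkage disequilibrium with
the HLA allele, genotyped on the standard platform and used to infer
carriage — plus, where no reliable tag SNV exists (B\*58:01 in European
populations), allele-specific amplification assays read out against a
ß-Globin internal control like an ordinary two-cluster genotyping assay.

`hlatag` is for labs and method developers who need to (a) turn raw panel
output (genotype calls, or endpoint fluorescence) into per-sample carrier
verdicts under explicit combination rules, and (b) quantify how well those
verdicts agree with reference typing.

## What it computes

Each sample's verdict for target allele *T* is a three-valued Boolean
combination of marker states (positive / negative / indeterminate).  A tag
SNV is positive when ≥1 copy of its configured tag allele is present; rules
combine markers as SINGLE, ANY (≥1 positive) or ALL (conjunction — used for
A\*31:01, where either SNV alone over-calls but their conjunction removes
the false positives).

Validation against reference typing partitions determinate verdicts into a
2×2 table (indeterminates are excluded and counted separately) and reports

    sensitivity = TP/(TP+FN)   specificity = TN/(TN+FP)
    PPV = TP/(TP+FP)           NPV = TN/(TN+FN)

with 95% CIs: exact Clopper–Pearson (beta quantiles; the x = n lower bound
is (α/2)^(1/n)) for sensitivity/specificity, and adjusted-logit intervals
(normal interval on log((x+½)/(n−x+½)), back-transformed) for the
predictive values, falling back to Clopper–Pearson at degenerate estimates.
The CI method used is always recorded per interval.  Marker zygosity is
additionally cross-tabulated against reference allele copy number — tag
SNVs identify carriers but do not reliably count alleles, so any copy
prediction is flagged non-clinical.

The package also includes a deterministic allelic-discrimination cluster
caller for endpoint (FAM, VIC) fluorescence, and a synthetic-cohort
generator (Hardy–Weinberg copy numbers, per-marker tagging
sensitivity/specificity, zygosity discordance, indeterminate injection,
Gaussian fluorescence clouds) so every pipeline stage is testable without
patient data.

## Worked example

Build a 125-sample cohort in which two A\*31:01 tag SNVs over-call on
disjoint non-carrier subsets (5 and 6 samples), then validate both single
markers and their conjunction:

```python
from hlatag import CarrierValidation, crossed_two_marker_fixture

refs, calls = crossed_two_marker_fixture(
    22, 5, 6, 92, "A*31:01", "ANKCPPX", "C__33415939_10"
)
results = CarrierValidation(calls, refs).fit()
print(results.summary())
```

```
Carrier-inference panel validation
==================================
Samples with calls: 125    Reference typings: 125    Confidence level: 95%

A*31:01 vs rs1061235+rs17179220 (ALL)
  TP 22  FP 0  FN 0  TN 103
  Sensitivity   100.0%  (84.6% to 100.0%, clopper_pearson)
  Specificity   100.0%  (96.5% to 100.0%, clopper_pearson)
  PPV           100.0%  (84.6% to 100.0%, clopper_pearson)
  NPV           100.0%  (96.5% to 100.0%, clopper_pearson)

A*31:01 vs rs1061235 (SINGLE)
  TP 22  FP 5  FN 0  TN 98
  Sensitivity   100.0%  (84.6% to 100.0%, clopper_pearson)
  Specificity    95.1%  (89.0% to 98.4%, clopper_pearson)
  PPV            81.5%  (61.7% to 91.2%, adjusted_logit)
  NPV           100.0%  (96.3% to 100.0%, clopper_pearson)

A*31:01 vs rs17179220 (SINGLE)
  TP 22  FP 6  FN 0  TN 97
  Sensitivity   100.0%  (84.6% to 100.0%, clopper_pearson)
  Specificity    94.2%  (87.8% to 97.8%, clopper_pearson)
  PPV            78.6%  (59.1% to 89.2%, adjusted_logit)
  NPV           100.0%  (96.3% to 100.0%, clopper_pearson)
```

Reading it: each tag SNV alone finds every true carrier (sensitivity 100%)
but its positive verdicts are only ~80% reliable (PPV); requiring *both*
SNVs removes all 11 false positives without losing a carrier, lifting PPV
to 100% with an exact lower bound of 84.6%.

The same objects accept real data: `CarrierValidation.from_files("calls.tsv",
"reference.tsv")` (or a VCF with `calls_format="vcf"`), and the `hlatag`
CLI wraps the library (`hlatag validate`, `hlatag simulate`,
`hlatag call-clusters`).

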
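# ddxbench

Benchmarking framework for ranked differential-diagnosis outputs — from
symptom-checker apps, clinicians, or simulated raters — against
gold-standard clinical vignettes.

Accuracy studies of medical self-diagnostic tools follow a standard design:
a suite of peer-reviewed clinical vignettes (each with an adjudicated main
diagnosis and a ranked differential) is run through every rater, and each
session's ordered disease list is scored against the gold list. `ddxbench`
implements that whole pipeline for people running or replicating such
studies: the vignette schema and supermajority standardization workflow,
disease-name match adjudication, the seven-metric accuracy suite, the
session-failure taxonomy with its three evaluation regimes, group
comparison statistics, and a synthetic-data generator with known ground
truth for end-to-end validation.

## The metrics

For a vignette with gold ranked list $g_1, \dots, g_n$ ($g_1$ the main
diagnosis) and a rater's differential $d_1, \dots, d_m$:

- **M1 / M3 / M5** — indicator that the main diagnosis is matched within
  the top 1 / 3 / 5 positions of the differential; reported as the
  percentage of vignettes satisfying it.
- **Recall** — fraction of the $n$ gold diseases matched by at least one
  differential entry.
- **Precision** — fraction of the $m$ differential entries that match a
  gold disease (each gold disease grants at most one credit).
- **F1** — harmonic mean $2RP/(R+P)$ of the *aggregate* average recall and
  precision.
- **NDCG** — $\mathrm{DCG}/\mathrm{DCG}_{gold}$ with graded relevance
  $n-i+1$ for the disease at gold position $i$ and discount
  $\log_2(\text{rank}+1)$; a 2-disease gold list carries relevancies 2
  and 1. NDCG is 1 exactly when the matched prefix realizes the gold
  ordering.

A predicted disease *matches* a gold disease when it is the same disease
after normalization, a listed alternative name, an umbrella term that
subsumes it, or a directly related disease (one hop, via a user-supplied
lexicon).

Sessions that fail — chief complaint not searchable, age refused, crash,
or no differential produced — are tallied in a failure table, and raters
are compared under three regimes: **all** vignettes (failures score zero),
**succeeded** only (blocked/crashed sessions leave the denominator), and
the **intersection** of vignettes every compared rater completed with a
differential.

## Worked example

```python
from ddxbench import (DiseaseLexicon, Vignette, aggregate_rater,
                      gold_ranked_list, score_vignette, summaries_frame)

lex = DiseaseLexicon.from_dict({
    "myocardial infarction": {"synonyms": ["heart attack"]},
    "acute coronary syndrome": {"umbrella_of": ["myocardial infarction"]},
})
v = Vignette(id="v1", age=58, sex="male", chief_complaints=["chest pain"],
             body_system="cardiovascular", commonness="common",
             gold_main="myocardial infarction",
             gold_differential=["unstable angina", "pericarditis"])

ddx = ["heart attack", "pulmonary embolism", "pericarditis"]
m = score_vignette(v.id, ddx, gold_ranked_list(v), lex)
print(m)
print(summaries_frame([aggregate_rater([m], rater_id="demo")]).to_string(index=False))
```

```
VignetteMetrics(vignette_id='v1', m1=1, m3=1, m5=1, recall=0.6666666666666666,
                precision=0.6666666666666666, ndcg=0.7350069851388743)
rater_id  n_vignettes  m1_pct  m3_pct  m5_pct  avg_recall_pct  avg_precision_pct  f1_pct  avg_ndcg_pct
    demo            1   100.0   100.0   100.0            66.7               66.7    66.7          73.5
```

"heart attack" resolves to the gold main diagnosis through the synonym
table, so M1 = 1. Two of the three gold diseases are matched (recall 2/3)
and two of the three predictions are credited (precision 2/3). The matched
diseases sit at ranks 1 and 3 while the gold list wants relevancies 3, 2, 1
at ranks 1, 2, 3, so NDCG = (3/log₂2 + 1/log₂4) / (3/log₂2 + 2/log₂3 +
1/log₂4) ≈ 0.735.

A thin CLI mirrors the library: `ddxbench validate|standardize|composition|
score|compare|simulate` (see `ddxbench --help`).

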
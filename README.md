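# anchorcut

Group standard setting for examinations from **clear-pass / clear-fail
anchors**: a cut-score with a statistical confidence attached, instead of a
bare pass mark.

## The problem

Deciding the score that separates passing from failing examinees (the
cut-score) is one of the most contested steps in criterion-referenced
assessment.  The classic Angoff procedure asks a panel of judges to
estimate, for every item, the proportion of *minimally competent*
examinees who would answer correctly — a vague, cognitively demanding
construct.  `anchorcut` implements an alternative in which each judge
answers two concrete questions about the examination as a whole, on the
percent scale:

* **L** — the *highest* score that still indicates the examinee is clearly
  incompetent (clear-fail anchor), and
* **H** — the *lowest* score that indicates the examinee is clearly
  competent (clear-pass anchor).

## The method

From the panel of *n* judges, compute the anchor means X̄_L, X̄_H and the
standard errors SE_L = SD_L/√n, SE_H = SD_H/√n.  The cut-score sits at the
interface of the two anchor sampling distributions — the same number *Z*
of standard errors above X̄_L as below X̄_H:

    Z·SE_L + Z·SE_H = X̄_H − X̄_L   ⟹   Z = (X̄_H − X̄_L) / (SE_L + SE_H)

    CS = X̄_L + Z·SE_L = X̄_H − Z·SE_H

Attached to the cut-score are:

* **confidence** = 2·Φ(Z) − 1, the normal mass separating the two anchor
  distributions (68% / 95% / 99.7% at Z = 1 / 2 / 3);
* the **one-tailed p** = 1 − Φ(Z);
* a **95% CI**, applicable while |Z| < 1.96: lower bound X̄_H − 1.96·SE_H
  (the lowest score the panel would accept as a clear pass), upper bound
  X̄_L + 1.96·SE_L (the highest score still compatible with a clear fail).

Because the two anchor variances are independent, the CI midpoint
generally differs from the cut-score, and unequal SEs pull the cut-score
away from the plain (X̄_L + X̄_H)/2 midpoint toward the anchor the judges
agree on more closely — an inherent moderating mechanism against extreme
judges.

The package also provides the classic Angoff grand-mean baseline, the mean
of directly suggested cut-scores, robustness remedies (symmetric trimming
of extreme judges, bootstrap SEs, normality diagnostics), and a seeded
judge-panel simulator with an analytic population oracle for property
studies such as confidence versus panel size.

## Worked example

A 17-judge panel with anchor means 62.65 (L) and 65.35 (H) and standard
errors 5.609 and 3.193 (`pilot.csv` holds one judge per row,
`judge_id,L,H[,suggested]`):

```sh
anchorcut cutscore pilot.csv
```

prints (baseline and provenance footer omitted):

```
Cut-score report — pilot.csv
========================================
Judges (n):            17
Clear fail  L: mean 62.65  SD 23.13  SE 5.609
Clear pass  H: mean 65.35  SD 13.17  SE 3.193
SE method:             analytic
Z:                     0.307
Cut-score (from L):    64.37
Cut-score (from H):    64.37
Cut-score:             64.37
Confidence:            24.1%
One-tailed p:          0.38
95% CI:                59.09 – 73.64
95% CI midpoint:       66.37
Anchor midpoint (L,H): 64.00
Suggested cut (mean):  60.47
```

Reading: the anchors are 0.307 joint standard errors apart, so the
cut-score 64.37 (identical from either anchor) carries a modest 24.1%
confidence — the judges' clear-pass and clear-fail thresholds are close,
which is itself a sign the examination discriminates well.  The 95% CI
says any score below 59.09 is a defensible fail and any score above 73.64
a defensible pass.  Note the cut-score differs from both the CI midpoint
(66.37) and the judges' directly suggested mean (60.47): the method
weights each anchor by the panel's agreement about it.

The same computation in Python:

```python
from anchorcut import read_panel_csv, summarize_panel, compute_cut_score

result = compute_cut_score(summarize_panel(read_panel_csv("pilot.csv")))
print(round(result.z, 3), round(result.cut_score, 2))   # 0.307 64.37
```

Other subcommands: `baseline-angoff`, `baseline-suggested`, `simulate`,
and `study-confidence` (confidence vs panel size tables); see
`anchorcut --help`.

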
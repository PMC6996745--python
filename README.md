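# emamotives

Why do people eat what they eat — and do their *beliefs* about their eating
motives match their motives *in the moment*?  Classic questionnaires such as
The Eating Motivation Survey (TEMS) measure eating motives as dispositions
(traits): one rating per motive, "why I usually eat what I eat".  Smartphone
diaries (ecological momentary assessment, EMA) instead capture the same 15
motives at each eating occasion (states).  `emamotives` is a small Python
library for comparing the two: it simulates or ingests trait + event tables,
aggregates events to person-level state profiles, quantifies trait–state
profile similarity, tests each motive for systematic overestimation, and
renders the person × motive data matrix that makes the individual differences
visible.

It is aimed at researchers working with intensive longitudinal Likert-scale
data who want a reproducible, scriptable version of the profile-similarity
workflow.

## The statistics at its core

A *profile* is the vector of 15 motive ratings x = (x₁, …, x₁₅).  For a trait
profile x and a state profile y (a participant's state ratings averaged over
all their eating occasions), similarity is decomposed into four indices:

- **Overall fit — double-entry intraclass correlation.**  With m the grand
  mean of all 2k values,

  ICC_de = Σᵢ (xᵢ−m)(yᵢ−m) / ( [Σᵢ (xᵢ−m)² + Σᵢ (yᵢ−m)²] / 2 ),

  equivalently the Pearson correlation over the doubled pairing
  {(xᵢ,yᵢ)} ∪ {(yᵢ,xᵢ)}.  It penalises disagreement in shape, scatter and
  elevation simultaneously; ICC_de² is the fraction of state-profile variance
  explained by the trait profile.
- **Shape — Pearson r** between x and y: do the same motives rank high?
- **Scatter — Var_D** = s²(x) − s²(y): is the spread across motives comparable?
- **Elevation — M_D** = x̄ − ȳ: positive values mean the questionnaire
  *overestimates* how strongly motives operate in the moment.

At the between-motive level, each motive gets a paired t test of trait vs.
mean state rating across participants, a Cohen's d standardized by the
average of the two between-person SDs (d_av), and the between-person
trait–state correlation.

## Worked example

```python
from emamotives import ProfilePair, similarity_profile

trait = (3.6, 3.4, 3.5, 2.9, 2.8, 3.0, 2.4, 2.5, 2.2, 2.0, 1.8, 1.9, 1.6, 1.5, 1.3)
state = (3.2, 2.9, 2.8, 2.5, 2.7, 2.6, 1.9, 2.0, 1.7, 1.5, 1.7, 1.4, 1.2, 1.1, 1.1)
s = similarity_profile(ProfilePair(trait, state))
```

prints (see `examples/02_profile_similarity.py`):

```
ICC_de  = +0.824   (overall fit; 68% of state variance explained)
shape r = +0.977   (rank-order agreement of the 15 motives)
Var_D   = +0.060   (trait variance minus state variance)
M_D     = +0.407   (trait mean minus state mean: positive = overestimation)
```

The motive *ordering* agrees almost perfectly (r ≈ 0.98) while every motive is
inflated by ~0.4 points on the 1–4 scale — the canonical signature of a trait
questionnaire that overestimates in-the-moment motives.  Running the full
pipeline on a simulated 35-participant cohort
(`examples/03_motive_comparisons.py`) flags 12 of 15 motives as significantly
overestimated (p < .05, paired t), with the three unbiased motives —
convenience, visual appeal, social image — correctly spared.

The other examples show cohort simulation + CSV round-tripping (`01`) and the
SVG person × motive matrix (`04`).  The same pipeline is scriptable from the
shell:

```bash
emamotives simulate --out-dir data --seed 1
emamotives report --traits data/traits.csv --events data/events.csv --out-dir results
```

## Layout

- `src/emamotives/` — `data` (types + CSV I/O), `simulate` (seeded generator),
  `aggregate` (event → person), `similarity` (the four indices),
  `stats` (per-motive tests), `viz` (SVG matrix), `pipeline`, `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
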
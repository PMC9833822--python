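# vocaldyad

Event-locked analysis of autonomic arousal and vocalisation timing in
caregiver–infant dyads.

## The problem

In day-long naturalistic home recordings, infants and caregivers wear
autonomic sensors (ECG, actigraphy) and duty-cycled microphones (a 5 s audio
snapshot every 60 s, i.e. 8% of each minute). The scientific questions are
how tightly each partner's vocalising is tied to autonomic arousal — their
own and their partner's — and how cries versus speech-like vocalisations
(protophones) reshape arousal, arousal stability and interpersonal arousal
coupling across the dyad. `vocaldyad` is for researchers analysing such
epoch-level dyadic physiology + vocal-event data, and for validating the
analysis chain end-to-end on synthetic data with known ground truth.

## The method

All analyses operate on a shared grid of 60 s epochs. Per participant, a
composite arousal index is built from heart rate, heart-rate variability
(sign-flipped) and movement: each channel is z-scored over valid
(home-and-awake) epochs, averaged, and re-z-scored, so 0 is that person's
mean analysed arousal and units are within-person SDs. For event-locked
averaging, the strong lag-1 autocorrelation is removed by per-participant
OLS AR(1) residualisation.

Relative to a set of reference events (vocalisations of a given speaker and
category, or arousal peaks above the top-10% threshold), the package
computes, per participant:

- **likelihood profiles** — P(≥1 target event in the bin `[t+a, t+b)`)
  for 2 min bins spanning ±20 min;
- **event-locked arousal trajectories** — mean arousal at 1 min lags
  −20…+20;
- **moving-window arousal stability** (lag-1 autocorrelation, window 10
  epochs, shift 5) and **arousal coupling** (zero-lag Spearman ρ of
  independently linearly detrended infant and caregiver arousal per
  window), excerpted around events;
- **ROC/AUC** of arousal predicting event presence by an all-thresholds
  sweep (identical to the rank-sum P(X_event > X_non-event) form).

Chance levels come from matched resampled controls: for each real event set,
pseudo-events are drawn uniformly (without replacement, many repetitions)
from valid epochs where neither partner vocalised. Real vs control (or vs
the chance level 0) is compared per bin with Mann-Whitney U across
participants, with the Hodges-Lehmann median-of-pairwise-differences as
effect size; multiple comparisons over time bins are corrected with a
permutation-based temporal cluster test: contiguous same-sign bins with
two-sided p < 0.05 form clusters scored by Σ|z|, referred to the permutation
distribution of the maximum cluster mass under within-participant label
swaps (or sign flips against chance 0), p = (1 + #{null ≥ obs}) / (n_perm + 1).

A forward simulator provides ground truth: bivariate AR(1) arousal with
optional cross-coupling, a logistic point-process for vocal events whose
log-odds depend on own/partner arousal plus a self-excitation term
(temporal clustering), category-specific post-event arousal impulses, block
validity masks, and the 5 s/60 s duty-cycled sampling operator.

## Worked example

Simulate a cohort, ask whether infant arousal is elevated around infant
cries, and cluster-correct the trajectory against chance:

```python
import numpy as np
from vocaldyad import (get_preset, simulate_cohort, filter_events,
                       remove_autocorrelation, event_locked_arousal,
                       permutation_cluster, default_lags, roc_auc_arousal)

lags = default_lags()
dyads = simulate_cohort(get_preset("paper_like"), n_dyads=20, seed=0)

rows, aucs = [], []
for d in dyads:
    cries = filter_events(d.events, "infant", "cry")
    if len(cries) == 0:
        continue
    whitened = remove_autocorrelation(d.infant)
    rows.append(event_locked_arousal(whitened, cries, lags).mean)
    aucs.append(roc_auc_arousal(d.infant, cries))

real = np.vstack(rows)
chance = np.where(np.isfinite(real), 0.0, np.nan)
res = permutation_cluster(real, chance, n_perm=1000, seed=0, mode="signflip")

print(f"{len(rows)} dyads with infant cries")
print(f"mean infant arousal at cry onset: {np.nanmean(real[:, 20]):+.2f} z")
print(f"mean AUC (infant arousal -> cry): {np.mean(aucs):.3f}")
for c in res.significant(0.05):
    print(f"cluster: lags {lags[c.start]:+d}..{lags[c.stop-1]:+d} min, "
          f"sign {c.sign:+d}, mass {c.mass:.1f}, p = {c.p:.3f}")
```

prints

```
20 dyads with infant cries
mean infant arousal at cry onset: +0.61 z
mean AUC (infant arousal -> cry): 0.840
cluster: lags -7..+0 min, sign +1, mass 39.3, p = 0.001
cluster: lags +1..+5 min, sign -1, mass 20.8, p = 0.015
```

Infant arousal is significantly elevated in the minutes up to cry onset
(positive cluster through lag 0), and falls below the day's baseline in the
minutes after the cry (negative cluster) — the generator's post-cry
down-regulation, recovered by the analysis. The AUC of 0.84 says arousal
alone predicts which epochs contain a cry far above the chance level 0.5.

The same pipeline is available from the shell:

```bash
vocaldyad simulate --preset paper_like --n-dyads 50 --seed 0 --out data/
vocaldyad validate --arousal data/arousal.tsv --events data/events.tsv
vocaldyad run --config config.yaml     # writes TSV tables + summary.json
```

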
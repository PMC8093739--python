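# tidaltag

Analysis of fine-scale oceanographic drivers of reef manta ray
(*Mobula alfredi*) visitation at a tidally forced feeding aggregation,
from passive acoustic telemetry.

Researchers who tag reef mantas with coded acoustic transmitters and moor
CTD/ADCP instruments beside the aggregation site face four chained
problems: screening false detections out of receiver logs, turning
detections into occupancy statistics (resident events, residency indices),
reducing raw instrument records to environmental predictors on a common
5-minute grid, and modelling presence/absence against those predictors
with boosted regression trees (BRT). `tidaltag` implements the whole
chain as a library with a thin command-line wrapper, plus a synthetic-data
generator that emulates the study conditions (semidiurnal tides,
flood-phase cold-water bores, diel warming, bore-coupled backscatter,
tidally oscillating slope currents) with known ground truth, so every
stage can be verified end to end.

## The statistics at the core

* **Residency index**: RI = 100 × (days detected) / (days from first to
  last detection, inclusive). A *resident event* opens at the second
  detection at a receiver within 60 min, extends while detections continue
  within 60 min, and closes on silence or on two detections at another
  receiver.
* **False-detection screen**: within each (tag, receiver) stream,
  inter-detection intervals are short (< 30 min) or long (> 12 h); an
  isolated detection in a stream with fewer short than long intervals is
  flagged.
* **BRT visitation model**: logistic gradient boosting of depth-limited
  least-squares trees fit to (y − p) residuals with one-step Newton leaf
  values, subsampled without replacement at bag fraction *bf*, shrunk by
  learning rate *lr*, with the tree count selected by stepwise ten-fold
  cross-validation (*ss* trees per step). Models are evaluated by training
  and cross-validated AUC, their gap ΔAUC, and deviance explained
  D² = 1 − residual/total deviance.
* **Interpretation**: relative influence (split-improvement shares summing
  to 100%), partial dependence at predictor means with bootstrap bands,
  and pairwise interaction sizes (departure of the fitted pair surface
  from additivity on a quantile lattice, ×1000) with permutation
  significance tests.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

```bash
python examples/fit_and_interpret.py
```

simulates a 7-day deployment and fits the visitation model:

```
selected 100 trees; T_AUC 0.946, CV_AUC 0.900 (outstanding), dAUC 0.046, D2 0.49

relative influence (% of total split improvement):
time_to_high_tide    43.7
temp_50m             19.6
ls_8_5               10.3
...

partial dependence of time_to_high_tide: response ranges 0.015 to 0.788
as the predictor sweeps its observed quantiles (others at means)
```

`time_to_high_tide` carries the largest share of the model's split
improvement — the generator's dominant effect is a strong flood-phase
preference (presence concentrated at negative hours relative to high
water) — and its dependence profile swings occupancy probability from
near zero at ebb to ~0.8 at peak flood. The cross-validated AUC of 0.90
says held-out 5-min bins are ranked almost perfectly; the small
training–CV gap (0.046) says little of that is overfitting, and D² = 0.49
means the model explains about half the binomial deviance. The other examples cover residency
statistics from the published Egmont Atoll deployment table
(`residency_summary.py`), detection QC and resident events
(`simulate_and_qc.py`), and instrument-series feature engineering
(`tide_and_features.py`).

The same stages are scriptable from a shell:

```bash
tidaltag simulate --seed 1 --size small --out data/
tidaltag run --config run.yaml --out results/run1
```

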
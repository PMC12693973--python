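# dcpm — dynamic connectome-based predictive modeling

`dcpm` predicts **trial-level behavior from moment-to-moment brain
connectivity**. Classic connectome-based predictive modeling (CPM) works
on one static connectivity matrix per subject; `dcpm` implements the
dynamic variant used to study how memory encoding and subjective arousal
fluctuate from one event to the next: connectivity is measured per
timepoint as phase synchrony, averaged over a short hemodynamically shifted
window around each trial, and used to predict that trial's outcome with
leave-one-trial-out cross-validation.

It is written for researchers who have node time series (any parcellation;
the reference design uses 377 nodes at a 1-s TR), a table of trial onsets
with behavioral outcomes (binary memory 0/1, ordinal arousal 1–4), and a
node→functional-network table for anatomy statistics. A synthetic-data
generator with planted edge–behavior couplings makes the whole pipeline
testable without scan data.

## The method

For nodes *i*, *j* with band-limited (0.008–0.12 Hz) signals and
instantaneous Hilbert phases φᵢ(t):

* **edge synchrony** sᵢⱼ(t) = cos(φᵢ(t) − φⱼ(t)) ∈ [−1, 1];
* **trial connectome**: mean of sᵢⱼ over [onset + 5 s, onset + 15 s);
* **per fold** (one trial held out, trials pooled across subjects): edges
  with Pearson P < 0.01 against behavior form positive / negative
  subnetworks; their per-trial synchrony sums feed a logistic (memory) or
  linear (arousal) regression; the held-out trial is predicted;
* **performance**: accuracy (memory) or Pearson r (arousal) over held-out
  predictions, with significance from 1000 permutations of behavior;
* **consensus network**: edges selected on every fold, per sign;
* **anatomy**: functional-network-pair composition and network overlap with
  upper-tail hypergeometric tests over the C(n, 2) edge universe
  (70,876 edges for 377 nodes), plus 2×2 chi-square overlap comparisons;
* **dynamics**: engagement = positive − negative subnetwork mean synchrony
  per sample; internetwork cofluctuation = correlation of two networks'
  engagement after shared-edge removal;
* **generalization**: edges selected on one run/construct, model refit and
  evaluated on another.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

```python
import dcpm
from dcpm import simulate as sim

# one run, 14 subjects x 40 trials, 50 nodes, 30 planted edges per sign
spec = sim.preset_strong_coupling(seed=0)
series, trials, truth = sim.simulate_dataset(spec)

tensors = [dcpm.compute_synchrony(ts) for ts in series]       # cos(dphi)
X = dcpm.trial_average(tensors, trials, construct="arousal")  # 560 x 1225

res = dcpm.loto_cv(X, construct="arousal", n_perm=250, seed=0)
net = dcpm.consensus_network(res)
tp = len(net.positive_edges & truth.planted_positive_edges)
print(f"r = {res.performance:.3f}, p = {res.p_value:.4f}")
print(f"consensus +edges: {len(net.positive_edges)}, "
      f"precision {tp / len(net.positive_edges):.2f}, "
      f"recall {tp / len(truth.planted_positive_edges):.2f}")
```

Output:

```
r = 0.895, p = 0.0040
consensus +edges: 33, precision 0.91, recall 1.00
```

The cross-validated correlation between predicted and observed arousal is
0.895; no permutation of behavior reached it (p = 1/251); and the
consensus positive subnetwork contains all 30 planted edges plus 3
chance-level selections — consistent with the ~α/2 · n_edges false
selections expected at P < 0.01.

The same analysis runs from the shell:

```bash
dcpm simulate --preset strong --seed 0 --out data/
dcpm synchrony --timeseries data/ts_sub000_cortisol_emotional.tsv --out t0.npz
dcpm fit --edges t0.npz --trials data/trials.tsv --construct arousal \
         --n-perm 250 --seed 0 --out fit.json
dcpm pipeline --seed 0 --output-dir out/      # full multi-condition run
```

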
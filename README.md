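# profilefit

Analysis toolkit for RNA and protein expression **time courses**, built
around the kind of experiment that follows a bacterial culture from
exponential growth deep into starvation: a handful of irregularly spaced
sampling times (hours to weeks), a few biological replicates, and paired
RNA-seq read counts and proteomic spectral counts for thousands of genes.

It answers three questions about such data:

1. **What does each gene do over time?**  Every profile is fit with a
   7-parameter piecewise continuous curve — plateau, ramp, plateau, ramp,
   plateau — with four duration parameters `t1..t4` (h) and three
   amplitudes `A1..A3`.  `t1` is the time to first inflection and
   `t2+t3+t4` the time from first inflection until the profile levels
   off.  The fit minimizes the replicate-error-scaled cost

       F = Σ_j (d(t_j) − s(t_j))² / σ(t_j)²

   with a differential-evolution (DE/rand/1/bin) population of 15 agents,
   crossover 0.75 and mixing strength 0.6, pooling the final populations
   of independent restarts into a fit *ensemble*.  Members that fit well
   (mean deviation ≤ 1 SD across the course) vote each gene into
   **up / down / transiently up / transiently down / flat**, with genes
   below a 90% agreement bar called **ambiguous**.

2. **How do proteins relate to their transcripts?**  Protein kinetics
   `dp/dt = k_s·m(t) − k_d·p` have two limits: fast degradation, where
   protein *tracks* its transcript (proportional regulation), and
   negligible degradation, where protein tracks the *running integral* of
   its transcript (integral regulation).  Each gene gets two Spearman
   correlations — protein vs mRNA (ρ_prop) and protein vs the trapezoidal
   cumulative mRNA integral (ρ_int) — and is labeled proportional or
   integral when the corresponding ρ exceeds 0.70, intermediate otherwise.

3. **Is co-transcription preserved at the protein level?**  Within each
   operon, all pairwise Spearman correlations are summarized (mean or
   median) separately for transcripts and proteins, and protein pair
   correlation is related to the bp distance between coding regions.

Everything is driven and validated by a **synthetic-data generator** with
full ground truth: piecewise transcript profiles with knots on the
sampling grid, exact closed-form protein trajectories for any `k_d`,
operons sharing one transcript shape, distance-coupled translation noise,
and negative-binomial count noise for both RNA-seq and spectral counts.

## Worked example

```python
import numpy as np
from profilefit import (DEConfig, PiecewiseParams, evaluate_piecewise,
                        fit_profile_de, call_gene_behavior)

times = np.array([3, 4, 5, 6, 8, 24, 48, 168, 336.0])   # hours
truth = PiecewiseParams(t0=3, t1=1, t2=2, t3=2, t4=16,
                        A1=0.3, A2=2.0, A3=0.4)          # transient pulse
d = evaluate_piecewise(truth, times)
sigma = np.full_like(d, 0.05)

ens = fit_profile_de(d, sigma, times, DEConfig(seed=1))
best = ens.best
print(f"best cost {ens.best_cost:.3g}")
print(f"t1={best.t1:.2f} h   levels-off after t2+t3+t4={best.t_change:.1f} h")
print(call_gene_behavior(ens, d, sigma))
```

prints

```
best cost 0
t1=1.00 h   levels-off after t2+t3+t4=20.0 h
BehaviorCall(category='transient_up', agreement=1.0, delta=0.05, n_good=204)
```

i.e. the fitter recovers the pulse exactly (cost 0), the timescales match
the truth (first inflection after 1 h, done changing 20 h later), and the
204 well-fitting members of the pooled ensemble unanimously call the gene
transiently up-regulated.

For a full experiment, run the pipeline from the command line:

```sh
profilefit run-all --outdir out --seed 0 --genes 2000
```

which simulates counts, filters (low counts, per-time significance vs
the 3 h baseline for RNA, ≥1.5 fold change for protein), normalizes
(depth → max), fits and classifies both molecule types, computes
regulation calls and per-time-point mRNA–protein correlations, operon
coherence and distance trends, K-means centroids (15 RNA / 25 protein
clusters), RNA-class fractions and gene-set enrichment, and writes a
`manifest.json` that makes the run byte-reproducible.

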
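# sconet

Structural covariance network topology of delay discounting.

`sconet` is a Python package for asking whether people who discount delayed
rewards steeply differ from shallow discounters in the *coordinated
organization* of brain morphology. It implements the full analysis chain
used in graph-theoretic studies of gray-matter structural covariance:

1. **Delay discounting.** Each subject's intertemporal choices (fixed
   immediate reward vs. larger delayed reward) are fitted with the
   hyperbolic value model `SV = A / (1 + kD)` and a logistic choice rule
   `P(delayed) = 1 / (1 + e^{-β(SV₁ − SV₂)})` by maximum likelihood,
   estimating the discount rate `k` (per day) and inverse temperature `β`
   per subject. Subjects are split at the median `k` into high- and
   low-discounting groups.
2. **Structural covariance networks.** Regional gray-matter volumes
   (90-region AAL parcellation) are residualized against age, sex,
   education, and total intracranial volume; each group's 90×90 Pearson
   correlation matrix over the corrected volumes is thresholded at fixed
   sparsities 0.25–0.53 (negatives zeroed first), giving binarized networks
   with identical edge counts across groups.
3. **Topology.** Mean clustering coefficient `Cp`, characteristic path
   length `Lp`, and small-worldness `σ = γ/λ` (with `γ = Cp/⟨Cp_rand⟩`,
   `λ = Lp/⟨Lp_rand⟩` from 100 degree-preserving random networks), plus
   nodal betweenness centrality (normalized by the network mean) and
   mean + 1 SD hub detection at sparsity 0.25.
4. **Inference.** Nonparametric permutation tests (1,000 relabelings by
   default) for group differences in every global metric at every sparsity
   and in nodal betweenness per region, with empirical 95% CIs, two-sided
   add-one p-values, and the 1/N nodal correction (p < 0.011 for N = 90).

Because subject-level morphometry is rarely shareable, the package ships a
synthetic-data module — a community factor model with closed-form implied
correlations and a hyperbolic/softmax choice simulator — so the entire
pipeline is testable against known ground truth.

## Worked example

```python
import sconet as sc

# --- behavior: value, choice rule, and per-subject MLE ------------------
sv = sc.subjective_value(17000, 24, 0.029)     # 17,000 KRW in 24 days
p  = sc.choice_probability(sv, 10000, 0.01)    # vs 10,000 KRW now
cfg = sc.ChoiceGeneratorConfig(k_true=0.029, beta_true=0.005, seed=42)
fit = sc.fit_discounting(sc.generate_choices(cfg, subject_id="demo"))

# --- networks: synthetic two-group cohort, topology at S = 0.25 ---------
high, low = sc.scenario_configs("planted", seed=11)
table = sc.residualize(sc.generate_morphometry(high, low, seed=11))
net = sc.zero_negatives(sc.covariance_matrix(table, "high"))
b = sc.binarize_at_sparsity(net, 0.25)
gm = sc.small_world(b.adjacency, n_random=100, seed=1)

# --- cohort statistics ---------------------------------------------------
t  = sc.two_sample_t_from_summaries(21.943, 2.920, 35, 22.057, 2.555, 35)
x2 = sc.chi_square_2x2(21, 14, 18, 17)
```

This prints (via the obvious f-strings):

```
true k = 0.029; recovered k = 0.0296, beta = 0.0051, -logL = 4.5
SV(17000 KRW, 24 d, k=0.029) = 10023.58
P(choose delayed) = 0.5587
high-group network at S=0.25: 1001 edges, 1065 negatives zeroed
Cp=0.417 Lp=1.806 gamma=1.241 lambda=1.020 sigma=1.216
age t = -0.174, df = 68, p = 0.863
sex chi2 = 0.521, p = 0.470
```

Reading the numbers: a delayed 17,000 KRW reward at 24 days is worth
≈ 10,024 KRW to a subject with `k = 0.029`/day — barely above the 10,000 KRW
immediate option, so the choice probability sits near indifference (0.56).
The MLE recovers the generating `k` from 120 simulated trials. The
high-discounting group's covariance network at sparsity 0.25 keeps exactly
`floor(0.25 × 4005) = 1001` edges and is small-world (`σ = 1.22 > 1`:
clustering 24% above degree-matched random networks at essentially random
path length). The cohort statistics reproduce the pooled two-sample t and
2×2 chi-square conventions for a demographic table.

## Command line

```bash
sconet make-fixtures --out data/ --seed 1 --scenario planted
sconet fit-dd --choices data/choices.tsv --out fits.tsv
sconet run-all --choices data/choices.tsv --volumes data/volumes.tsv \
               --covariates data/covariates.tsv --reps 1000 --seed 1 --out results/
```

`run-all` chains every stage (fits → median split → residualization →
networks → topology → permutation inference) and writes stage tables plus a
reproducibility manifest; reruns with the same manifest are byte-identical.

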
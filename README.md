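# dton — dynamic time order networks for time-series gene expression

`dton` infers *which genes respond later than which* from a single
time-course expression experiment, and uses that ordering to nominate
late-response genes as biomarker candidates. The motivating setting is a
stimulation time course (e.g. breast cancer cells treated with
17β-estradiol, sampled over 32 hours at t = 0, 1, 2, 4, 6, 8, 12, 16,
20, 24, 28, 32 h): early-response genes move within the first hours and
are poor indicators of a sustained drug effect, while late-response
genes — those still changing after ~17 h — are stable, clinically
useful readouts.

## The model

For each gene the log concentration ratio (LCR) trajectory
y(t) = log C_t/C_0 is fitted with a **three-piece natural cubic spline**
with knots K1, K2 at the 33rd/67th percentiles of the sampling times
(5.333 h and 17.333 h on the canonical grid). The 12 piecewise-cubic
coefficients obey 8 constraints (value, first- and second-derivative
continuity at both knots; f″ = 0 at both window ends), leaving **4 free
parameters** fit by OLS on a reduced 12 × 4 design matrix.

A directed time order G1 → G2 ("G2 responds later") is modelled by the
linear ODE

    df2/dt = k1 f1(t) + k2 f2(t),

whose integrated form f2(t) = k1 F1(t) + k2 F2(t) regresses a gene's
expression on the *cumulative* fitted curves F_i(t) = ∫ f_i. Both
orderings of a pair are scored with the Gaussian log-likelihood of

    y_later ~ b0 + b1 F1(t) + b2 F2(t),

and their difference ΔLL decides the direction (positive favours
G1 → G2). Using integrals rather than rates accumulates evidence over
the whole trajectory, so an order is resolvable even when the two
curves differ only briefly.

The pairwise ΔLL values form a complete weighted digraph. Small
networks are pruned by a weight quantile (median by default) followed
by transitive reduction; genome-scale networks are skeletonized by a
maximum-weight spanning tree (Prim). **Incoming-edge hubs** — nodes
with only incoming edges — are the late-response candidates; the more
incoming edges, the later the response.

## Worked example

Simulate a 12-gene two-wave cascade (5 early genes with onsets before
~5.3 h, 7 late genes with onsets after ~17.3 h, coupled through the
linear ODE) and run the full pipeline with the spanning-tree network:

```bash
dton simulate cascade --seed 1 --n-genes 12 --out demo
dton run --input demo_expression.tsv --out demo_out --mode mwst --skip-preprocess
```

which prints

```
wrote artifacts to demo_out/
hub	g005	in_degree=6
hub	g008	in_degree=3
hub	g006	in_degree=1
hub	g009	in_degree=1
```

and writes `demo_out/hub_report.tsv`:

```
gene	in_degree	trend	late_mean
g005	6	underexpressed	-2.05657393834
g008	3	overexpressed	1.5906197681
g006	1	underexpressed	-1.74579369837
g009	1	overexpressed	1.61719033427
```

The ground truth (`demo_truth.tsv`) places genes g005–g011 in the late
wave: every reported hub is a late-wave gene, and the top hub g005
(6 incoming edges) is correctly flagged as a late underexpressed
response — exactly the profile the method is designed to surface. The
`trend` column is the sign of the mean fitted LCR over the late window
[K2, 32 h].

For a real dataset, start from a raw probe × time intensity table and
drop `--skip-preprocess`; the pipeline then averages duplicate probes
(via the library API), keeps genes with coefficient of variation
above 0.15, converts to LCRs, and standardizes each time point before
fitting. Each stage is also available standalone
(`dton preprocess|fit|pairs|network|hubs`) so large runs can be
resumed.

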
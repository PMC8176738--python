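# dygnet

Time-varying gene regulatory network inference that fuses single-cell
expression data with transcription-factor DNA-binding evidence.

## The problem

Co-expression networks built from expression data alone cannot
distinguish regulation from correlation, and static networks cannot
describe a dynamic process like development, where regulators switch on
and off as cells differentiate. `dygnet` is for computational biologists
who have (a) a single-cell RNA-seq matrix spanning a differentiation
process and (b) a table of regulator→target binding probabilities (e.g.
posterior probabilities from DNase-seq footprinting), and who want a
genome-scale exploratory map of *which* regulators influence *which*
targets *when*.

## The model

Cells are first ordered in developmental pseudotime and binned into
stages t ∈ {1..T} (dimensionality reduction → PAM clustering → minimum
spanning tree over cluster medoids → marker-guided root selection).
Around each target gene *i*, with y the target's standardized
log-expression and **x** the other p−1 genes', a local sparse linear
model is fitted:

    y_t = b_t · x_tᵀ + ε_t ,   ε_t ~ N(0, σ²)

by minimizing

    Σ_t Σ_{c ∈ bin t} (y_c − b_t · x_c)²  +  λ ‖D vec(bᵀ)‖₁

The structural matrix **D** encodes two kinds of sparsity: single-entry
rows shrink each coefficient at each stage (sparsity *within* time), and
paired ±w rows shrink the change of each coefficient between adjacent
stages (sparsity *across* time — the fused-lasso smoothness that lets
edges switch on gradually). All 2T−1 rows belonging to predictor *j*
share one magnitude

    w_j = 1/η + (η−1)/η · log(p_ji)/log(p_min)   if p_ji ≥ p_min, else 1

where p_ji ∈ [0,1] is the binding probability of regulator *j* on target
*i*'s promoter. Strong binding evidence (p_ji → 1) lowers the penalty to
the floor 1/η, making those edges easier to select; absent or weak
evidence leaves the full penalty. Defaults: λ = 20, η = 4, p_min = 0.5.

Non-zero coefficients (after discarding |b| < τ, default τ = 0.05)
become time-stamped signed edges. Because lasso-type selections are
unstable, downstream analyses count how *consistently* a regulator is
selected across the per-target fits of a curated gene-set, and partition
a gene-set by co-regulation between two TFs. A static
thresholded-correlation network (|ρ| ≥ 0.5 by convention) is provided
as the baseline.

The solver is ADMM with a cached sparse factorization — a single fit
against ~200 candidate predictors over 5 stages takes about two seconds,
so genome-wide panels are practical.

## Worked example

```python
from dygnet import io, simulate, solver, network
from dygnet.penalty import PenaltyConfig, build_weight_vector, build_penalty_matrix

# synthetic dataset: 50 candidate genes, 3 stages, 3 true regulators
truth = simulate.simulate_truth(50, 3, 3, seed=4)
ds = simulate.simulate_expression(truth, cells_per_bin=80, seed=4)
priors = simulate.simulate_priors(truth, fidelity=1.0, seed=4)

expr, _ = io.standardize(io.log1p_transform(ds.expr))
cfg = PenaltyConfig()                    # lambda=20, eta=4, p_min=0.5
design = solver.assemble_design(expr, ds.times, "TARGET")
wv = build_weight_vector("TARGET", design.predictor_ids, priors, cfg)
D = build_penalty_matrix(wv, design.T)
fit = solver.fit_target(design, D, cfg)
net = network.edges_from_fit(solver.threshold_coefficients(fit, 0.05))
for e in sorted(net.edges, key=lambda e: (e.time, e.regulator)):
    print(f"{e.regulator} -> {e.target}  t={e.time}  b={e.coefficient:+.3f}")
```

prints

```
G0045 -> TARGET  t=1  b=+0.069
G0035 -> TARGET  t=2  b=+0.532
G0045 -> TARGET  t=2  b=+0.715
G0035 -> TARGET  t=3  b=+0.531
G0045 -> TARGET  t=3  b=+0.715
G0047 -> TARGET  t=3  b=+0.539
```

The three true regulators in this simulation are G0035, G0045 and G0047
with activation stages 2, 2 and 3 and effects 0.54, 0.69 and 0.59: the
fit recovers each edge at (or adjacent to) its true activation stage
with shrunken but correctly signed coefficients, and selects no false
regulators.

The same pipeline is available from the shell:

```bash
dygnet simulate --p 50 --t 3 --k 3 --seed 4 --out-dir sim/
dygnet fit --expr sim/expression.tsv --times sim/times.tsv \
           --priors sim/priors.tsv --target TARGET --out net.tsv
dygnet aggregate --network net.tsv --gene-set genes.txt --time 3 --out counts.tsv
```

plus `dygnet pseudotime` (stage inference from expression) and
`dygnet baseline` (thresholded-correlation comparison).

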
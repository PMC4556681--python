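# lemnorm

Reference-gene-free normalization of parallel qPCR Ct data via a
sequentially estimated linear error model, with the classical
reference-gene comparators (ΔΔCt, geNorm), the evaluation statistics needed
to judge them, and a ground-truth simulator.

## The problem

Microfluidic qPCR arrays (48×48 / 96×96 chips) measure every assay against
every loaded sample in one run. Expression is read out as the threshold
cycle Ct — one extra cycle means half the starting cDNA. Before Ct values
can be compared across conditions, technical error must be removed.
The standard route normalizes against *reference genes* (RGs) assumed stable
across conditions, either one gene (ΔΔCt) or the geometric mean of several
chosen by the geNorm stability criteria (M-values, pairwise variation V with
a 0.15 cutoff). That route fails silently when the candidate RGs are
coexpressed and respond to the condition: their mutual ratios stay constant,
so the stability criteria accept them, and the normalization then shifts
every gene's condition mean by the RGs' own response.

## The model

The chip layout itself identifies the technical structure without any
reference gene. Each chamber measurement is decomposed additively (cycles):

```
Y  =  ε_P:A + ε̃ + ε_S   +   Δ_T + Δ_T:G + ε
      └── removed ────┘      └── retained ───┘
```

* `ε_P:A` — probe error per array: mean of a gene's measurements on a chip
  (probe pipetting, channel);
* `ε̃` — systematic batch effects (e.g. cDNA-conversion runs), estimated
  only from variation orthogonal to the treatment, or from a single-stranded
  cDNA quantification covariate;
* `ε_S` — sample error: mean of a sample over all genes (sample pipetting,
  extraction);
* `Δ_T` — global treatment shift of the all-gene average, retained;
* `Δ_T:G` — per-gene treatment effect, the biology of interest;
* `ε` — residual (biological variation + non-systematic noise), empirically
  Student-t with heavy tails.

The effects are plain group means estimated **in this order** — probe/array,
batch, global treatment, sample, per-gene treatment — and the order matters:
estimating the sample error first would absorb the global treatment shift.
Retained values `Ŷ = Δ_T + Δ_T:G + ε` give per-gene contrasts against the
reference condition, `−ΔCt = −(Ŷ − mean Ŷ_reference)`, and fold changes
`2^−ΔCt`. A key assumption: a group-wise systematic error and the global
treatment shift are indistinguishable from chip data alone; an external
per-sample cDNA quantification (the `ssdna` covariate) separates them.

## Worked example

```python
import lemnorm as ln

table, design, truth = ln.simulate(
    ln.SimConfig(seed=42, global_shift=(0.0, 0.4), de_fraction=0.25))
fit = ln.fit_lem(table, design)
print(fit.conservation_error())                 # 3.55e-15
print(fit.global_treatment_contrast()["treat1"])  # 0.502
```

Running `python examples/01_simulate_and_fit.py` prints:

```
simulated 2304 reaction chambers (48 genes x 24 samples)
conservation error: 3.55e-15 cycles (components + residual reconstruct every raw Ct)
global treatment shift vs control: +0.502 cycles (simulated: +0.400)

fold changes of three truly regulated genes (treated group mean):
  g001: estimated   0.90x   (true effect -0.05 cycles -> 1.04x)
  g010: estimated   0.22x   (true effect +1.77 cycles -> 0.29x)
  g013: estimated   0.63x   (true effect +0.13 cycles -> 0.91x)
```

The conservation error shows the decomposition is exactly additive; the
estimated global shift and per-gene fold changes recover the simulated
truth up to sampling noise (a +1.77-cycle true effect is a 0.29× fold
change, estimated 0.22×).

The other examples cover the geNorm ranking and back-transform
(`02_reference_gene_methods.py`), the coexpressed-RG failure mode
(`03_coexpressed_rg_failure.py`), the nested variance decomposition and
heteroscedasticity regression (`04_variance_decomposition.py`), the
Student-t residual fit with Kolmogorov–Smirnov and Kuiper tests
(`05_residual_distribution.py`) and the config-driven three-arm workflow
(`06_workflow.py`). A thin CLI wraps the same functions:
`lemnorm simulate|fit|genorm|run --help`.

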
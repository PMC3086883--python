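# calpcleave

Prediction of calpain cleavage sites in protein substrates with multiple
kernel learning (MKL).

Calpain is an intracellular calcium-dependent cysteine protease that
regulates its substrates by limited proteolysis. Unlike trypsin or the
caspases it has no dominant residue preference at the scissile bond, so
cleavage-site prediction needs to combine weak, heterogeneous signals:
position-specific residue preferences around the bond, local secondary
structure, and solvent accessibility. `calpcleave` trains a support vector
machine over a *learned* convex combination of sub-kernels, one per feature
track, so that each kind of feature keeps its own representation and kernel
parameters, and the learned weights report how much each track contributes.

## Model

A candidate cleavage site is the peptide bond between residues P1 and P1′
(bond index *i* between residues *i* and *i+1*). Each candidate is described
by windows cut from three per-residue tracks: the amino-acid sequence, a
3-class secondary-structure string over {H, E, C}, and a 2-class solvent
accessibility string over {B, A} (below/above 25% relative accessibility).

Sub-kernel families:

* **linear / RBF** on one-hot encoded windows (20 binary values per
  sequence position): k(x, y) = x·y and exp(−‖x−y‖²/2σ²);
* **string kernel** (position-dependent): the number of identical k-mers at
  identical offsets in two equal-length windows, summed over k = 1..d;
* **gapped spectrum kernel** (position-independent): Φ(s)·Φ(t), where Φ
  counts occurrences of every pattern of length ≤ d′ with up to g interior
  wildcard positions — suited to the positionally flexible structure tracks.

Each sub-kernel Gram matrix is cosine-normalized; the combined kernel is
K = Σₖ βₖ Kₖ with β on the probability simplex. The decision function is
the standard SVM form f(x) = Σᵢ αᵢ yᵢ Σₖ βₖ kₖ(xᵢ, x) + b. The weights β
are learned jointly with (α, b) through the semi-infinite linear
programming formulation of MKL: alternate libsvm solves on the combined
kernel with cutting-plane LP updates of β, with a line search that keeps
the dual objective monotonically non-increasing.

The evaluation protocol is repeated stratified cross-validation (10×10 by
default) scored by ROC AUC with its standard error, pooled-variance t-tests
between kernel configurations, exhaustive/two-stage grid search over kernel
parameters, and coordinate-descent optimization of per-kernel window
extensions. A whole-sequence scanner evaluates the decision function at
every internal bond, min-max normalizes the profile, and flags the top 5%
of bonds as predicted sites.

Because curated substrate collections are small and access-restricted, the
package ships a synthetic substrate generator that emulates their structure
(position-specific residue preferences around planted sites, loop/exposed
bias in the structure tracks, short- vs long-footprint isoform contrast) so
every stage of the method is testable end to end.

## Worked example

```python
from calpcleave import (KernelConfig, SyntheticConfig, WindowSpec,
                        build_instances, cross_validate, fit_mkl, generate,
                        scan)

spec = WindowSpec(6, 5)          # P6..P1 | P1'..P5'
configs = [
    KernelConfig("rbf", "sequence", spec, sigma=2.1),
    KernelConfig("string", "sequence", spec, order_d=5),
    KernelConfig("spectrum", "ss", spec, order_dprime=5, gaps_g=1),
]

substrates = generate(SyntheticConfig(n_sequences=30, seed=17))
report = cross_validate(substrates, configs, C=1.67, folds=2, repeats=10,
                        seed=23)
print(report.summary())

instances = build_instances(substrates, spec, neg_ratio=10, rng_seed=0)
model = fit_mkl(instances, configs, C=1.67)
print("sub-kernel weights:", model.display_weights.round(3))

fresh = generate(SyntheticConfig(n_sequences=1, seed=99))[0]
result = scan(model, fresh, top_fraction=0.05)
print("planted sites:", fresh.cleavage_sites)
print("top-5% bonds:", result.above_threshold)
```

prints

```
rbf[sequence] win=(6,5) sigma=2.1 + string[sequence] win=(6,5) d=5 + spectrum[ss] win=(6,5) d'=5 g=1 C=1.67: AUC 99.92% (SEM 0.02%) over 20 folds
sub-kernel weights: [0.    1.    0.054]
planted sites: [84, 336]
top-5% bonds: [17, 45, 74, 75, 84, 85, 90, 123, 130, 131, 180, 241, 248, 255, 258, 264, 266, 302, 315, 336]
```

The cross-validation line is the mean AUC (and SEM) over 20 fold
evaluations of the three-kernel MKL classifier on a planted-motif substrate
set. The weight vector (rescaled so the largest weight is 1) shows the
string kernel dominating, with a small but non-zero contribution from the
secondary-structure spectrum kernel. The scan of a fresh sequence places
both planted sites (bonds 84 and 336) inside the top-5% score set.

The same workflow is available from the shell:

```
calpcleave synth --kind cal1-like --seed 7 --out-prefix toy
calpcleave train --fasta toy.fa --sites toy.sites.tsv --ss toy.ss.txt \
    --sa toy.sa.txt --left 6 --right 5 --out model.json
calpcleave scan --model model.json --fasta toy.fa --ss toy.ss.txt \
    --sa toy.sa.txt --top-fraction 0.05 --out scan.tsv
```

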
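# modselect

Modularity-guided feature selection and classification for functional brain
networks (FBNs).

Resting-state fMRI studies represent each subject as a signed, weighted
network: nodes are brain regions (ROIs), edge weights are correlations
between the regions' BOLD time series. Mass-univariate or flat-sparse edge
selection ignores a robust property of these networks — their modular
organisation. `modselect` is for researchers who want edge-level
classification (e.g. patients vs. controls, disease-stage discrimination)
in which the *module structure itself guides the selection*, keeping the
selected connectivity patterns interpretable at the module level.

## The method

1. **Network estimation.** Per scan, `W ∈ R^{m×m}` from pairwise Pearson
   correlation of the ROI time series, Fisher r-to-z transformed
   (`z = arctanh r`); sparse inverse covariance (partial correlations) is
   available as an alternative estimator.
2. **Module discovery** by spectral clustering of the *signed* graph. With
   the signed degree `d_i = Σ_j |w_ij|` and `D = diag(d_i)`, the signed
   normalized Laplacian `L = I − D^{−1/2} W D^{−1/2}` is PSD with spectrum
   in [0, 2] even for negative weights. The K smallest eigenvectors are
   row-normalised and k-means clustered, minimising (in relaxation) the
   signed normalized cut `sNcut = Σ_k (x_kᵀLx_k)/(x_kᵀDx_k)`. Modules are
   discovered from the mean control-group network of the training fold.
3. **Modularity-induced group LASSO.** Edges are vectorised module-blockwise
   and grouped: one group per module's within-module edges, one singleton
   group per between-module edge. Selection solves

       min_ω ½‖Y − Xω‖² + λ Σ_g √(d_g) ‖ω_g‖₂

   by monotone FISTA with block soft-thresholding, zeroing whole groups.
4. **Classification** with a linear SVM (C = 1) under nested five-fold
   *subject-level* cross-validation: folds are assigned by subject (repeat
   scans never straddle train/test), an inner five-fold CV picks λ from
   {0.01, 0.1, …, 1}×λ_max, and the data partition is repeated with paired
   t-tests between methods. Baseline schemes: global clustering
   coefficient, node statistics (LCC/DC/BC/CC/EC) with t-test or LASSO
   selection, and edge weights with t-test or flat LASSO.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

```python
import modselect as ms

cohort, baseline = ms.worked_example()   # 20 ROIs, 4 modules, 40 subjects,
nets = cohort.networks()                 # 2 edges weakened in patients

scheme = ms.SchemeConfig("mlfs", k_modules=4)
(acc, sen, spe, auc), folds = ms.nested_cv(nets, cohort.manifest, scheme, seed=0)
print(f"ACC {acc:.1f}%  AUC {auc:.1f}%")
for f in folds:
    print(f"lambda={f.param:.2f}  edges selected: {len(f.selected)}")
```

prints

```
ACC 100.0%  AUC 100.0%
lambda=0.90  edges selected: 10
lambda=0.90  edges selected: 10
lambda=0.90  edges selected: 10
lambda=0.90  edges selected: 10
lambda=0.90  edges selected: 10
```

Every outer fold's inner CV picks the sparsest accurate penalty
(0.9·λ_max), and the group penalty selects exactly one within-module group —
the 10 edges of the module containing both planted discriminative edges —
so the planted effect is recovered inside its module context and the
held-out scans are classified perfectly.

The statsmodels-style model interface is available directly for the core
fit: `ms.GroupLasso(y, design).fit(lam)` returns a results object with
coefficients, objective trace, KKT residual and a `summary()` table.

A CLI mirrors the library: `modselect simulate | estimate | cluster |
design | select | evaluate` (see `modselect --help`).

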
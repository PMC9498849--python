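# enrichsim

Simulation study of SNP-heritability **enrichment** estimation in
strong-LD (livestock-like) populations.

Heritability enrichment asks whether an annotated SNP category — say,
SNPs in pathway genes — carries more than its per-SNP share of a trait's
heritability:

    fold = (h²_subset / h²) / (N_subset / N_total)

Estimates of this fold from two-component GREML depend on how the
kinship matrix weights SNPs by minor allele frequency (MAF) and linkage
disequilibrium (LD).  `enrichsim` simulates genotype panels with
controlled MAF spectra and LD decay, traits with known causal
architecture, builds kinships under four model families — VanRaden
(α = 0), GCTA (α = −1), the α-model (α free), and LDAK (α = −0.25 with
inverse-Σr² LD weights) — fits the two-component mixed model by AI-REML,
and measures the bias of corrected enrichment folds against analytic
truth.  It is aimed at quantitative geneticists who want a controlled
testbed for enrichment-model behaviour before trusting folds from real
panels.

## Worked example

```python
import numpy as np
from enrichsim import (
    simulate_panel, apply_qc, define_functional_subset, select_cvs,
    simulate_phenotypes, GRMSpec, build_grm, grm_pca, reml_fit,
    estimate_enrichment, true_enrichment, correct_enrichment,
)

panel, report = apply_qc(simulate_panel(500, 5000, seed=1))
functional = define_functional_subset(panel, target_size=round(0.1 * panel.m), seed=2)
rest = functional.complement(panel.m)

g_f = build_grm(panel, GRMSpec(model="gcta", subset=functional), normalize_diag=True)
g_r = build_grm(panel, GRMSpec(model="gcta", subset=rest), normalize_diag=True)
X = np.column_stack([np.ones(panel.n),
                     grm_pca(build_grm(panel, GRMSpec()), k=10).matrix])

cvs = select_cvs(panel, functional, n_cv=200, n_functional=50, seed=3)
traits = simulate_phenotypes(panel, cvs, h2=0.8, n_replicates=1, seed=4)
y = traits.phenotypes[:, 0]

fit = reml_fit(y, X, g_f, g_r)
res = estimate_enrichment(fit, functional.size, panel.m)
res.enrichment_true = true_enrichment(cvs, traits.effect_set(0), functional,
                                      panel, float(np.var(y, ddof=1)))
res = correct_enrichment(res, nominal=3.0)
print(f"raw fold       {res.enrichment_raw:.3f}")
print(f"true fold      {res.enrichment_true:.3f}")
print(f"corrected fold {res.enrichment_corrected:.3f}")
```

Output:

```
raw fold       2.316
true fold      1.827
corrected fold 3.802
```

The ~500 functional SNPs (10% of the panel) hold 50 of the 200 causal
variants, so the design-level true fold is 2.5; this replicate's
analytic truth is 1.827 because the squared effects of 50 CVs fluctuate.
The GREML estimate is 2.316; the standard correction rescales each
replicate so its truth maps to the nominal 3.000, giving 3.802 here — a
+27% error, which is typical single-replicate noise for a variance-share
ratio at n = 500.  The study design therefore always averages
replicates: 30 of them (see `analysis/03_model_comparison.py`) give
3.03 ± 0.25 for this matched model, while a random SNP category of the
same size is markedly less stable (1.45 ± 0.26 against a truth of 1).

## Analysis drivers

Numbered scripts under `analysis/` reproduce the study's experiments at
desk scale and write tab-separated tables to `results/`:

| script | what it does |
|---|---|
| `01_simulate_panel.py` | panel + QC summary, LD-decay profile |
| `02_calibrate_traits.py` | realized h² calibration per CV MAF range |
| `03_model_comparison.py` | four kinship models × functional/random subsets |
| `04_alpha_sweep.py` | α-model across the 7-value grid, two trait types |
| `05_ld_window_sweep.py` | LDAK windows 1–5000 kb vs the unweighted model |

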
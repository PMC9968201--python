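# deprivix

Bayesian weighted-index regression for neighborhood deprivation and
indoor chemical mixtures in case-control studies, with spatial risk
surfaces, cluster detection, and a pseudo-participant simulation for
selection bias.

## The problem

Area socioeconomic status and household chemical exposures are both
plausible, mutually confounded risk factors for outcomes such as
childhood leukemia.  Single SES variables are arbitrary and strongly
correlated, as are congeners within a chemical class, so neither can
be entered jointly in an ordinary logistic regression.  `deprivix`
estimates *weighted quantile indices* instead: each group of variables
is collapsed to Σ_j w_j q_ij, where q_ij is the subject's decile score
(0–9) on variable j and the weights w lie on the probability simplex
under a Dirichlet prior, estimated jointly with the health effect.
The core models, fit by MCMC, are

    crude:      logit(p_i) = β0 + β1 Σ_j w_j1 q_ij1                        (NDI alone)
    adjusted:   … + z_i'φ                                                  (individual covariates)
    mixtures:   … + Σ_{k=2}^{8} β_k Σ_j w_jk q_ijk + z_i'φ                 (7 chemical-class indices)
    spatial:    … + u_i + v_i,  u_i ~ N(0, σ_u²),  v ~ MVN(0, Σ(ψ)),
                Σ_ij = exp(−ψ d_ij)

exp(β1) is the odds ratio per one-decile increase of the neighborhood
deprivation index; posterior weights rank the component variables.
Subjects whose spatial odds exp(v_i) exceed 1 with posterior
probability ≥ 0.90 form an elevated-risk area.  A Kulldorff-type
Bernoulli circular scan and a Besag–York–Mollié model with an ICAR
prior on Voronoi-cell adjacency provide covariate-free cluster
detection, and a selection-bias module adds pseudo-participants at
tract-weighted random locations up to full eligibility to test whether
a detected cluster survives differential participation.  Univariate
Firth-penalized regressions compare exposure effects inside a risk
area against the full sample.  A seeded synthetic-study generator with
known truth underpins every test.

Audience: biostatisticians and spatial epidemiologists analyzing
case-control studies with area-level SES, multi-pollutant exposure
panels, and residential coordinates.

## Worked example

```python
import deprivix as dx
from deprivix.index_models import IndexModelSpec, McmcSettings

cfg = dx.GeneratorConfig(seed=0, n_cases=1000, n_controls=1000)    # true β1 = 0.4
study = dx.generate_study(cfg)

for model in ("crude", "adjusted"):
    data = dx.build_model_data(study["participants"], study["blockgroups"], model=model)
    spec = IndexModelSpec(mcmc=McmcSettings(n_burn=1000, n_save=2000, seed=5))
    samples = dx.fit_index_model(spec, data)
    s = dx.summarize_index(samples, "NDI")
    print(f"{model:9s} NDI OR {s['or_mean']:.2f} "
          f"(95% CI {s['or_lower']:.2f}, {s['or_upper']:.2f}); "
          f"top weight {s['weights'].idxmax()} = {s['weights'].max():.2f}")
```

prints

```
crude     NDI OR 1.61 (95% CI 1.55, 1.68); top weight hisp_seg = 0.52
adjusted  NDI OR 1.51 (95% CI 1.43, 1.59); top weight hisp_seg = 0.53
```

The generating effect is β1 = 0.4 (OR 1.49 per decile) with dominant
weight 0.6 on Hispanic segregation.  The generator's default study has
an SES-linked covariate structure (e.g., Hispanic ethnicity raises
both deprivation and case odds), so the crude OR overshoots the truth
and adjustment moves it back toward 1.49 — the crude-vs-adjusted
divergence the index models are designed to expose.  Posterior weights
identify the dominant component in both fits.

A full pipeline — generate, fit, spatial exceedance map, scan/BYM
detection, bias simulation, markdown report — runs from the shell:

```bash
deprivix run --config cfg.yaml --seed 1
deprivix simulate --seed 1 --outdir study/
deprivix detect --method scan --input study/participants.csv
```

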
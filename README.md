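# linscr

Maximum-likelihood spatial capture–recapture (SCR) for populations
confined to **linear, dendritic habitat networks** — river systems and
their branches — paired with the upstream non-invasive genotyping
pipeline that turns replicate-PCR microsatellite calls from fecal samples
into individual detection histories, plus latrine site-fidelity indices
and population-genetic summaries for source-vs-reintroduced comparisons.

It is aimed at wildlife biologists assessing semi-aquatic mustelids
(river otters and kin) whose home ranges are stretches of river rather
than circles on a map: conventional SCR with Euclidean distances and 2-D
state spaces misstates both how far animals travel and where their
activity centers can be, which biases density.  Here distances are
measured **along the network** and activity centers live on a
discretized 1-D state space restricted to the network itself.

## The model

Latrines are *count* detectors: individual *i* with activity center *s*
yields Poisson counts at detector *k* in occasion *o* with hazard
half-normal rate

```
mu = effort[k,o] · λ0 · exp( −d(s,k)² / 2σ² )
```

where *d* is the along-network distance, λ0 the baseline detection rate
and σ the spatial scale.  λ0 can differ by sex (a finite mixture with
proportion ψ of males; known sexes are degenerate memberships) and by a
persistent latrine-specific behavioral response *bk*; σ can differ by
sex.  Activity centers follow an (in)homogeneous Poisson point process
with intensity D(s) (animals/km), optionally log-linear in latitude or in
network distance from a release site.  The full likelihood marginalizes
each detected individual over the state space and includes the expected
number of detected individuals, so abundance N = Σ D(s)·cell(s) and
density are estimated directly.  Models are ranked by AICc (sample size =
detected individuals), competing models (ΔAICc ≤ 2) are model-averaged
with unconditional SEs, and fit is checked by parametric-bootstrap
deviance ratios.  See `docs/methods.md` for the full account.

The genotype pipeline implements replicate-consensus calling (2
replicates to confirm a heterozygote allele, 3 for a homozygote),
Y-marker sexing, PIsibs-based locus sufficiency, and conservative vs
lenient multilocus matching — the two rules bracket the effect of
genotyping error (ghost individuals) on density.

## Worked example

Simulate a survey under the default scenario (100-km sinuous network, 20
latrines, 8 occasions, λ0 = 0.3, σ = 5 km, D = 0.5 otter/km, replicate-PCR
genotyping with 29% allelic dropout and 5% false alleles), run the
genotype pipeline, and fit an SCR model:

```python
from linscr import *
from linscr.simulate import SimulationConfig, simulate_survey, genotypes_to_history

cfg = SimulationConfig()            # 100-km network, 20 latrines, 8 occasions
data = simulate_survey(cfg, seed=5)
assignment, history = genotypes_to_history(data, rule="conservative")
print(f"{history.n_individuals} individuals from "
      f"{history.total_detections} genotyped detections "
      f"({history.n_spatial_recaptures()} spatial recaptures)")

space = buffer_state_space(discretize(data.net, spacing=100.0),
                           data.detectors, sigma=5000.0)
model = fit(history, space, data.detectors, SCRModelSpec(lambda0="sex"), seed=0)
d = model.derived()
D, N = d["density_per_km"], d["N"]
print(f"D = {D.estimate:.2f} otter/km (95% CI {D.lcl:.2f}-{D.ucl:.2f}), "
      f"i.e. 1 otter/{1/D.estimate:.2f} km")
print(f"N = {N.estimate:.0f} ({N.lcl:.0f}-{N.ucl:.0f}) on "
      f"{space.total_length/1000:.0f} km of network")
g = exponential_growth(33, N.estimate, 8, nt_ci=(N.lcl, N.ucl))
print(f"growth = {g.lam:.2f}/yr ({g.lcl:.2f}-{g.ucl:.2f})")
```

which prints (seed 5):

```
41 individuals from 131 genotyped detections (62 spatial recaptures)
D = 0.44 otter/km (95% CI 0.33-0.60), i.e. 1 otter/2.26 km
N = 44 (33-60) on 100 km of network
growth = 1.04/yr (1.00-1.08)
```

Read: the genotyping funnel (sample failure, subsampling, consensus
thresholds) recovered 41 of the simulated individuals; the fitted density
0.44/km is within the CI of the true 0.5/km; abundance over the 100-km
state space and the implied exponential growth from a 33-animal founder
group follow.  The asymmetric CIs are log-scale Wald intervals.

## The analysis

Numbered drivers under `analysis/` run the full study on synthetic data
and write tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_survey.py` | network, latrines, population, detections, field samples |
| `02_genotype_to_individuals.py` | subsampling, consensus, error rates, both matching rules |
| `03_density_scr.py` | state space, candidate model set, AICc, averaging, GOF, growth |
| `04_site_fidelity.py` | SSFI per individual-latrine, sex means, latrine-use IRR |
| `05_popgen_summary.py` | diversity table, percent declines, Weir–Cockerham FST |
| `06_validation.py` | recovery, GOF-calibration and FST-recovery studies |

Run as `cd analysis && python 01_simulate_survey.py` (and so on).  A
config-driven pipeline (`linscr run --config cfg.yaml`) and `simulate` /
`fit` subcommands wrap the same library.

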
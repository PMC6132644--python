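# bidcm

Two-region bilinear dynamic causal modelling (DCM) of task fMRI, with
group-level random-effects Bayesian model selection and Bayesian
parameter averaging.

## The problem

How does the dorsolateral prefrontal cortex (DLPFC) regulate access of
novel information to working memory through the anterior striatum?  A
standard way to ask this with fMRI is effective-connectivity modelling:
posit a small directed network — here DLPFC ⇄ striatum with bidirectional
intrinsic coupling — let the experimental conditions of a Sternberg
item-recognition task (encoding/retrieval × novel/practiced) drive the
regions and modulate the connections, fit every structural variant of
that network to each subject's region time series, and ask which
structure the group's data support.  `bidcm` implements this analysis as
a reusable, tested Python package, together with a synthetic-data
generator that emulates the paradigm (74 subjects, TR = 1.79 s, 3.5-s
encoding, 22-s probe trains), so the whole pipeline runs and is testable
without any data downloads.

## The model

Neural states x (one per region) follow the deterministic bilinear
equation

    dx/dt = (A + Σ_j u_j(t) B_j) x + C u(t)

with intrinsic coupling A, condition-specific modulations B_j (the two
encoding conditions may modulate each directed connection) and driving
inputs C over the four condition inputs (EN, EP, RN, RP).  A balloon/
Windkessel haemodynamic cascade per region maps x to BOLD.  Systematic
variation of modulations (2⁴ = 16 patterns = model families) and input
routings (2⁴ − 1 = 15 non-empty patterns) yields 240 candidate models.

Each model × subject is inverted by variational Laplace — Gauss–Newton
ascent on the free energy F = accuracy − KL(posterior‖prior) — giving a
Gaussian parameter posterior and F as the evidence approximation.
Group inference is random-effects BMS: a Dirichlet posterior over model
frequencies, exceedance probabilities by Monte-Carlo, the Bayes omnibus
risk BOR (posterior probability that all models are equally frequent)
and protected exceedance probabilities pxp = xp·(1−BOR) + BOR/M.  Family
inference equalises prior mass across families; the winning model is
summarised across subjects by precision-weighted Bayesian parameter
averaging.

## Worked example

Simulate one subject from the structure reported best for this paradigm
(all condition inputs to DLPFC only, full modulation of both
connections), add AR(1) noise at SNR 1, and fit the generating model:

```python
import numpy as np
import bidcm

space = bidcm.enumerate_models()          # 240 models, 16 families
st = space.model(space.winner_model_id)
print(bidcm.describe_model(space, space.winner_model_id))

params = bidcm.default_group_params(st)   # group-mean parameters (Hz)
design = bidcm.build_design(seed=1)       # 16-trial Sternberg session
inputs = bidcm.design_to_inputs(design)   # EN/EP/RN/RP on microtime grid

rec = bidcm.simulate_bold(params, inputs, structure=st, subject_id="sub-01")
lam = -2 * np.log(rec.y.std(axis=0))      # noise SD = signal SD (SNR 1)
noisy = bidcm.add_noise(rec, lam, rho=0.2, seed=7)

res = bidcm.BilinearDCM(noisy, st, inputs).fit()
print(res.summary())
```

```
Bilinear two-region DCM (variational Laplace)
subject: sub-01   model: 234
free energy: 897.57 nats   iterations: 36   converged: True

parameter                     post. mean  post. sd
A_self_DLPFC                      0.0009    0.0619
A_self_Striatum                  -0.0214    0.0612
A_DLPFC->Striatum                 0.4640    0.0768
A_Striatum->DLPFC                 0.2481    0.0556
B_EN_DLPFC->Striatum              0.5644    0.3262
...
```

The self-connection entries are log-deviations from −0.5 Hz; the
coupling rows are in Hz.  The fitted `A_DLPFC->Striatum` (0.46 ± 0.08)
and `B_EN_DLPFC->Striatum` (0.56 ± 0.33) recover the generating values
(0.45 and 0.50): at SNR 1 the strong top-down coupling is sharply
identified while single-subject modulation estimates remain uncertain —
which is exactly why the analysis pools subjects.

Group-level selection on a subjects × models free-energy matrix:

```python
F = np.random.default_rng(0).normal(0, 2, (12, 4))
F[:, 1] += 8                              # model 1 dominates
bms = bidcm.RandomEffectsBMS(F).fit(seed=0)
print(bms.summary())
```

```
Random-effects BMS
models: 4   subjects: 12
converged: True (4 iterations)
Bayes omnibus risk: 0.0000
 model     alpha    E[r]      xp     pxp
     0     1.000   0.063   0.000   0.000
     1    12.996   0.812   1.000   1.000
     2     1.001   0.063   0.000   0.000
     3     1.002   0.063   0.000   0.000
```

Behavioural validation of the paradigm (paired t tests on the calibrated
synthetic cohort):

```python
table = bidcm.generate_behavior(bidcm.BehaviorSpec(seed=0))
out = bidcm.behavior_tests(table)
print("rt:", out["rt"].summary())
```

```
rt: t(73) = 13.90, p = 3.43e-22, mean difference = 52.45 [44.92, 59.97]
```

## Full pipeline and CLI

`bidcm.run_pipeline` (or the `bidcm` command line: `simulate`, `fit`,
`bms`, `bpa`, `run`, `report`) executes the three-step group analysis on
a dataset directory: fit models × subjects (cached, resumable), family-
level BMS, model-level BMS with protected exceedance inside the winning
family, and BPA of the winning model, plus the behavioural tests —
written to a JSON report.

```bash
bidcm simulate /tmp/cohort --n-subjects 12 --seed 1
bidcm run config.yaml
```

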
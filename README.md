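# gazeflow

Analysis pipeline for studying how human agents embedded in a virtual city
reshape visual exploration and spatial learning. Participants freely explore
a VR environment while a head-mounted eye tracker records gaze at 90 Hz;
agents are placed so that their implied action matches the surrounding
location (congruent), mismatches it (incongruent), or carries no object
(acontextual). The pipeline quantifies how encounters with these agents
change the *structure* of scanning — not just where people look, but how
predictably their gaze moves — and whether those changes carry over into
spatial memory measured by a pointing task.

The raw recordings of such a study are not distributable, so the package
ships a synthetic-data generator that reproduces the statistical structure
the analysis assumes (category-labelled fixation sequences driven by Markov
transition matrices, Gamma dwell durations, agent encounters that flatten the
post-encounter transition structure, and pointing errors from a Gamma–log
model). Every stage is exercised end to end against that generator.

## The measures and models

**Gaze transition entropy (GTE).** Each fixation is assigned to one of 8
visual categories (background, buildings, task-relevant residential/public
buildings, landmarks, and the three agent types). Forward transitions between
consecutive fixations give a count matrix; each row's conditional
distribution gets a Chao-Shen bias-corrected Shannon entropy

H(X) = − Σₓ p̂(x)·log₂ p̂(x) / la(x),  p̂(x) = C·p_ML(x),  C = 1 − S₁/N,

where S₁ counts transition types seen once in the row and la(x) =
1 − (1 − p̂(x))^N is the probability of having observed x at all. Rows are
averaged with stationary-distribution weights π (principal left eigenvector
of the row-normalized matrix) and normalized by log₂ k, so H_norm ∈ [0, 1]:
0 = fully predictable scanning, 1 = maximally dispersed.

**Agent-locked windows.** Every retained fixation on an agent (first valid
fixation per agent collider within 30 s, both windows inside the session)
defines a 30-s pre window and a 30-s post window; GTE is computed per window.

**Five Bayesian hierarchical models** (MCMC via an ensemble sampler, priors
N(0,1) on slopes, Cauchy(0,2.5) / Student-t(3,0,2.5) on intercepts and group
SDs, non-centered random intercepts):

| model | likelihood/link | fixed effects | grouping |
|---|---|---|---|
| DWELL | Gamma, log | object kind × agent congruency | participant, session-in-participant |
| PREPOST | Beta, logit | pre/post + spline s(k, 5) over encounter index | participant, session-in-participant |
| POSTGTE | Beta, logit | agent type, sum-to-zero coded | participant, session-in-participant |
| PERF | Gamma, log | agent type + building type + GTE + z-scored dwells | participant × start location |
| MEDIATOR | Beta, logit | agent type + building type | participant × start location |

Entropy responses are squeezed into (0,1) with the Smithson–Verkuilen map
H* = (H(n−1) + 0.5)/n before Beta fitting.

**Counterfactual mediation.** Parametric g-computation pairs one
mediator-model draw with one outcome-model draw per replication, plugs the
plug-in mediator mean under each agent level into the outcome model, averages
over building context with empirical weights, and reports natural direct,
indirect and total effects (NDE = Y₁₀−Y₀₀, NIE = Y₁₁−Y₁₀, TE = Y₁₁−Y₀₀) with
risk-ratio counterparts; TE = NDE + NIE and RR_TE = RR_NDE·RR_NIE hold
exactly per draw.

## Worked example

```bash
python analysis/01_simulate.py 0        # 8 sessions, 90 Hz samples
python analysis/02_classify_fixations.py
python analysis/03_entropy.py
python analysis/04_encounter_windows.py
python analysis/05_descriptives.py
python analysis/06_fit_models.py 0
python analysis/07_mediation.py 0
python analysis/08_report.py
```

With seed 0 the early stages print:

```
simulated 8 sessions (432,000 gaze samples, 8,203 fixations)
classified 8,202 fixations (ground truth 8,203); recovery 100.0%
normalized GTE by condition (mean +- sd):
  congruent    0.764 +- 0.021 (n=4)
  incongruent  0.809 +- 0.014 (n=4)
223 encounters retained (223 with both windows)
window GTE pre 0.763, post 0.806; paired diff +0.043 +- 0.007 (SE)
```

The classifier recovers essentially every generated fixation; incongruent
sessions scan more diffusely than congruent ones (higher normalized GTE);
and the 30-s windows around agent encounters show the post-encounter rise in
scanning entropy that the PREPOST model then estimates on the logit scale.
The mediation stage ends with, e.g.

```
incongruent vs acontextual (R=4000, w_pub=0.51):
 NDE -6.81 [-10.28, -3.93]   RR_NDE 0.839
 NIE +0.01 [ -0.12,  0.14]   RR_NIE 1.000
 TE  -6.81 [-10.24, -3.92]   RR_TE  0.839
identity: NDE+NIE-TE = 0.0
```

read as: on this synthetic run the incongruent condition lowers expected
pointing error by ~16% almost entirely through the direct path, the
GTE-mediated path is null within Monte-Carlo error, and the additive
decomposition is exact.

The same stages are scriptable through the `gazeflow` CLI
(`simulate | classify | entropy | windows | describe | fit | mediate |
report`).

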
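# igtlab

Computational modeling of the Iowa gambling task (IGT): the task
environment, the two most recent reinforcement-learning models of IGT
choice — **ORL** (outcome-representation learning) and **VSE** (value
plus sequential exploration) — together with the classic EV/PVL family,
choice-pattern classification, parameter space partitioning (PSP),
synthetic cohort generation, and hierarchical Bayesian fitting with
AIC/BIC/WAIC model comparison.

It is written for computational cognitive scientists who want to ask
not only *how well does a model fit IGT data?* but also *what range of
behaviors can the model produce at all?* — the flexibility/
generalizability question that PSP answers by mapping a model's entire
parameter space to the choice patterns it generates.

## The task and the models

Four decks (A–D) are drawn card by card for 100 trials.  A and B pay
100 points per card but lose 1250 per block of 10 (A: five losses of
250; B: one loss of 1250), netting −250 per block; C and D pay 50 and
lose 250 per block (C: five of 50; D: one of 250), netting +250.  C and
D are therefore *good* decks, A and C the *frequent-loss* decks.

**ORL** tracks, per deck j, an expected value, a win frequency, and a
perseverance trace:

    EV_j ← EV_j + A·(x − EV_j)            A = A_rew if x ≥ 0 else A_pun
    EF_j ← EF_j + A·(sgn(x) − EF_j)       chosen deck
    EF_j' ← EF_j' + A·(−sgn(x)/3 − EF_j') each unchosen deck
    PS_j = 1/(1+K) if chosen, PS_j/(1+K) otherwise,   K = 3^K' − 1
    V_j = EV_j + EF_j·β_F + PS_j·β_P,     P(j) ∝ exp(V_j)

**VSE** splits value into exploitation and directed exploration:

    v = Gain^θ − Loss^θ
    Exploit_d ← Exploit_d·Δ (+ v if chosen)
    Explore_d ← 0 if chosen, else Explore_d + α·(φ − Explore_d)
    P(d) ∝ exp((Explore_d + Exploit_d)·c),   c = 3^β − 1

Outcomes are rescaled by 1/100 before entering either model (a
configurable `outcome_scale`).

A subject's 100 choices are classified by two contrasts —
`d_value = (C+D) − (A+B)` and `d_freq = (B+D) − (A+C)` — into
Good-Over-Bad / Bad-Over-Good / Infrequent-Over-Frequent /
Frequent-Over-Infrequent (broad definition; a restricted definition
additionally requires the dominant pair to reach 65 of 100 choices).
Sequential-exploration indices DE3/DE4 count sliding windows of 3/4
distinct decks, DE4F counts distinct-deck chunks among the 25 fixed
blocks of 4.

## Worked example

```python
from igtlab import (build_standard_schedule, simulate_agent, ORLParams,
                    count_choices, classify_broad, classify_restricted,
                    seqe_indices, run_psp, GridSpec)

params = ORLParams(a_rew=0.35, a_pun=0.10, k_prime=1.0, beta_f=2.0, beta_p=1.0)
sched = build_standard_schedule(100, seed=7)
seq = simulate_agent("ORL", params, sched, seed=11)
counts = count_choices(seq)
print("deck counts:", counts)
print("broad label:", classify_broad(counts))
print("restricted label:", classify_restricted(counts))
print("SeqE:", seqe_indices(seq))
```

prints

```
deck counts: PatternCounts(na=7, nb=45, nc=2, nd=46)
broad label: IOF
restricted label: IOF
SeqE: SeqEIndex(de3=5, de4=0, de4f=0)
```

— this agent's low punishment learning rate and positive frequency
weight pull it to the infrequent-loss decks B and D (91 of 100 picks,
an Infrequent-Over-Frequent pattern under both definitions), and its
near-zero DE indices show it exploits rather than sweeping through all
four decks.  A desk-scale PSP run then asks how typical that pattern is
of the model as a whole:

```python
r = run_psp("ORL", GridSpec("ORL", n_points=6), seed=1)
for k, v in r.broad.items():
    print(f"  {k:10s} {v:.3f}")
```

```
  GOB        0.411
  BOG        0.072
  IOF        0.086
  FOI        0.430
  Remaining  0.000
```

ORL's parameter space is heavily concentrated on Good-Over-Bad and
Frequent-Over-Infrequent behavior; IOF agents like the one above come
from a small region.

The same workflow is scriptable from the shell:

```sh
igtlab psp --model orl --points 10 --seed 1 --out psp_orl.json
igtlab generate --style gob --seed 0 --out trials.csv --meta meta.json
igtlab fit --model vse --data trials.csv --seed 1 --out fit_vse.json
igtlab compare fit_orl.json fit_vse.json
igtlab run --config run.yaml        # full generate→classify→psp→fit→compare
```

Hierarchical fits place each subject's five parameters under group-level
normals in probit-transformed space and are sampled by a
Metropolis-within-Gibbs backend (alternatives: emcee ensemble,
importance-corrected Laplace, mean-field); `compare` applies the
decision rule that a model is superior only when AIC, BIC and WAIC all
agree *and* |ΔWAIC| exceeds the larger WAIC standard error.

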
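# rhdrisk

Probabilistic risk model for transfusing **RhD-positive red cells or low-titre
group O whole blood (LTOWB)** to bleeding trauma patients in the prehospital
setting.

Blood services face a supply squeeze on group O D-negative units. Issuing
D-positive units prehospital would relieve it, but risks harming recipients who
turn out to be D-negative — above all females of childbearing potential (CBP,
under 50), who may form anti-D and lose a child to haemolytic disease of the
foetus and newborn (HDFN) in a future pregnancy. This package is for
transfusion-medicine researchers and blood-service policy analysts who want to
quantify those risks, with honest uncertainty, before changing policy.

## The model

Three harms are modelled, each requiring an ordered chain of contingent events
`X1, …, Xk` (e.g. *recipient is D-negative* → *recipient survives* → *forms
anti-D* → *future pregnancy* → *foetus D-positive* → *severe HDFN*):

* haemolytic transfusion reaction (HTR) at the **index** transfusion,
* HTR at a **future** transfusion,
* **HDFN** death or lifelong disability in a future pregnancy.

With conditional probabilities `N1, …, Nk` for the chain events, the
per-transfusion probability of a harm is the product

```
P(harm) = Π_i N_i ,          P(any harm) = Σ_harms P(harm)  (capped at 1),
```

and each input `N_i` is a bounded probability *distribution* (point, uniform,
triangular, beta or log-uniform) expressing how uncertain its value is. A
Monte Carlo simulation (default 1000 iterations) draws one value per input per
iteration, producing a distribution of harm probabilities summarised as a mean
and an equal-tailed 95% credibility interval, reported in reciprocal form —
"one event per N transfusions". Scaling by the annual number of prehospital
transfusion episodes (incidence × population / 10⁶ × subgroup fraction) turns
risks into expected **years to first event**; a bootstrap compares life-years
gained from a survival benefit of whole blood against life-years lost to HDFN
(83 years per event); and first-order Sobol indices
`S_i = Var(E[Y|N_i]) / Var(Y)` rank which input uncertainties drive the output
uncertainty.

Two populations share one chain definition: *all recipients*, and *D-negative
females of CBP*, for whom the subgroup-defining events are overridden to
probability 1.

The shipped `default_config.yaml` carries the full 14-event, 3-harm,
2-population structure with **placeholder** uncertainty bands of plausible
magnitude; reproducing any published table requires transcribing the original
input distributions into the same schema (see `docs/methods.md`).

## Worked example

```bash
rhdrisk run src/rhdrisk/data/default_config.yaml --out out/
rhdrisk tables out/results.json
```

prints (placeholder inputs, seed 1234, 1000 iterations):

```
Risk of harm (one event every N transfusions, 95% CI)
  htr_index    1 in 22000 (10000–65000)  |  1 in 3400 (1600–9300)
  htr_future   1 in 160000 (58000–680000)  |  1 in 24000 (9000–100000)
  hdfn         1 in 33000 (14000–110000)  |  1 in 500 (230–1500)
  any_harm     1 in 12000 (6900–26000)  |  1 in 430 (210–1100)

Years to first event
  [all_recipients] transfusions/year: 5561
    htr_index    4 (1.8–12)
    ...
  [dneg_females_cbp] transfusions/year: 100
    hdfn         5 (2.3–15)
    any_harm     4.3 (2.1–11)
```

Left column: all recipients; right: D-negative females of CBP. Under these
placeholder inputs a severe HDFN case would be expected roughly once per 500
D-positive transfusions to the subgroup — about one every 5 years in England
at ~100 subgroup episodes/year. The same run via the library:

```python
import rhdrisk

cfg = rhdrisk.default_config()
est = rhdrisk.run_simulation(cfg, "dneg_females_cbp")
print(est["hdfn"].summary()["display"])   # {'one_in': '1 in 500', 'ci': [230.0, 1500.0]}

res = rhdrisk.tradeoff_bootstrap(est["hdfn"].samples, cfg.life_years, seed=0)
print(res.break_even_benefit)             # 0.885  (% survival improvement)
```

The trade-off result reads: with these inputs one can be 95% confident that a
survival improvement of ≥ 0.885 percentage points from whole-blood transfusion
gains more life-years than HDFN loses. Other subcommands: `validate`,
`sensitivity` (Sobol indices + scatter CSV), `tradeoff`, `scenario`
(synthetic configs with closed-form ground truth).

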
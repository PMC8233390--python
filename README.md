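# flocklearn

Tools for asking whether wild predators learn about food from each other,
and whether that learning travels along their social network.  The package
targets the kind of data produced by RFID-logged feeder arrays visited by
mixed flocks of birds (e.g. blue tits and great tits, adults and
juveniles): every visit is a timestamped record of who chose which of two
differently coloured foods, one palatable and one not.

## What it computes

1. **Gathering events** — temporal clusters of visits at each station,
   found by BIC-selected 1-D Gaussian mixtures over visit timestamps
   ("gambit of the group": birds in the same cluster are associating).
2. **Association network** — the simple ratio index for each pair,
   `SRI = x / (x + y_A + y_B + y_AB)`, the fraction of sampling periods in
   which the two birds were in the same group; plus its *homogenized*
   null counterpart (each column replaced by its mean, total audience
   preserved).
3. **Expected observations** — for every choice by bird *i* at time *t*,
   the network-weighted count of feeding events it could have witnessed,
   `O±_i(t) = Σ_{j≠i} N±_j(t) a_ij`, split by the demonstrator's age and
   species relation to the chooser.
4. **Choice models** — binomial mixed models (per-bird random intercept,
   adaptive Gauss–Hermite quadrature) of each choice:
   `p(unpalatable) = logit⁻¹(α + β_asoc+ N+ + β_asoc− N− + β_soc+ O+ + β_soc− O− + B_i)`,
   with demonstrator-class splits, difference reparameterisations, daily
   learning curves, and AIC comparison.
5. **Network-effect null test** — re-simulates the choices under
   *homogenized* social learning (same fitted effect sizes, every bird
   equally likely to observe every feed), refits, and locates the observed
   Wald Z in the null Z distribution (distance-from-mean simulation
   p-value `p_s`).
6. **Order-of-acquisition diffusion analysis (OADA)** — for reversal
   learning: the rate at which a naive bird first samples the
   previously-avoided food is `exp(β_A x_i) + Σ_m s_m exp(β_S x_i)
   Σ_j a^(m)_ij z_j(t)`; transmission rates `s_m` per demonstrator-class
   network, species individual-level variables, AICc model sets with
   Akaike weights, profile-likelihood CIs, and the percentage of
   acquisitions attributable to social transmission (%ST).

A fully seeded synthetic-data generator (`flocklearn.synthetic_data`)
produces visit streams, choice outcomes, and reversal diffusions from these
same models with known parameters, so every stage of the pipeline can be
validated against ground truth.  See `docs/methods.md` for the models,
defaults, and limitations.

## Worked example

Simulate a 50-bird colony, estimate its network from pre-training visits,
fit the social/asocial choice model to the avoidance phase, and run the
diffusion analysis on reversal learning:

```python
import numpy as np
import flocklearn as fl
from flocklearn import oada as od
from flocklearn.association_network import AssociationMatrix
from flocklearn.choice_models import model_spec

cfg = fl.SimConfig(n_birds=50, seed=2)
roster, true_net = fl.simulate_population(cfg)

pre, _ = fl.simulate_pretraining_stream(roster, cfg)
events = fl.detect_events(pre, seed=2)
net_hat = fl.sri(events, roster)

am = AssociationMatrix(birds=list(roster["bird_id"]), weights=true_net)
visits, _ = fl.simulate_avoidance_stream(roster, true_net, cfg)
table = fl.build_choice_table(visits, am, roster)
fit = fl.fit_choice_model(table, model_spec("base"))

diff = fl.simulate_reversal_diffusion(roster, true_net, cfg)
rev = diff.to_visit_table(roster, cfg)
data = od.build_acquisition_order(rev, cfg.colour_pair[0], roster=roster)
m = od.fit_oada(data, od.OadaSpec(network_class="observed", by_age=True),
                network=am, seed=2)
```

Output of the accompanying prints:

```
4892 pre-training visits -> 182 gathering events
estimated SRI network: MAE vs closed-form truth 0.056
4496 avoidance choices by 50 birds
beta_soc- = -0.0679 +/- 0.0264 (truth -0.05), z = -2.57
OADA (truth s_adult=10, s_juv=0): s_adult = 4.94 (95% CI 1.22-25.72), s_juvenile = 0.00
77% of acquisitions attributed to the adult network; Akaike weight on observed-network models 100%
```

Reading the numbers: the detected events yield a network close to the
generator's closed-form association probabilities; the fitted social
avoidance coefficient `β_soc−` is negative (each expected observation of a
negative feeding event lowers the odds of choosing the unpalatable colour)
with the true value inside its CI; and the diffusion analysis attributes
the reversal spread to the adult-demonstrator network, with the juvenile
rate on the zero boundary — matching how the data were generated.

## Command line

A thin CLI wraps the library for file-based runs:

```sh
flocklearn simulate     --config cfg.yaml --seed 1 --out simdata
flocklearn run          --config cfg.yaml --seed 1
flocklearn null-test    --config cfg.yaml --n-sims 1000
flocklearn fit-oada     --config cfg.yaml
```

`cfg.yaml` names the visit/roster CSVs (or a `simulate:` block), the
colour→palatability map, phase labels, and the null-test and OADA
settings; every output embeds the config hash and seed, and a rerun with
the same seed is byte-identical.

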
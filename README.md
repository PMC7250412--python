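# clotsim

A kinetic ODE model of coagulation and fibrinolysis centred on the
two-binding-site pharmacodynamics of tranexamic acid (TXA) on
plasmin(ogen). The package simulates TF-initiated thrombin generation and
clot formation, plasminogen activation by tPA (fibrin-templated) and uPA
(solution-phase), the plasmin-inhibitor system (antiplasmin, α1-antitrypsin,
α2-macroglobulin, PCI, PAI), and the resulting clot-lysis dynamics — and
reproduces the in-silico experiments in which TXA switches from
anti-fibrinolytic to pro-fibrinolytic behaviour depending on the
tPA:uPA balance and the presence of the secondary plasmin inhibitors.

## Model highlights

* Plasminogen carries two independent TXA sites: the low-affinity **x**
  site (Kd = 600 µM) whose occupancy speeds uPA-mediated activation
  3-fold, and the high-affinity **y** site (Kd = 1.1 µM) through which
  plasmin(ogen) binds fibrin and is attacked by antiplasmin. Site
  occupancy expands the zymogen into Pg/Pgx/Pgy/Pgxy and plasmin into
  Pn/Pny.
* tPA activates only y-free plasminogen, with catalytic efficiency scaled
  up to exactly 500-fold by a saturating fibrin-cofactor term; uPA
  activates all four variants in solution.
* Inhibitor scopes: antiplasmin reaches y-free plasmin (solution or
  fibrin-bound) and is blocked by y-site TXA (displacement happens through
  the reversible binding equilibrium); A2M/A1AT take any solution-phase
  plasmin but never fibrin-bound plasmin.
* The whole network is data: a versioned JSON model file
  (`src/clotsim/models/full_model.json`, schema in
  `src/clotsim/models/schema.json`); the coagulation cascade ships as a
  separate fragment so fibrinolysis-only simulations can exclude it.
* Stiff BDF integration with exact-arithmetic conserved-moiety analysis
  backing the conservation tests (drift < 1e-6 in every scenario).

## Library use

```python
from clotsim import Scenario, build_full_model, run_dose_sweep

network = build_full_model()
sweep = run_dose_sweep(Scenario(tpa=2.5e-9), network=network)  # molar units
print(sweep.to_frame())          # lysis metrics per TXA dose
print(sweep.classification)      # anti_fibrinolytic / neutral / pro_fibrinolytic
```

Key entry points: `run_dose_sweep` (TXA dose ladder), `run_knockout_panel`
(A2M/A1AT presence–absence grid under uPA), `run_tpa_upa_balance`
(uPA fixed, tPA stepped), `compute_lysis_metrics`, `thrombin_metrics`,
`local_sensitivity`, and the network primitives
(`load_network`, `validate`, `conserved_moieties`, `simulate`).

## CLI

```bash
clotsim simulate --config scenario.json --out timecourse.csv
clotsim sweep    --config scenario.json --out sweep.csv
clotsim panel    --config scenario.json --out-prefix fig5
clotsim balance  --config scenario.json --out-prefix fig6
clotsim metrics  timecourse.csv
```

`--model` points at any schema-conforming model JSON (default: the packaged
full model). Scenario configs are JSON with molar fields
`tf/tpa/upa/txa/ap/a1at/a2m/pci` and an optional `solver` block
(`t_end`, `output_points`, `rtol`, `atol`).

Example config for the uPA hyperfibrinolysis regime:

```json
{"upa": 5e-9, "a2m": 0.0, "a1at": 0.0}
```

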
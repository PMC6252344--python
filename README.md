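# superchild

Population-based ("super-child") compartmental modelling of vitamin A total
body stores and whole-body retinol kinetics in children.

## The problem

Vitamin A status in children is best quantified as total body stores (TBS,
µmol), but the reference technique — retinol isotope dilution (RID) after an
oral dose of stable-isotope-labeled retinyl acetate — relies on coefficients
that account for absorption, retention and tracer mixing, and classical
compartmental modelling needs many blood samples per child. The super-child
design sidesteps both problems: every child gives only **two** samples (all
children at 4 d plus one additional randomized time), a composite
geometric-mean plasma tracer curve is modelled for the whole group, and the
fitted population model supplies both group kinetics and population-specific
RID coefficients for individual TBS prediction.

This package implements the full theoretical validation of that design for
public-health nutrition researchers: it generates cohorts of *theoretical
children* with known (assigned) kinetics, simulates their plasma tracer
responses, builds the composite data sets for three sampling protocols, fits
them, and measures how well the known group and individual TBS are
recovered.

## The model

Oral tracer passes through gastrointestinal processing (compartments 1–2),
a discrete transit delay DT(3) (where the unabsorbed fraction, 1 − 0.8 by
default, is lost), and hepatic processing (compartment 4) before reaching
the plasma retinol pool (compartment 5). Plasma exchanges with a slow
storage pool (compartment 6 ≡ TBS, with irreversible disposal at rate
L(10,6)·M(6)) and optionally a fast extravascular pool (compartment 7).
Transfers are first-order with fractional transfer coefficients L(I,J) per
day; the tracee system is in steady state, so fixing the plasma pool M(5)
back-solves every other mass, in particular

    M(6) = L(6,5)·M(5) / (L(5,6) + L(10,6)).

Composite curves are fitted by weighted nonlinear least squares with
fractional-SD weights (FSD 0.01; 0.05 with 0.01 at the 4-d anchor for
sparse super-child composites), and one- versus two-pool variants are
compared with an F-test on the weighted sums of squares. RID predicts
individual TBS as

    TBS = Fa × S / SA_p,    Fa × S = M(6)·F(5)(t)/M(5),

where SA_p = FD_p/M(5) is each child's measured plasma specific activity
and Fa × S comes once from the population model.

## Worked example

```python
from superchild import (FitConfig, PopulationTracerModel, REDUCED11,
                        build_protocol2, evaluate, generate_cohort)
from superchild.protocols import simulate_cohort_curves
from superchild.rid import predict_cohort

cohort = generate_cohort("high_intake_50", seed=42)   # 50 theoretical children
curves = simulate_cohort_curves(cohort, REDUCED11)    # per-child FD_p
composite = build_protocol2(cohort, curves)           # geometric-mean curve
model = PopulationTracerModel(composite, cohort.gm_m5,
                              FitConfig("simplified", "auto", 0.01))
results = model.fit(seed=42, known_tbs=cohort.gm_tbs)
print(results.summary())

fas4 = results.rid_coefficients([4.0]).at(4.0)        # population Fa x S
pred = predict_cohort(fas4, cohort, 4.0)              # per-child RID
print(evaluate(pred.predicted_tbs, pred.assigned_tbs).summary())
```

prints (abridged):

```
model variant: simplified   extravascular pools: 2
...
M(6) = TBS                 519.7 µmol
dietary input U            5.248 µmol/d
MST_RBP                   0.5362 d
pool selection: F = 986.3, P = 4.095e-06, rule = f_test

within 25% of assigned:   74%
within 50% of assigned:   98%
mean predicted/assigned:  1.02 (range 0.51-1.52)
Spearman Rs:              0.83 (P = 4.9e-14)
```

The fitted population TBS (519.7 µmol) recovers the known group geometric
mean (528.5 µmol) within 1.7%; applying the single population coefficient
Fa × S(4 d) = 0.85 with each child's own 4-d specific activity ranks the 50
children correctly (Rs = 0.83) and puts 74% of individual predictions
within 25% of their assigned stores.

## Command line

The whole validation (cohort → protocols 1–3 → fits → RID → evaluation,
all outputs as delimited/structured text with a checksummed manifest) runs
from a shell:

```sh
superchild run-all --seed 7 --out run7
superchild report --run-dir run7     # pass/fail table of the criteria
```

Individual stages (`generate`, `simulate`, `protocols`, `fit`, `rid`,
`evaluate`) are also exposed; identical seed and configuration give
byte-identical outputs.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
re-runs the complete validation pipeline from scratch at the given seed and
writes the headline quantities (group-TBS recovery for each protocol,
per-scenario RID coverage bands, rank correlation, 7-d versus 4-d
comparison, coefficient levels) as JSON. See `docs/methods.md` for what the
generator emulates, every tunable default, and known limitations.
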
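# irmsim

Polygenic truncation-selection model of insecticide resistance evolution
under insecticide decay, for comparing insecticide resistance management
(IRM) strategies in malaria vector control.

## The problem

Long-lasting insecticidal nets and indoor residual sprays lose killing
efficacy over the months after deployment, yet most models used to compare
IRM strategies — deploy insecticides one at a time in sequence, or together
as a mixture? full dose or reduced dose? — assume constant efficacy.
`irmsim` models resistance to each insecticide as a polygenic quantitative
trait (the *polygenic resistance score*, PRS) and asks how decaying efficacy
changes (a) the per-generation selection pressure for resistance and (b)
which deployment strategy keeps insecticides effective longer.

It is written for quantitative entomologists and infectious-disease
modellers: everything is a plain function or dataclass over numpy/pandas,
with a thin `irmsim` command-line wrapper.

## The model

Resistance of a population to insecticide *i* is summarised by the mean PRS
z̄_I with fixed phenotypic standard deviation σ (default 20). Mean PRS maps
to the operational measurement, bioassay survival, through a
Michaelis–Menten/Hill curve

    K_B = z̄ⁿ / (z̄ⁿ + Kⁿ)        (K = 900, n = 1)

and bioassay survival maps to expected field survival of exposed mosquitoes
under current efficacy ω as `1 − ω·(1 − (φ₁K_B + φ₂))`, clamped to [0, 1]
(φ₁ = 0.48, φ₂ = 0.15). Survival of exposure is by truncation: the top-p
fraction of the trait distribution survives, so among exposed survivors the
mean shifts by σ·i(p), with i(p) the standard-normal tail intensity. A
fraction 1 − x of the population escapes exposure and dilutes the survivors,
giving the monotherapy selection differential

    S = x·p·σ·i(p) / ((1 − x) + x·p),

and for a mixture (sequential truncation by both components)

    S_i = x·p_i·p_j·σ·i(p_i) / ((1 − x) + x·p_i·p_j).

Between generations the mean responds via the sex-specific Breeder's
equation R = h²·(S_♀ + S_♂)/2·β, plus a correlated response
α·√(h²_I h²_J)·S̄_j·β for cross resistance α. Deployed efficacy follows a
two-stage linear decay (slow base rate for 15 generations, then 0.08 per
generation), refreshed at scheduled redeployments every 30 generations. The
multi-generation simulator tracks a treated deme and untreated refugia
coupled by dispersal, withdraws insecticides at 10% bioassay survival
(returning them below 8%), and reports strategy lifespans in years
(10 generations/year, capped at 50 years).

## Worked example

```python
from irmsim import (PopulationState, Monotherapy, ExposureConfig, ModelParams,
                    single_generation_step, prs_to_bioassay, StrategyConfig,
                    compare_strategies)

state = PopulationState(mean_prs_i=100.0, sigma=20.0)   # 10% bioassay survival
outcome, new = single_generation_step(
    state, Monotherapy("i", efficacy=1.0), ExposureConfig(female_exposure=0.7),
    ModelParams(),
)
print(f"selection differential (female): {outcome.differential_female_i:.2f} PRS units")
print(f"response to selection:          {outcome.response_i:.2f} PRS units")
print(f"bioassay survival: {100*prs_to_bioassay(state.mean_prs_i):.1f}% -> "
      f"{100*prs_to_bioassay(new.mean_prs_i):.1f}%")
print(f"degree of control: {outcome.degree_of_control:.2f}")

diff, mix, seq = compare_strategies(StrategyConfig(record_trajectory=False))
print(f"mixture lifespan:  {mix.lifespan_years:.1f} years")
print(f"sequence lifespan: {seq.lifespan_years:.1f} years")
print(f"difference:        {diff:+.1f} years")
```

prints

```
selection differential (female): 8.88 PRS units
response to selection:          1.78 PRS units
bioassay survival: 10.0% -> 10.2%
degree of control: 0.56
mixture lifespan:  22.1 years
sequence lifespan: 20.2 years
difference:        +1.9 years
```

A population at 10% bioassay survival exposed at 70% to a full-dose
insecticide gains 1.78 PRS units per generation (+0.2 percentage points of
bioassay survival) while 56% of adult females are killed. Over many
generations with default two-stage decay, the full-dose mixture outlasts the
monotherapy sequence by 1.9 years — far less than the ~20-year advantage the
same comparison gives when decay is ignored (`DecayProfile(mode="none")`).

## Command line

```sh
irmsim singlegen --mode mixture --out mixture_grid.csv   # 60,840-cell sweep
irmsim strategy --out comparison.csv --trajectory traj.csv
irmsim scenario 1 --out scenario1.csv                    # 90 comparisons
irmsim oracle --out oracle.csv --n 200000                # Monte-Carlo check
```

Each command accepts `--config config.yaml`; an empty file means all
defaults, unknown keys are rejected. CSVs carry a metadata header (version,
config hash, seed, column units).

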
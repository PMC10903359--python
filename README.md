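# surveycost

Cost-effectiveness analysis of ecological survey methods: beach seining,
species-specific qPCR, and eDNA metabarcoding.

Managers choosing how to monitor an estuarine fish — or a whole fish
community — face methods that differ both in what a sample detects and in
what a sample costs. `surveycost` makes that trade-off explicit. It pairs a
survey cost model (in the common currency of technician-hours) with a
detection-probability model for single-species surveys and a
species-accumulation model for community surveys, then sweeps survey-design
scenarios to produce detection-versus-cost and richness-versus-cost curve
tables. It also implements the consensus-taxonomy procedure used to turn
metabarcoding ASV hit tables into a defensible species list.

## The models

**Cost.** A program visits `L` locations; at each, `k` sites are visited and
`n` samples taken per site. Investment per location is

    H = fixed + variable
    fixed    = (P + G + A)/L + B + W·V + R
    variable = k·(v + n·(t·W + E + D + q))

with permit management `P`, gear `G`, assay development `A`, background
knowledge `B`, crew size `W`, per-visit travel `V`, reporting `R`, per-site
time `v`, per-sample field time `t`, environmental impact `E`, data entry
`D`, and sequencing `q` — all in technician-hours ($30/h conversion helper
included). Default parameters for five method columns (qPCR, goby/fish
metabarcoding, goby/fish seining) ship with the package.

**Detection.** Per-sample detectability γ is estimated by a binomial GLM
(logit link) on site and method factors; effort converts to cumulative
detection `d = 1 − (1 − γ)^(n·k)` with Wald CIs mapped through the monotone
transform. A "rare-case" parameterization for a low-detection site ships as
a constant set: γ = 0.62 (CI 0.42–0.78) for the eDNA methods, γ = 0.25
(CI 0.12–0.43) for seining.

**Species accumulation.** Collector's curves are built by resampling random
orderings of sites (1,000 by default), then fitted with the Polce–Kunin
multi-scale model `S = (a + k^z·n^c)/(b + n^c)`, where `z` grows with beta
diversity among sites — so the fitted curve can be projected to unsampled
effort levels and linked to cost.

**Consensus taxonomy.** ASVs with < 8 reads are dropped; only maximum
percent-identity hits are kept; hits absent from a user-supplied plausible
species list are reassigned to their closest plausible relative; multiple
surviving candidates collapse to their lowest common taxon; non-estuarine
taxa are flagged as exogenous DNA (e.g. transported in bird feces).

## Worked example

Price a one-location, one-site, one-sample goby seining survey with the
packaged parameter table:

```sh
$ surveycost cost --method goby_seine --L 1 --k 1 --n 1
fixed_hours=37.0
variable_hours=4.9
total_hours=41.9
```

Fixed costs (permit 15 h + gear 3 h, a four-person crew's travel 16 h,
reporting 3 h) dominate: ~42 h for a single seine haul, versus 12.0 h for a
single metabarcoding water sample (7.5 fixed + 4.5 variable).

How many eDNA samples make detection confident at a low-detection site?

```python
>>> import surveycost as sc
>>> sc.min_samples(0.62, target=0.99)
5
>>> sc.cumulative_detection(0.62, n=1, k=5).d
0.9920764832
```

Five samples exceed a 99% chance of detecting the species where it is
present. Sweeping the full scenario grid and ranking methods by the cost of
reaching 99% detection at a ten-location program:

```python
>>> t1 = sc.default_cost_params()
>>> curves = sc.detection_cost_curves(
...     {"seine": t1["goby_seine"], "qPCR": t1["qPCR"],
...      "metabarcode": t1["goby_metabarcode"]},
...     sc.rare_case_estimates())
>>> sc.summarize_crossovers(curves).query("L == 10 and threshold == 0.99")
```

| method      | scenario  | cost at d ≥ 0.99 (h/location) |
|-------------|-----------|------------------------------:|
| qPCR        | A=0       | 21.05                         |
| qPCR        | A=8       | 21.85                         |
| metabarcode | base      | 29.55                         |
| qPCR        | A=85      | 29.55                         |
| seine       | no_P_no_E | 51.60                         |
| seine       | no_E      | 53.10                         |
| seine       | full      | 104.10                        |

With a validated assay in hand (`A=0`) qPCR is the cheapest route to
confident detection across many locations; metabarcoding wins when an assay
would have to be developed; seining is never the most cost-effective option
at this confidence level, even with its permitting and environmental costs
waived.

Community counts from the packaged published detection table:

```sh
$ surveycost counts --mode edna_all     # 16 taxa detected by eDNA
16
$ surveycost counts --mode seine        # 8 species captured by seine
8
```

Synthetic inputs for every stage (detection records, community matrices,
ASV hit tables with embedded ground truth) come from `surveycost simulate`
or the `surveycost.simulate` module.

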
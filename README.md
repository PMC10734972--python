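# nmaplan

Power and sample-size planning for a new two-arm binary-outcome trial whose
result will be analysed **jointly with an existing network meta-analysis
(NMA)**.

## The problem

Suppose a randomized trial is planned to compare treatments A and B, both of
which already appear in a connected network of earlier trials but have never
been compared head to head. The network supplies an *indirect* estimate of
the A-vs-B log odds ratio with standard error σ<sub>AB,eNMA</sub>. If the
analysis plan is to add the new trial to the network and re-fit, the
precision of the updated estimate is the sum of the trial's and the
network's precisions:

```
σ²_AB,uNMA = ( 1/σ²_AB,trial + 1/σ²_AB,eNMA )⁻¹ ,
σ²_AB,trial = 1/(n_A π_A (1−π_A)) + 1/(n_B π_B (1−π_B)) ,
```

where π<sub>i</sub> are the event risks and n<sub>i</sub> the group sizes.
The two-sided power of the z-test of H₀: lor = 0 at level α is

```
Power = Φ(lor/s.d. − z_{1−α/2}) + Φ(−lor/s.d. − z_{1−α/2})
```

with s.d. the trial-only ("without") or the combined ("with") standard
deviation. `nmaplan` fits the fixed-effect contrast-based NMA by weighted
least squares (μ̂ = (XᵀS⁻¹X)⁻¹XᵀS⁻¹y), extracts σ<sub>AB,eNMA</sub>, and
solves the two design problems:

* **`ssanma`** — fixed total N: the variance-minimising split
  n₁* = N·√a/(√a+√b) with a = 1/(π₁q₁), b = 1/(π₂q₂), rounded to the better
  integer neighbour (this split is the same whichever analysis is planned);
* **`ssnma`** — target power: the target is converted to a required
  standard deviation by root-finding, to a required trial precision
  (subtracting the network precision when analysing jointly), and to
  integer group sizes by the ceiling of the continuous Lagrange solution.

Two Monte-Carlo protocols (fixed-N and target-power) validate the formulas
on synthetic binomial networks, and a brute-force grid search cross-checks
the solvers.

It is aimed at trial statisticians and evidence-synthesis researchers — the
motivating application is veterinary (antibiotic treatments for bovine
respiratory disease in feedlot cattle), but nothing is species-specific.

## Worked example

Risks 0.2 and 0.3, network SE 0.3, target power 0.8, α = 0.05:

```sh
$ nmaplan ssnma --p1 0.2 --p2 0.3 --enma-sigma 0.3 --power 0.8 \
          --method with --allocation uneven
sample_size: 187 163
power: 0.801

$ nmaplan ssnma --p1 0.2 --p2 0.3 --enma-sigma 0.3 --power 0.8 \
          --method without --allocation uneven
sample_size: 317 277
power: 0.801
```

Planning to analyse with the network shrinks the required trial from
594 to 350 subjects at the same power. With a fixed budget of 200 subjects
the best split and its power under each analysis:

```sh
$ nmaplan ssanma --p1 0.2 --p2 0.3 --enma-sigma 0.3 --n-total 200 --method with
sample_size: 107 93
power: 0.679

$ nmaplan ssanma --p1 0.2 --p2 0.3 --enma-sigma 0.3 --n-total 200 --method without
sample_size: 107 93
power: 0.37
```

The same library calls:

```python
from nmaplan import DesignInput, ssnma

sol = ssnma(DesignInput(p1=0.2, p2=0.3, enma_sigma=0.3), power_level=0.8)
print(sol.n1, sol.n2, round(sol.power, 3))   # 187 163 0.801
```

The indirect SE itself comes from contrast-level data
(`studlab,treat1,treat2,TE,seTE` CSV):

```sh
$ nmaplan nma --contrasts network.csv --pair "Ceftiofur pin" "Tildipirosin"
```

and `nmaplan simulate --config scenario.json --out results.csv` runs the
Monte-Carlo protocols (see `docs/methods.md`).

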
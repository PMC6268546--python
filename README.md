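# pampa-skin

Data reduction for PAMPA (Parallel Artificial Membrane Permeability Assay)
skin-permeability screens of topical corticosteroids and their C-21 ester
prodrug candidates. The package turns per-well HPLC measurements of a PAMPA
sandwich (donor at t₀, donor at t, acceptor at t) into:

* the **membrane retention factor** R — the mole fraction lost to the
  membrane and plate materials, from the compartment mass balance
  `R = 1 − C_D(t)/C_D(0) − (V_A/V_D)·C_A(t)/C_D(0)`;
* the **permeation parameter** `C_A(t)/C_D(0)` — the fraction of the initial
  donor amount found in the acceptor after incubation;
* the **effective permeability** Pe (cm/s) from the integrated
  two-compartment first-order transport model with a steady-state lag time
  τ_LAG and a retention-corrected acceptor equilibrium:

  `Pe = −[V_A·V_D / ((V_A+V_D)·A·ε·(t−τ_LAG))] · ln(1 − (V_A+V_D)/((1−R)·V_D) · C_A(t)/C_D(0))`

  where `A·ε` is the filter area times its nominal porosity;
* the predicted **human-skin permeability** log K_p via the published linear
  correlation for the 70% silicone-oil / 30% isopropyl-myristate membrane,
  `log K_p = (1.34 ± 0.12)·log Pe + (0.28 ± 0.56)`;
* a **permeate group label**: I (retention and permeation both < 30%),
  II (low retention, permeation ≥ 30%), III (retention ≥ 30%, low
  permeation — the membrane acting as a trap, the profile desired of a
  topical prodrug).

A two-compartment kinetic simulator generates synthetic plates from known
ground truth (Pe, R, peak-area noise), so the whole pipeline is testable
without wet-lab data. A packaged 26-compound reference table (20 synthesized
corticosteroid C-21 esters + 6 standards) ships with the package.

Intended users: medicinal chemists and ADME scientists reducing 96-well
PAMPA skin screens, and anyone needing a reproducible reference
implementation of the retention/permeability algebra.

## Worked example

Simulate a noisy plate over a small Pe × retention grid, analyze and
classify it:

```bash
pampa-skin simulate --pe 3e-6 --pe 5e-5 --retention 0.05 --retention 0.6 \
    --noise-cv 0.02 --seed 42 --out demo
pampa-skin analyze demo/plate.csv --out demo_results
```

`demo_results/summaries.csv` (selected columns):

```
compound,n,R_pct_mean,perm_pct_mean,logPe_mean,logKp,group
SIM-PE1-R1,3,7.85,3.18,-5.51,-7.11,I
SIM-PE1-R2,3,58.94,1.37,-5.53,-7.13,III
SIM-PE2-R1,3,4.48,30.48,-4.30,-5.49,II
SIM-PE2-R2,3,60.20,12.75,-4.30,-5.48,III
```

(values shown rounded; the CSV stores full precision). The slow, unretained
compound lands in group I; the fast unretained one in group II; both highly
retained compounds in group III. The recovered log Pe of the two fast
compounds (−4.30) matches their simulated ground truth of 5×10⁻⁵ cm/s
(log₁₀ = −4.301) to within the 2% measurement noise, and log Kp is the
regression applied to the mean log Pe.

Classify and summarize the packaged reference table:

```bash
pampa-skin fixture --out table1.csv
pampa-skin classify table1.csv
pampa-skin report table1.csv
```

prints

```
group  count  R% range        perm% range
I          9    0.5- 17.2     0.8- 23.8
II         4    0.5- 13.5    31.6- 38.1
III       13   32.4- 86.5     1.3- 27.1
UNDEFINED  0      -            -
```

— 13 group III compounds: the 12 highly-retained esters plus the potent
standard mometasone furoate (R = 81%, permeation 7.7%). Retentions printed
as `0.5` are below-detection rows (reported as `<1` in the `R_display`
column).

The same operations are available as library calls (`simulate_plate`,
`read_plate_table`, `analyze_measurement`, `aggregate_triplicates`,
`classify_summaries`, `summarize_groups`).

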
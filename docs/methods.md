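# Methods

## The assay and its reduction

A PAMPA sandwich holds a donor well (volume V_D) beneath an acceptor well
(V_A), separated by a filter of area A coated with an artificial lipid
membrane (here the skin-mimetic 70% silicone oil / 30% isopropyl myristate
mixture). A compound dosed into the donor at concentration C_D(0) partitions
into the membrane and diffuses into the acceptor over an incubation time t.
Three concentrations per well are measured by HPLC: donor at time zero,
donor at t, and acceptor at t, each obtained by single-point comparison of
the peak area with the time-zero donor peak (shared linear detector response
across compartments; no calibration curve, consistent with how such screens
are quantified).

All internal units are cm, cm³, s and mol·cm⁻³; percentages exist only at
the reporting boundary.

### Retention factor

R is the mole fraction unaccounted for in either compartment at the end of
incubation — material held by the membrane, filter and plate:

    R = 1 − C_D(t)/C_D(0) − (V_A/V_D)·C_A(t)/C_D(0)        ("actual" mode)
    R = 1 − C_D(t)/C_D(0) − C_A(t)/C_D(0)                  ("equal" mode)

The "equal" form is the commonly quoted equal-volume simplification; the
"actual" form is the exact mole balance for unequal volumes and is the
package default, because the standard plate design uses 300 µL donor /
400 µL acceptor. The two coincide when V_A = V_D. Raw R within ±0.05 of the
[0, 1] interval is clamped and flagged (detector noise on nearly-unretained
compounds routinely crosses zero); values further outside raise an error,
since they indicate an inconsistent mass balance rather than noise.

### Effective permeability

After a lag time τ_LAG during which the transmembrane gradient establishes
itself, transfer is modelled as first-order relaxation between two
well-stirred compartments through an effective area A_eff = A·ε (filter area
times nominal porosity ε). Retention is treated as an instantaneous sink at
the lag boundary: of the dosed material, a fraction R never participates in
the donor/acceptor exchange. The acceptor then approaches the
retention-corrected equilibrium

    C_eq = (1 − R)·C_D(0)·V_D/(V_A + V_D)

with rate k = Pe·A_eff·(1/V_A + 1/V_D). Inverting the integrated solution at
the sampling time t gives, with t' = t − τ_LAG:

    Pe = −[V_A·V_D/((V_A+V_D)·A_eff·t')]·ln(1 − (V_A+V_D)/((1−R)·V_D)·C_A(t)/C_D(0))

and the equal-volume form (V = V_D):

    Pe = −[V/(2·A_eff·t')]·ln(1 − 2·(C_A(t)/C_D(0))/(1−R))

When the log argument is ≤ 0 the acceptor is at or past equilibrium and the
rate is unidentifiable at this incubation time; the pipeline flags the
replicate's Pe as undefined and continues, rather than aborting a plate —
screening ergonomics over strictness. Pe is strictly increasing in the
permeation parameter at fixed R, and in R at fixed positive permeation
(the same transfer achieved by a smaller mobile pool implies faster
transport).

A three-compartment kinetic treatment of the membrane was deliberately not
used: the assay measures no membrane time course, so a kinetic membrane
compartment would add parameters the data cannot constrain. The static-sink
picture is exactly the assumption under which the closed form above holds.

### Skin-permeability prediction

Human-skin log K_p is predicted from the membrane log Pe with the published
linear correlation for this membrane and 7 h incubation (31 compounds,
r² = 0.81):

    log K_p = (1.34 ± 0.12)·log Pe + (0.28 ± 0.56)

The coefficients are configuration (`KpRegression`), never refit here — the
training data belong to the original correlation study. Printed tables carry
two decimals, so reported log K_p uses decimal round-half-up (ties away from
zero); raw values are retained in memory and in CSV output.

### Aggregation

Replicates (triplicate by design) aggregate to per-compound means with
sample standard deviations (n−1). log Pe statistics are computed in the
log10 domain, matching how such tables report "log Pe ± sd"; log K_p is the
regression applied to the mean log Pe. Replicates with undefined Pe are
excluded from the log Pe statistics but remain counted (`n_pe_defined`
records how many contributed). The spread label is SD, not SEM — the source
table does not say which it prints; SD is the assumption documented here.

### Classification

Compounds are assigned permeate groups from their triplicate-mean retention
and permeation with 30% thresholds: both low → I; low R, high permeation →
II; high R, low permeation → III. Boundary values go to the high side. The
high-R/high-permeation cell has no name in the established taxonomy and is
labelled UNDEFINED rather than silently folded into a neighbour. The −6
log K_p cutoff that originally motivated the groups is carried as an
annotation only: assignment by (R, permeation) alone is what reproduces the
published memberships (one ester has predicted log K_p = −7.33 yet sits in
group III by its retention/permeation profile). Group labels for compounds
the reference discussion never names individually (the eight non-group-III
esters) are outputs of this rule, a documented interpretation rather than a
published claim.

## The synthetic-data generator

`synthetic_data` simulates exactly the model the analysis inverts:
instantaneous retention at the lag boundary, then exponential relaxation of
the acceptor towards C_eq. Mass is conserved identically at every time.
HPLC readout is emulated as multiplicative Gaussian noise on peak areas,
`area = response_factor·C·(1 + ε)`, ε ~ N(0, noise_cv), truncated at zero —
area error scales with signal, and this is the simplest model consistent
with t₀-ratio quantitation. One seeded generator drives a whole plate, with
draws in row-major order (per row: t₀, donor-t, acceptor-t), so plates are
byte-reproducible.

Defaults mirror the reference plate design: V_D = 0.3 cm³, V_A = 0.4 cm³,
A = 0.28 cm², ε = 0.70, t = 25 200 s (7 h), τ_LAG = 1200 s (≈20 min,
unstirred), C_D(0) = 10⁻⁷ mol·cm⁻³ (100 µM), triplicates. All are
overridable via a YAML geometry file; every value used is echoed into the
run manifest. τ_LAG is global, not per-compound — no per-compound lag data
exist to estimate it from. The noise CV has no measured reference value;
0.02 (a typical HPLC-UV area repeatability) is the package's synthetic
assumption.

What passing round-trip tests show — and what they do not: the noise-free
simulator→analysis grid test demonstrates that the implementation inverts
its own forward model to 10⁻⁹ relative error, and the noisy-plate test that
the log Pe estimator is essentially unbiased (<0.05 log units) under 2%
area noise at a mid-range operating point. Neither says anything about
membrane-model adequacy for real plates: real data add DMSO cosolvent
effects, evaporation, unstirred-water layers, pH/ionization and inter-well
variability, none of which are simulated. The 26-compound reference table is
correspondingly treated as measured input, not as something the pipeline
re-derives: its printed log Pe values cannot be regenerated from its printed
mean R and permeation columns under any single (volume-mode, τ_LAG) choice,
presumably because the original values were computed per well and averaged
afterwards from unpublished raw data. Whether the original calculations
applied the 70% porosity factor is likewise not verifiable from the text;
the package applies it, as the geometry states.

## Numerical conventions and edge cases

* Retentions reported only as "below 1%" are encoded as 0.005 (midpoint of
  the reportable band) wherever a number is required, with a
  `below_detection_R` flag preserved end-to-end; the results CSV renders
  them `<1` in a display column while keeping the numeric column.
* The acceptor timecourse uses `expm1` for small-rate accuracy.
* Results CSVs write floats via `repr`, so write→read round-trips are exact
  to float64; empty cells encode absent SDs (fewer than two replicates).
* Fully-retained wells (R = 1 after clamping) and zero-transfer wells yield
  defined R/permeation but undefined log Pe; a compound with no usable
  replicate reports undefined permeability fields with a warning, never a
  crash.
* Problem sizes in the test suite (10×10 recovery grid, 1000 noisy plates
  for the bias check, 3000 draws for the noise-CV calibration check) were
  chosen to make the statistical assertions stable at fixed seeds while the
  whole suite stays fast.

## Known limitations

* The two-compartment model assumes iso-pH, purely passive transport and
  well-stirred compartments; active transport and unstirred-layer effects
  are out of scope.
* The log K_p regression is specific to the silicone/IPM membrane and 7 h
  protocol; applying it to other membranes or times is unsupported
  extrapolation.
* Classification thresholds (30%/30%) are conventions inherited from the
  original permeate taxonomy, not fitted quantities; `ClassificationRule`
  exposes them for sensitivity analyses.
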
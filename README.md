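# cryoactin

Quantification of single-cell F-actin networks and classification of
cryopreservation-induced cytoskeletal damage.

Cryopreservation (slow freezing or vitrification) stresses adherent cells —
human mesenchymal stem cells are the motivating system — and one of the
clearest structural readouts of that stress is the actin cytoskeleton:
filaments buckle, depolymerize, and the network develops holes and cracks.
`cryoactin` implements an analysis chain that quantifies these changes in
*identical* cells imaged before freezing and after thawing, classifies each
cell's damage, and summarises cohorts with nonparametric statistics.  A
first-class synthetic-data module generates ground-truth cohorts with
parameterized damage so every stage of the chain can be validated end to
end.

## The descriptors and the classification

From a table of detected straight filaments per cell (length *lᵢ*, width
*wᵢ*, orientation *αᵢ* to the horizontal), three per-cell descriptors are
computed:

- **Circular standard deviation** ν = √(−2 ln R), where
  nR = √((Σ sin αᵢ)² + (Σ cos αᵢ)²) is the length of the resultant of the
  orientations taken as unit vectors.  ν = 0 means perfectly parallel
  filaments; large ν means an isotropic, branched network.
- **F-actin content** F = Σ lᵢ·wᵢ (μm²), an area proxy for total
  polymerised actin.
- **Mean filament length** L = (1/n) Σ lᵢ (μm).

For each cell the descriptors are computed pre-freeze (*b*) and post-thaw
(*a*) and combined into signed percentage alterations
Δ = 100(a/b − 1), summarised by the total alteration

&nbsp;&nbsp;&nbsp;&nbsp;Δ_T = (|Δ_F| + |Δ_L| + |Δ_ν|) / 3.

Class assignment is gated by an Annexin-V apoptosis readout (positive when
the standard deviation of the Annexin fluorescence exceeds 6000 a.u.):
apoptosis-negative cells are class I; positive cells are class I
(Δ_T ≤ 10 %), II (10 % < Δ_T ≤ 20 %) or III (Δ_T > 20 %); cells that lost
surface contact during cryopreservation are "detached".  Cohorts are
summarised as class fractions (mean ± SD over replicates), Δ medians and
quartiles, and two-sided Mann–Whitney U tests of each cryopreservation
condition against the unfrozen control (p < 0.05).

## Worked example

```python
from cryoactin import GeneratorConfig, generate_cohort, summarize_cohort
from cryoactin.pipeline import alterations_from_tables

cohort = generate_cohort(GeneratorConfig(), seed=1)   # 4 conditions x 3 times x 45 cells
alt = alterations_from_tables(cohort.filament_table, cohort.manifest)
summary = summarize_cohort(alt)
print(summary.fractions.query("condition=='slow_1C' and recovery_min==15"))
```

```
condition  recovery_min assigned_class  mean_fraction  sd_fraction
  slow_1C            15              I       0.466667     0.066667
  slow_1C            15             II       0.111111     0.101835
  slow_1C            15            III       0.111111     0.101835
  slow_1C            15       detached       0.311111     0.101835
```

Fifteen minutes after thawing from 1 °C/min slow freezing, under the
shipped illustrative damage presets, less than half the cells keep an
undisrupted network (class I), about a fifth show slight or severe
disruption, and a third have detached.  The corresponding rank test against
the unfrozen control flags the mean-filament-length alteration as
significant:

```
recovery_min reference condition parameter     U        p  n_ref   n  significant
          15   control   slow_1C   delta_L 932.0 0.013388     45  31         True
```

The same chain runs from the command line, stage by stage or end to end:

```bash
cryoactin simulate --seed 1 --out out/
cryoactin classify --filaments out/filaments.csv --manifest out/manifest.csv --out out/alterations.csv
cryoactin stats --alterations out/alterations.csv --out out/
cryoactin run-all --seed 1 --out out/       # all of the above + metrics + manifest
```

Image-based inputs are supported too: `cryoactin extract` turns a TIFF
(single plane or z-stack, collapsed by maximum-intensity projection) into
the same filament-table CSV via a simplified ridge-filter / skeleton /
straight-segment detector.

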
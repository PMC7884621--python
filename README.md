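# dbsfem

Electro-quasistatic field modelling for rodent deep brain stimulation (DBS)
electrode design.

In rodent DBS experiments the stimulating lead is usually implanted *cranial
to* the target nucleus — the subthalamic nucleus (STN) or the entopeduncular
nucleus (EPN) — because the electrode is large relative to the target, and
direct placement would destroy it.  The cost is field spread into the
thalamus and internal capsule above the target.  `dbsfem` is for modellers
and electrophysiologists who want to compare bipolar lead geometries for this
configuration: it solves the volume-conductor problem around parametric
electrode models in a synthetic rodent-brain phantom and ranks designs by how
much of the predicted neural activation lands in the target.

## Model

The complex potential obeys the electro-quasistatic equation

    ∇·[(σ(r,ω) + jωε(r,ω)) ∇φ(r)] = 0,

with Dirichlet conditions on the two electrode contacts and insulating
(natural) conditions elsewhere.  Stimulation is current-controlled: solutions
are rescaled by linearity so the core contact carries the prescribed current.
The stimulus is a rectangular pulse train (60 µs, 60 µA, 130 Hz); the
equation is solved per spectral component (Fourier FEM), with the number of
solves reduced by grouping harmonics into octave bands.  Neural activation is
estimated on a 0.05 mm probe lattice within 2 mm of the core contact by two
field criteria,

    |E| > 0.323 V/mm        and        |∇·E| > 0.309 V/mm²,

and each design is scored by the share (%) of the activated volume inside the
target nucleus.  Four designs are compared: two conventional concentric
bipolar leads (SNEX-100-like and CEAX-100-like, contacts near the tip) and
two modified designs with the return contact moved to the upper shaft and a
spherical or blunt (bottom-exposed-only) tip.

The tissue volume, anisotropy tensors and dispersive dielectric tables are
generated by the package (parametric ellipsoid/slab phantom, volume-
normalised tensor mapping, Cole-Cole dispersion anchored at 50 kHz); labelled
volumes can also be supplied as NIfTI.  See `docs/methods.md` for the full
model description and numerical choices.

## Worked example

```python
from dbsfem import StudyConfig, run_study

result = run_study(StudyConfig(output_dir="study_out"))
print(result.table[["design", "target", "share_E_pct",
                    "total_volume_E_mm3"]].to_string(index=False))
```

prints (a few minutes on one CPU):

```
   design target  share_E_pct  total_volume_E_mm3
  SNEX100    STN     0.121655            0.102750
  SNEX100    EPN     3.448276            0.105125
  CEAX100    STN     2.720348            0.114875
  CEAX100    EPN     6.764706            0.127500
SPHERICAL    STN     8.071749            0.083625
SPHERICAL    EPN    19.271624            0.082375
    BLUNT    STN    27.259036            0.083000
    BLUNT    EPN    31.750742            0.084250
```

Reading the numbers: with a conventional lead (SNEX-100-like) almost none of
the activated tissue is the target — the return contact sits close above the
tip and the field spreads along the whole current path.  Moving the return to
the upper shaft (SPHERICAL) already improves the target share several-fold,
and additionally insulating the tip laterally so current exits only downward
(BLUNT) gives the best focalization for both nuclei.  The compact EPN is
easier to target than the oblate STN for every design.  Absolute volumes
depend on the assumed tissue conductivities and electrode dimensions (see
`docs/methods.md`); the ranking is the robust output.

A command-line interface wraps the same pipeline:

```bash
dbsfem run study.json --out study_out --seed 0   # configured study
dbsfem validate                                  # analytic oracle suite
dbsfem phantom --out phantom                     # emit the phantom as NIfTI
dbsfem report study_out                          # re-tabulate saved results
```

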
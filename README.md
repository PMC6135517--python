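# hystnet

Hysteresis of brain functional networks during loss and recovery of
consciousness: an EEG network-trajectory statistic, and a delayed
oscillator model of the cortex that explains the path dependence through
explosive synchronization.

## The problem

During anesthetic state transitions the forward (induction) and reverse
(emergence) pathways of the brain are not mirror images: the drug level at
which consciousness is lost differs from the level at which it returns,
and the functional network reorganizes along different routes.  `hystnet`
provides both sides of a quantitative treatment:

1. **Measurement.**  From multichannel EEG annotated with four states
   (baseline → induction → unconscious → emergence), functional networks
   are built per 10-s window from the phase lag index
   (PLI_ij = |⟨sign Δθ_ij(t)⟩|), corrected by the median PLI of 20
   segment-swap surrogates and binarized at a fixed threshold.  Each state
   is a point in the plane spanned by *topographic similarity* (Pearson
   correlation of a window's node-degree vector with the baseline mean
   degree vector) and *average node degree*; the shoelace area of the
   closed four-state quadrilateral is the **hysteresis size**.  A band
   sweep (2-Hz bins, 0.1–31 Hz) locates the frequency carrying the
   hysteresis, a band-power version of the same trajectory serves as the
   control analysis, and one-way ANOVA with Tukey–Kramer correction
   compares areas across bands.

2. **Mechanism.**  78 Stuart–Landau oscillators on a spatially embedded
   connectome with distance-proportional conduction delays (8.6 m/s):

       ṙ_j = (λ_j − r_j²) r_j + S Σ_k A_jk r_k cos(θ_k(t−τ_jk) − θ_j)
       θ̇_j = ω_j + ξ_j + R_j^Z S Σ_k A_jk (r_k/r_j) sin(θ_k(t−τ_jk) − θ_j)

   The adaptive feedback R_j^Z (node synchrony
   R_j = |(e^{iθ_j} + N⁻¹Σe^{iθ_k})/2|, power Z) makes the
   synchronization transition discontinuous: quasi-static sweeps of the
   coupling S trace different up and down branches of the order parameter
   R(S), with critical couplings s_inc > s_dec enclosing a bistable band.
   Larger feedback power Z and larger natural-frequency spread Δω both
   enlarge the hysteresis; S_eff = S·R^Z links Z to the Hill slope of an
   anesthetic dose–response curve.

A synthetic-data module generates connectomes and four-state EEG with
known injected hysteresis (the model itself produces the carriers), so
the entire pipeline is testable end to end without any recordings.

## Worked example

Analysis side — generate four-state EEG with hysteresis injected at the
10 Hz carrier (a 3.5-unit coupling gap between the induction and
emergence legs) and sweep the 2-Hz analysis bins:

```python
from hystnet import (SynthConnectomeSpec, SynthEEGSpec, band_sweep,
                     synth_connectome, synth_eeg)

conn = synth_connectome(SynthConnectomeSpec(seed=1))
rec, truth = synth_eeg(SynthEEGSpec(seed=20181, rate=250.0), conn=conn)
table = band_sweep(rec, seed=20182)
best = table.loc[table.area.idxmax()]
print(f"{best.lo:g}-{best.hi:g} Hz  area={best.area:.2f}")
```

prints (roughly eight minutes of compute on one CPU)

```
9-11 Hz  area=12.24
```

— the hysteresis area peaks in the bin holding the injected carrier, and
against a 200-draw permutation null of the window-to-state assignment it
is significant at p ≈ 0.005.  Model side — one quasi-static coupling
sweep with and without the adaptive feedback:

```python
from hystnet import ModelParams, run_sweep
from hystnet.sweep import default_s_grid

for z in (4.0, 0.0):
    p = ModelParams(S=0.0, Z=z, delta_omega=1.0, seed=3)
    res = run_sweep(conn, p, default_s_grid(40, 14.0),
                    t_transient=2.0, t_measure=2.0, seed=3)
    print(f"Z={z:g}: s_inc={res.s_inc:.2f} s_dec={res.s_dec:.2f} "
          f"area={res.hysteresis_area:.2f}")
```

```
Z=4: s_inc=2.06 s_dec=2.08 area=0.14
Z=0: s_inc=0.78 s_dec=0.77 area=0.03
```

The feedback moves the transition from S ≈ 0.8 to S ≈ 2 and multiplies
the area between the legs; the hysteresis keeps growing with Z (area
≈ 0.66 at Z = 8) and both critical couplings rise linearly with the
frequency spread Δω.  With the optional feedback memory
(`ModelParams(feedback_tau=0.5)`) the transition becomes strongly
bistable, with synchrony lost near S ≈ 2.2 but not regained until
S ≈ 3.5–4.3; see `docs/methods.md` for the trade-offs of that mode.

A thin CLI mirrors the library (`hystnet synth|filter|connectivity|
trajectory|simulate|sweep`); run `hystnet --help`.

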
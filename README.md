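# pefskin

Modelling and quantification tools for **pulsed electric field (PEF) skin
treatment** — a non-thermal skin-rejuvenation modality in which trains of
short high-voltage square pulses permeabilize cell membranes (electroporation)
while sparing the extracellular matrix.

The package serves researchers designing or analysing PEF protocols on
layered skin, and covers four computational tasks:

1. **Electro-thermal simulation** of a dorsal skin fold pinched between two
   plate electrodes. The DC conduction problem ∇·(σ∇U) = 0 gives the
   per-layer electric field E = −∇U; the transient bioheat problem
   ρc_p ∂T/∂t = ∇·(λ∇T) + q, with duty-cycle-averaged Joule sources
   q = σ|E|²·(t_p·f), gives the per-layer temperature history. The built-in
   material registry holds per-layer conductivities and thermal properties
   for rat skin in the normal and electroporated membrane states.
2. **Taguchi L25 dose ranking.** Each of 25 orthogonal-array runs over
   three factors (voltage, pulse length, pulse number) at five levels is
   collapsed to a larger-is-better signal-to-noise ratio
   S/N = −10·log₁₀(mean(1/y²)); per-factor level means, their range
   Δ = max − min, and competition ranks quantify each factor's leverage on
   collagen synthesis.
3. **Histology quantification.** Collagen masks from the trichrome
   blue/red ratio (> 2), local fiber density within a 50 px disc, pixel-wise
   axial orientation from the structure tensor, local directional variance
   1 − |⟨e^{2iθ}⟩| (0 = aligned, a scar signature; 1 = isotropic),
   Fourier phase-correlation registration of adjacent sections, and the
   Herovici blue/red ratio as an index of collagen fiber age.
4. **Tensile mechanics.** Young's modulus Y as the least-squares slope of
   stress (F/A₀) versus strain (ΔL/L₀) over the linear window.

A synthetic-data module generates fiber-texture images with known density
and axial von Mises orientation statistics, L25 response tables with known
factor effects, and stress–strain curves with known modulus, so every
pipeline stage is testable without external data.

## Worked example

```python
import pefskin as pk
from pefskin.thermal import (joule_source_map, solve_transient,
                             steady_state_temperatures, time_to_steady)

stack = pk.default_stack("electroporated")
domain = pk.build_fold_domain(stack)              # mirrored fold, 2x1010 um
protocol = pk.PulseProtocol(voltage=500.0, t_p=70e-6, n_pulses=200, freq=3.0)

potential = pk.solve_potential_2d(domain, protocol.voltage)
emap = pk.efield_from_potential(potential)
print(pk.per_layer_field(emap, domain).round(1))

q = joule_source_map(emap, domain, protocol)
series = solve_transient(domain, q, pk.ThermalBoundary(), dt=0.05, t_end=70.0)
print({k: round(v, 1) for k, v in steady_state_temperatures(series).items()})
print(f"settled by {time_to_steady(series):.1f} s")
```

prints

```
stratum corneum        108.2
epidermis              135.2
dermis                 135.2
panniculus carnosus    108.2
subcutaneous           540.8
{'stratum corneum': 37.5, 'epidermis': 37.6, 'dermis': 42.0,
 'panniculus carnosus': 44.5, 'subcutaneous': 47.4}
settled by 11.5 s
```

The field drops across the well-conducting epidermis/dermis (135 V/mm) and
concentrates in the poorly conducting subcutaneous tissue (541 V/mm) at the
fold centre — a 4–5× contrast that decides which cell populations are
electroporated. The average Joule load (~1.2 W over 1 cm²) warms the fold
centre by ~10 °C above body temperature within ~11 s, after which the
profile is steady: heating is bounded and brief, consistent with a
non-thermal mechanism. See `docs/methods.md` for model assumptions and a
discussion of the deep-layer temperatures.

The same computations are available from the shell:

```sh
pefskin field --voltage 500 --out field.csv --summary layers.csv
pefskin thermal --t-end 70 --dt 0.05 --out temps.csv
pefskin taguchi --responses responses.csv
pefskin fibers --trichrome a.png --herovici b.png --px-size 0.46 --out stats.csv
pefskin youngs --input curve.csv --a0 5 --l0 10
pefskin synth fibers --seed 7 --out fibers.png
```

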
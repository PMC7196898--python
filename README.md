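# pdquant

Quantitative analysis of plasmodesmata-associated fluorescence microscopy
and connectivity assays, for plant cell biologists studying how signaling
(e.g. chitin perception by LysM receptor kinases) closes plasmodesmata —
the membrane-lined channels connecting neighboring plant cells.

Plasmodesmal responses are read out through several independent
quantitative modalities, all implemented here as one tested package:

| Readout | Module | Statistic |
| --- | --- | --- |
| Callose puncta in aniline-blue z-stacks | `image_quant` | per-spot and per-image fluorescence |
| Plasmodesmal enrichment of a tagged protein | `image_quant` | PD index = mean(PD ROI) / mean(PM ROI) |
| Homo-FRET / receptor clustering | `photophysics` | steady-state anisotropy *r* with G-factor and high-NA corrections |
| Hetero-FRET / receptor association | `photophysics` | TCSPC lifetime fits, amplitude-weighted τ<sub>av</sub>, efficiency E = 1 − τ<sub>DA</sub>/τ<sub>D</sub> |
| Receptor mobility | `kinetics` | FRAP mobile fraction (% recovery 60 s postbleach) |
| ROS burst | `kinetics` | background-corrected 0–25 min luminescence integral |
| Cell-to-cell connectivity (bombardment) | `connectivity_stats` | mock-normalized GFP-spread counts, rank tests, Tukey letters |

No raw microscope exports ship with the package; instead the
`synthetic_data` module generates every input modality with known ground
truth (cell mosaics with boundary-restricted puncta under Poisson + read
noise, periodic IRF-convolved photon decays, polarized intensity pairs,
FRAP traces with acquisition bleaching, luminol burst kinetics,
overdispersed bombardment counts), so every analysis chain is validated
end-to-end against the truth it should recover.

## Core models

**Anisotropy** (polarized detection through a high-NA objective):

    r = (I∥ − G·I⊥) / ((1 − 3L₂)·I∥ + (2 − 3L₁)·G·I⊥)

with calibration defaults G = 0.481, L₁ = 0.013, L₂ = 0.037. At G = 1,
L₁ = L₂ = 0 this reduces to the textbook (I∥ − I⊥)/(I∥ + 2I⊥). ROI
anisotropy pools photons before the ratio.

**TCSPC decay fitting**: expected counts per bin are
n·Σᵢ αᵢ·(decay(τᵢ) ⊛ IRF) + B under periodic 40 MHz excitation (25 ns
period, wrapped tails), maximized under the Poisson likelihood with
multi-start L-BFGS-B. τ<sub>av</sub> = Σαᵢτᵢ/Σαᵢ;
FRET efficiency E = 1 − τ<sub>av,DA</sub>/τ<sub>D</sub>.

**FRAP**: double normalization
F<sub>norm</sub> = [(F−B)/(R−B)]·[(R<sub>pre</sub>−B<sub>pre</sub>)/(F<sub>pre</sub>−B<sub>pre</sub>)]
removes background and acquisition bleaching; mobile fraction
Mf = 100·(F̄(60 s) − F₀)/(1 − F₀).

**Counts**: per-site GFP-spread counts are normalized to the mock mean
within genotype and compared by two-sided Mann-Whitney (default) or
permutation tests; multi-group figures use one-way ANOVA + Tukey HSD with
a compact letter display.

## Worked example

Anisotropy of one ROI (summed parallel/perpendicular intensities):

```sh
$ pdquant aniso --par 200 --perp 100
{"r": 0.5582012030540477, "G": 0.481, "L1": 0.013, "L2": 0.037, "variant": "standard"}
```

Fit a simulated two-component decay (100 000 photons, τ = 0.8/3.0 ns at
amplitude fractions 0.4/0.6, true τ_av = 2.12 ns):

```python
from pdquant.photophysics import IRFModel, fit_decay
from pdquant.synthetic_data import DecaySimSpec, simulate_decay

spec = DecaySimSpec(lifetimes=(0.8, 3.0), amplitude_fractions=(0.4, 0.6),
                    n_photons=10**5, background_fraction=0.01)
hist = simulate_decay(spec, seed=11)
fit = fit_decay(hist, IRFModel(kind="gaussian", center=2.0, sigma=0.1), 2)
print(fit.lifetimes, fit.amplitudes, fit.tau_av)
```

prints lifetimes `[0.804, 3.023]` ns, fractions `[0.402, 0.598]` and
τ_av `2.13` ns — the 0.8/3.0 ns mixture recovered from photon-limited
data. `pdquant demo --seed 0 --out demo/` runs the full
simulate → detect → summarize → compare loop on rendered mock/chitin
image pairs and reports the direction of the punctum-fluorescence effect.

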
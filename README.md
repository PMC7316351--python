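# tricolo

Three-color single-molecule localization microscopy (SMLM) colocalization
analysis: does a third molecular species sit, at nanometre scale, in a
defined geometry relative to a correlated pair of two others?

The motivating assay images the MCM replicative helicase, nascent DNA (EdU),
and G-quadruplex (G4) DNA structures in pre-extracted nuclei, and asks how
the density of replisome-associated G4 structures responds to the G4
stabilizer pyridostatin (PDS). `tricolo` implements the full computational
path from raw sCMOS frames to that per-nucleus endpoint, and ships a
synthetic-data generator so every stage is testable against known ground
truth without microscope data.

## The statistics at the core

For localization densities ρ₁, ρ₂, ρ₃ of three channels inside a nuclear
region of interest, with δρᵢ = ρᵢ − ⟨ρᵢ⟩, the **triple-correlation function**

    f(r₁, r₂) = ⟨δρ₁(R) δρ₂(R+r₁) δρ₃(R+r₂)⟩_R / (⟨ρ₁⟩⟨ρ₂⟩⟨ρ₃⟩)

is zero when any channel is independent of the others and peaks at the
internal geometry (r₁, r₂, Δθ) of a recurring three-species pattern. Because
patterns are randomly oriented, f is θ-averaged and re-indexed to
(r₁, r₂, r₃) with r₃ the third side of the displacement triangle. The
**conditional local density**

    C3(r₁, r₂) = ⟨δρ₁ δρ₂ δρ₃⟩ / ⟨δρ₁(R) δρ₂(R+r₁)⟩

gives the density of the third species at r₂−r₁ *given* a pair correlating
at r₁ — directly interpretable in molecules/µm².

Upstream of the correlation analysis: sCMOS-aware emitter localization
(variance-weighted detection, integrated-Gaussian MLE with the
variance-shifted Poisson likelihood, Cramér–Rao precision), blink merging of
consecutive-frame localizations within 2.5× the combined precision, and
bead-calibrated quadratic polynomial registration of all channels into a
reference channel. Downstream: per-nucleus counting of G4 structures with
both an MCM and an EdU structure within an association radius, and NT vs PDS
fold change with delta-method propagated SEM and Welch's t-test.
`docs/methods.md` documents every model and default.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study and
write their tables under `results/`:

```sh
python analysis/01_simulate.py    # scene + raw stack + bead field
python analysis/02_localize.py    # frames -> localization tables
python analysis/03_register.py    # bead-based chromatic map
python analysis/04_tcf.py         # f(r1,r2,Δθ), f(r1,r2,r3), C3
python analysis/05_associate.py   # per-nucleus densities, NT vs PDS cohort
python analysis/06_quantify.py    # fold change + t-test
```

`01` plants 166 triplets at (r₁=100 nm, r₂=150 nm, Δθ=60°) over 10/µm²
background in a 6×6 µm ROI. `04` then prints:

```
f peak: r1 in [80,120) nm, r2 in [120,160) nm, dtheta = 60 deg (f = 15.9)
planted: r1 = 100 nm, r2 = 150 nm, dtheta = 60 deg
C3 peak at the same geometry: True; local density 276/µm² vs ROI mean 16/µm²
```

— the correlation peak lands in the bins containing the planted geometry,
and C3 reads as a ~17-fold local enrichment of the G4 channel inside the
pattern over its ROI mean. `05`/`06` run a 20+20-nucleus cohort with planted
densities 0.5 (NT) and 0.8 (PDS) structures/µm² — a true ratio of 1.6 — and
print:

```
WT: NT 0.399 ± 0.082/µm² (n=20), PDS 0.678 ± 0.149/µm² (n=20)
  fold change 1.70 ± 0.11 (propagated SEM), Welch p = 4.05e-08
```

Absolute densities sit below the planted values (structures occasionally
fall under the minimum cluster size), but the effect ratio is recovered
within its propagated uncertainty.

A `tricolo` CLI wraps the same stages for file-based use:
`tricolo simulate|localize|register|tcf|associate|summarize|run` (see
`tricolo <cmd> --help`).

## Layout

```
src/tricolo/      simulate, localize, register, correlate, associate,
                  quantify, pipeline, io, cli
analysis/         numbered narrative drivers for the synthetic study
tests/            unit + property + acceptance suites, brute-force oracles
docs/methods.md   models, defaults, design choices, limitations
```
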
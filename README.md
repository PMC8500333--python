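# midzone

Quantitative analysis of central-spindle (midzone) dynamics in dividing
cells: averaged spindle kymographs, constrained multi-Gaussian fitting of
midzone intensity profiles, FRAP turnover kinetics, and microtubule
plus-end comet statistics — exercised end to end against a synthetic
movie generator with known ground truth.

## Scientific problem

During anaphase, antiparallel microtubules between the separating
chromosomes form a compacting overlap zone marked by the crosslinker
PRC1. Three linked measurements characterize this process:

1. **Overlap geometry over time.** Along the pole-to-pole axis, the PRC1
   fluorescence profile is a central peak (the antiparallel overlap)
   flanked by two side peaks near the poles. Fitting a constrained
   three-Gaussian model per time point yields the overlap length
   *L* (central-peak FWHM), the total spindle width
   *W* = side-peak separation + one side-peak FWHM, and the peak
   intensity *I*max. The spindle elongates from ≈8 to ≈20 µm while the
   overlap compacts exponentially to a final length of ≈1.7 µm.
2. **Protein turnover.** FRAP curves, normalized and averaged per
   mitotic stage, are fitted with
   *I(t) = I₀ + Iₐ(1 − e^(−t/τ))*; the recovery time τ and mobile
   fraction *mf = Iₐ/(1 − I₀)* report how crosslinker binding slows as
   the midzone matures (PRC1: τ from 6 s in metaphase to >100 s in
   telophase).
3. **Plus-end growth.** EB1 "comet" trajectories give per-stage growth
   speeds, track-duration survival curves, and spatial distributions
   between the poles.

Because raw microscopy data for such experiments are typically not
deposited, the package ships a synthetic generator
(`midzone.simulate`) that renders movies, FRAP curves, and comet tracks
from the published parameter values; every analysis stage is validated
by recovering the generating parameters from the synthetic data.

## Running the tests

```bash
python -m pytest -q tests/
```

## Worked example

```python
import numpy as np
from midzone.simulate import (SpindleSimConfig, generate_spindle_movie,
                              generate_frap_curves, FRAP_STAGE_KINETICS)
from midzone.kymograph import build_cell_kymographs
from midzone.profiles import build_timecourse, fit_overlap_decay
from midzone.frap import normalize_frap, average_curves, fit_recovery

# simulate a 15-minute two-channel movie and analyze it
cfg = SpindleSimConfig(seed=1)
stack, truth = generate_spindle_movie(cfg)
kymos = build_cell_kymographs(stack, truth.centrosome_track())
print("detected anaphase onset frame:", kymos["protein"].anaphase_onset_frame,
      "(truth:", cfg.anaphase_onset_frame, ")")

tc = build_timecourse(kymos["protein"], kymos["dna"])
decay = fit_overlap_decay(tc)
print(f"overlap decay: L0={decay.length_initial_um:.2f} um, "
      f"Linf={decay.length_final_um:.2f} um, tau={decay.tau_min:.2f} min")
post = tc.times_min >= 0
print(f"final total width: {np.nanmedian(tc.total_width_um[post][-3:]):.2f} um")

# simulate and fit one FRAP ensemble
params = FRAP_STAGE_KINETICS["PRC1"]["metaphase"]
records, _ = generate_frap_curves(params, 15, noise_sd=0.02, seed=1)
fit = fit_recovery(average_curves([normalize_frap(r) for r in records]))
print(f"PRC1 metaphase FRAP: tau={fit.tau_s:.2f} s, "
      f"mf={fit.recovery_fraction:.3f}")
```

Output:

```
detected anaphase onset frame: 6 (truth: 6 )
overlap decay: L0=5.05 um, Linf=1.70 um, tau=2.00 min
final total width: 20.01 um
PRC1 metaphase FRAP: tau=5.93 s, mf=0.551
```

The configured truth is L∞ = 1.7 µm, τ_L = 2 min, plateau width 20 µm,
and PRC1 metaphase kinetics τ = 6 s, mf = 0.55 — all recovered.

The same pipeline is available on the command line:

```bash
spindle simulate movie --config run.yaml --out movie/
spindle kymo build --stack movie/movie.tif --poles movie/poles.csv --out kymo/
spindle kymo average kymo/kymo_protein.csv --out avg.csv
spindle timecourse --protein avg.csv --dna kymo/kymo_dna.csv --out tc.csv
spindle simulate frap --protein KIF4A --n-curves 15 --seed 2 --out frap/
spindle fit-frap --manifest frap/manifest.yaml --out frap.json
spindle simulate comets --n-tracks 100 --seed 5 --out comets/
spindle comets --tracks comets/metaphase.csv --poles-um -10 10 --out comets.json
```

## Reproduction

`scripts/acceptance.py` recomputes the headline parameter-recovery
numbers (FRAP τ and mobile fractions for PRC1/KIF4A/CLASP1 stages and
the noiseless profile geometry) from freshly simulated data:

```bash
python scripts/acceptance.py --seed 1 --out results.json
```

All randomness derives from `--seed`; the deterministic profile targets
(`t8`–`t10`) are seed-independent. Expected values and tolerances:
τ(PRC1 telophase) ≈ 124 s within 20% (window-limited), the remaining
kinetic parameters within 10% of their generating values, and the
noiseless geometry (1.7 / 20 / 8 µm) to ≤1%.

## Documentation

See `docs/methods.md` for the full model description, parameter tables,
numerical choices, and known limitations.
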
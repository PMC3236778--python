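# smtpm

Single-molecule tethered-particle-motion (TPM) analysis of helicase DNA
unwinding, with the ensemble kinetics that accompany it.

## The problem

In a TPM unwinding assay a fork DNA substrate is anchored to a coverslip and
carries a sub-micron bead on its distal, biotinylated strand.  The restricted
Brownian motion (BM) of the bead reports on the flexibility of the tether: as
a replicative helicase converts duplex DNA into single strands, the BM
amplitude rises, and when the whole bead-proximal duplex (90 bp here) is
open, the bead-carrying strand dissociates and the bead disappears.  The
assay is nearly force-free, so unwinding velocities are measured without the
force dependence that tweezers-based assays impose.

The analysis chain this package implements:

1. **Substrate geometry** — a fork substrate built from three annealed
   oligonucleotides (145 nt scaffold, 18 nt dig-labelled partner, 90 nt
   biotinylated partner) gives a 108 bp duplex with a 37 nt 5′ loading
   overhang; a mimicked-unwound control (scaffold truncated to 37 nt) gives a
   37 bp duplex with a 71 nt single-stranded bead-proximal tail.
2. **BM amplitude** — centroid trajectories recorded at 30 Hz are
   drift-corrected, QC-filtered (x/y MSD ratio within [0.9, 1.1] keeps only
   single-tether beads), and converted to windowed BM series:
   per 20-frame window (0.66 s), MSD = ⟨x²⟩−⟨x⟩² per axis and
   BM = √((MSD_x+MSD_y)/2).
3. **Calibration** — the mean BM difference between the mimicked-unwound and
   intact fork populations (15.00 − 9.90 nm) over their 71 bp duplex
   difference gives the conversion factor c = 0.0718 nm per unwound base pair.
4. **Per-molecule velocity** — the unwinding onset is the changing point of
   the first derivative of the BM time-course (95% marginal band of the
   baseline derivative, persistence rule, hinge-fit refinement); the velocity
   is estimated both as the least-squares slope of the rising BM section
   divided by c (v_slope) and as 90 bp over the dwell time from onset to
   maximum BM (v_dwell).  Molecules that pause before release, or that
   disappear without a rising BM, are excluded.
5. **Ensemble kinetics** — ordinary nonparametric bootstrap of cohort mean
   velocities; Michaelis–Menten fit v = V_max·S/(K_M+S) of the ATP
   dependence; ATPase rates from coupled-assay A340 slopes
   (rate [µM/min] = |ΔA340/Δt| [1/s] × 9820); gel-shift normalization
   %Unwound = (%U_S−%U_0)/(%U_100°C−%U_0); cumulative tether-disappearance
   curves with a saturating-exponential fit.

Because raw microscopy recordings for such experiments are rarely released,
the package ships a first-class synthetic-data generator
(`smtpm.simulate`): bead centroids follow a stationary mean-reverting
process whose per-axis amplitude is affine in the number of unwound base
pairs, with recording dead time, stage drift, anisotropic (multi-tether)
beads, stochastic unwinding initiation, optional pre-release pauses and bead
disappearance at completion.  Every estimator is validated against this
known ground truth.

## Worked example

```python
import numpy as np
from smtpm import (SimulationConfig, simulate_population, simulate_cohort,
                   population_bm, calibrate, bm_series, correct_drift,
                   UnwindingDetector, bootstrap_mean, VelocityCohort)

cfg = SimulationConfig(duration=600.0, tau=0.01, seed=1)
rng = np.random.default_rng(1)
fork_pop  = simulate_population(cfg, 66, 9.90, 2.18, rng=rng)
mimic_pop = simulate_population(cfg, 57, 15.00, 4.23, rng=rng)
pf, pm = population_bm(fork_pop), population_bm(mimic_pop)
cal = calibrate(pf, pm, delta_bp=71)
print(f"fork BM  {pf.mean:5.2f} +/- {pf.sd:4.2f} nm  (n={pf.n})")
print(f"mimic BM {pm.mean:5.2f} +/- {pm.sd:4.2f} nm  (n={pm.n})")
print(f"conversion factor c = {cal.c:.4f} nm/bp")

trajs = simulate_cohort(SimulationConfig(duration=600.0, tau=0.01,
                                         v_true=3.58, seed=2),
                        15, all_unwind=True)
vs = []
for tr in trajs:
    s = bm_series(correct_drift(tr))
    det = UnwindingDetector(c=cal.c).fit(s, disappeared=tr.disappeared)
    if det.qualifies_ and not det.paused_:
        vs.append(det.v_slope_)
cohort = VelocityCohort("WT-like", vs)
bs = bootstrap_mean(cohort, resamples=100, seed=3)
print(f"cohort velocity {cohort.mean:4.2f} +/- {cohort.sd:4.2f} bp/s (n={cohort.n})")
print(f"bootstrap mean  {bs.mean:4.2f} +/- {bs.sd:4.2f} bp/s ({bs.resamples} resamples)")
```

prints

```
fork BM   9.89 +/- 1.80 nm  (n=56)
mimic BM 15.19 +/- 4.75 nm  (n=48)
conversion factor c = 0.0746 nm/bp
cohort velocity 3.33 +/- 0.66 bp/s (n=12)
bootstrap mean  3.31 +/- 0.19 bp/s (100 resamples)
```

The two populations are simulated with the published BM statistics; the
symmetry filter drops a handful of beads (n = 56 and 48 of 66 and 57), the
calibration recovers the conversion factor to within a few percent of the
0.0718 nm/bp used to generate the data, and a 15-molecule cohort unwinding
at 3.58 bp/s is recovered at 3.33 ± 0.66 bp/s from the qualifying,
non-paused molecules, with a bootstrap standard error of 0.19 bp/s.

The same stages are available from the shell:

```bash
smtpm run --config run.yaml --seed 1 --out outdir
smtpm kinetics mm --input atp_table.csv
smtpm kinetics gel --us 50 --u0 10 --u100 90
```

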
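# gcscreen

Suspect screening for gas chromatography–electron ionization–high-resolution
mass spectrometry (GC-EI-HRMS), built for environmental analysts who screen
complex extracts (biota, passive samplers) against accurate-mass EI
libraries.

GC-EI-HRMS screening hinges on four steps that this package implements and
makes testable end to end:

1. **Deconvolution.** Profile-mode scans are centroided, centroids are
   clustered into extracted-ion chromatograms (EICs), chromatographic peaks
   are integrated valley-to-valley, and peaks that co-maximize with the same
   shape are grouped into *components* — pseudo-spectra of co-eluting
   fragment ions.
2. **Library matching.** Component spectra are scored against an
   accurate-mass EI library (MSP dialect). Ions are paired one-to-one within
   an accurate mass tolerance (AMT, ppm); both spectra are weighted
   Stein–Scott style, *w = I^0.5 · (m/z)^1.3*, and a reverse score *R*
   (over library ions only) and forward score *F* (over the ion union) are
   combined through the pure weight factor:

   *MF = 100 · (pwf · F + (1 − pwf) · R)*,

   so pwf = 0 is a purely reverse and pwf = 1 a purely forward search.
3. **Retention indices.** A per-batch C7–C40 n-alkane table (CRT file) maps
   retention time to the linear Kovats index (alkane C*n* ≡ 100·*n*). The
   library entry's RI predicts an expected RT; the deviation enters the
   score as a multiplicative trapezoidal penalty (free window → linear ramp
   → rejection), which is what separates isomers with identical spectra.
4. **Validation machinery.** Given spiked-replicate experiments with a truth
   table: FP/FN scoring, match-factor cutoff calibration at a target
   false-negative rate, AMT × PWF grid sweeps, and screening detection
   limits (SDL: the lowest level detected in ≥ 95% of replicates).

A first-class synthetic-data generator (`gcscreen.simdata`) emulates the
acquisition — 5 spectra/s over m/z 40–1000, resolution-dependent profile
widths, systematic + random ppm mass errors, Gaussian/tailing peaks,
co-elution, matrix background — so the entire workflow is testable with
known ground truth and no instrument.

## Worked example

```python
import gcscreen as g
from gcscreen.rical import ri_to_rt
from gcscreen.simdata import PlantedCompound, SimConfig

lib = g.simulate_library(10, seed=1, richness_range=(4, 15))
calib = g.default_calibration()          # C7-C40 alkane schedule
planted = [PlantedCompound(name=e.name, rt=float(ri_to_rt(e.ri, calib)),
                           mz=e.mz, rel=e.rel_intensity, base_area=2e5,
                           level=10.0)
           for e in lib.entries]
run, truth = g.simulate_run(planted, SimConfig(seed=1))

config = g.ScreenConfig(libraries=[(lib, g.MatchParams())], calib=calib)
result = g.screen_sample(run, config)
for h in result.identifications:
    print(f"{h.entry_name:28s} score={h.final_score:6.2f} ri={h.component_ri:7.1f}")
```

prints (abridged)

```
Simulated compound 001       score=100.00 ri= 1026.2
Simulated compound 002       score=100.00 ri= 1213.7
...
Simulated compound 010, TMS  score=100.00 ri= 2557.8
```

Every planted compound is recovered with a match factor of 100: the
deconvoluted spectra are exact copies of the library spectra and each apex
retention time lands inside the penalty-free RI window. The scripts in
`examples/` walk through each capability (screening, RI calibration,
forward/reverse matching, PWF optimization, library building/migration)
with a line on what the printed numbers mean. `examples/04_optimize_pwf.py`
shows the characteristic trade-off on the standard benchmark: mean false
positives fall monotonically as the PWF moves from reverse toward forward
search, while false negatives rise — pwf ≈ 0.1 is the usual compromise.

## Command line

A thin CLI wraps the library:

```bash
gcscreen simulate --seed 1 --out exp/           # synthetic experiment
gcscreen screen exp/500ngml-r1.run.txt \
         --library exp/library.msp --crt exp/alkanes.crt.csv --out hits.csv
gcscreen evaluate exp/ --out eval/              # two-stage optimization
gcscreen sweep exp/ --amt 10,20,50 --pwf 0,0.5,1 --out sweep.csv
gcscreen build-lib ... ; gcscreen migrate-lib ...
```

Runs are read/written as mzML or a plain-text internal format; libraries as
an MSP dialect with `RI:` and `Comments:` (e.g. `derivatized=TMS`) fields;
calibrations as CRT CSV (`name,rt,ri`).

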
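# radstar

Model-based T2\* mapping from multi-echo golden-angle **rad**ial MRI with
joint k-space trajectory auto-correction.

## The problem

Quantitative T2\* (effective transverse relaxation time) mapping is a
candidate hypoxia surrogate for MR-guided radiotherapy. Radial multi-echo
acquisitions make it fast and motion-robust, but they are exquisitely
sensitive to gradient timing delays: a shift of a single dwell time
misregisters every spoke in k-space and turns into streaking, banding and
biased T2\* estimates. On hybrid MR-Linac systems the delays drift with
hardware state, so a data-driven correction that needs no calibration scan
is attractive.

`radstar` reconstructs proton density `M0` and `T2*` maps while *jointly*
estimating the per-axis gradient delays, by alternating minimization of

```
sum_{n,c} || F_n(dk_n) S_c x_n - y_{n,c} ||^2  +  lambda sum_n || x_n - xhat_n(M0, T2*) ||^2
```

over the echo images `x_n`, the trajectory shifts `dk_n` (parameterized by a
delay pair `(tau_x, tau_y)` per readout polarity, in dwell-time units) and
the relaxation maps, with `xhat_n = M0 exp(-TE_n/T2*)` carrying the phase of
`x_n` and `lambda = 1`. Three modes are provided for comparison:
`uncorrected` (delays pinned at zero), `sequential` (trajectory correction
first, mono-exponential fit afterwards) and the proposed `joint` alternation.
A seeded numerical brain phantom (GM / WM / CSF / skull with
tissue-constant `T2*` = 84 / 66 / 2000 / 10 ms, `M0` = 100), simulated
8-channel coils, gradient-delay corruption, complex Gaussian noise and two
retrospective 2x undersampling schemes (`uniform`, `alternate`) make the
whole validation study reproducible offline. See `docs/methods.md` for the
algorithms and conventions.

Audience: MR physicists and image-reconstruction researchers who want a
self-contained, CPU-only reference implementation of trajectory
auto-corrected model-based relaxometry.

## Worked example

Simulate a delay-corrupted, undersampled acquisition at the reduced
`--quick` profile (64x64 grid, 100 spokes), reconstruct it with and without
correction, and score it:

```sh
radstar simulate --seed 7 --noise 0.1 --delay 1 -1 --quick --out corrupted.h5
radstar undersample --input corrupted.h5 --scheme alternate --out under.h5
radstar reconstruct --input under.h5 --mode joint --out maps.nii.gz
radstar evaluate --maps maps.nii.gz --truth corrupted.h5
```

The reconstruction writes `maps.nii.gz` (T2\* in ms), `maps_m0.nii.gz` and a
`maps.json` sidecar with the estimated delays and the cost trace. On this
example the sidecar contains

```
"delays_dwell": {"odd": [1.0114, -1.0081], "even": [1.0121, ...]}
```

i.e. the simulated `(1, -1)` dwell delay is recovered from the corrupted
data alone to about 0.01 dwell, and `evaluate` prints the masked metrics of
the T2\* map against the simulated ground truth (skull and background
excluded):

```
{
  "rmse_ms": 139.17,
  "relative_error_by_tissue": {"GM": 0.094, "WM": 0.051, "CSF": 0.288},
  "n_pixels_evaluated": 1646
}
```

The RMSE in ms is dominated by CSF, which at this reduced 64x64 profile sits
at the edge of identifiability (its T2\* of 2000 ms decays only ~2% over the
echo train; see `docs/methods.md`); the GM/WM relative errors carry the
signal. Running `reconstruct --mode uncorrected` on the same container shows
the penalty of ignoring the delay — RMSE 200.94 ms and a grey-matter
relative error of 0.140 instead of 0.094.

The same works from Python:

```python
import radstar, radstar.evaluate as ev
row = ev.run_cell("alternate", (1.0, -1.0), "joint", noise_level=0.1,
                  seed=7, profile=ev.StudyProfile.quick())
print(row["rmse_ms"], row["tau_x_odd"], row["tau_y_odd"])
```

`radstar study --grid table1 --quick --out study.csv` runs the full
factorial (scheme x delay x mode x noise) and writes one row per cell.

## Limitations

2-D single-slice; no B0/motion correction; rigid per-axis delay model. The
default anatomy is procedural — absolute RMSE values are not comparable
across anatomies; supply your own labeled slice via `--labels` for
anatomy-matched studies.
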
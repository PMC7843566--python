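# onhpleth — video plethysmography of the optic nerve head

Cardiac-cycle blood-volume changes in the microvascular tissue of the optic
nerve head (ONH) modulate how much light the tissue absorbs. A video
ophthalmoscope recording ~10 s of the fundus at 25 frames/s therefore
carries a photoplethysmographic signal: the ONH gets slightly darker with
every systole. In glaucoma, where ONH perfusion is reduced, the pulse is
flatter and rises more slowly. `onhpleth` implements the full analysis
chain from raw fundus video frames to the averaged cardiac pulse and its
waveform parameters, together with the group-statistics layer used to
compare diagnostic groups, and synthetic phantom/cohort generators so that
every stage can be validated against known ground truth.

## The signal and its parameters

For a registered video, the mean grey level `I(n)` over the ONH tissue ROI
(the manually segmented disc minus the dilated large-vessel tree) is
converted to a relative absorption trace

```
A(n) = 1 − I(n) / I_avg(n)
```

where `I_avg(n)` is a slowly varying trend. `A·100` is expressed in %A;
the display convention adds 100, so a value of 105 means absorption 5 %
above trend. Heartbeats are delimited by labelled minima of the trace,
re-referenced to their starting value, resampled to a common length and
averaged. Five descriptors are extracted from the averaged pulse:

| parameter | units | definition |
|---|---|---|
| peak amplitude | %A | maximum of the averaged pulse |
| steepness | %A/s | rise from 30 % to 70 % of peak amplitude over the elapsed time |
| time-to-peak | s, % | time of the maximum from beat start (also % of duration) |
| FWHM | s, % | full width at half the peak amplitude (also % of duration) |
| pulse duration | s | mean duration of the contributing beats |

The statistics layer compares the four diagnostic groups (normal, ocular
hypertension, preperimetric and perimetric glaucoma) with Kruskal-Wallis
and Bonferroni-corrected Mann-Whitney tests, correlates parameters with
OCT-measured retinal nerve fibre layer (RNFL) thickness (Spearman), fits
regression lines per 10 µm RNFL, and computes the test-retest coefficient
of variation from repeated measurements via repeated-measures ANOVA.

## Worked example

Render a phantom with a known injected pulse and recover it end-to-end:

```
python analysis/01_simulate_phantom.py
python analysis/02_pulse_recovery.py
```

which prints (abridged):

```
still:  amplitude 5.026 %A, steepness 16.68 %A/s, time-to-peak 0.320 s, FWHM 0.500 s, duration 1.000 s, 7 pulses, pulse rate 60 bpm
moving: amplitude 5.052 %A, steepness 16.95 %A/s, time-to-peak 0.320 s, FWHM 0.502 s, duration 1.000 s, 7 pulses, pulse rate 60 bpm
```

The injected beat was 5.0 %A amplitude, 0.30 s systolic rise (steepness
16.67 %A/s), 0.50 s FWHM and 1.0 s duration: the pipeline recovers
amplitude and steepness within ~1 % even under ±4 px eye drift and sensor
noise, and the timing parameters to within one frame period (0.04 s).

Cohort-level analysis on a synthetic 110-subject cohort calibrated to the
published group summary statistics:

```
python analysis/03_cohort_stats.py
python analysis/04_significance_pattern.py
```

The first reproduces the qualitative pattern of the study — highly
significant group differences for peak amplitude and steepness (Kruskal-
Wallis p < 0.001), strong positive correlation of both with RNFL
thickness, and an amplitude loss near 0.6 %A per 10 µm RNFL — and prints
the test-retest CV of a simulated repeat session. The second quantifies,
over 200 replicate cohorts, how reliably each parameter's test rejects.

A command-line interface mirrors the scripts:
`onhpleth simulate`, `onhpleth simulate-cohort`, `onhpleth analyze`,
`onhpleth batch`, `onhpleth cohort-stats` (see `onhpleth --help`).

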
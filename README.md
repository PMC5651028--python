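# motormap

Automatic cortical motor mapping at desk scale: motor-threshold (MT)
estimation algorithms, a closed-loop multi-electrode stimulation scheduler,
virtual subjects standing in for the animal and hardware, and the
reliability statistics used to validate motor maps.

Cortical stimulation mapping locates the motor representation of a muscle
by measuring, at each electrode of a surface array, the motor threshold —
the lowest stimulus intensity whose motor evoked potential (MEP) exceeds a
predetermined EMG amplitude. Conventional MT estimation ("significant MEPs
in at least 5 of 10 consecutive trials", 1-Hz stimulation) is reliable but
slow, which matters when mapping must fit within stable anesthesia or when
short-term plasticity is the object of study. This package implements a
fast alternative — a threshold-*tracking* staircase in the tradition of
peripheral-nerve excitability testing, interleaved across all 32 electrodes
of an 8×4 epidural array at 4 Hz under a 2-s same-electrode refractory
rule — together with everything needed to evaluate it against the
conventional procedure on simulated subjects.

**Who it is for:** neurophysiologists and methods developers who want to
prototype closed-loop mapping schedules and MT criteria, quantify their
efficiency/reliability trade-offs on simulated cortex, or analyse recorded
motor maps (CSV/JSON) with the standard reliability statistics.

## The algorithms

Intensities live on a 20–100% grid of maximum stimulator output (MSO, 1.0
mA) in 5% steps; mapping starts at 50% MSO.

* **Tracking criterion** — after each stimulus, step the intensity down 5%
  if the MEP was significant, up 5% otherwise. Stop once the last five
  intensities are confined to two adjacent levels; then
  MT = mean of the last two intensities. An electrode demanding a step
  above 100% MSO is nonresponsive.
* **Conventional criterion** — classify each level positive (≥5
  significant of up to 10) or negative (≥6 nonsignificant), walking down
  after positive and up after negative levels;
  MT = the positive level of the first adjacent positive/negative pair.
* **Scheduler** — on each stimulus slot (4 Hz or 1 Hz) a uniformly random
  eligible electrode (unresolved, outside its 2-s refractory window)
  receives its algorithm-demanded intensity; pauses fill empty slots.
* **Statistics** — tied-rank Spearman correlation with a 2,000-resampling
  permutation null (significant above the null's 99th percentile),
  McGraw–Wong ICC(A,1) of minimum MT and map area across sessions,
  triangulation-based map interpolation, rank correlation of interpolated
  surface maps against intracortical-microstimulation (ICMS) point maps,
  and Friedman/Wilcoxon session tests at α = 0.01.

Virtual subjects carry spatially structured threshold fields (a
low-threshold hotspot with a radial gradient and jitter) and respond
stochastically through a cumulative-Gaussian recruitment curve
P(MEP | I) = Φ((I − θ)/s). See `docs/methods.md` for the model, defaults
and limitations.

## Worked example

```python
import motormap as mm

subject = mm.make_subject(seed=7)                    # one simulated rat
novel = mm.run_mapping(subject, "novel", mm.ScheduleConfig.novel(seed=7))
conv  = mm.run_mapping(subject, "conventional", mm.ScheduleConfig.conventional(seed=7))

print(f"novel:        {novel.n_stimuli} stimuli in {novel.duration_s:.1f} s "
      f"({novel.n_pause_slots} pause slots)")
print(f"conventional: {conv.n_stimuli} stimuli in {conv.duration_s:.1f} s")
comp = mm.spearman_permutation_test(novel.motor_map, conv.motor_map, seed=7)
print(f"spearman rho={comp.rho:.3f}, p={comp.p_perm:.4f}, significant={comp.significant}")
```

prints

```
novel:        310 stimuli in 87.8 s (41 pause slots)
conventional: 888 stimuli in 888.0 s
spearman rho=0.972, p=0.0005, significant=True
```

The tracking procedure maps the same cortex in 88 s instead of 888 s
(~1/10 of the time, ~1/3 of the stimuli) and the two maps' MT rank orders
agree almost perfectly (rho = 0.97, far above the permutation null).

The same operations are available from the shell:

```bash
motormap simulate-subject --seed 7 --out subject.json
motormap run-mapping --subject subject.json --algorithm novel \
         --seed 7 --out-map map.json --out-log log.csv
motormap compare-maps map_a.json map_b.json
motormap validate-log log.csv            # slot-clock + refractory audit
motormap run-protocol --n-subjects 12 --seed 1 --out protocol.json
```

`run-protocol` performs the four-session validation design (pre1, pre2,
novel, post on each subject) and reports median durations and stimulus
counts, ICC tables, per-pair significant-correlation counts and the
Friedman omnibus on mapping times.

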
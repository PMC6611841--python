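#!/usr/bin/env python
"""Generate a synthetic three-patient overnight cohort.

Each patient gets a dual-sensor recording whose differential signal
carries a cardiac and a respiratory gradient component at the cohort-mean
structure (amplitude ratio 2.85, cardiac period about a quarter of the
respiratory period), plus sensor noise, slow drift and a couple of step
artifacts to exercise the window-vetting stage. Recordings (large CSVs)
go to scratch/recordings; ground-truth side-cars ride along.
"""

from pathlib import Path

from aqueductflow import SyntheticSpec, generate_recording, write_recording

OUT = Path("scratch/recordings")

# per-patient (heart rate bpm, resp rate bpm, cardiac gradient mmHg/m)
PATIENTS = [
    ("sim1", 62.0, 15.0, 1.46, "22:00:00", (2.5,), (1500.0,)),
    ("sim2", 55.0, 13.5, 1.15, "23:30:00", (), ()),
    ("sim3", 70.0, 17.0, 1.80, "21:00:00", (-2.2,), (3000.0,)),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (pid, hr, rr, a_card, clock, steps, times) in enumerate(PATIENTS):
        spec = SyntheticSpec(
            duration=2.0 * 3600.0,  # 2 h -> 20 six-minute windows
            cardiac_grad_amplitude=a_card,
            cardiac_freq=round(hr / 60 * 360) / 360,  # whole periods per window
            resp_grad_amplitude=a_card / 2.85,
            resp_freq=round(rr / 60 * 360) / 360,
            drift_amplitude=0.05,
            drift_freq=0.01,
            noise_sd=0.02,
            artifact_times=times,
            artifact_steps=steps,
            seed=1000 + i,
        )
        rec = generate_recording(spec, patient_id=pid, start_clock=clock)
        path = write_recording(rec, OUT / f"{pid}.csv")
        print(f"{pid}: {len(rec.time)} samples, cardiac {a_card:.2f} mmHg/m at "
              f"{hr:.0f}/min, resp {a_card / 2.85:.2f} mmHg/m at {rr:.0f}/min -> {path}")


if __name__ == "__main__":
    main()
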
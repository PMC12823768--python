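"""Generate a small synthetic recording session and inspect it.

Builds a 2-subject dataset (one repetition per task to keep it quick),
writes it to disk in the package's interchange formats (CSV per EMG
channel, WAV for the cutaneous sound, JSON manifest), reloads it, and
prints basic amplitude statistics that show the class structure: the
jaw closers roar during clenching and stay near the noise floor during
swallowing.
"""

import tempfile
from pathlib import Path

import numpy as np

from bruxhmm import GeneratorConfig, generate_dataset, load_dataset


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def main():
    cfg = GeneratorConfig(
        n_subjects=2, reps_per_task=1, inter_rep_gap=1.0,
        inter_task_rest=2.0, master_seed=7,
    )
    out = Path(tempfile.mkdtemp()) / "demo_dataset"
    manifest = generate_dataset(cfg, out)
    print(f"dataset written under {out}")

    segments = load_dataset(manifest)
    print(f"loaded {len(segments)} labelled 5-s segments "
          f"({cfg.n_subjects} subjects x 10 tasks x {cfg.reps_per_task} rep)")

    print("\nright-masseter RMS per task, subject S01 (a.u.):")
    for seg in segments:
        if seg.subject_id != "S01":
            continue
        x, _ = seg.channels["right_masseter"]
        print(f"  {seg.task:18s} [{seg.class_label:6s}]  {rms(x):.3f}")
    print("\nHigh values mark the forceful jaw-closer tasks (clenching,")
    print("bracing, tapping, grinding); everyday movements sit near the")
    print("resting noise floor, which is what the classifier exploits.")


if __name__ == "__main__":
    main()
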
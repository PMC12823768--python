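"""Turn one segment's channels into the MFCC+delta sequences the HMMs see.

Synthesizes a single subject in memory, takes one clenching repetition,
and extracts features from a 1 kHz EMG channel and the 44.1 kHz sound
channel. Both yield exactly 99 frames (100 ms Hamming windows, 50 ms
shift over 5 s), which is what lets a multi-stream model consume them
frame-synchronously.
"""

import numpy as np

from bruxhmm import GeneratorConfig, extract_features
from bruxhmm.io_signals import cut_segments
from bruxhmm.simulate import generate_subject_recording


def main():
    cfg = GeneratorConfig(n_subjects=2, reps_per_task=1,
                          inter_rep_gap=1.0, inter_task_rest=2.0, master_seed=7)
    _, recording, entries = generate_subject_recording(cfg, 0)
    segments = cut_segments(recording, entries)
    clench = next(s for s in segments if s.task == "clenching")

    emg = extract_features(clench, "right_masseter")
    snd = extract_features(clench, "sound")
    print(f"right_masseter features: {emg.values.shape}  (frames x [13 MFCC + 13 delta])")
    print(f"sound features:          {snd.values.shape}")
    print(f"frame times span {emg.frame_times[0]:.3f}..{emg.frame_times[-1]:.3f} s")

    c0 = emg.values[:, 0]
    print(f"\nC0 (log-energy) of the masseter over the repetition:")
    print(f"  start {c0[0]:.1f} -> plateau {np.median(c0[20:80]):.1f} -> end {c0[-1]:.1f}")
    print("The rise and fall follow the contraction envelope; the higher")
    print("cepstral coefficients encode the spectral shape of the burst,")
    print("and the delta half tracks how both change frame to frame.")


if __name__ == "__main__":
    main()
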
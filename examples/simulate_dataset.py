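"""Generate a synthetic multi-patient EEG ensemble and inspect it.

Writes a small dataset to ./example_data and verifies the generative
contract: focal segments carry twice the θ+α (4-16 Hz) band power of
non-focal segments, while patients differ in amplitude/spectral style.
"""

import numpy as np
from scipy import signal

from focusloc import SyntheticConfig, generate_dataset, write_manifest

cfg = SyntheticConfig(n_patients=3, segment_seconds=2.0,
                      n_segments_per_class=20, class_effect=1.0, seed=42)
segments = generate_dataset(cfg)
manifest = write_manifest(segments, "example_data")
print(f"wrote {len(segments)} segments, manifest: {manifest}")


def band_power(x, band):
    f, p = signal.welch(x, fs=cfg.fs, nperseg=256)
    sel = (f >= band[0]) & (f < band[1])
    return np.trapezoid(p[sel], f[sel])


by_class = {}
for seg in segments:
    by_class.setdefault(seg.class_label, []).append(
        band_power(seg.samples, cfg.focal_band))
ratio = np.mean(by_class["focal"]) / np.mean(by_class["non-focal"])
print(f"focal/non-focal theta+alpha power ratio: {ratio:.3f} "
      f"(generator target: {1 + cfg.class_effect:.1f})")

for p in range(cfg.n_patients):
    rms = np.mean([np.sqrt(np.mean(s.samples ** 2)) for s in segments
                   if s.patient_id == f"P{p:02d}"])
    print(f"patient P{p:02d}: mean segment RMS {rms:.3f} "
          "(patient-specific style scale)")
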
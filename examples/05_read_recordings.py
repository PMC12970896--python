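"""Read EEG segments in the two supported on-disk dialects.

Round-trips a recording through the one-sample-per-line text format and a
MAT v5 file, applies a calibration factor (raw ADC units -> µV) and the
optional 0.5–70 Hz zero-phase band-pass, and windows the result.
"""

import tempfile
from pathlib import Path

import numpy as np
import scipy.io

import eegmark as em

tmp = Path(tempfile.mkdtemp())

profile = em.default_profiles()["interictal"]
rec, _ = em.generate_recording(profile, duration_s=23.6, fs=em.BONN_FS,
                               seed=1, recording_id="demo")

# text dialect (one ASCII sample per line), with a 0.5 µV/unit calibration
em.write_bonn_text(rec, tmp / "demo.txt")
text_rec = em.read_bonn_text(tmp / "demo.txt", fs=em.BONN_FS,
                             calibration=0.5)
print(f"text dialect : {len(text_rec)} samples, "
      f"first = {text_rec.samples[0]:.3f} µV (calibrated x0.5)")

# MAT dialect (single numeric vector per file)
scipy.io.savemat(tmp / "demo.mat", {"eeg": rec.samples[:1024]})
mat_rec = em.read_mat_segment(tmp / "demo.mat", fs=em.NDSC_FS)
print(f"MAT dialect  : {len(mat_rec)} samples at {mat_rec.fs} Hz")

filtered = em.bandpass_filter(mat_rec, lo=0.5, hi=70.0)
windows = em.segment(filtered, window_len=256, overlap_frac=0.5)
print(f"band-passed 0.5-70 Hz and segmented into {len(windows)} windows "
      f"of 256 samples (50% overlap)")
print(em.windows_to_manifest(windows).head(3).to_string(index=False))
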
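"""Build the MLAPV excitation waveform and inspect its plateau structure."""

from etongue import WaveformSpec, build_waveform, plateau_slices, voltage_at_sample

w = build_waveform(WaveformSpec())  # -1..+1 V ladder, 0.1 V steps, 0.1 s plateaus

print(f"plateaus: {w.n_plateaus}, samples/electrode: {w.n_samples}")
print(f"first five plateau levels (V): {w.plateau_levels[:5]}")
print(f"sample 0 -> {voltage_at_sample(w, 0):+.1f} V (first ladder level)")
print(f"sample 40 -> {voltage_at_sample(w, 40):+.1f} V (first recovery plateau)")
print(f"first three plateau sample ranges: {plateau_slices(w)[:3]}")

# Every odd plateau is a 0 V recovery step; 21 levels x 2 = 42 plateaus and
# 42 x 40 = 1680 samples reproduce the published excitation geometry.
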
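"""Wavelet time-of-coherence of a planted phase-locked oscillation.

Two noisy channels share a 20 s sinusoid over the central half of a
416-sample record.  The time-of-coherence in the [16, 32) s band, in-phase
class, should read back roughly the planted 50% of the scan duration.
"""

import rsndyn as r
from rsndyn.wavelet import surrogate_threshold, time_of_coherence

T, dt = 416, 2.0
ts = r.gen_phase_locked_pair(
    period_s=20.0, coherent_fraction=0.5, phase_offset_rad=0.0,
    T=T, dt=dt, noise_sd=0.5, seed=7,
)
x, y = ts.values[:, 0], ts.values[:, 1]

scal = r.coherence_pair(x, y, dt)
print(f"scalogram: {len(scal.periods)} scales ({scal.periods[0]:.1f}-{scal.periods[-1]:.0f} s) "
      f"x {len(scal.times)} time points")

thr = surrogate_threshold(0.3, 0.3, T, dt, n_surrogates=100, alpha=0.05, seed=0)
r.significance_mask(x, y, scal, threshold=thr)

toc = time_of_coherence(scal)
print("\ntime-of-coherence (% of scan) per band and phase class:")
print(toc.round(1).to_string())
print("\nband s3 = [16, 32) s contains the planted 20 s rhythm; its 'ip'"
      "\n(in-phase) entry should be near the planted 50% (smoothing adds a"
      "\nfew points).  Neighbouring bands pick up ridge leakage from the"
      "\nsame rhythm; bands far from 20 s stay near the 5% floor.")
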
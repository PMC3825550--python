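"""Time-volume-curve analysis of an analytically known volume series.

Fits the five-harmonic Fourier model to v(t) = 50 + 10 cos(2 pi t / 400 ms)
sampled at 20 fps for 5 s, then reads the full TVC parameter set off the
fitted curve and its analytic derivative.  Every printed value has a closed
form (e.g. 1/3EF = 100 (60 - 55)/60 = 8.33 %), so this doubles as a
by-hand check of the parameter definitions.
"""

import warnings

import numpy as np

from zfcardio import VolumeSeries, fourier_fit, tvc_parameters

times = np.arange(100) * 50.0  # ms
volumes = 50.0 + 10.0 * np.cos(2 * np.pi * times / 400.0)  # pl

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # 5th harmonic of 400 ms sits at Nyquist
    fit = fourier_fit(VolumeSeries(times, volumes), period_ms=400.0)
m = tvc_parameters(fit)

print(f"EDV (V1)  = {m.V1:7.3f} pl      ESV (V2) = {m.V2:7.3f} pl")
print(f"EF        = {m.EF_pct:7.3f} %    1/3EF    = {m.one_third_EF_pct:7.3f} %")
print(f"1/3FF     = {m.one_third_FF_pct:7.3f} %")
print(f"TPE       = {m.TD1:7.2f} ms     TPF      = {m.TD2:7.2f} ms")
print(f"|D1| = D2 = {-m.D1:7.5f} pl/ms (= 10 * 2 pi / 400)")
print(f"PER = PFR = {m.PER:7.4f}  (peak rate x 1000 / EDV)")
# The symmetric cosine gives TPE = TPF = T/4 and equal peak ejection and
# filling rates; asymmetric real cycles separate these numbers.
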
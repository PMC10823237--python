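"""Small band-limited signal helpers shared by the simulator and the
waveform analysis (fractional-sample delays for ADC stagger handling)."""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft


def fractional_shift(x: np.ndarray, shift_samples: np.ndarray | float) -> np.ndarray:
    """Delay each row of ``x`` by a (possibly fractional) number of samples.

    Positive shift moves the signal later in time.  Implemented as an FFT
    phase ramp, i.e. ideal band-limited (periodic) interpolation; shifts are
    expected to be sub-sample to a few samples, far smaller than the trace
    length, so the circular wrap-around is negligible.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    shifts = np.broadcast_to(np.asarray(shift_samples, dtype=float), (x.shape[0],))
    if np.all(shifts == 0):
        return x.copy()
    freqs = sp_fft.rfftfreq(n)
    spec = sp_fft.rfft(x, axis=-1)
    phase = np.exp(-2j * np.pi * freqs[None, :] * shifts[:, None])
    # the Nyquist bin of an even-length real signal must stay real
    if n % 2 == 0:
        phase[:, -1] = phase[:, -1].real
    return sp_fft.irfft(spec * phase, n=n, axis=-1)
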
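"""Poisson rate coding of an intensity image.

Builds a small grayscale image, encodes it as an event stream whose
per-pixel Poisson rates are proportional to intensity (total normalized
to 5 keps), and shows that bright pixels carry proportionally more
events.
"""

import numpy as np

from spikegrad import poisson_encode, poisson_rates

image = np.array([
    [0.0, 0.2, 0.0],
    [0.8, 1.0, 0.8],
    [0.0, 0.2, 0.0],
])

rates = poisson_rates(image, total_rate=5000.0)
print(f"summed rate parameter: {rates.sum():.1f} events/s")

stream = poisson_encode(image, total_rate=5000.0, duration=1.0, seed=0)
counts = np.bincount(stream.sources, minlength=image.size).reshape(3, 3)
print(f"{len(stream)} events in 1 s; per-pixel counts:")
print(counts)
print("The count map mirrors the intensity pattern: the centre pixel "
      "(intensity 1.0) collects ~5x the events of the 0.2 pixels, and "
      "zero-intensity pixels stay silent.")
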
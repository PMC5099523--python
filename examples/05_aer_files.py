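"""AER event-file round trips and event-window sampling.

Generates a moving-pattern stream (two polarity channels on a 34x34
grid, the DVS sensor layout), writes it as a 5-byte-record AER binary
file, reads it back, and samples a 300-event training window — the
subsampling used when training directly on sensor recordings.
"""

import pathlib
import tempfile

import numpy as np

from spikegrad import make_moving_task, read_nmnist, sample_event_window, write_nmnist

task = make_moving_task(n_classes=4, grid=(34, 34), n_phases=3, seed=0,
                        duration=0.3)
stream, label = task.train_sample(0, 0.3, np.random.default_rng(1))
print(f"class {label}: {len(stream)} events over {stream.duration * 1e3:.0f} ms "
      f"on {stream.n_sources} sources (34 x 34 x 2 polarity channels)")

with tempfile.TemporaryDirectory() as d:
    path = pathlib.Path(d) / "sample.bin"
    write_nmnist(stream, path)
    print(f"AER file size: {path.stat().st_size} bytes "
          f"({path.stat().st_size // len(stream)} bytes/event)")
    back = read_nmnist(path)
    dt = np.abs(back.times - stream.times).max()
    print(f"round trip: {len(back)} events, max timestamp error {dt * 1e6:.2f} us")

window = sample_event_window(stream, 300, seed=7)
print(f"sampled window: {len(window)} consecutive events spanning "
      f"{window.duration * 1e3:.1f} ms (times re-zeroed to window start)")
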
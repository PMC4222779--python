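"""The built-in craniofacial landmark scheme and coordinate file I/O.

Prints the catalogue structure, then writes one synthetic configuration to
CSV and TPS and reads it back, demonstrating lossless round-trips.
"""

import tempfile
from pathlib import Path

import numpy as np

from embryomorph import (
    Configuration,
    TrialDataset,
    builtin_scheme,
    read_dataset,
    write_dataset,
)

scheme = builtin_scheme()
print(f"{scheme.count} landmarks: {len(scheme.midline_ids)} midline, "
      f"{(scheme.count - len(scheme.midline_ids)) // 2} bilateral pairs")
for subset in ("Nasal", "MaxMand", "NonFacial"):
    print(f"  {subset:10s}: {len(scheme.subset_ids(subset))} landmarks")
trouble = sorted({scheme.pair_label(i) for i in scheme.trouble_ids})
print(f"  trouble labels (high placement error): {trouble}")
print(f"  landmark 9 pairs with {scheme.pair(9)} "
      f"(subset {scheme[9].subset}); ids 19 and 36 are unused")

rng = np.random.default_rng(0)
cfg = Configuration.from_array(
    scheme, rng.normal(0, 1, (36, 3)), "demo01", "E10.5", "obs1", 1
)
ds = TrialDataset(scheme, [cfg])
with tempfile.TemporaryDirectory() as tmp:
    for fmt in ("csv", "tps"):
        path = write_dataset(ds, Path(tmp) / f"demo.{fmt}", fmt)
        back = read_dataset(path, fmt)
        delta = np.abs(
            back.configurations[0].array(scheme) - cfg.array(scheme)
        ).max()
        print(f"{fmt.upper()} round trip: max coordinate delta {delta:.1e} mm")
# deltas are ~1e-12 mm: the text formats preserve coordinates far below
# any biologically meaningful scale
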
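"""Write a phantom volume to disk, read it back, and pick the central slice.

Builds a small digital-sphere volume, round-trips it through both on-disk
layouts (16-bit raster stack and DICOM series) and selects the analysis
slice as the one with the largest tumor cross-section through the seed.
"""

import tempfile
from pathlib import Path

import numpy as np

from cbctresp import (
    read_volume,
    select_central_slice,
    volume_from_array,
    write_dicom_series,
    write_raster_stack,
)

zz, rr, cc = np.mgrid[0:15, 0:41, 0:41]
inside = (zz - 7) ** 2 + (rr - 20) ** 2 + (cc - 20) ** 2 <= 8**2
volume = volume_from_array(np.where(inside, 60.0, -800.0),
                           spacing=(0.9, 0.9), slice_thickness=2.0)

with tempfile.TemporaryDirectory() as tmp:
    raster_dir = write_raster_stack(volume, Path(tmp) / "stack", hu_offset=-1024)
    dicom_dir = write_dicom_series(volume, Path(tmp) / "dcm")
    for fmt, path in (("raster_stack", raster_dir), ("dicom_series", dicom_dir)):
        back = read_volume(path, fmt)
        lossless = bool(np.array_equal(back.as_array(), volume.as_array()))
        print(f"{fmt}: {len(back)} slices, spacing {back.spacing}, lossless={lossless}")

central = select_central_slice(volume, seed=(4, 20, 20), iso_value=-375.0)
print(f"central slice (largest cross-section through the seed): index {central}")
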
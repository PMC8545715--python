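"""Published per-replicate reference measurements for softwood-pellet char.

These are the printed per-sample estimates for the five scanned replicates
(two pyrolyzed at 550 °C, three at 700 °C): total porosity of the 1024³
region of interest, volume fraction and volume of the largest pore, its
surface-to-volume ratio, and the ratio of an equal-volume sphere.  They are
used for desk-check arithmetic (cohort means and unit conversions); the raw
tomography volumes are not publicly deposited.
"""
from __future__ import annotations

import pandas as pd

#: Voxel edge length of the reference scans, µm.
REFERENCE_VOXEL_EDGE_UM = 0.87

#: Edge of the cubic region of interest, voxels.
REFERENCE_ROI_EDGE_VOX = 1024

REFERENCE_SAMPLES = pd.DataFrame(
    [
        # sample, group, total_porosity, largest_pore_fraction,
        # largest_pore_volume_mm3, largest_pore_sa_v, sphere_equiv_sa_v
        ("SWP550-1", "SWP550", 0.577, 0.9993, 0.408, 0.242, 0.00567),
        ("SWP550-2", "SWP550", 0.582, 0.9991, 0.411, 0.220, 0.00566),
        ("SWP700-1", "SWP700", 0.565, 0.9992, 0.399, 0.231, 0.00572),
        ("SWP700-2", "SWP700", 0.582, 0.9994, 0.411, 0.235, 0.00566),
        ("SWP700-3", "SWP700", 0.578, 0.9992, 0.408, 0.225, 0.00567),
    ],
    columns=[
        "sample",
        "group",
        "total_porosity",
        "largest_pore_fraction",
        "largest_pore_volume_mm3",
        "largest_pore_sa_v",
        "sphere_equiv_sa_v",
    ],
)
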
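"""Build a library entry from a standard injection and migrate an RT library.

Library building: a single-compound standard is injected with the alkane
mix; the dominant deconvoluted component near the expected retention time
becomes the entry, and its Kovats RI is computed from the batch calibration.

Migration: a vendor library annotated with retention times (for a reference
column/program) is mapped onto the local RT scale by a linear fit through a
few anchor compounds, then converted to RIs.
"""

import numpy as np

import gcscreen as g
from gcscreen.rical import ri_to_rt, rt_to_ri
from gcscreen.simdata import PlantedCompound, SimConfig

calib = g.default_calibration()

# --- entry building -------------------------------------------------------
true_mz = np.array([91.0542, 120.0575, 165.0699, 180.0934])
true_rel = np.array([999.0, 550.0, 300.0, 120.0])
rt = float(ri_to_rt(1500.0, calib))
std = PlantedCompound(name="std", rt=rt, mz=true_mz, rel=true_rel, base_area=1e6)
run, _ = g.simulate_run([std], SimConfig(seed=21))

entry = g.build_entry_from_run(run, expected_rt=rt, calib=calib, name="My compound")
print(f"built entry {entry.name!r}: RI {entry.ri:.1f} (planted 1500), "
      f"{entry.mz.size} ions")
g.write_msp(g.SpectralLibrary(entries=[entry]), "/tmp/inhouse.msp")

# --- RT-library migration -------------------------------------------------
rng = np.random.default_rng(4)
entries = []
for k in range(12):
    mz = np.sort(rng.uniform(50, 400, 5).round(4))
    rel = np.sort(np.append(rng.uniform(50, 900, 4), 999.0))
    entries.append(g.LibraryEntry(name=f"P{k}", mz=mz, rel_intensity=rel,
                                  rt=200.0 + 60.0 * k))
vendor = g.SpectralLibrary(entries=entries, source="vendor")

a, b = 0.98, 6.0  # our column runs slightly faster with a 6 s offset
anchors = [(e.name, e.rt, a * e.rt + b) for e in entries]
migrated, fit = g.migrate_rt_library(vendor, anchors, calib)
print(f"anchor fit: rt_exp = {fit.a:.4f} * rt_lib + {fit.b:.2f}  "
      f"(R^2 = {fit.r_squared:.6f}, max |residual| = "
      f"{np.max(np.abs(fit.residuals)):.2e} s)")
print(f"entry P0: rt {entries[0].rt:.0f} s -> RI {migrated.entries[0].ri:.1f} "
      f"(= RI of corrected rt: {rt_to_ri(a * entries[0].rt + b, calib):.1f})")
# With exactly affine anchors the fit is exact and every entry's RI equals
# the RI of its corrected retention time.
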
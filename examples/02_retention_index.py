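"""Kovats retention-index calibration: CRT tables and RT<->RI conversion.

The linear (temperature-programmed) convention assigns an n-alkane with n
carbons the index 100*n and interpolates linearly between the bracketing
alkanes.  The CRT file is a per-batch CSV of alkane retention times.
"""

import gcscreen as g

run, calib, _ = g.simulate_alkane_run((7, 40), config=g.SimConfig(seed=2))
print(f"alkane run: {len(run)} scans, C7 at {calib.rt[0]:.0f}s, "
      f"C40 at {calib.rt[-1]:.0f}s")

g.write_crt(calib, "/tmp/alkanes.crt.csv")
calib = g.load_crt("/tmp/alkanes.crt.csv")

for rt in (600.0, 636.0, 1000.0):
    ri = g.rt_to_ri(rt, calib)
    print(f"rt {rt:7.1f} s -> RI {ri:7.1f} (covered: {calib.covers_rt(rt)})")
print(f"RI 1500 -> rt {g.ri_to_rt(1500.0, calib):.1f} s")
# An alkane's own retention time maps to exactly 100*n; the midpoint between
# two alkanes maps to 100*n + 50; conversion is exactly invertible.
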
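"""Forward vs reverse library matching and the pure weight factor (PWF).

A deconvoluted spectrum from a matrix sample usually carries extra ions that
do not belong to the analyte.  A reverse search (PWF = 0) ignores them; a
forward search (PWF = 1) penalizes them.  The composite score is the convex
combination 100 * (pwf * F + (1 - pwf) * R).
"""

import numpy as np

import gcscreen as g

lib_pairs = [(70.0, 300.0), (100.0, 999.0), (230.1, 120.0)]
matrix_extras = [(55.5, 80.0), (81.2, 140.0), (150.6, 90.0)]

mz, rel = map(np.array, zip(*lib_pairs))
entry = g.LibraryEntry(name="analyte", mz=mz, rel_intensity=rel)

q = sorted(lib_pairs + matrix_extras)
query = g.CentroidSpectrum(rt=0.0, mz=np.array([m for m, _ in q]),
                           intensity=np.array([i for _, i in q]))

for pwf in (0.0, 0.1, 0.25, 0.5, 0.75, 1.0):
    print(f"pwf={pwf:4.2f}  match factor = {g.match_factor(query, entry, pwf=pwf):7.3f}")
# At pwf=0 the contaminated query still scores 100 (reverse search ignores
# query-only ions); the score falls linearly toward the pure forward cosine
# as the PWF rises — this is the dial that trades false positives against
# false negatives in suspect screening.

p = g.MatchParams(penalty_free_s=10, rt_range_s=30, max_rt_penalty=20)
for d in (5.0, 20.0, 30.0, 35.0):
    mult = g.rt_penalty(d, p)
    print(f"|dRT| = {d:4.0f} s -> penalty multiplier "
          f"{'REJECT' if mult is None else f'{mult:.2f}'}")
# The trapezoidal retention penalty: free within 10 s, ramps linearly to a
# 20-point penalty at 30 s, and rejects the hit entirely beyond the range.
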
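"""2-D stability grid: adhesion vs sloughing.

Classifies full-system stability over a log-spaced grid of the biofilm
adhesion rate (alpha) and the cooperator sloughing rate (beta_X), everything
else at the stable medians with cheaters present.  Faster sloughing demands
faster adhesion — the stable region's boundary climbs.
"""

from biofilmchemostat import run_grid

g = run_grid("alpha", "beta_X", resolution=12)
print("rows: beta_X (sloughing, increasing down)  "
      "cols: alpha (adhesion, increasing right)")
print("'#' = full stable coexistence, '.' = anything less\n")
for iy, beta_x in enumerate(g.y_values):
    row = "".join("#" if s else "." for s in g.stable[iy])
    print(f"beta_X={beta_x:7.4f}  {row}")
print(f"\nstable cells: {int(g.stable.sum())}/{g.stable.size}")
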
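"""Generate the adaptive milestone pathway between the hinge endpoints.

Both endpoints are deformed toward each other along adaptively re-selected
soft modes until the frontiers meet (fitted RMSD < 1.5 Å).  The milestones
are the coarse-grained transition pathway later compressed into the 1D
progress coordinate.
"""

from wepath import (
    Embedding2D,
    HingeSpec,
    build_polyline,
    embed,
    generate_pathway,
    make_hinge_endpoints,
    progress,
)

a, b = make_hinge_endpoints(HingeSpec())
pathway = generate_pathway(a, b)

print(f"converged:     {pathway.converged}")
print(f"intermediates: M = {pathway.M} (bound 40)")
print(f"final gap:     {pathway.final_gap:.3f} Å (criterion 1.5 Å)")

embedding = Embedding2D(a, b)
polyline = build_polyline(pathway, embedding)
print(f"polyline:      {polyline.n_segments} segments (= M + 2)")
print("\nmilestone  side  (rmsd to A, rmsd to B)  progress")
for m, side in zip(pathway.milestones, pathway.sides):
    x, y = embed(m, embedding)
    p = progress((x, y), polyline).value
    print(f"{m.name or 'endpoint':>9}  {side:>4}  ({x:5.2f}, {y:5.2f})"
          f"      {p:6.3f}")

# Progress runs monotonically 0 -> M+2 along the pathway: the polyline
# coordinate orders the milestones correctly, which is what makes it a
# usable 1D progress coordinate for weighted-ensemble binning.
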
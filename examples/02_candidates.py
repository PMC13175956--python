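"""Generate candidate isocenter locations by two sphere-packing strategies.

The hexagonal-close-packed (HCP) strategy tiles the target with 4 mm spheres
(shrinking in 0.5 mm steps until at least max(ceil(1.4 x reference), 6)
candidates exist); the grassfire strategy packs 4/3/2 mm spheres at the
deepest interior points of the target. Both append the target centroid.
"""
import gkplan as gk

spec = gk.PhantomSpec(
    targets=[gk.TargetSpec(volume_cc=1.0, prescription_dose=18.0)],
    grid_shape=(36, 36, 36),
    spacing_mm=(1.5, 1.5, 1.5),
    skull_semi_axes_mm=(18.0, 18.0, 18.0),
)
phantom = gk.build_phantom(spec)
target = phantom.targets[0]

reference = 4  # isocenter count of the (emulated) historical plan
required = gk.required_candidate_count(reference)
print(f"reference plan has {reference} isocenters -> need >= {required} candidates")

hcp = gk.hcp_candidates(target, phantom.grid, required=required)
print(f"HCP: {hcp.count} candidates at packing diameter {hcp.diameter_mm} mm")

gf = gk.grassfire_candidates(target, phantom.grid, required=required)
placed = [float(d) for d in gf.sphere_diameters_mm if d > 0]
print(
    f"grassfire: {gf.count} candidates "
    f"({len(placed)} packed spheres with diameters {sorted(set(placed), reverse=True)} mm)"
)
# Every candidate's center voxel lies inside the target; the planning model
# later decides which of them to actually use.
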
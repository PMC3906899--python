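"""Trace the endothelial surface of a phantom and compute CLN-5 density.

Density = total above-threshold CLN-5 intensity inside the closed contour
surface / surface area (intensity per um^2).  Comparing a fragmented vessel
against an intact one recovers the simulated junctional coverage.
"""

import vesselquant as vq


def measure(coverage, seed=3):
    spec = vq.PhantomSpec(
        cln5_coverage=coverage,
        noise_model="none",
        n_nuclei={"luminal": 0, "perivascular": 0, "parenchymal": 0},
        seed=seed,
    )
    stack, truth = vq.generate_phantom(spec)
    contours = vq.extract_slice_contours(stack, "CD31", surface_name="endothelial_bm")
    mesh = vq.loft_surface(contours, stack.voxel_spacing, ring_vertices=64)
    res = vq.cln5_density(stack, "CLN-5", mesh)
    return res, truth


intact, truth = measure(1.0)
fragmented, _ = measure(0.4)

print(f"surface area (lofted): {intact.surface_area:9.1f} um^2")
print(f"surface area (true):   {truth.analytic_areas['endothelial_bm']:9.1f} um^2")
print(f"density, intact vessel:     {intact.density:7.2f} intensity/um^2")
print(f"density, fragmented vessel: {fragmented.density:7.2f} intensity/um^2")
print(f"percent change: {vq.percent_change(intact, fragmented):.1f}%  (coverage was 0.4)")
# the ~-60% change mirrors the loss of junctional staining when only 40% of
# the tight-junction lattice is retained.
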
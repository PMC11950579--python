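"""Reconstruct one intervertebral disc in 3D and sample it three ways.

Takes the L3/4 disc of a phantom patient from its label mask to a
millimetre-space surface mesh (marching cubes + low-shrinkage smoothing +
edge splitting) and draws point clouds with the three sampling schemes:
native voxel centres, rejection sampling inside the mesh, and a
regularized pattern inside the bounding ellipsoid.
"""
import numpy as np

from ivdpipe import reconstruction as rec
from ivdpipe.phantom import PhantomSpec, generate_patient

spec = PhantomSpec(n_patients=1, slices_per_patient=9, slice_shape=(96, 96),
                   pixel_spacing_mm=(1.0, 1.0), slice_spacing_mm=3.0, seed=7)
stack, labels, records = generate_patient(spec, 0)
code, level = 9, "L3/4"

occupancy, intensity = rec.masks_to_field(labels, stack, code)
voxel_volume = occupancy.values.sum() * occupancy.voxel_volume_mm3
print(f"{level} disc: {int(occupancy.values.sum())} voxels "
      f"= {voxel_volume:.0f} mm^3 at spacing {occupancy.spacing_mm} mm")

mesh = rec.extract_surface(occupancy, provenance=(stack.patient_id, level))
refined = rec.refine_mesh(mesh, smoothing_iterations=10, max_edge_length=3.0)
print(f"marching cubes: {len(mesh.faces)} faces, volume {mesh.volume_mm3:.0f} mm^3")
print(f"after refinement: {len(refined.faces)} faces, volume {refined.volume_mm3:.0f} mm^3 "
      f"({100 * abs(refined.volume_mm3 - mesh.volume_mm3) / mesh.volume_mm3:.1f}% change)")

clouds = {
    "voxel (80%)": rec.sample_voxel(occupancy, intensity, fraction=0.8, seed=0),
    "rejection": rec.sample_rejection(refined, 512, seed=0, intensity_field=intensity),
    "ellipsoid": rec.sample_ellipsoid(refined, 512, seed=0, intensity_field=intensity),
}
for name, cloud in clouds.items():
    ext = cloud.points.max(axis=0) - cloud.points.min(axis=0)
    print(f"{name:>12}: {len(cloud.points):4d} points, extent "
          f"{np.round(ext, 1)} mm, mean intensity {cloud.intensity.mean():.3f}")

print("\nThe mesh volume stays within 5% through refinement, and all three"
      "\nclouds share the disc's oblate geometry (thin cranio-caudal axis).")
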
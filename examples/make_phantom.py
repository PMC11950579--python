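"""Generate a small synthetic lumbar-spine cohort and describe it.

Builds 5 phantom patients (sagittal T2-like volumes, anatomy label masks,
per-disc Pfirrmann grades), writes them as NIfTI + CSV, and prints how disc
thickness and signal intensity vary with grade — the morphological signal
the downstream classifier is trained to recover.
"""
import numpy as np

from ivdpipe.phantom import DISC_CLASS_CODES, PhantomSpec, generate_cohort, generate_patient

spec = PhantomSpec(n_patients=5, slices_per_patient=9, slice_shape=(96, 96),
                   pixel_spacing_mm=(1.0, 1.0), slice_spacing_mm=3.0, seed=7)
manifest = generate_cohort(spec, "scratch/phantom_cohort")
print(f"wrote {manifest['n_patients']} patients under {manifest['root']}")

print(f"\n{'patient':>8} {'level':>6} {'grade':>5} {'thickness_vox':>13} {'mean_signal':>11}")
for i in range(spec.n_patients):
    stack, labels, records = generate_patient(spec, i)
    for j, rec in enumerate(records):
        mask = labels.labels == DISC_CLASS_CODES[j]
        rows = np.flatnonzero(mask.any(axis=(0, 2)))
        thickness = rows.max() - rows.min() + 1
        signal = stack.intensities[mask].mean()
        print(f"{rec.patient_id:>8} {rec.level:>6} {rec.grade:>5} "
              f"{thickness:>13d} {signal:>11.3f}")

print("\nHigher grades have thinner, darker discs: that monotone coupling is"
      "\nwhat makes the grade recoverable from geometry plus intensity.")
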
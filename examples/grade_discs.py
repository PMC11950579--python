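"""Train the dual-graph classifier to recover Pfirrmann grades on phantoms.

Builds disc graphs (48 node features: intensity, centre distance, six
hypernode distances, 20 Laplacian-eigenvector and 20 random-walk
positional-encoding dimensions; 0.1-radius edges) for a small balanced
cohort, trains the GCN + x-convolution model with the composite
focal/cross-entropy loss, and reports held-out accuracy per grade.
Runs in a few minutes.
"""
import numpy as np

from ivdpipe import reconstruction as rec
from ivdpipe.discgraph import GraphConfig, build_disc_graph
from ivdpipe.gnn import ModelConfig
from ivdpipe.phantom import DISC_CLASS_CODES, LEVELS, PhantomSpec, generate_patient
from ivdpipe.training import TrainConfig, classification_report, train_classifier

spec = PhantomSpec(n_patients=25, slices_per_patient=9, slice_shape=(96, 96),
                   pixel_spacing_mm=(1.0, 1.0), slice_spacing_mm=3.0,
                   grade_distribution=(0.2,) * 5, seed=11)
graphs = []
for i in range(spec.n_patients):
    stack, labels, records = generate_patient(spec, i)
    for j, code in enumerate(DISC_CLASS_CODES):
        occ, inten = rec.masks_to_field(labels, stack, code)
        cloud = rec.sample_voxel(occ, inten, fraction=0.1, seed=i * 8 + j,
                                 provenance=(stack.patient_id, LEVELS[j]))
        graphs.append(build_disc_graph(cloud, records[j].grade, GraphConfig()))

pids = sorted({g.patient_id for g in graphs})
test_p = set(pids[:5])
train_g = [g for g in graphs if g.patient_id not in test_p]
test_g = [g for g in graphs if g.patient_id in test_p]
print(f"{len(train_g)} training discs, {len(test_g)} held-out discs")

model, history = train_classifier(
    train_g, test_g,
    ModelConfig(hidden_dims=(32, 64, 64), xconv_neighbors=8, attention_heads=4,
                dropout=0.1, seed=0),
    TrainConfig(epochs=20, learning_rate=1e-3, weight_decay=1e-2, seed=0),
)
print(f"final epoch: train loss {history['train_loss'][-1]:.3f}, "
      f"val accuracy {history['val_accuracy'][-1]:.2f}")

preds = [model(g) for g in test_g]
report = classification_report(preds, [g.label for g in test_g],
                               [g.level for g in test_g])
print("\nper-level macro F1 over grades:")
print(report.level_macro("f1").round(2).to_string())
print(f"\noverall macro F1: {report.overall_macro('f1'):.2f} "
      "(majority guessing on a balanced cohort would score about 0.07)")
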
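import numpy as np
import pytest

from clearquant.glomeruli import analyze_stack
from clearquant.synthetic import KidneySceneSpec, generate_kidney_stack


@pytest.fixture(scope="session")
def default_kidney_scene():
    """One default 43-glomeruli scene (3 border-truncated) shared by tests."""
    spec = KidneySceneSpec(seed=11)
    stack, truth = generate_kidney_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def analyzed_kidney_scene(default_kidney_scene):
    spec, stack, truth = default_kidney_scene
    labels, records, hist, summary = analyze_stack(stack)
    return spec, stack, truth, labels, records, hist, summary


def match_detection(records, truth_row, label_map, voxel_size=(5.0, 5.0, 5.0)):
    """Detected record whose object contains a planted center, or None."""
    c_vox = np.array(
        [truth_row.center_z_um, truth_row.center_y_um, truth_row.center_x_um]
    ) / np.asarray(voxel_size)
    c = np.clip(
        np.round(c_vox).astype(int), 0, np.array(label_map.shape) - 1
    )
    lbl = int(label_map.labels[tuple(c)])
    if lbl == 0:
        return None
    by_label = {r.label: r for r in records}
    return by_label.get(lbl)
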
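import numpy as np
import pytest

import morphocensus as mc


@pytest.fixture(scope="session")
def dense_spec():
    return mc.SlideSpec("dense", n_tiles=2, cell_density=90, seed=11)


@pytest.fixture(scope="session")
def dense_slide(dense_spec):
    return mc.generate_slide(dense_spec)


@pytest.fixture(scope="session")
def processed_slide(dense_slide):
    return mc.process_slide([p for p, _ in dense_slide], slide_id="dense")


@pytest.fixture(scope="session")
def bin_model(processed_slide):
    return mc.fit_bin_model([processed_slide], seed=0)


def synth_patch(h_conc, e_conc, slide_id="syn", row=0, col=0):
    """Render concentration maps to a TilePatch through the known mixing."""
    pixels = mc.synthetic.render_concentrations(np.asarray(h_conc, float),
                                                np.asarray(e_conc, float))
    return mc.TilePatch(pixels, slide_id, row, col)


@pytest.fixture(scope="session")
def tumor_normal_patches():
    """Separable patch label set: dense large-cell 'tumor' vs sparse 'normal'."""
    patches, labels, pids = [], [], []
    for i in range(10):
        tumor = mc.SlideSpec(f"T{i}", n_tiles=3, cell_density=120,
                             area_mu=float(np.log(700)), seed=100 + i)
        normal = mc.SlideSpec(f"N{i}", n_tiles=3, cell_density=25,
                              area_mu=float(np.log(300)), seed=200 + i)
        for spec, lab in ((tumor, "tumor"), (normal, "normal")):
            for t in range(spec.n_tiles):
                patch, _ = mc.generate_tile(spec, t)
                patches.append(patch)
                labels.append(lab)
                pids.append(f"pat{i}")
    return mc.PatchLabelSet(patches, np.array(labels), np.array(pids))
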
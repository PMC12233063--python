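import numpy as np
import pytest

from hexeye.classify import train_models
from hexeye.synthfly import (
    SyntheticEyeSpec,
    annotation_from_ground_truth,
    generate_lattice,
    ideal_probability_maps,
    render_image,
)


@pytest.fixture(scope="session")
def ideal_eye():
    """A mid-size curved synthetic eye with noise-free probability maps."""
    spec = SyntheticEyeSpec(n_target=300, seed=7)
    gt = generate_lattice(spec)
    maps = ideal_probability_maps(gt, spec)
    return spec, gt, maps


def flat_patch_spec(k: int = 4, seed: int = 0) -> SyntheticEyeSpec:
    """A nearly flat hexagonal patch holding exactly the k-ring facet count.

    The sphere radius is made huge and the cap angle tiny, so the surface
    patch radius sits between ring k's outermost facet (k*s) and ring k+1's
    innermost one (sqrt(3)/2*(k+1)*s).
    """
    s = 16.0
    R = 1.0e6
    r_max = (k + 0.2) * s
    return SyntheticEyeSpec(
        n_target=3 * k * (k + 1) + 1,
        sphere_radius=R,
        cap_angle=np.degrees(r_max / R),
        facet_spacing=s,
        seed=seed,
    )


@pytest.fixture(scope="session")
def flat_patch():
    """Flat 61-facet (4-ring) patch with ideal maps."""
    spec = flat_patch_spec(k=4, seed=3)
    gt = generate_lattice(spec)
    maps = ideal_probability_maps(gt, spec)
    return spec, gt, maps


@pytest.fixture(scope="session")
def trained_models():
    """Pixel models trained on one rendered synthetic eye (150 annotated
    facets), plus a second same-spec eye for held-out evaluation."""
    spec_train = SyntheticEyeSpec(n_target=800, seed=11)
    gt_train = generate_lattice(spec_train)
    img_train = render_image(gt_train, spec_train)
    ann = annotation_from_ground_truth(gt_train, spec_train, n_facets=150, seed=11)
    eye_model, facet_model = train_models([ann], [img_train], seed=0)
    spec_test = SyntheticEyeSpec(n_target=800, seed=12)
    gt_test = generate_lattice(spec_test)
    img_test = render_image(gt_test, spec_test)
    return {
        "spec": spec_train,
        "gt_train": gt_train,
        "img_train": img_train,
        "annotation": ann,
        "eye_model": eye_model,
        "facet_model": facet_model,
        "gt_test": gt_test,
        "img_test": img_test,
    }
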
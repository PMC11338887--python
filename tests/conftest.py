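import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import myelometry as m


def make_annulus_scene(r_in=70.0, thickness=30.0, shape=(512, 512), noise_sd=0.0, seed=0):
    """One circular annulus centered in the image, with its spec and axon."""
    spec = m.SceneSpec(
        image_shape=shape, n_axons=0, layer1_depth_px=shape[0] / 4, noise_sd=noise_sd, seed=seed
    )
    center = (shape[0] / 2.0, shape[1] / 2.0)
    axon = m.AxonSpec(
        axon_id=0,
        center=center,
        inner_semi_axes=(r_in, r_in),
        orientation=0.0,
        g_true=r_in / (r_in + thickness),
        thickness_true=thickness,
    )
    image, truth_mask, table = m.render_scene([axon], spec)
    return spec, axon, image, truth_mask, table


@pytest.fixture(scope="session")
def annulus_scene():
    return make_annulus_scene()


def measure_scene_vs_truth(spec):
    """Render one scene, run segmentation + morphometry, join to ground truth."""
    axons = m.sample_axon_population(spec)
    image, _, truth = m.render_scene(axons, spec)
    mask = m.segment_myelin_reference(image)
    labels = m.label_sheaths(mask)
    meas, _ = m.measure_sheaths(labels, px_size_nm=spec.px_size_nm, layer_spec=spec.layer_spec)
    centers = np.array([ax.center for ax in axons])
    dist, idx = cKDTree(centers).query(meas[["depth_px", "center_col_px"]].to_numpy())
    assert dist.max() < 2.0, "measured sheath centers should match rendered axon centers"
    meas = meas.assign(axon_id=[axons[i].axon_id for i in idx])
    return meas.merge(truth, on="axon_id")


def measure_cohort_vs_truth(n_images=8, noise_sd=0.0, seed0=100, **spec_kwargs):
    frames = [
        measure_scene_vs_truth(m.SceneSpec(noise_sd=noise_sd, seed=seed0 + k, **spec_kwargs))
        for k in range(n_images)
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """200 axons (8 default scenes) rendered without noise, matched to truth."""
    df = measure_cohort_vs_truth(n_images=8, noise_sd=0.0, seed0=100)
    assert len(df) == 200
    return df


@pytest.fixture(scope="session")
def healthy_default_cohort():
    """200 axons under the generator's full defaults (noise included)."""
    df = measure_cohort_vs_truth(n_images=8, noise_sd=m.SceneSpec().noise_sd, seed0=300)
    assert len(df) == 200
    return df


def truth_cohort_table(control_spec, treated_spec, n_per_group, rng):
    """Per-sheath metric table drawn from the generators' morphology marginals.

    Used for large-scale statistical calibration of the compare stage, where
    rendering every cohort would add nothing: under identical specs the two
    groups are exchangeable whatever the imaging stage does.
    """
    frames = []
    for group, spec in (("control", control_spec), ("treated", treated_spec)):
        df = m.sample_truth_metrics(spec, n_per_group, rng)
        frames.append(
            pd.DataFrame(
                {
                    "thickness_mean_nm": df.thickness_true_nm,
                    "g_ratio": df.g_true,
                    "axon_diameter_nm": df.diameter_true_nm,
                    "layer": df.layer_true,
                    "group": group,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def ellipse_points(center, a, b, theta, n=36, phase=0.0):
    """Exact points on an ellipse, (row, col) convention."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    u = a * np.cos(t)
    v = b * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    return np.column_stack(
        [center[0] + u * ct - v * st, center[1] + u * st + v * ct]
    )
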
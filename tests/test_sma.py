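"""Fluorescence vessel masking, branch decomposition, SMA coverage."""

import numpy as np
import pytest

from pericytometry import (
    BranchRecord,
    SmaParams,
    branch_decompose,
    coverage_by_diameter,
    measure_branches,
    sma_mask,
    vessel_mask,
)
from pericytometry.synthetic import generate_if_image


def _tube(width_um=10.0, cov=0.4, noise=3.0, seed=0, grad=0.0):
    line = np.array([[40.5, 10.0], [40.5, 390.0]])
    return generate_if_image(
        400, 80, 1.0, [(line, width_um, cov)],
        noise_sigma=noise, gradient_amplitude=grad, seed=seed,
    )


def test_vessel_mask_covers_tube():
    img, truth = _tube()
    m = vessel_mask(img, 1.0)
    tube = truth[0]["tube_mask"]
    overlap = (m & tube).sum() / tube.sum()
    assert overlap > 0.95
    assert (m & ~tube).sum() < 0.05 * tube.sum()


def test_vessel_mask_background_invariance():
    m_flat = vessel_mask(_tube(grad=0.0)[0], 1.0)
    m_grad = vessel_mask(_tube(grad=30.0)[0], 1.0)
    sym_diff = (m_flat ^ m_grad).sum()
    assert sym_diff < 0.05 * m_flat.sum()


def test_uniform_image_gives_empty_mask():
    img = np.full((64, 64), 80.0)
    assert vessel_mask(img, 1.0).sum() == 0


def test_sma_mask_recovers_coverage_fraction():
    img, truth = _tube(cov=0.4)
    m = vessel_mask(img, 1.0)
    s = sma_mask(img, 1.0, vessel=m)
    assert s.sum() / m.sum() == pytest.approx(0.40, abs=0.05)


def test_zero_sma_image_warns_and_is_empty():
    img, _ = _tube(cov=0.0)
    with pytest.warns(UserWarning, match="unimodal"):
        s = sma_mask(img, 1.0)
    assert s.sum() == 0


def test_branch_assignment_partitions_mask():
    branches = [
        (np.array([[20.5, 5.0], [20.5, 195.0]]), 8.0, 0.5),
        (np.array([[60.5, 5.0], [60.5, 195.0]]), 12.0, 0.5),
    ]
    img, _ = generate_if_image(200, 84, 1.0, branches, noise_sigma=2, seed=3)
    m = vessel_mask(img, 1.0)
    records, assignment = branch_decompose(m, 1.0)
    assert len(records) == 2  # two parallel disjoint tubes
    assert ((assignment > 0) == m).all()  # exact partition
    for rec in records:
        assert (assignment == rec.branch_id).sum() > 0


def test_y_junction_three_branches():
    j = [
        (np.array([[100.5, 10.0], [100.5, 250.0]]), 10.0, 0.8),
        (np.array([[30.5, 480.0], [100.5, 250.0]]), 6.0, 0.4),
        (np.array([[180.5, 480.0], [100.5, 250.0]]), 20.0, 0.1),
    ]
    img, _ = generate_if_image(512, 256, 1.0, j, noise_sigma=0.0, seed=1)
    recs = measure_branches(img, 1.0)
    assert len(recs) == 3
    diams = sorted(r.mean_diameter_um for r in recs)
    assert diams[0] == pytest.approx(6.0, rel=0.15)
    assert diams[2] == pytest.approx(20.0, rel=0.15)


@pytest.mark.parametrize("width", [4.0, 10.0, 20.0, 30.0])
def test_tube_diameter_within_10pct(width):
    img, _ = _tube(width_um=width)
    recs = measure_branches(img, 1.0)
    assert len(recs) == 1
    assert recs[0].mean_diameter_um == pytest.approx(width, rel=0.10)


def test_single_pixel_scale_mask_degenerate_branch():
    m = np.zeros((32, 32), bool)
    m[10, 10] = True
    recs, assignment = branch_decompose(m, 1.0)
    assert len(recs) == 1
    assert assignment[10, 10] == 1


def test_coverage_by_diameter_binning():
    branches = [
        BranchRecord(1, 6.0, 50.0, 300.0, 90.0),
        BranchRecord(2, 15.0, 50.0, 700.0, 30.0),
    ]
    table = coverage_by_diameter(branches, [0, 10, 25, 40])
    assert table.loc[0, "mean_coverage_pct"] == 90.0
    assert table.loc[1, "mean_coverage_pct"] == 30.0
    assert table.loc[2, "n_branches"] == 0 and np.isnan(
        table.loc[2, "mean_coverage_pct"]
    )


def test_programmed_width_coverage_trend_recovered():
    """Coverage programmed to fall with width -> monotone bin means."""
    specs = [(6.0, 0.9), (14.0, 0.6), (24.0, 0.3)]
    rows = []
    for i, (w, c) in enumerate(specs):
        img, _ = _tube(width_um=w, cov=c, seed=10 + i)
        rows.extend(measure_branches(img, 1.0))
    table = coverage_by_diameter(rows, [0, 10, 20, 30])
    means = table["mean_coverage_pct"].to_numpy()
    assert means[0] > means[1] > means[2]
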
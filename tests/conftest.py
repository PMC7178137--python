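"""Shared fixtures and independent brute-force oracles.

The oracles are deliberately written as plain Python loops, separate from
the library's vectorised/spatial-index code paths, so that agreement
between the two is a meaningful check.
"""

import math

import numpy as np
import pytest

from ppisite import synthetic
from ppisite.features import FEATURE_COLUMNS


# ---------------------------------------------------------------------------
# oracles


def brute_force_knn_disagreement(X, y, k=3):
    """Indices whose k nearest neighbours (self excluded, Euclidean) hold a
    strict majority of the opposite label. Ties broken by index order, as
    a stable sort on distance gives."""
    n = len(X)
    flagged = []
    for i in range(n):
        dists = sorted(
            (math.dist(X[i], X[j]), j) for j in range(n) if j != i
        )
        neighbors = [j for _, j in dists[:k]]
        n_diff = sum(1 for j in neighbors if y[j] != y[i])
        if n_diff >= (k // 2 + 1):
            flagged.append(i)
    return flagged


def brute_force_renn(X, y, k=3, target="all", max_iter=100):
    """Reference RENN: batch removal per sweep until a sweep removes
    nothing. Returns the surviving original indices."""
    majority = 0 if np.sum(y == 0) >= np.sum(y == 1) else 1
    alive = list(range(len(X)))
    for _ in range(max_iter):
        Xa = [X[i] for i in alive]
        ya = [y[i] for i in alive]
        flagged = brute_force_knn_disagreement(Xa, ya, k)
        if target == "negatives_only":
            flagged = [p for p in flagged if ya[p] == majority]
        if not flagged:
            break
        flagged_set = set(flagged)
        alive = [i for p, i in enumerate(alive) if p not in flagged_set]
        if len(alive) < k + 1:
            break
    return alive


def brute_force_interface_pairs(coords_a, coords_b, cutoff):
    """All (i, j) index pairs with Euclidean distance <= cutoff."""
    pairs = set()
    for i, a in enumerate(coords_a):
        for j, b in enumerate(coords_b):
            if math.dist(a, b) <= cutoff:
                pairs.add((i, j))
    return pairs


def metric_formulas_scalar(tp, tn, fp, fn):
    """Independent scalar evaluation of the six measures (duplicate-formula
    oracle; no shared code with the evaluation module)."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sen = tp / (tp + fn) if tp + fn else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    spe = tn / (fp + tn) if fp + tn else 0.0
    f = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    return acc, sen, pre, spe, f, mcc


def two_sphere_exposed_areas(r1, r2, d, probe):
    """Closed-form solvent-accessible areas of two spheres at distance d.

    Each accessible sphere has radius R_i = r_i + probe; the buried part of
    sphere 1 is the spherical cap cut off by the radical plane:
    A_buried = 2 pi R1 (R1 - (d^2 + R1^2 - R2^2) / (2 d)).
    """
    R1, R2 = r1 + probe, r2 + probe
    a1 = 4 * math.pi * R1**2
    a2 = 4 * math.pi * R2**2
    if d < R1 + R2:
        h1 = R1 - (d**2 + R1**2 - R2**2) / (2 * d)
        h2 = R2 - (d**2 + R2**2 - R1**2) / (2 * d)
        a1 -= 2 * math.pi * R1 * h1
        a2 -= 2 * math.pi * R2 * h2
    return a1, a2


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_scenario_samples():
    """The default overlap scenario (with planted ground truth), shared
    across tests to avoid regenerating."""
    samples, overlap_keys = synthetic.make_samples(synthetic.OverlapScenario())
    return samples, overlap_keys


@pytest.fixture(scope="session")
def contact_fixture_pdb(tmp_path_factory):
    """Two 8-residue chains with exactly two cross-chain contacts."""
    text = synthetic.make_structure_fixture(
        n_residues=(8, 8), contact_pairs=((2, 2), (5, 5))
    )
    path = tmp_path_factory.mktemp("pdb") / "contact.pdb"
    path.write_text(text)
    return path


@pytest.fixture()
def feature_rows_for_chain():
    def _make(chain_id, residue_numbers, seed=0):
        return synthetic.make_feature_rows(chain_id, residue_numbers, seed=seed)

    return _make


def assert_profile_rows_valid(X, feature_names):
    """FeatureRow invariants on a sample matrix: every 24-column block's
    profile part is non-negative and sums to 1."""
    block = len(FEATURE_COLUMNS)
    assert X.shape[1] % block == 0
    for b in range(X.shape[1] // block):
        prof = X[:, b * block : b * block + 20]
        assert np.all(prof >= 0)
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=0.01)
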
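"""Synthetic fixtures: toy structures and imbalanced overlapping samples.

Everything the pipeline consumes can be generated here without external
data: (a) two-chain poly-alanine coordinate sets with an exactly controlled
cross-chain contact map, emitted as standard PDB text, and (b) labeled
sample clouds that mimic the statistical structure of real surface-residue
datasets — a minority interface class, a majority non-interface class, and
a planted subset of negatives drawn from the *positive* class distribution.

The planted negatives make the class-overlap hypothesis concrete and
testable: they are exactly the samples a good editing/undersampling method
should remove, so resamplers can be scored against known ground truth
rather than against downstream classifier performance alone.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .features import FEATURE_COLUMNS, FeatureRow, SampleSet, window_feature_names

__all__ = ["OverlapScenario", "make_structure_fixture", "make_samples", "make_feature_rows"]

_ALA_OFFSETS = {
    # local atom offsets from CA (Angstrom); compact, chemically plausible
    "N": (-1.20, 0.65, 0.40),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.22, 0.62, -0.38),
    "O": (1.90, 1.52, -0.40),
    "CB": (0.05, -1.03, 1.10),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_structure_fixture(
    n_residues: tuple[int, int] = (8, 8),
    gap: float = 30.0,
    contact_pairs: tuple[tuple[int, int], ...] = (),
    contact_distance: float = 8.0,
    spacing: float = 20.0,
    seed: int = 0,
    jitter: float = 0.0,
) -> str:
    """Two-chain poly-alanine PDB text with an exact cross-chain contact map.

    Chain A Calphas sit on a line at ``spacing`` Angstrom intervals; chain B
    runs parallel at distance ``gap``. For each requested contact pair
    (i, j) — 0-based residue indices into chains A and B — residue j of
    chain B is relocated opposite residue i at ``contact_distance``, so the
    Calpha-Calpha contact set at the 12 Angstrom interface cutoff is
    exactly the requested pairs. A contradictory request (e.g. a contact
    the geometry cannot isolate, or ``contact_distance`` beyond the cutoff)
    raises ValueError.
    """
    n_a, n_b = n_residues
    if n_a < 1 or n_b < 1:
        raise ValueError("each chain needs at least one residue")
    cutoff = 12.0
    if contact_distance > cutoff:
        raise ValueError(
            f"contact_distance {contact_distance} exceeds the {cutoff} A cutoff"
        )
    if gap <= cutoff:
        raise ValueError(f"gap {gap} must exceed the {cutoff} A cutoff")
    contact_pairs = tuple((int(i), int(j)) for i, j in contact_pairs)
    for i, j in contact_pairs:
        if not (0 <= i < n_a and 0 <= j < n_b):
            raise ValueError(f"contact pair {(i, j)} outside chain bounds")
    if len({j for _, j in contact_pairs}) != len(contact_pairs):
        raise ValueError("each chain-B residue may appear in one contact pair only")

    rng = np.random.default_rng(seed)
    ca_a = np.array([[i * spacing, 0.0, 0.0] for i in range(n_a)])
    ca_b = np.array([[j * spacing, gap, 0.0] for j in range(n_b)])
    for i, j in contact_pairs:
        ca_b[j] = [i * spacing, contact_distance, 0.0]
    if jitter > 0:
        ca_a = ca_a + rng.normal(scale=jitter, size=ca_a.shape)
        ca_b = ca_b + rng.normal(scale=jitter, size=ca_b.shape)

    # Verify the emitted geometry realises exactly the requested contacts.
    d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=-1)
    realised = {(i, j) for i, j in zip(*np.nonzero(d <= cutoff))}
    if realised != set(contact_pairs):
        raise ValueError(
            "contradictory fixture spec: requested contacts "
            f"{sorted(set(contact_pairs))} but geometry realises {sorted(realised)}"
        )

    n_atoms_per_res = len(_ALA_OFFSETS)
    total = (n_a + n_b) * n_atoms_per_res
    atoms = struc.AtomArray(total)
    coords, chain_ids, res_ids, atom_names, elements = [], [], [], [], []
    for chain_id, cas in (("A", ca_a), ("B", ca_b)):
        for idx, ca in enumerate(cas):
            for name, off in _ALA_OFFSETS.items():
                coords.append(ca + np.asarray(off))
                chain_ids.append(chain_id)
                res_ids.append(idx + 1)
                atom_names.append(name)
                elements.append(_ELEMENTS[name])
    atoms.coord = np.asarray(coords)
    atoms.chain_id = np.asarray(chain_ids)
    atoms.res_id = np.asarray(res_ids)
    atoms.res_name = np.full(total, "ALA")
    atoms.atom_name = np.asarray(atom_names)
    atoms.element = np.asarray(elements)
    atoms.hetero = np.zeros(total, dtype=bool)

    pdb = PDBFile()
    pdb.set_structure(atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


@dataclass
class OverlapScenario:
    """Generator settings for an imbalanced, partially overlapping dataset.

    ``n_overlap`` of the ``n_negative`` negatives are *planted*: drawn from
    the positive-class distribution but labeled negative, a ground-truth
    overlap region (fraction ``n_overlap / n_negative`` of the majority
    class). ``separation`` is the distance between the clean class means in
    units of the within-class spread; ``spread`` the isotropic
    standard deviation per feature (raw space, before profile
    normalisation).
    """

    n_positive: int = 300
    n_negative: int = 1100
    n_overlap: int = 100
    dim: int = 24
    separation: float = 4.0
    spread: float = 1.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("class counts must be positive")
        if not (0 <= self.n_overlap <= self.n_negative):
            raise ValueError("n_overlap must lie within [0, n_negative]")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.spread <= 0:
            raise ValueError("spread must be positive")

    @property
    def overlap_fraction(self) -> float:
        return self.n_overlap / self.n_negative


def _feature_names(dim: int) -> list[str]:
    if dim == len(FEATURE_COLUMNS):
        return list(FEATURE_COLUMNS)
    if dim % len(FEATURE_COLUMNS) == 0:
        return window_feature_names(dim // len(FEATURE_COLUMNS))
    return [f"f{i}" for i in range(dim)]


def _softmax_profile_blocks(X: np.ndarray) -> np.ndarray:
    """Map each 24-column block's first 20 columns onto the probability
    simplex (softmax per row) so profile invariants hold; the 4 scalar
    columns per block pass through."""
    X = X.copy()
    block = len(FEATURE_COLUMNS)
    if X.shape[1] % block != 0:
        return X
    for b in range(X.shape[1] // block):
        cols = slice(b * block, b * block + 20)
        z = X[:, cols]
        z = np.exp(z - z.max(axis=1, keepdims=True))
        X[:, cols] = z / z.sum(axis=1, keepdims=True)
    return X


def make_samples(
    scenario: OverlapScenario | None = None,
) -> tuple[SampleSet, list[tuple[str, int]]]:
    """Draw an imbalanced two-class sample cloud with planted overlap.

    Clean positives ~ N(mu, spread^2 I), clean negatives ~ N(0,
    spread^2 I) with |mu| = separation * spread along a fixed direction;
    the planted negatives are drawn from the positive distribution. Profile
    blocks are normalised to the simplex afterwards. Returns the sample set
    (rows shuffled, reproducibly) and the provenance keys of the planted
    overlap negatives.
    """
    sc = scenario or OverlapScenario()
    rng = np.random.default_rng(sc.seed)
    # Class contrast must survive profile normalisation: a softmax is
    # invariant to a constant shift of all 20 logits, so the shift
    # alternates sign across profile positions (interface residues differ
    # in residue *composition*, not in overall profile level) and is
    # uniform across the scalar conservation features.
    u = np.empty(sc.dim)
    block = len(FEATURE_COLUMNS)
    if sc.dim % block == 0:
        for b in range(sc.dim // block):
            u[b * block : b * block + 20] = [(-1.0) ** i for i in range(20)]
            u[b * block + 20 : (b + 1) * block] = 1.0
    else:
        u[:] = [(-1.0) ** i for i in range(sc.dim)]
    u /= np.linalg.norm(u)
    mu = sc.separation * sc.spread * u

    n_clean_neg = sc.n_negative - sc.n_overlap
    X_pos = rng.normal(loc=mu, scale=sc.spread, size=(sc.n_positive, sc.dim))
    X_neg = rng.normal(loc=0.0, scale=sc.spread, size=(n_clean_neg, sc.dim))
    X_ovl = rng.normal(loc=mu, scale=sc.spread, size=(sc.n_overlap, sc.dim))

    X = np.vstack([X_pos, X_neg, X_ovl])
    X = _softmax_profile_blocks(X)
    y = np.concatenate(
        [np.ones(sc.n_positive, int), np.zeros(n_clean_neg + sc.n_overlap, int)]
    )
    provenance = (
        [("P", i) for i in range(sc.n_positive)]
        + [("N", i) for i in range(n_clean_neg)]
        + [("O", i) for i in range(sc.n_overlap)]
    )
    order = rng.permutation(len(y))
    samples = SampleSet(
        X=X[order],
        y=y[order],
        provenance=[provenance[i] for i in order],
        feature_names=_feature_names(sc.dim),
        meta={"scenario": sc.__dict__.copy()},
    )
    overlap_keys = [("O", i) for i in range(sc.n_overlap)]
    return samples, overlap_keys


def make_feature_rows(
    chain_id: str,
    residue_numbers: list[int],
    seed: int = 0,
) -> list[FeatureRow]:
    """Random per-residue conservation descriptors satisfying the row
    invariants (Dirichlet profile summing to 1, non-negative entropy)."""
    rng = np.random.default_rng(seed)
    rows = []
    for resnum in residue_numbers:
        profile = rng.dirichlet(np.ones(20))
        entropy = float(-np.sum(profile * np.log(np.clip(profile, 1e-12, None))))
        rows.append(
            FeatureRow(
                chain_id=chain_id,
                residue_number=int(resnum),
                profile=profile,
                entropy=entropy,
                relative_entropy=float(rng.normal()),
                weight=float(rng.uniform(0.5, 1.5)),
                conservation=float(rng.uniform(0, 9)),
            )
        )
    return rows
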
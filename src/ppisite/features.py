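"""Per-residue conservation descriptors and spatial-window encoding.

Each residue carries a 24-dimensional evolutionary-conservation descriptor:
a 20-entry sequence profile (amino-acid frequencies, summing to 1), sequence
information entropy, relative entropy, sequence weight, and a conservation
score. Descriptors arrive as tab-separated tables (they originate from
alignment databases / conservation servers upstream of this package).

A surface residue is encoded for classification by concatenating its own
descriptor with those of its 10 nearest surface neighbors on the same chain
(Calpha Euclidean distance, increasing; ties broken by ascending residue
number), giving an 11 x 24 = 264-dimensional sample vector. Chains with
fewer than 11 usable surface residues are zero-padded and the pad count is
recorded per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import LABEL_INTERFACE, ResidueSite

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "FEATURE_COLUMNS",
    "WINDOW_SIZE",
    "FeatureRow",
    "SampleSet",
    "read_feature_table",
    "write_feature_table",
    "build_windows",
    "read_sample_table",
    "write_sample_table",
    "window_feature_names",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROFILE_COLUMNS = tuple(f"p_{a}" for a in AMINO_ACIDS)
SCALAR_COLUMNS = ("entropy", "relative_entropy", "weight", "conservation")
FEATURE_COLUMNS = PROFILE_COLUMNS + SCALAR_COLUMNS  # 24 names
KEY_COLUMNS = ("chain", "resnum")
WINDOW_SIZE = 11  # target residue + 10 spatial neighbors


@dataclass
class FeatureRow:
    """24-dimensional conservation descriptor of one residue."""

    chain_id: str
    residue_number: int
    profile: np.ndarray  # (20,) non-negative frequencies
    entropy: float
    relative_entropy: float
    weight: float
    conservation: float

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (20,):
            raise ValueError("profile must have exactly 20 entries")
        if np.any(self.profile < 0):
            raise ValueError("profile frequencies must be non-negative")

    @property
    def vector(self) -> np.ndarray:
        """The 24-entry descriptor in canonical column order."""
        return np.concatenate(
            [
                self.profile,
                [self.entropy, self.relative_entropy, self.weight, self.conservation],
            ]
        )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass
class SampleSet:
    """Labeled feature matrix with per-row provenance.

    For window-encoded data ``X`` has 264 columns (11 residues x 24
    features); the synthetic generator may produce reduced dimensionality.
    ``window_map`` lists, per row, the (chain, resnum) keys of the residues
    contributing to the window, target first; ``pad_counts`` the number of
    zero-padded neighbor slots.
    """

    X: np.ndarray
    y: np.ndarray  # 1 = interface, 0 = non_interface
    provenance: list[tuple[str, int]]
    feature_names: list[str]
    window_map: list[list[tuple[str, int]]] | None = None
    pad_counts: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.y) != len(self.X) or len(self.provenance) != len(self.X):
            raise ValueError("X, y and provenance must have equal length")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(positives, negatives)."""
        return int(np.sum(self.y == 1)), int(np.sum(self.y == 0))

    def subset(self, indices: np.ndarray) -> "SampleSet":
        indices = np.asarray(indices)
        return SampleSet(
            X=self.X[indices],
            y=self.y[indices],
            provenance=[self.provenance[i] for i in indices],
            feature_names=list(self.feature_names),
            window_map=(
                [self.window_map[i] for i in indices] if self.window_map else None
            ),
            pad_counts=(
                self.pad_counts[indices] if self.pad_counts is not None else None
            ),
            meta=dict(self.meta),
        )


def read_feature_table(path: str | Path) -> list[FeatureRow]:
    """Read a per-residue feature TSV.

    The header must name the two key columns (chain, resnum) and exactly the
    24 feature columns; duplicate (chain, resnum) keys and non-numeric cells
    are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    expected = set(KEY_COLUMNS) | set(FEATURE_COLUMNS)
    present = set(df.columns)
    missing = sorted(expected - present)
    extra = sorted(present - expected)
    if missing or extra:
        raise ValueError(
            f"feature table column mismatch: missing={missing} extra={extra}"
        )
    for col in FEATURE_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = int(values.index[values.isna()][0]) + 2  # 1-based + header
            raise ValueError(f"non-numeric cell in column {col!r} at line {row}")
        df[col] = values
    keys = list(zip(df["chain"], df["resnum"].astype(int)))
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (chain, resnum) keys: {dupes[:5]}")
    rows = []
    for (_, rec), key in zip(df.iterrows(), keys):
        rows.append(
            FeatureRow(
                chain_id=key[0],
                residue_number=key[1],
                profile=rec[list(PROFILE_COLUMNS)].to_numpy(dtype=float),
                entropy=float(rec["entropy"]),
                relative_entropy=float(rec["relative_entropy"]),
                weight=float(rec["weight"]),
                conservation=float(rec["conservation"]),
            )
        )
    return rows


def write_feature_table(rows: list[FeatureRow], path: str | Path) -> None:
    records = []
    for r in rows:
        rec = {"chain": r.chain_id, "resnum": r.residue_number}
        rec.update(dict(zip(FEATURE_COLUMNS, r.vector)))
        records.append(rec)
    df = pd.DataFrame.from_records(
        records, columns=list(KEY_COLUMNS) + list(FEATURE_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def window_feature_names(window: int = WINDOW_SIZE) -> list[str]:
    return [f"w{j}_{name}" for j in range(window) for name in FEATURE_COLUMNS]


def _site_coord(site: ResidueSite) -> np.ndarray | None:
    if site.ca_coordinates is not None:
        return site.ca_coordinates
    if len(site.carbon_coordinates):
        return site.carbon_coordinates[0]
    return None


def build_windows(
    sites: list[ResidueSite],
    rows: list[FeatureRow],
    window: int = WINDOW_SIZE,
) -> SampleSet:
    """Encode every labeled surface residue as a spatial-window vector.

    Neighbors are the nearest surface residues of the *same* chain by
    Calpha distance; the target's own descriptor comes first, then the
    ``window - 1`` neighbors by increasing distance (ties by ascending
    residue number). Surface residues without a feature row or without
    coordinates are dropped (counted in ``meta``).
    """
    feature_map = {r.key: r for r in rows}
    by_chain: dict[str, list[ResidueSite]] = {}
    n_dropped = 0
    for s in sites:
        if not s.is_surface:
            continue
        if (s.chain_id, s.residue_number) not in feature_map:
            logger.warning(
                "surface residue %s%d has no feature row; dropped",
                s.chain_id,
                s.residue_number,
            )
            n_dropped += 1
            continue
        if _site_coord(s) is None:
            logger.warning(
                "surface residue %s%d has no coordinates; dropped",
                s.chain_id,
                s.residue_number,
            )
            n_dropped += 1
            continue
        by_chain.setdefault(s.chain_id, []).append(s)

    dim = window * len(FEATURE_COLUMNS)
    X_rows, labels, provenance, window_map, pads = [], [], [], [], []
    for chain_id in sorted(by_chain):
        chain_sites = sorted(by_chain[chain_id], key=lambda s: (s.residue_number, s.icode))
        coords = np.vstack([_site_coord(s) for s in chain_sites])
        resnums = np.array([s.residue_number for s in chain_sites])
        dists = cdist(coords, coords)
        for i, s in enumerate(chain_sites):
            # neighbors ordered by (distance, residue number); self excluded
            order = np.lexsort((resnums, dists[i]))
            order = order[order != i][: window - 1]
            members = [s] + [chain_sites[j] for j in order]
            vec = np.concatenate(
                [
                    feature_map[(m.chain_id, m.residue_number)].vector
                    for m in members
                ]
            )
            n_pad = dim - len(vec)
            if n_pad:
                vec = np.concatenate([vec, np.zeros(n_pad)])
            X_rows.append(vec)
            labels.append(1 if s.label == LABEL_INTERFACE else 0)
            provenance.append((s.chain_id, s.residue_number))
            window_map.append([(m.chain_id, m.residue_number) for m in members])
            pads.append(n_pad // len(FEATURE_COLUMNS))

    if not X_rows:
        raise ValueError("no usable surface residues to encode")
    return SampleSet(
        X=np.vstack(X_rows),
        y=np.array(labels),
        provenance=provenance,
        feature_names=window_feature_names(window),
        window_map=window_map,
        pad_counts=np.array(pads),
        meta={"n_dropped_no_features": n_dropped, "window": window},
    )


def write_sample_table(samples: SampleSet, path: str | Path) -> None:
    """Sample matrix as dense TSV: keys, pad count, label, feature columns."""
    df = pd.DataFrame(samples.X, columns=samples.feature_names)
    df.insert(0, "chain", [p[0] for p in samples.provenance])
    df.insert(1, "resnum", [p[1] for p in samples.provenance])
    df.insert(
        2,
        "pad",
        samples.pad_counts if samples.pad_counts is not None else 0,
    )
    df.insert(3, "label", samples.y)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_sample_table(path: str | Path) -> SampleSet:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    for col in ("chain", "resnum", "pad", "label"):
        if col not in df.columns:
            raise ValueError(f"sample table lacks required column {col!r}")
    feature_names = [
        c for c in df.columns if c not in ("chain", "resnum", "pad", "label")
    ]
    return SampleSet(
        X=df[feature_names].to_numpy(dtype=float),
        y=df["label"].to_numpy(dtype=int),
        provenance=list(zip(df["chain"], df["resnum"].astype(int))),
        feature_names=feature_names,
        pad_counts=df["pad"].to_numpy(dtype=int),
    )
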
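"""Surface and interface residue labeling from multi-chain structures.

The pipeline's geometric ground truth: each residue of a complex is assigned
an absolute accessible surface area (ASA, Shrake-Rupley on the isolated
chain), a relative accessible surface area (RASA = ASA / residue-type
maximum), and a label:

* ``surface``: RASA strictly greater than the threshold (default 16%),
  computed in the monomer state so that residues buried by the partner chain
  still count as surface.
* ``interface``: a surface residue within the distance cutoff (default
  12 Angstrom = 1.2 nm, inclusive) of any residue of the partner chain,
  either Calpha-Calpha or minimum over all carbon-atom pairs.
* ``non_interface``: surface but beyond the cutoff.
* ``buried``: not surface.

RASA normalisation uses the Tien et al. (2013) theoretical maximum ASA
values shipped with the package; an alternative table may be supplied.
Note that an isolated residue (no flanking peptide) can exceed RASA 1.0
because the reference maxima are defined in a Gly-X-Gly context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
import biotite.structure.info as struc_info
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueSite",
    "load_max_asa",
    "load_structure",
    "compute_residue_sites",
    "label_surface",
    "label_interface",
    "write_site_table",
    "read_site_table",
    "DEFAULT_RASA_THRESHOLD",
    "DEFAULT_CUTOFF_A",
]

DEFAULT_RASA_THRESHOLD = 0.16
DEFAULT_CUTOFF_A = 12.0  # 1.2 nm

LABEL_INTERFACE = "interface"
LABEL_NON_INTERFACE = "non_interface"
LABEL_BURIED = "buried"


@dataclass
class ResidueSite:
    """One residue of one chain with geometry, accessibility and label."""

    chain_id: str
    residue_number: int
    icode: str
    residue_name: str
    ca_coordinates: np.ndarray | None  # (3,) in Angstrom, None if no CA
    carbon_coordinates: np.ndarray  # (n_carbon, 3) in Angstrom
    asa: float  # absolute, Angstrom^2
    rasa: float  # asa / max_asa(residue_name)
    is_surface: bool = False
    label: str = LABEL_BURIED

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.icode)


def load_max_asa(path: str | Path | None = None) -> dict[str, float]:
    """Residue-type maximum ASA table (3-letter code -> Angstrom^2).

    Defaults to the packaged Tien et al. 2013 theoretical values; a custom
    two-column TSV (residue, max_asa) may be supplied instead.
    """
    if path is None:
        ref = resources.files("ppisite").joinpath("data/max_asa_tien2013.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, value = line.split("\t")
        table[name.strip()] = float(value)
    bad = [k for k, v in table.items() if v <= 0]
    if bad:
        raise ValueError(f"max-ASA values must be positive; offending residues: {bad}")
    return table


def load_structure(path: str | Path) -> struc.AtomArray:
    """Read a PDB file into an atom array.

    First model only; highest-occupancy alternate conformer; hydrogens and
    HETATM records dropped, except selenomethionine (MSE) which is converted
    to MET (SE renamed to SD).
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    # MSE -> MET before the hetero filter
    mse = atoms.res_name == "MSE"
    if np.any(mse):
        atoms.res_name[mse] = "MET"
        atoms.hetero[mse] = False
        se = mse & (atoms.atom_name == "SE")
        atoms.atom_name[se] = "SD"
        atoms.element[se] = "S"
    keep = ~atoms.hetero & ~np.isin(atoms.element, ("H", "D"))
    return atoms[keep]


def _atom_radii(atoms: struc.AtomArray) -> np.ndarray:
    """ProtOr van der Waals radii with a per-element fallback."""
    radii = np.empty(atoms.array_length())
    for i in range(atoms.array_length()):
        try:
            radii[i] = struc_info.vdw_radius_protor(atoms.res_name[i], atoms.atom_name[i])
        except (KeyError, ValueError):
            r = struc_info.vdw_radius_single(atoms.element[i])
            if r is None:
                r = 1.7
            radii[i] = r
    return radii


def compute_residue_sites(
    atoms: struc.AtomArray,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    max_asa: dict[str, float] | None = None,
) -> list[ResidueSite]:
    """Per-residue ASA/RASA for every chain of a complex.

    ASA is computed with the Shrake-Rupley method on each chain in
    isolation (monomer state), so residues occluded only by the partner
    chain keep their full accessibility and can later be labeled interface.

    Residues without atoms or without a max-ASA entry are excluded with a
    logged warning.
    """
    if atoms.array_length() == 0:
        raise ValueError("structure contains no atoms")
    if max_asa is None:
        max_asa = load_max_asa()
    sites: list[ResidueSite] = []
    for chain_id in np.unique(atoms.chain_id):
        chain = atoms[atoms.chain_id == chain_id]
        known = np.isin(chain.res_name, list(max_asa))
        unknown_names = set(chain.res_name[~known])
        if unknown_names:
            logger.warning(
                "chain %s: excluding residues with no max-ASA entry: %s",
                chain_id,
                sorted(unknown_names),
            )
        chain = chain[known]
        if chain.array_length() == 0:
            logger.warning("chain %s: no residues usable for ASA", chain_id)
            continue
        atom_sasa = struc.sasa(
            chain,
            probe_radius=probe_radius,
            point_number=sphere_points,
            vdw_radii=_atom_radii(chain),
        )
        res_starts = struc.get_residue_starts(chain, add_exclusive_stop=True)
        for start, stop in zip(res_starts[:-1], res_starts[1:]):
            res = chain[start:stop]
            res_asa = float(np.nansum(atom_sasa[start:stop]))
            name = res.res_name[0]
            ca = res.coord[res.atom_name == "CA"]
            carbons = res.coord[res.element == "C"]
            sites.append(
                ResidueSite(
                    chain_id=str(chain_id),
                    residue_number=int(res.res_id[0]),
                    icode=str(res.ins_code[0]).strip(),
                    residue_name=str(name),
                    ca_coordinates=ca[0].copy() if len(ca) else None,
                    carbon_coordinates=carbons.copy(),
                    asa=res_asa,
                    rasa=res_asa / max_asa[name],
                )
            )
    return sites


def label_surface(
    sites: list[ResidueSite], threshold: float = DEFAULT_RASA_THRESHOLD
) -> list[ResidueSite]:
    """Mark residues with RASA strictly above ``threshold`` as surface.

    Strict inequality: RASA exactly at the threshold is buried.
    """
    out = []
    for s in sites:
        on_surface = s.rasa > threshold
        out.append(
            replace(
                s,
                is_surface=on_surface,
                label=LABEL_NON_INTERFACE if on_surface else LABEL_BURIED,
            )
        )
    return out


def _reference_coords(site: ResidueSite, mode: str) -> np.ndarray:
    """Coordinates a residue contributes to the distance computation."""
    if mode == "ca_ca":
        if site.ca_coordinates is not None:
            return site.ca_coordinates.reshape(1, 3)
        if len(site.carbon_coordinates):
            logger.warning(
                "residue %s%d%s has no CA; falling back to first carbon atom",
                site.chain_id,
                site.residue_number,
                site.icode,
            )
            return site.carbon_coordinates[:1]
        raise ValueError(
            f"residue {site.chain_id}{site.residue_number} has no carbon atoms"
        )
    if mode == "min_carbon":
        if len(site.carbon_coordinates) == 0:
            raise ValueError(
                f"residue {site.chain_id}{site.residue_number} has no carbon atoms"
            )
        return site.carbon_coordinates
    raise ValueError(f"unknown distance mode {mode!r}; use 'ca_ca' or 'min_carbon'")


def label_interface(
    chain_a: list[ResidueSite],
    chain_b: list[ResidueSite],
    cutoff: float = DEFAULT_CUTOFF_A,
    mode: str = "ca_ca",
) -> list[ResidueSite]:
    """Label the surface residues of ``chain_a`` against partner ``chain_b``.

    A surface residue becomes ``interface`` iff its distance to some residue
    of the partner chain is <= cutoff (inclusive; only distances strictly
    beyond 1.2 nm are non-interface) under the chosen mode:
    ``ca_ca`` (Calpha-Calpha) or ``min_carbon`` (minimum over all carbon
    pairs). Buried residues keep the ``buried`` label.
    """
    if not chain_b:
        raise ValueError("partner chain is empty")
    b_coords = np.vstack([_reference_coords(s, mode) for s in chain_b])
    out = []
    for s in chain_a:
        if not s.is_surface:
            out.append(replace(s, label=LABEL_BURIED))
            continue
        d = cdist(_reference_coords(s, mode), b_coords)
        near = bool(d.min() <= cutoff)
        out.append(replace(s, label=LABEL_INTERFACE if near else LABEL_NON_INTERFACE))
    return out


def write_site_table(
    sites: list[ResidueSite],
    path: str | Path,
    cutoff: float | None = None,
    mode: str | None = None,
    probe_radius: float | None = None,
    rasa_threshold: float | None = None,
) -> None:
    """Tab-separated site table; parameters recorded in ``#`` header lines."""
    lines = []
    if cutoff is not None:
        lines.append(f"# cutoff_A={cutoff:g}")
    if mode is not None:
        lines.append(f"# distance_mode={mode}")
    if probe_radius is not None:
        lines.append(f"# probe_radius_A={probe_radius:g}")
    if rasa_threshold is not None:
        lines.append(f"# rasa_threshold={rasa_threshold:g}")
    lines.append(
        "chain\tresnum\ticode\tresname\tca_x\tca_y\tca_z\tasa\trasa\tlabel"
    )
    for s in sites:
        ca = s.ca_coordinates
        ca_txt = (
            "\t".join(f"{v:.3f}" for v in ca) if ca is not None else "nan\tnan\tnan"
        )
        lines.append(
            f"{s.chain_id}\t{s.residue_number}\t{s.icode or '.'}\t{s.residue_name}"
            f"\t{ca_txt}\t{s.asa:.4f}\t{s.rasa:.6f}\t{s.label}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_site_table(path: str | Path) -> list[ResidueSite]:
    """Inverse of :func:`write_site_table` (carbon coordinates are not
    persisted; ``ca_ca`` neighbor geometry is)."""
    sites = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("chain\t"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 10:
            raise ValueError(f"malformed site-table row: {line!r}")
        chain, resnum, icode, resname, x, y, z, asa, rasa, label = parts
        ca = None
        if x != "nan":
            ca = np.array([float(x), float(y), float(z)])
        sites.append(
            ResidueSite(
                chain_id=chain,
                residue_number=int(resnum),
                icode="" if icode == "." else icode,
                residue_name=resname,
                ca_coordinates=ca,
                carbon_coordinates=np.empty((0, 3)),
                asa=float(asa),
                rasa=float(rasa),
                is_surface=label in (LABEL_INTERFACE, LABEL_NON_INTERFACE),
                label=label,
            )
        )
    return sites
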
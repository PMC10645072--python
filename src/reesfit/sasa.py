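"""Per-tryptophan solvent-accessible surface area from PDB structures.

SASA is computed with the Shrake-Rupley dot method: each atom's van der
Waals sphere is expanded by the probe radius (default 1.4 Angstrom, a
water molecule) and covered with a deterministic golden-spiral point
set; the accessible area is the fraction of points not buried inside
any neighbour's expanded sphere times the expanded sphere area.  The
deterministic point set makes results exactly reproducible.

Tryptophan exposure is reported two ways: absolute SASA per residue
(backbone + side-chain atoms) and relative exposure as a percentage of
a reference maximum Trp SASA (default 264.0 A^2, the theoretical
Gly-Trp-Gly maximum of Tien et al. 2013); 0% is a completely buried
residue.  The average SASA per Trp — total Trp SASA divided by the
number of Trp residues — is the molecule-level summary used to compare
variants with different tryptophan content.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "TrpSASAReport",
    "VDW_RADII",
    "MAX_TRP_SASA",
    "parse_structure",
    "write_pdb",
    "shrake_rupley",
    "trp_report",
]

# van der Waals radii (Angstrom); Bondi-style values for the elements of
# heavy-atom protein models.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# theoretical maximum Trp SASA in a Gly-Trp-Gly tripeptide (Tien et al.
# 2013), used as the relative-exposure denominator
MAX_TRP_SASA = 264.0

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


@dataclass(frozen=True)
class StructureModel:
    """Heavy-atom coordinate model with per-atom vdW radii attached.

    Residue numbering is kept exactly as authored in the source file.
    """

    chain_ids: np.ndarray  # str
    residue_numbers: np.ndarray  # str, number + insertion code
    residue_names: np.ndarray  # str
    atom_names: np.ndarray  # str
    elements: np.ndarray  # str, upper-case
    coords: np.ndarray  # (n, 3) float, Angstrom
    radii: np.ndarray  # (n,) float, Angstrom

    def __post_init__(self) -> None:
        n = len(self.coords)
        if n == 0:
            raise ValueError("structure has no atoms")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be a finite (n, 3) array")
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError("radii must be positive, one per atom")
        for name in ("chain_ids", "residue_numbers", "residue_names", "atom_names", "elements"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match atom count")

    def __len__(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> list[tuple[str, str, str]]:
        """Unique (chain, residue number, residue name) in file order."""
        seen: dict[tuple[str, str, str], None] = {}
        for c, rn, rname in zip(self.chain_ids, self.residue_numbers, self.residue_names):
            seen.setdefault((c, rn, rname))
        return list(seen)


def _lookup_radius(element: str, atom_label: str, radii: dict[str, float]) -> float:
    try:
        return radii[element.upper()]
    except KeyError:
        raise ValueError(
            f"no van der Waals radius for element {element!r} (atom {atom_label}); "
            "extend the radii table to include it"
        ) from None


def parse_structure(
    path,
    *,
    include_hydrogens: bool = False,
    include_hetero: bool = False,
    radii: dict[str, float] | None = None,
) -> StructureModel:
    """Load a PDB file into a :class:`StructureModel`.

    Defaults follow heavy-atom homology-model conventions: hydrogens,
    waters and heteroatoms are excluded; for alternate locations the
    highest-occupancy conformer is kept.  Only the first model of a
    multi-model file is read.
    """
    path = Path(path)
    radii = dict(VDW_RADII if radii is None else radii)
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in file")
    model = structure[0]
    rows: list[tuple] = []
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            if not include_hetero and residue.het_flag == "H":
                continue
            # for alternate locations keep the highest-occupancy conformer
            best_by_name: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best_by_name.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best_by_name[atom.name] = atom
            for atom in best_by_name.values():
                if not include_hydrogens and atom.element.is_hydrogen:
                    continue
                element = atom.element.name.upper()
                label = f"{chain.name}/{residue.seqid}{residue.name}/{atom.name}"
                rows.append(
                    (
                        chain.name,
                        str(residue.seqid).strip(),
                        residue.name,
                        atom.name,
                        element,
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                        _lookup_radius(element, label, radii),
                    )
                )
    if not rows:
        raise ValueError(f"{path}: no ATOM records after filtering")
    return StructureModel(
        chain_ids=np.array([r[0] for r in rows]),
        residue_numbers=np.array([r[1] for r in rows]),
        residue_names=np.array([r[2] for r in rows]),
        atom_names=np.array([r[3] for r in rows]),
        elements=np.array([r[4] for r in rows]),
        coords=np.array([r[5] for r in rows], dtype=float),
        radii=np.array([r[6] for r in rows], dtype=float),
    )


def write_pdb(structure: StructureModel, path) -> None:
    """Write a minimal PDB file (ATOM records + END) for a model."""
    lines = []
    for i in range(len(structure)):
        name = structure.atom_names[i]
        # PDB atom-name column convention: 1-letter elements start in col 14
        padded = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = structure.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {padded:<4s} {structure.residue_names[i]:<3s} "
            f"{structure.chain_ids[i]:1s}{int(structure.residue_numbers[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{structure.elements[i]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def golden_spiral_points(n: int) -> np.ndarray:
    """Quasi-uniform deterministic points on the unit sphere (Fibonacci
    lattice)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _test_point_set(n: int) -> np.ndarray:
    """Inversion-symmetric Fibonacci point set (odd n rounded up).

    Closing the set under p -> -p cancels odd-order discretization error
    in the buried-fraction estimate.
    """
    half = golden_spiral_points((n + 1) // 2)
    return np.vstack([half, -half])


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))
_INV_PHI = (np.sqrt(5.0) - 1.0) / 2.0


def _atom_rotation(i: int) -> np.ndarray:
    """Deterministic rotation of the test point set for index ``i``.

    Decorrelates the discretization error between neighbouring atoms so
    per-atom errors average out in residue and molecule totals instead
    of adding coherently.
    """
    a = _GOLDEN_ANGLE * i
    b = 2.0 * np.pi * _INV_PHI * i
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    return rx @ rz


def _point_set_indices(structure: StructureModel) -> np.ndarray:
    """Rotation index per atom: within-residue position plus the
    residue's rank within its chain.

    Chain identity is deliberately excluded so that equivalent residues
    of identical chains (e.g. the two copies of a homodimer, or a
    translated duplicate molecule) receive bit-identical point sets.
    """
    idx = np.empty(len(structure), dtype=int)
    atom_in_res: dict[tuple[str, str, str], int] = {}
    res_rank: dict[tuple[str, str, str], int] = {}
    next_rank: dict[str, int] = {}
    for i, key in enumerate(
        zip(structure.chain_ids, structure.residue_numbers, structure.residue_names)
    ):
        if key not in res_rank:
            chain = key[0]
            res_rank[key] = next_rank.get(chain, 0)
            next_rank[chain] = res_rank[key] + 1
        atom_in_res[key] = atom_in_res.get(key, -1) + 1
        idx[i] = atom_in_res[key] + 37 * res_rank[key]
    return idx


def shrake_rupley(
    structure: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in A^2.

    For each atom, test points on the probe-expanded sphere are checked
    against every neighbouring expanded sphere; the accessible fraction
    times 4*pi*(r_vdw + probe)^2 is the atom's SASA.  Neighbours are
    found with a KD-tree at the maximum possible interaction distance.
    """
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 12:
        raise ValueError("n_points must be >= 12 for a meaningful estimate")
    coords = structure.coords
    expanded = structure.radii + probe_radius
    sphere = _test_point_set(n_points)
    n_points = len(sphere)
    tree = cKDTree(coords)
    cutoff = 2.0 * expanded.max()
    neighbor_lists = tree.query_ball_point(coords, r=cutoff)
    point_set_index = _point_set_indices(structure)
    sasa = np.empty(len(structure))
    for i in range(len(structure)):
        pts = coords[i] + expanded[i] * (
            sphere @ _atom_rotation(point_set_index[i]).T
        )
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            # only spheres that can actually intersect atom i's shell
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= expanded[i] + expanded[j]:
                continue
            within = np.einsum(
                "ij,ij->i", pts - coords[j], pts - coords[j]
            ) < expanded[j] ** 2
            accessible &= ~within
            if not accessible.any():
                break
        sasa[i] = accessible.mean() * 4.0 * np.pi * expanded[i] ** 2
    return sasa


@dataclass(frozen=True)
class TrpSASAReport:
    """Tryptophan exposure summary for one structure."""

    per_residue: pd.DataFrame  # chain, resnum, sasa_A2, rel_exposure_pct
    total_trp_sasa: float
    n_trp: int
    average_sasa_per_trp: float
    max_trp_sasa_reference: float
    warnings: tuple[str, ...] = ()


def trp_report(
    structure: StructureModel,
    per_atom_sasa: np.ndarray,
    *,
    max_trp_sasa: float = MAX_TRP_SASA,
    expected_n_trp: int | None = None,
) -> TrpSASAReport:
    """Aggregate per-atom SASA into the per-tryptophan report.

    Each Trp residue's SASA sums backbone plus side-chain atoms.
    Relative exposure above 100% (possible for models exceeding the
    reference maximum) is kept but flagged in ``warnings``.
    """
    if len(per_atom_sasa) != len(structure):
        raise ValueError("per-atom SASA does not match the structure")
    warnings: list[str] = []
    rows = []
    for chain, resnum, resname in structure.residue_keys():
        if resname != "TRP":
            continue
        mask = (
            (structure.chain_ids == chain)
            & (structure.residue_numbers == resnum)
            & (structure.residue_names == resname)
        )
        res_sasa = float(per_atom_sasa[mask].sum())
        rel = 100.0 * res_sasa / max_trp_sasa
        if rel > 100.0:
            warnings.append(
                f"Trp {chain}/{resnum}: relative exposure {rel:.1f}% exceeds the "
                f"reference maximum ({max_trp_sasa:g} A^2)"
            )
        rows.append(
            {"chain": chain, "resnum": resnum, "sasa_A2": res_sasa, "rel_exposure_pct": rel}
        )
    if not rows:
        raise ValueError("structure contains no TRP residues")
    per_residue = pd.DataFrame(rows)
    n_trp = len(per_residue)
    total = float(per_residue["sasa_A2"].sum())
    if expected_n_trp is not None and expected_n_trp != n_trp:
        warnings.append(
            f"expected {expected_n_trp} Trp residues from metadata, found {n_trp}"
        )
    return TrpSASAReport(
        per_residue=per_residue,
        total_trp_sasa=total,
        n_trp=n_trp,
        average_sasa_per_trp=total / n_trp,
        max_trp_sasa_reference=max_trp_sasa,
        warnings=tuple(warnings),
    )
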
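"""Trajectory post-processing: protein-DNA contacts, H-bonds, SASA.

Operates on multi-model PDB coordinate files (MODEL/ENDMDL frames) with a
constant atom roster; atoms are partitioned into protein residues and DNA
atoms by residue-name whitelist. Three analyses mirror standard MD
post-processing of deaminase-DNA complexes:

* residue-to-DNA minimum distances, time-averaged over frames;
* hydrogen-bond occupancy — fraction of frames in which at least one
  donor-acceptor pair satisfies geometric criteria;
* solvent-accessible surface area by Shrake-Rupley quadrature, and the
  derived fraction-buried of a residue against a maximally exposed
  reference state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

#: Bondi van der Waals radii (Angstrom).
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "ZN": 1.39, "NA": 2.27, "MG": 1.73, "K": 2.75, "CA": 2.31,
}

#: Theoretical maximum ASA (Angstrom^2) of residue X in an extended
#: Gly-X-Gly tripeptide (Tien et al. 2013), the default burial reference.
MAX_ASA_GXG: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DNA_RESNAMES: frozenset[str] = frozenset({"DA", "DC", "DG", "DT"})


@dataclass
class Trajectory:
    """Frames of labeled coordinates split into protein residues and DNA.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; per-atom
    metadata arrays share the atom axis. The atom roster is constant
    across frames.
    """

    coords: np.ndarray
    elements: np.ndarray       # str per atom
    atom_names: np.ndarray
    residue_index: np.ndarray  # int per atom
    resnames: np.ndarray
    chain_class: np.ndarray    # "protein" | "dna"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[1]
        for name in ("elements", "atom_names", "residue_index", "resnames", "chain_class"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length mismatch with atom axis")
            setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def protein_residue_atoms(self, residue_index: int) -> np.ndarray:
        mask = (self.chain_class == "protein") & (self.residue_index == residue_index)
        if not mask.any():
            raise ValueError(f"no protein atoms for residue {residue_index}")
        return np.flatnonzero(mask)

    @property
    def dna_atoms(self) -> np.ndarray:
        return np.flatnonzero(self.chain_class == "dna")

    def select_frames(self, frames) -> "Trajectory":
        """Restrict to a frame selection (e.g. the unconstrained tail)."""
        idx = np.arange(self.n_frames)[frames]
        if np.size(idx) == 0:
            raise ValueError("empty frame selection")
        return Trajectory(
            coords=self.coords[idx].reshape(-1, self.n_atoms, 3),
            elements=self.elements, atom_names=self.atom_names,
            residue_index=self.residue_index, resnames=self.resnames,
            chain_class=self.chain_class,
        )

    @classmethod
    def from_pdb(cls, path, dna_resnames: frozenset[str] = DNA_RESNAMES) -> "Trajectory":
        """Load a multi-model PDB; chains are classed DNA by residue name."""
        from Bio.PDB import PDBParser

        structure = PDBParser(QUIET=True).get_structure("traj", str(path))
        frames = []
        meta = None
        for model in structure:
            xyz, elements, names, resids, resnames = [], [], [], [], []
            for chain in model:
                for residue in chain:
                    for atom in residue:
                        xyz.append(atom.coord)
                        elements.append((atom.element or atom.get_name()[0]).upper())
                        names.append(atom.get_name())
                        resids.append(residue.id[1])
                        resnames.append(residue.get_resname().strip())
            frames.append(np.array(xyz, dtype=float))
            key = (tuple(names), tuple(resids), tuple(resnames))
            if meta is None:
                meta = (elements, names, resids, resnames, key)
            elif key != meta[4]:
                raise ValueError("atom roster differs between models")
        if not frames:
            raise ValueError(f"no MODEL frames found in {path}")
        elements, names, resids, resnames, _ = meta
        resnames = np.array(resnames)
        return cls(
            coords=np.stack(frames),
            elements=np.array(elements),
            atom_names=np.array(names),
            residue_index=np.array(resids, dtype=int),
            resnames=resnames,
            chain_class=np.where(np.isin(resnames, sorted(dna_resnames)), "dna", "protein"),
        )


def min_residue_dna_distance(traj: Trajectory, frame: int, residue_index: int) -> float:
    """Minimum distance (Angstrom) from any residue atom to any DNA atom."""
    dna = traj.dna_atoms
    if dna.size == 0:
        raise ValueError("trajectory contains no DNA atoms")
    res = traj.protein_residue_atoms(residue_index)
    return float(cdist(traj.coords[frame, res], traj.coords[frame, dna]).min())


@dataclass
class ContactMatrix:
    """Time-averaged residue-to-DNA minimum distances with per-frame series."""

    mean: pd.Series            # residue -> mean of per-frame minima
    per_frame: pd.DataFrame    # frames x residues

    def to_frame(self) -> pd.DataFrame:
        return self.mean.rename("mean_min_distance_A").to_frame()


def time_averaged_contacts(
    traj: Trajectory, residues, frames=None
) -> ContactMatrix:
    """Per-residue arithmetic mean of per-frame minimum distances to DNA.

    ``frames`` optionally restricts the analysis window, e.g. to the tail
    of a trajectory recorded after constraints were released.
    """
    t = traj if frames is None else traj.select_frames(frames)
    data = {
        r: [min_residue_dna_distance(t, f, r) for f in range(t.n_frames)]
        for r in residues
    }
    per_frame = pd.DataFrame(data)
    return ContactMatrix(mean=per_frame.mean(axis=0), per_frame=per_frame)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (closed thresholds).

    Defaults (donor-acceptor distance <= 3.5 A, donor-hydrogen-acceptor
    angle >= 140 deg) are a stated convention; the angle test is skipped
    when no hydrogen positions are supplied.
    """

    max_distance: float = 3.5
    min_angle: float = 140.0

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not 0 < self.min_angle <= 180:
            raise ValueError("min_angle must be in (0, 180]")


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1, v2 = d - h, a - h
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_occupancy(
    traj: Trajectory,
    donors,
    acceptors,
    criteria: HBondCriteria | None = None,
    hydrogens: dict[int, list[int]] | None = None,
    frames=None,
) -> float:
    """Fraction of frames with >= 1 donor-acceptor pair within criteria.

    ``donors`` and ``acceptors`` are atom indices; ``hydrogens`` maps a
    donor atom index to its hydrogen atom indices for the angle test.
    Without hydrogens a heavy-atom distance-only criterion applies (with
    a warning). Thresholds are closed: a pair exactly at the distance
    cutoff counts.
    """
    criteria = criteria or HBondCriteria()
    donors = np.atleast_1d(np.asarray(donors, dtype=int))
    acceptors = np.atleast_1d(np.asarray(acceptors, dtype=int))
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("need at least one donor and one acceptor atom")
    if hydrogens is None:
        warnings.warn("no hydrogen positions given; distance-only H-bond criterion", stacklevel=2)
    t = traj if frames is None else traj.select_frames(frames)
    hits = 0
    for f in range(t.n_frames):
        xyz = t.coords[f]
        dmat = cdist(xyz[donors], xyz[acceptors])
        found = False
        for i, j in zip(*np.nonzero(dmat <= criteria.max_distance)):
            if hydrogens is None:
                found = True
                break
            d_idx, a_idx = int(donors[i]), int(acceptors[j])
            for h_idx in hydrogens.get(d_idx, []):
                if _dha_angle(xyz[d_idx], xyz[h_idx], xyz[a_idx]) >= criteria.min_angle:
                    found = True
                    break
            if found:
                break
        hits += found
    return hits / t.n_frames


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def atom_radii(elements, radii: dict[str, float] | None = None) -> np.ndarray:
    table = radii or BONDI_RADII
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = str(el).upper()
        if key not in table:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        out[i] = table[key]
    return out


def sasa_atoms(
    coords: np.ndarray,
    elements,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom SASA by Shrake-Rupley quadrature.

    For each atom, the fraction of ``n_points`` sphere points at radius
    r_atom + probe that fall outside every neighbouring solvent-expanded
    sphere, times the sphere area 4*pi*(r_atom+probe)^2.
    """
    coords = np.asarray(coords, dtype=float)
    r = atom_radii(elements, radii) + probe_radius
    unit = sphere_points(n_points)
    n = len(coords)
    areas = np.empty(n)
    dmat = cdist(coords, coords)
    for i in range(n):
        neighbours = np.flatnonzero((dmat[i] < r[i] + r) & (np.arange(n) != i))
        pts = coords[i] + r[i] * unit
        if neighbours.size:
            buried = np.zeros(n_points, dtype=bool)
            for j in neighbours:
                buried |= np.linalg.norm(pts - coords[j], axis=1) < r[j]
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return areas


def sasa(
    traj: Trajectory,
    frame: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> pd.Series:
    """Per-residue SASA (sum of atom SASA) for one frame."""
    areas = sasa_atoms(traj.coords[frame], traj.elements, probe_radius, n_points, radii)
    return pd.Series(areas).groupby(pd.Series(traj.residue_index)).sum().rename("sasa_A2")


def fraction_buried(
    traj: Trajectory,
    residue_index: int,
    reference: float | str = "gxg",
    probe_radius: float = 1.4,
    n_points: int = 960,
    frames=None,
    radii: dict[str, float] | None = None,
) -> float:
    """1 - mean(residue SASA over frames) / reference SASA, clamped to [0, 1].

    ``reference`` is either an explicit reference SASA (Angstrom^2) or
    ``"gxg"`` to look the residue type up in the extended Gly-X-Gly
    maximum-exposure table.
    """
    t = traj if frames is None else traj.select_frames(frames)
    atoms = t.protein_residue_atoms(residue_index)
    if isinstance(reference, str):
        if reference != "gxg":
            raise ValueError(f"unknown reference mode {reference!r}")
        resname = str(t.resnames[atoms[0]]).upper()
        if resname not in MAX_ASA_GXG:
            raise KeyError(f"residue type {resname!r} missing from the reference table")
        ref_sasa = MAX_ASA_GXG[resname]
    else:
        ref_sasa = float(reference)
        if ref_sasa <= 0:
            raise ValueError("reference SASA must be positive")
    # occlusion by atoms outside the residue matters: compute in full context
    per_frame = []
    for f in range(t.n_frames):
        all_areas = sasa_atoms(t.coords[f], t.elements, probe_radius, n_points, radii)
        per_frame.append(all_areas[atoms].sum())
    return float(np.clip(1.0 - np.mean(per_frame) / ref_sasa, 0.0, 1.0))


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Serialize a trajectory as a plain multi-model PDB file."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                chain = "B" if traj.chain_class[i] == "dna" else "A"
                name = str(traj.atom_names[i])[:4]
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s}{str(traj.resnames[i])[:3]:>4s} {chain}"
                    f"{int(traj.residue_index[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {str(traj.elements[i]):>2s}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
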
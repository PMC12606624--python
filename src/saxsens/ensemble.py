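"""Structural ensembles: containers, PDB I/O, selection, alignment, coarse-graining.

Coordinates are Ångström throughout; residue numbering is 1-based as in the
source PDB; chains are identified by their PDB chain id.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomEnsemble",
    "BeadEnsemble",
    "load_ensemble",
    "write_pdb",
    "select_atoms",
    "compute_rg",
    "align_frames",
    "map_to_beads",
    "relative_exposure",
    "MARTINI_LIKE_SCHEME",
]

# Atomic masses (Da) for elements commonly found in proteins, plus a generic
# pseudo-atom mass used by bead-level synthetic structures.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "X": 110.0,
}

_ELEMENT_FROM_NAME = re.compile(r"^\s*\d*([A-Za-z])")


def _infer_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (e.g. 'CA' -> C, '1HB' -> H)."""
    m = _ELEMENT_FROM_NAME.match(atom_name)
    if not m:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    two = atom_name.strip()[:2].upper()
    if two in ("SE",):
        return "SE"
    sym = m.group(1).upper()
    if sym not in ATOMIC_MASSES:
        raise ValueError(f"unknown element for atom {atom_name!r}")
    return sym


@dataclasses.dataclass
class AtomEnsemble:
    """A conformational ensemble: per-frame coordinates plus per-atom metadata.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å. All frames share atom count and ordering.
    elements, atom_names, residue_names : arrays of str, length n_atoms
    residue_ids : int array, length n_atoms
        1-based residue numbers as in the source PDB.
    chain_ids : array of str, length n_atoms
    masses : float array, length n_atoms, in Da
    bias : optional per-frame energy (kcal/mol), e.g. a metadynamics bias.
    frame_weights : optional per-frame statistical weights, normalized.
    """

    coords: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    masses: np.ndarray
    bias: np.ndarray | None = None
    frame_weights: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        for name in ("elements", "atom_names", "residue_names", "chain_ids"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        n_atoms = self.coords.shape[1]
        for name in ("elements", "atom_names", "residue_ids",
                     "residue_names", "chain_ids", "masses"):
            if len(getattr(self, name)) != n_atoms:
                raise ValueError(f"{name} length does not match atom count {n_atoms}")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (self.n_frames,):
                raise ValueError("bias must be per-frame")
            if not np.isfinite(self.bias).all():
                raise ValueError("bias energies must be finite")
        if self.frame_weights is not None:
            w = np.asarray(self.frame_weights, dtype=float)
            if w.shape != (self.n_frames,) or (w < 0).any():
                raise ValueError("frame_weights must be per-frame and non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("frame_weights must sum to 1")
            self.frame_weights = w

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray) -> "AtomEnsemble":
        return dataclasses.replace(self, coords=np.asarray(coords, dtype=float))


@dataclasses.dataclass
class BeadEnsemble:
    """Coarse-grained ensemble: per-frame bead positions and form-factor kinds.

    ``exposure`` is the per-bead solvent-exposure fraction in [0, 1] used by
    the solvent-layer term of the bead scattering factor; ``residue_map``
    records which source residues each bead represents.
    """

    bead_coords: np.ndarray           # (n_frames, n_beads, 3) Å
    bead_kind: np.ndarray             # (n_beads,) str, keys into a form-factor table
    exposure: np.ndarray              # (n_beads,) in [0, 1]
    residue_map: list                 # bead index -> list of (chain, resid)
    members: list | None = None       # bead index -> source atom indices

    def __post_init__(self):
        self.bead_coords = np.asarray(self.bead_coords, dtype=float)
        self.bead_kind = np.asarray(self.bead_kind)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if ((self.exposure < 0) | (self.exposure > 1)).any():
            raise ValueError("exposure must lie in [0, 1]")
        if self.bead_coords.shape[1] != len(self.bead_kind):
            raise ValueError("bead_kind length must match bead count")

    @property
    def n_frames(self) -> int:
        return self.bead_coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.bead_coords.shape[1]


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

def _parse_pdb_models(path: Path):
    """Parse a (multi-model) PDB into per-model atom records."""
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
                element = line[76:78].strip().upper() if len(line) >= 78 else ""
                current.append((name, resname, chain, resid, x, y, z, element))
    if current:
        models.append(current)
    return [m for m in models if m]


def load_ensemble(paths: str | Path | Sequence[str | Path],
                  topology: str | Path | None = None) -> AtomEnsemble:
    """Load a structural ensemble from multi-model PDB files or a trajectory.

    ``paths`` may be one or more multi-model PDB files (concatenated in
    order), or a single trajectory file (DCD/XTC/...) together with a
    ``topology`` PDB, in which case MDTraj handles the binary format.

    Raises
    ------
    ValueError
        If frames disagree in atom count (the offending model is named), or
        an element cannot be inferred for an atom.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]

    if topology is not None:
        import mdtraj

        traj = mdtraj.load(*(str(p) for p in paths), top=str(topology))
        top_ens = load_ensemble(topology)
        if traj.n_atoms != top_ens.n_atoms:
            raise ValueError(
                f"trajectory has {traj.n_atoms} atoms but topology has {top_ens.n_atoms}")
        coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
        return dataclasses.replace(top_ens, coords=coords)

    all_models = []
    for p in paths:
        models = _parse_pdb_models(p)
        if not models:
            raise ValueError(f"no ATOM records found in {p}")
        all_models.extend(models)

    ref = all_models[0]
    n_atoms = len(ref)
    for k, model in enumerate(all_models[1:], start=2):
        if len(model) != n_atoms:
            raise ValueError(
                f"model {k} has {len(model)} atoms, expected {n_atoms}")

    names = np.array([a[0] for a in ref])
    resnames = np.array([a[1] for a in ref])
    chains = np.array([a[2] for a in ref])
    resids = np.array([a[3] for a in ref], dtype=int)
    elements = []
    for a in ref:
        elements.append(a[7] if a[7] in ATOMIC_MASSES else _infer_element(a[0]))
    elements = np.array(elements)
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    coords = np.array([[(a[4], a[5], a[6]) for a in m] for m in all_models])

    return AtomEnsemble(coords=coords, elements=elements, atom_names=names,
                        residue_ids=resids, residue_names=resnames,
                        chain_ids=chains, masses=masses)


def write_pdb(ens: AtomEnsemble, path: str | Path,
              frames: Iterable[int] | None = None,
              remarks: Sequence[str] = ()) -> None:
    """Write the ensemble as a multi-model PDB (one MODEL per frame)."""
    frames = range(ens.n_frames) if frames is None else list(frames)
    with open(path, "w") as fh:
        for r in remarks:
            fh.write(f"REMARK   1 {r}\n")
        for mi, fi in enumerate(frames, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            for ai in range(ens.n_atoms):
                x, y, z = ens.coords[fi, ai]
                name = ens.atom_names[ai]
                pad = f" {name:<3s}" if len(name) < 4 else name[:4]
                fh.write(
                    f"ATOM  {ai + 1:5d} {pad}"
                    f" {ens.residue_names[ai]:<3s} {ens.chain_ids[ai][:1]}"
                    f"{ens.residue_ids[ai]:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {ens.elements[ai]:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# Selections
# --------------------------------------------------------------------------

def selection_mask(ens: AtomEnsemble, selection: str) -> np.ndarray:
    """Evaluate a selection expression to a boolean atom mask.

    Grammar: clauses joined by ``and``; each clause is one of

    - ``name N1 [N2 ...]`` — atom name is one of the listed names
    - ``chain C1 [C2 ...]`` — chain id is one of the listed ids
    - ``resid A:B`` or ``resid R1 [R2 ...]`` — residue number in range
      (inclusive) or in the listed set
    - ``all``
    """
    mask = np.ones(ens.n_atoms, dtype=bool)
    for clause in re.split(r"\s+and\s+", selection.strip()):
        tokens = clause.split()
        if not tokens:
            continue
        key, args = tokens[0].lower(), tokens[1:]
        if key == "all":
            continue
        if not args:
            raise ValueError(f"selection clause {clause!r} has no arguments")
        if key == "name":
            mask &= np.isin(ens.atom_names, args)
        elif key == "chain":
            mask &= np.isin(ens.chain_ids, args)
        elif key == "resid":
            if len(args) == 1 and ":" in args[0]:
                lo, hi = (int(v) for v in args[0].split(":"))
                mask &= (ens.residue_ids >= lo) & (ens.residue_ids <= hi)
            else:
                mask &= np.isin(ens.residue_ids, [int(a) for a in args])
        else:
            raise ValueError(f"unknown selection keyword {key!r}")
    return mask


def select_atoms(ens: AtomEnsemble, selection: str) -> AtomEnsemble:
    """Subset the ensemble by a selection expression, preserving frame order,
    bias and weights. Raises on an empty selection."""
    mask = selection_mask(ens, selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    return AtomEnsemble(
        coords=ens.coords[:, mask], elements=ens.elements[mask],
        atom_names=ens.atom_names[mask], residue_ids=ens.residue_ids[mask],
        residue_names=ens.residue_names[mask], chain_ids=ens.chain_ids[mask],
        masses=ens.masses[mask], bias=ens.bias, frame_weights=ens.frame_weights)


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def compute_rg(ens: AtomEnsemble, mass_weighted: bool = True) -> np.ndarray:
    """Per-frame radius of gyration (Å).

    Rg_t = sqrt( Σ_a m_a |r_a − r_com|² / Σ_a m_a ); unit masses when
    ``mass_weighted`` is off.
    """
    if ens.n_atoms < 1:
        raise ValueError("ensemble has no atoms")
    m = ens.masses if mass_weighted else np.ones(ens.n_atoms)
    m = m / m.sum()
    com = np.einsum("a,fax->fx", m, ens.coords)
    d2 = ((ens.coords - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt(np.einsum("a,fa->f", m, d2))


def align_frames(ens: AtomEnsemble, ref_selection: str = "all",
                 ref_frame: int = 0) -> AtomEnsemble:
    """Rigid-body superpose every frame onto ``ref_frame`` using the selected
    atoms (optimal least-squares rotation + translation); all atoms move."""
    mask = selection_mask(ens, ref_selection)
    if mask.sum() < 3:
        raise ValueError("alignment needs at least 3 selected atoms")
    if not (0 <= ref_frame < ens.n_frames):
        raise ValueError(f"ref_frame {ref_frame} out of range")
    ref = ens.coords[ref_frame, mask]
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(ens.coords)
    for f in range(ens.n_frames):
        sel = ens.coords[f, mask]
        cen = sel.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, sel - cen)
        out[f] = rot.apply(ens.coords[f] - cen) + ref.mean(axis=0)
    return ens.with_coords(out)


# --------------------------------------------------------------------------
# Coarse-graining
# --------------------------------------------------------------------------

# Heavy-atom groupings per residue type for the MARTINI-like scheme: the
# backbone bead (N, CA, C, O) plus side-chain beads. Bead counts span 1
# (ALA, GLY) to 5 (TRP), as in MARTINI-style protein mappings.
_BB = ("N", "CA", "C", "O")
MARTINI_LIKE_SCHEME: dict[str, list[tuple[str, ...]]] = {
    "GLY": [_BB],
    "ALA": [_BB],
    "CYS": [_BB, ("CB", "SG")],
    "VAL": [_BB, ("CB", "CG1", "CG2")],
    "LEU": [_BB, ("CB", "CG", "CD1", "CD2")],
    "ILE": [_BB, ("CB", "CG1", "CG2", "CD1")],
    "PRO": [_BB, ("CB", "CG", "CD")],
    "MET": [_BB, ("CB", "CG", "SD", "CE")],
    "SER": [_BB, ("CB", "OG")],
    "THR": [_BB, ("CB", "OG1", "CG2")],
    "ASN": [_BB, ("CB", "CG", "OD1", "ND2")],
    "GLN": [_BB, ("CB", "CG", "CD", "OE1", "NE2")],
    "ASP": [_BB, ("CB", "CG", "OD1", "OD2")],
    "GLU": [_BB, ("CB", "CG", "CD", "OE1", "OE2")],
    "LYS": [_BB, ("CB", "CG", "CD"), ("CE", "NZ")],
    "ARG": [_BB, ("CB", "CG", "CD"), ("NE", "CZ", "NH1", "NH2")],
    "HIS": [_BB, ("CB", "CG"), ("CD2", "NE2"), ("ND1", "CE1")],
    "PHE": [_BB, ("CB", "CG"), ("CD1", "CE1"), ("CD2", "CE2", "CZ")],
    "TYR": [_BB, ("CB", "CG"), ("CD1", "CE1"), ("CD2", "CE2", "CZ", "OH")],
    "TRP": [_BB, ("CB", "CG"), ("CD1", "NE1"), ("CE2", "CD2"),
            ("CE3", "CZ3", "CH2", "CZ2")],
}


def _iter_residues(ens: AtomEnsemble):
    seen = {}
    order = []
    for i in range(ens.n_atoms):
        key = (ens.chain_ids[i], int(ens.residue_ids[i]))
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(i)
    return [(key, seen[key]) for key in order]


def map_to_beads(ens: AtomEnsemble, scheme: str = "single-bead",
                 exposure: np.ndarray | None = None,
                 probe_radius: float = 1.4) -> BeadEnsemble:
    """Map an atomistic ensemble to beads.

    ``single-bead``: one bead per residue, positioned at the heavy-atom
    center of mass, kind = residue name. ``martini-like``: the per-residue
    bead table of :data:`MARTINI_LIKE_SCHEME` (1–5 beads per residue).

    Exposure is the per-bead relative solvent accessibility computed on the
    first frame (Shrake–Rupley, probe 1.4 Å) unless supplied directly.
    """
    if scheme not in ("single-bead", "martini-like"):
        raise ValueError(f"unknown scheme {scheme!r}")
    heavy = ens.elements != "H"
    bead_pos_parts = []   # list over beads of atom index arrays
    kinds = []
    residue_map = []
    for (chain, resid), atom_idx in _iter_residues(ens):
        atom_idx = [i for i in atom_idx if heavy[i]]
        if not atom_idx:
            raise ValueError(f"residue {chain}{resid} has no heavy atoms")
        resname = ens.residue_names[atom_idx[0]]
        if scheme == "single-bead":
            groups = [tuple(ens.atom_names[i] for i in atom_idx)]
            bead_kinds = [str(resname)]
        else:
            if resname not in MARTINI_LIKE_SCHEME:
                raise ValueError(
                    f"residue type {resname!r} ({chain}{resid}) not in the "
                    f"martini-like mapping table")
            groups = MARTINI_LIKE_SCHEME[resname]
            bead_kinds = [f"{resname}:{g}" for g in range(len(groups))]
        name_to_idx = {}
        for i in atom_idx:
            name_to_idx.setdefault(ens.atom_names[i], i)
        for grp, kind in zip(groups, bead_kinds):
            members = [name_to_idx[n] for n in grp if n in name_to_idx]
            if not members:
                continue
            bead_pos_parts.append(np.array(members))
            kinds.append(kind)
            residue_map.append([(str(chain), int(resid))])

    n_beads = len(kinds)
    coords = np.empty((ens.n_frames, n_beads, 3))
    for b, members in enumerate(bead_pos_parts):
        w = ens.masses[members]
        coords[:, b] = np.einsum("a,fax->fx", w / w.sum(), ens.coords[:, members])

    if exposure is None:
        exposure = relative_exposure(coords[0], probe_radius=probe_radius)
    exposure = np.asarray(exposure, dtype=float)
    return BeadEnsemble(bead_coords=coords, bead_kind=np.array(kinds),
                        exposure=exposure, residue_map=residue_map,
                        members=bead_pos_parts)


def relative_exposure(positions: np.ndarray, radii: np.ndarray | float = 3.0,
                      probe_radius: float = 1.4, n_points: int = 256,
                      seed: int = 0) -> np.ndarray:
    """Per-particle relative solvent accessibility by Shrake–Rupley.

    Each particle gets a sphere of ``radius + probe_radius`` sampled with a
    Fibonacci point set; the exposed fraction is the share of points not
    buried inside any neighbour's inflated sphere. The result is already
    normalized to [0, 1] (an isolated particle scores 1).
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    inflated = radii + probe_radius
    # Fibonacci sphere: deterministic quasi-uniform points
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1 - 2 * k / n_points)
    theta = np.pi * (1 + 5 ** 0.5) * k
    sphere = np.stack([np.sin(phi) * np.cos(theta),
                       np.sin(phi) * np.sin(theta),
                       np.cos(phi)], axis=1)
    out = np.empty(n)
    for i in range(n):
        pts = pos[i] + inflated[i] * sphere
        buried = np.zeros(n_points, dtype=bool)
        d = np.linalg.norm(pos - pos[i], axis=1)
        for j in np.nonzero((d < inflated + inflated[i]) & (np.arange(n) != i))[0]:
            buried |= np.linalg.norm(pts - pos[j], axis=1) < inflated[j]
        out[i] = 1.0 - buried.mean()
    return out
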
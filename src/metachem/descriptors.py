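"""The 20-descriptor chemical property panel.

Counts are taken from the hydrogen-complete graph.  AlogP98 is an atom-type
contribution logP of the Ghose-Crippen family; PSA is the topological polar
surface area.  AREA is the solvent-accessible surface over one embedded
conformer; VOL and PV (polar volume) come from a voxelized union of van der
Waals spheres, PV restricted to N/O/P/S atoms and their attached hydrogens.
When 3D embedding fails, AREA/VOL/PV fall back to additive per-atom
increments and the vector is flagged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Lipinski, rdFreeSASA, rdMolDescriptors, Descriptors

from metachem.io import Metabolite

logger = logging.getLogger(__name__)

#: Column order of the descriptor panel.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "MW", "AREA", "VOL", "AtomCount", "Carbons", "Oxygens", "Nitrogens",
    "Sulfurs", "Phosphorus", "AlogP98", "PSA", "PV", "Acceptor", "Donor",
    "Hydrophobe", "RingCount", "AromaticRings", "BondCount", "RotBonds",
    "Chiral",
)

#: Descriptors that require a 3D conformer.
CONFORMER_DESCRIPTORS = ("AREA", "VOL", "PV")

#: Polarity-associated subset used for reaction net-change summaries.
POLARITY_DESCRIPTORS = ("AlogP98", "PSA", "PV", "Acceptor", "Donor")

_POLAR_ELEMENTS = frozenset([7, 8, 15, 16])

_VDW_RADII = {1: 1.10, 6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 15: 1.80,
              16: 1.80, 17: 1.75, 35: 1.85, 53: 1.98}
_VDW_DEFAULT = 1.70


class EmbeddingError(RuntimeError):
    """Raised when no 3D conformer can be generated."""


def embed_3d(m: Metabolite | Chem.Mol, seed: int = 0xF00D) -> Chem.Mol:
    """Embed one conformer (distance geometry + MMFF relaxation), deterministically.

    Returns a hydrogen-complete copy with a single 3D conformer.  The same
    seed always yields the same coordinates.
    """
    mol = m.mol if isinstance(m, Metabolite) else m
    molH = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.useRandomCoords = False
    if AllChem.EmbedMolecule(molH, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molH, params) != 0:
            raise EmbeddingError(f"embedding failed for {Chem.MolToSmiles(mol)}")
    try:
        AllChem.MMFFOptimizeMolecule(molH)
    except Exception:  # pragma: no cover - MMFF missing params
        AllChem.UFFOptimizeMolecule(molH)
    return molH


def _vdw_radius(atom: Chem.Atom) -> float:
    return _VDW_RADII.get(atom.GetAtomicNum(), _VDW_DEFAULT)


def _polar_atom_mask(molH: Chem.Mol) -> np.ndarray:
    """N/O/P/S atoms plus hydrogens attached to them."""
    mask = np.zeros(molH.GetNumAtoms(), dtype=bool)
    for atom in molH.GetAtoms():
        z = atom.GetAtomicNum()
        if z in _POLAR_ELEMENTS:
            mask[atom.GetIdx()] = True
        elif z == 1:
            nbrs = atom.GetNeighbors()
            if nbrs and nbrs[0].GetAtomicNum() in _POLAR_ELEMENTS:
                mask[atom.GetIdx()] = True
    return mask


def _voxel_volumes(molH: Chem.Mol, spacing: float = 0.35) -> tuple[float, float]:
    """(total, polar) van der Waals volume by voxel counting.

    A voxel inside any atomic sphere counts toward the total; it counts as
    polar when the nearest covering atom centre is polar (N/O/P/S or an
    attached H).
    """
    conf = molH.GetConformer()
    coords = conf.GetPositions()
    radii = np.array([_vdw_radius(a) for a in molH.GetAtoms()])
    polar = _polar_atom_mask(molH)

    lo = (coords - radii[:, None]).min(axis=0) - spacing
    hi = (coords + radii[:, None]).max(axis=0) + spacing
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    # distance of every voxel to every atom, in chunks to bound memory
    best_d = np.full(len(pts), np.inf)
    best_atom = np.full(len(pts), -1, dtype=int)
    inside = np.zeros(len(pts), dtype=bool)
    for i in range(len(coords)):
        d = np.linalg.norm(pts - coords[i], axis=1)
        within = d <= radii[i]
        inside |= within
        closer = within & (d < best_d)
        best_d[closer] = d[closer]
        best_atom[closer] = i
    voxel = spacing**3
    total = float(inside.sum() * voxel)
    polar_vol = float((inside & polar[best_atom]).sum() * voxel)
    return total, polar_vol


def _sasa(molH: Chem.Mol, probe_radius: float = 1.4) -> float:
    radii = [_vdw_radius(a) for a in molH.GetAtoms()]
    opts = rdFreeSASA.SASAOpts()
    opts.probeRadius = probe_radius
    return float(rdFreeSASA.CalcSASA(molH, radii, -1, None, opts))


def _increment_surface_volume(molH: Chem.Mol, probe_radius: float = 1.4) -> tuple[float, float, float]:
    """Additive per-atom approximation used when no conformer is available.

    Each atom contributes a fixed fraction of its isolated-sphere surface
    and volume (the remainder is assumed buried in bonds); polar volume is
    the polar-atom share.
    """
    radii = np.array([_vdw_radius(a) for a in molH.GetAtoms()])
    polar = _polar_atom_mask(molH)
    area = float((4 * np.pi * (radii + probe_radius) ** 2 * 0.25).sum())
    vols = 4.0 / 3.0 * np.pi * radii**3 * 0.80
    return area, float(vols.sum()), float(vols[polar].sum())


def _count_rotatable(mol: Chem.Mol) -> int:
    """Single, non-ring bonds between two non-terminal heavy atoms, excluding
    amide C-N bonds."""
    amide = Chem.MolFromSmarts("[CX3](=O)-[NX3]")
    amide_bonds = set()
    for match in mol.GetSubstructMatches(amide):
        b = mol.GetBondBetweenAtoms(match[0], match[2])
        if b is not None:
            amide_bonds.add(b.GetIdx())
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetIdx() in amide_bonds:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() > 1 and b.GetDegree() > 1:
            n += 1
    return n


def _count_hydrophobe(mol: Chem.Mol) -> int:
    """Maximal connected subgraphs of >=3 non-polar atoms.

    Eligible atoms are carbon, halogen, and thioether sulfur, uncharged and
    not bonded to N, O, P or to any charged atom.
    """
    halogens = {9, 17, 35, 53}
    eligible = set()
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if atom.GetFormalCharge() != 0:
            continue
        if z == 16:
            nbrs = atom.GetNeighbors()
            if not (atom.GetDegree() == 2 and all(n.GetAtomicNum() == 6 for n in nbrs)):
                continue
        elif z != 6 and z not in halogens:
            continue
        bad = any(
            n.GetAtomicNum() in (7, 8, 15) or n.GetFormalCharge() != 0
            for n in atom.GetNeighbors()
        )
        if not bad:
            eligible.add(atom.GetIdx())
    # connected components within the eligible subgraph
    seen: set[int] = set()
    count = 0
    for start in eligible:
        if start in seen:
            continue
        stack, comp = [start], 0
        seen.add(start)
        while stack:
            idx = stack.pop()
            comp += 1
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j in eligible and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if comp >= 3:
            count += 1
    return count


def compute_descriptors(
    m: Metabolite | Chem.Mol,
    conformer: Optional[Chem.Mol] = None,
    probe_radius: float = 1.4,
    allow_fallback: bool = True,
) -> pd.Series:
    """Compute the 20-descriptor vector for one standardized molecule.

    ``conformer`` is a hydrogen-complete molecule with 3D coordinates (from
    :func:`embed_3d`).  Without it, the 3D-derived fields (AREA, VOL, PV)
    use the additive increment approximation if ``allow_fallback`` is true,
    and otherwise raise naming the missing field.
    """
    mol = m.mol if isinstance(m, Metabolite) else m
    molH = Chem.AddHs(mol)

    counts = {z: 0 for z in (6, 7, 8, 15, 16)}
    for atom in molH.GetAtoms():
        z = atom.GetAtomicNum()
        if z in counts:
            counts[z] += 1

    values = {
        "MW": Descriptors.MolWt(mol),
        "AtomCount": molH.GetNumAtoms(),
        "Carbons": counts[6],
        "Oxygens": counts[8],
        "Nitrogens": counts[7],
        "Sulfurs": counts[16],
        "Phosphorus": counts[15],
        "AlogP98": Crippen.MolLogP(mol),
        "PSA": rdMolDescriptors.CalcTPSA(mol),
        # Lipinski conventions: acceptors = N+O atoms, donors = N-H/O-H hydrogens
        "Acceptor": Lipinski.NOCount(mol),
        "Donor": Lipinski.NHOHCount(mol),
        "Hydrophobe": _count_hydrophobe(mol),
        "RingCount": rdMolDescriptors.CalcNumRings(mol),
        "AromaticRings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "BondCount": molH.GetNumBonds(),
        "RotBonds": _count_rotatable(mol),
        "Chiral": len(
            Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
        ),
    }

    if conformer is not None and conformer.GetNumConformers() > 0:
        values["AREA"] = _sasa(conformer, probe_radius)
        vol, pv = _voxel_volumes(conformer)
        values["VOL"] = vol
        values["PV"] = pv
    elif allow_fallback:
        area, vol, pv = _increment_surface_volume(molH, probe_radius)
        values["AREA"], values["VOL"], values["PV"] = area, vol, pv
    else:
        raise ValueError("missing conformer for 3D descriptors: AREA, VOL, PV")

    return pd.Series(values, index=list(DESCRIPTOR_NAMES), dtype=float)


def descriptor_table(
    metabolites: Sequence[Metabolite],
    seed: int = 0xF00D,
    embed: bool = True,
    probe_radius: float = 1.4,
) -> pd.DataFrame:
    """Descriptor matrix (rows: metabolite ids, columns: the 20 descriptors).

    With ``embed=False`` the 3D fields use the increment approximation for
    every molecule, which is much faster for large panels where only
    topological fields matter.
    """
    rows = {}
    for i, m in enumerate(metabolites):
        conf = None
        if embed:
            try:
                conf = embed_3d(m, seed=(seed + i) & 0x7FFFFFFF)
            except EmbeddingError:
                logger.warning("3D embedding failed for %s; using increment fallback", m.id)
        rows[m.id] = compute_descriptors(m, conformer=conf, probe_radius=probe_radius)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df[list(DESCRIPTOR_NAMES)]


def write_descriptor_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")
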
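"""Reading and standardizing chemical structures.

Standardization follows the common salt-stripping protocol for metabolite
datasets: keep the largest fragment (counter-ions and solvent molecules are
dropped), neutralize formal charges by protonation-state changes only, and
complete implicit hydrogens.  Records carrying query/wildcard atoms (R
groups, polymeric forms) are rejected rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

from rdkit import Chem
from rdkit.Chem import RWMol

logger = logging.getLogger(__name__)

SetLabel = Literal["setA", "setB"]
EraLabel = Literal["early", "late"]

# +1 atoms that carry an H (so removable), or -1 atoms, excluding atoms whose
# charge is balanced by an adjacent opposite charge (zwitterion-internal salt
# bridges like nitro groups stay untouched).
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


@dataclass(frozen=True)
class Metabolite:
    """A single identified molecule with its set (and optional era) label."""

    id: str
    mol: Chem.Mol
    set_label: str
    era_label: Optional[str] = None
    flags: tuple[str, ...] = field(default=())

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def with_mol(self, mol: Chem.Mol, extra_flags: Iterable[str] = ()) -> "Metabolite":
        return replace(self, mol=mol, flags=self.flags + tuple(extra_flags))


@dataclass
class Rejection:
    """A record that could not be turned into a valid molecule."""

    record: str
    index: int
    reason: str


@dataclass
class ParseResult:
    metabolites: list[Metabolite]
    rejected: list[Rejection]

    def __iter__(self):
        return iter(self.metabolites)

    def __len__(self) -> int:
        return len(self.metabolites)


def _has_query_atoms(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 0 or a.HasQuery() for a in mol.GetAtoms())


def parse_structures(
    path: str | Path,
    format: str = "smiles-lines",
    set_label: str = "setA",
    era_label: Optional[str] = None,
) -> ParseResult:
    """Read molecules from a SMILES line file (``SMILES id``) or an SDF.

    Every input record either becomes a :class:`Metabolite` (its id keeps
    the source line/record index) or a logged :class:`Rejection`; nothing is
    silently dropped.  A missing file or a file with zero parseable records
    raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    if format not in ("smiles-lines", "sdf"):
        raise ValueError(f"unknown format: {format!r}")

    metabolites: list[Metabolite] = []
    rejected: list[Rejection] = []

    if format == "smiles-lines":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smi = parts[0]
            name = parts[1] if len(parts) > 1 else f"line{lineno}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                rejected.append(Rejection(line, lineno, "unparseable SMILES"))
                continue
            if _has_query_atoms(mol):
                rejected.append(Rejection(line, lineno, "query/wildcard atom (R group or polymer)"))
                continue
            metabolites.append(
                Metabolite(id=f"{name}", mol=mol, set_label=set_label, era_label=era_label)
            )
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for idx, mol in enumerate(supplier):
            if mol is None:
                rejected.append(Rejection(f"record {idx}", idx, "unparseable SDF record"))
                continue
            if _has_query_atoms(mol):
                rejected.append(
                    Rejection(f"record {idx}", idx, "query/wildcard atom (R group or polymer)")
                )
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record{idx}"
            metabolites.append(
                Metabolite(id=name, mol=mol, set_label=set_label, era_label=era_label)
            )

    for rej in rejected:
        logger.warning("rejected %s (index %d): %s", rej.record, rej.index, rej.reason)
    if not metabolites:
        raise ValueError(f"no parseable records in {path}")
    return ParseResult(metabolites, rejected)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Largest fragment by heavy-atom count; ties broken by canonical SMILES
    lexicographic order (keep the first)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise ValueError("molecule has no fragments")
    best = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), _neg_smiles_key(f)))
    if best.GetNumHeavyAtoms() == 0:
        raise ValueError("largest fragment has zero heavy atoms")
    return best


class _neg_smiles_key:
    """Reversed lexicographic comparison so max() keeps the canonically-first
    SMILES among equally sized fragments."""

    def __init__(self, mol: Chem.Mol):
        self.s = Chem.MolToSmiles(mol)

    def __lt__(self, other: "_neg_smiles_key") -> bool:
        return self.s > other.s


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, list[str]]:
    """Neutralize formal charges by adding/removing protons only.

    Carboxylates, phosphates, alkoxides etc. gain an H; protonated amines
    lose one.  Permanently charged centres (quaternary N, internal salt
    bridges) are left alone and flagged.
    """
    mol = RWMol(mol)
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        chg = atom.GetFormalCharge()
        hcount = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(hcount - chg)
        atom.UpdatePropertyCache()
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    flags = []
    residual = Chem.GetFormalCharge(out)
    if residual != 0:
        flags.append(f"residual_charge:{residual:+d}")
    return out, flags


def standardize(m: Metabolite) -> Metabolite:
    """Keep the largest fragment, neutralize, complete implicit hydrogens.

    Idempotent; never adds heavy atoms or rewrites heavy-atom bonds.
    """
    frag = _largest_fragment(m.mol)
    neutral, flags = _neutralize(frag)
    return m.with_mol(neutral, flags)


def standardize_all(metabolites: Iterable[Metabolite]) -> list[Metabolite]:
    return [standardize(m) for m in metabolites]


def write_smiles_table(metabolites: Iterable[Metabolite], path: str | Path) -> None:
    """Write a TSV of (id, set_label, smiles)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tset_label\tsmiles\n")
        for m in metabolites:
            fh.write(f"{m.id}\t{m.set_label}\t{m.smiles}\n")
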
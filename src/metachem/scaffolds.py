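"""Murcko scaffold extraction and between-set scaffold census comparison.

A scaffold is the contiguous ring systems of a molecule plus the chains
linking them: terminal atoms not in a ring and not on a ring-ring linker
path are pruned iteratively.  Double bonds exocyclic to rings (e.g. a ring
C=O) and double bonds within linkers are retained; pruning only deletes
atoms and never rewrites bond orders.  Acyclic molecules have no scaffold
and are counted separately (they are never treated as a shared "empty
scaffold" between two sets).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from metachem.io import Metabolite

#: Marker returned for molecules with no ring.
ACYCLIC = ""


def num_rings(mol: Chem.Mol) -> int:
    """SSSR ring count with explicit ring perception.

    Forces ring perception before reading the count; RDKit's lazily
    initialized RingInfo can otherwise raise on molecules whose cache was
    never populated.
    """
    Chem.GetSymmSSSR(mol)
    return mol.GetRingInfo().NumRings()


def extract_scaffold(m: Metabolite | Chem.Mol) -> str:
    """Canonical SMILES of the Murcko scaffold, or :data:`ACYCLIC` ("") for
    ring-free molecules."""
    mol = m.mol if isinstance(m, Metabolite) else m
    if num_rings(mol) == 0:
        return ACYCLIC
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    if scaf is None or scaf.GetNumAtoms() == 0:
        return ACYCLIC
    return Chem.MolToSmiles(scaf)


@dataclass
class ScaffoldCensus:
    """Distinct scaffolds with occurrence counts for one metabolite set."""

    scaffolds: Counter
    n_metabolites: int
    n_acyclic: int

    @property
    def n_distinct(self) -> int:
        return len(self.scaffolds)

    @property
    def density(self) -> float:
        """Distinct scaffolds per metabolite, reported to 3 decimals."""
        return round(self.n_distinct / self.n_metabolites, 3)


def census(metabolites: Sequence[Metabolite]) -> ScaffoldCensus:
    """Scaffold census of one set: distinct scaffolds, counts, density."""
    if not metabolites:
        raise ValueError("cannot take a scaffold census of an empty set")
    counts: Counter = Counter()
    n_acyclic = 0
    for m in metabolites:
        s = extract_scaffold(m)
        if s == ACYCLIC:
            n_acyclic += 1
        else:
            counts[s] += 1
    return ScaffoldCensus(counts, len(metabolites), n_acyclic)


@dataclass
class CensusComparison:
    shared: set[str]
    novel_in_b: set[str]
    #: b's scaffolds by occurrence, descending; ties broken canonically.
    ranking: list[tuple[str, int]]


def compare_censuses(a: ScaffoldCensus, b: ScaffoldCensus) -> CensusComparison:
    """Shared scaffolds, scaffolds novel to *b*, and *b*'s prevalence ranking."""
    if not a.n_metabolites or not b.n_metabolites:
        raise ValueError("both censuses must be non-empty")
    keys_a, keys_b = set(a.scaffolds), set(b.scaffolds)
    ranking = sorted(b.scaffolds.items(), key=lambda kv: (-kv[1], kv[0]))
    return CensusComparison(keys_a & keys_b, keys_b - keys_a, ranking)


def write_census_table(a: ScaffoldCensus, b: ScaffoldCensus, path: str | Path) -> None:
    """TSV of (scaffold, count_setA, count_setB) over the union of scaffolds."""
    keys = sorted(set(a.scaffolds) | set(b.scaffolds))
    with Path(path).open("w") as fh:
        fh.write("scaffold\tcount_setA\tcount_setB\n")
        for k in keys:
            fh.write(f"{k}\t{a.scaffolds.get(k, 0)}\t{b.scaffolds.get(k, 0)}\n")
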
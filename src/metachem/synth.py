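"""Synthetic-data generator with known ground truth.

Everything the pipeline consumes can be generated here with controlled
statistical structure: two metabolite sets differing in polarity and
rigidity by tunable amounts, reaction chains with known per-step descriptor
deltas, and enzyme cofactor/residue annotations drawn from configured
probability vectors.  Molecules come from a scaffold-plus-decoration
grammar (a ring-scaffold pool partitioned into shared / A-only / B-only,
decorated with terminal polar or non-polar substituents), so each
molecule's scaffold and generation parameters are known by construction
and recorded in a truth ledger.

Defaults mirror the headline two-network comparison this package was built
around: 1,174 vs 520 metabolites, 34 shared + 131 B-only scaffolds, a mean
hydrophobicity (AlogP98) gap of ~2.2 and a mean ring-count gap of ~1.2
between sets, and enzyme annotation sizes of 154 vs 121 (cofactors) and
453 vs 257 enzymes x 3 catalytic residues (residue sites).  All randomness
flows through one seeded generator; the same seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import RWMol

from metachem.io import Metabolite
from metachem.descriptors import compute_descriptors
from metachem.enzymes import AMINO_ACIDS
from metachem.reactions import Reaction
from metachem.scaffolds import extract_scaffold, num_rings

# ---------------------------------------------------------------------------
# scaffold grammar

_SINGLE_RING_TEMPLATES = [
    "c{0}ccccc{0}",      # benzene
    "c{0}ccncc{0}",      # pyridine
    "C{0}CCCCC{0}",      # cyclohexane
    "C{0}CCCC{0}",       # cyclopentane
    "c{0}ccoc{0}",       # furan
    "c{0}ccsc{0}",       # thiophene
    "c{0}cc[nH]c{0}",    # pyrrole
    "C{0}CCOC{0}",       # tetrahydrofuran
    "C{0}CCNCC{0}",      # piperidine
    "C{0}=CCCCC{0}",     # cyclohexene
    "c{0}cncnc{0}",      # pyrimidine
    "C{0}CCC{0}",        # cyclobutane
]

_FUSED_TEMPLATES = [
    "c{0}ccc{1}ccccc{1}c{0}",     # naphthalene
    "c{0}ccc{1}ncccc{1}c{0}",     # quinoline
    "c{0}ccc{1}[nH]ccc{1}c{0}",   # indole
    "C{0}CCC{1}CCCCC{1}C{0}",     # decalin
]

_LINKERS = ["C", "CC", "C=C", "CCC"]

POLAR_SUBSTITUENTS = ["O", "N", "CO", "C(=O)O", "C(N)=O"]
NONPOLAR_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "CCCC", "Cl"]

# empirical per-substituent AlogP98 effects used only to map a requested
# mean shift onto decoration probabilities (direction is what matters)
_MEAN_NONPOLAR_EFFECT = 0.55
_MEAN_POLAR_EFFECT = -0.75
_MEAN_DECORATIONS = 2.5


def scaffold_pool() -> dict[int, list[str]]:
    """Deduplicated scaffold SMILES grouped by ring count (1, 2, 3)."""
    pool: dict[int, list[str]] = {1: [], 2: [], 3: []}
    seen: set[str] = set()

    def add(smiles: str, rings: int) -> None:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return
        canon = extract_scaffold(mol)
        if canon and canon not in seen:
            seen.add(canon)
            pool[rings].append(canon)

    for t in _SINGLE_RING_TEMPLATES:
        add(t.format(1), 1)
    for t in _FUSED_TEMPLATES:
        add(t.format(1, 2), 2)
    for t1, t2 in itertools.product(_SINGLE_RING_TEMPLATES, repeat=2):
        for link in _LINKERS:
            add(t1.format(1) + link + t2.format(2), 2)
    for t1 in _SINGLE_RING_TEMPLATES[:6]:
        for t2 in _FUSED_TEMPLATES:
            for link in _LINKERS[:2]:
                add(t1.format(1) + link + t2.format(2, 3), 3)
    return pool


def _attach(mol: Chem.Mol, atom_idx: int, frag_smiles: str) -> Chem.Mol:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _decoration_sites(mol: Chem.Mol) -> list[int]:
    """Carbon atoms with at least one substitutable hydrogen."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1 and a.GetFormalCharge() == 0
    ]


def _decorate(scaffold_smiles: str, substituents: Sequence[str], rng: np.random.Generator) -> Chem.Mol:
    mol = Chem.MolFromSmiles(scaffold_smiles)
    for sub in substituents:
        sites = _decoration_sites(mol)
        if not sites:
            break
        mol = _attach(mol, int(rng.choice(sites)), sub)
    return mol


def _acyclic_molecule(substituents: Sequence[str], rng: np.random.Generator) -> Chem.Mol:
    length = int(rng.integers(3, 7))
    mol = Chem.MolFromSmiles("C" * length)
    for sub in substituents:
        sites = _decoration_sites(mol)
        mol = _attach(mol, int(rng.choice(sites)), sub)
    return mol


# ---------------------------------------------------------------------------
# configuration

#: Cofactor usage proportions for the two oxidoreductase sets
#: (organic-cofactor-heavy set A, metal-cofactor-heavy set B).
DEFAULT_COFACTOR_PROBS_A = {
    "NAD(H)": 70 / 154, "NADP(H)": 46 / 154, "NAD/P(H)": 20 / 154,
    "FAD": 15 / 154, "Ascorbate": 0.0, "Fe-S": 8 / 154, "Iron": 4 / 154,
    "Heme": 2 / 154, "Molybdenum": 1 / 154, "Copper": 0.0,
}
DEFAULT_COFACTOR_PROBS_B = {
    "NAD(H)": 12 / 121, "NADP(H)": 32 / 121, "NAD/P(H)": 15 / 121,
    "FAD": 22 / 121, "Ascorbate": 8 / 121, "Fe-S": 9 / 121, "Iron": 32 / 121,
    "Heme": 32 / 121, "Molybdenum": 5 / 121, "Copper": 6 / 121,
}

_POLAR_RESIDUES = ("Asp", "Glu", "Lys", "Arg")
_NONPOLAR_RESIDUES = ("Trp", "Ile")


def _residue_probs(bias_polar: float) -> dict[str, float]:
    """Uniform residue distribution with polar residues boosted by
    ``bias_polar`` (can be negative to boost the non-polar pair)."""
    probs = {aa: 1.0 for aa in AMINO_ACIDS}
    for aa in _POLAR_RESIDUES:
        probs[aa] *= 1.0 + max(bias_polar, 0.0)
    for aa in _NONPOLAR_RESIDUES:
        probs[aa] *= 1.0 + max(-bias_polar, 0.0)
    total = sum(probs.values())
    return {aa: p / total for aa, p in probs.items()}


@dataclass
class SynthConfig:
    """Knobs of the synthetic-data generator; defaults emulate the study
    conditions (see module docstring)."""

    n_setA: int = 1174
    n_setB: int = 520
    polarity_shift: float = 2.2     # target mean AlogP98 difference (B - A)
    rigidity_shift: float = 1.2     # target mean ring-count difference (B - A)
    n_shared_scaffolds: int = 34
    n_unique_scaffolds_A: int = 170
    n_unique_scaffolds_B: int = 131
    mean_rings_A: float = 1.4
    acyclic_frac_A: float = 0.35
    acyclic_frac_B: float = 0.15
    reaction_chain_length: int = 8
    residue_probs_A: Optional[dict[str, float]] = None   # default: polar-biased
    residue_probs_B: Optional[dict[str, float]] = None   # default: non-polar-biased
    cofactor_probs_A: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COFACTOR_PROBS_A))
    cofactor_probs_B: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COFACTOR_PROBS_B))
    ec_probs_A: Sequence[float] = (0.25, 0.2, 0.2, 0.15, 0.1, 0.1)
    ec_probs_B: Sequence[float] = (0.50, 0.12, 0.12, 0.1, 0.08, 0.08)
    n_enzymes_A: int = 154
    n_enzymes_B: int = 121
    n_sites_A: int = 453
    n_sites_B: int = 257
    residues_per_site: int = 3
    residue_bias: float = 0.8       # polarity bias between the residue sets
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_setA", "n_setB", "n_shared_scaffolds",
                     "n_unique_scaffolds_A", "n_unique_scaffolds_B"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.residue_probs_A is None:
            self.residue_probs_A = _residue_probs(self.residue_bias)
        if self.residue_probs_B is None:
            self.residue_probs_B = _residue_probs(-self.residue_bias)
        for name in ("residue_probs_A", "residue_probs_B"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        for name in ("ec_probs_A", "ec_probs_B"):
            if abs(sum(getattr(self, name)) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


# ---------------------------------------------------------------------------
# metabolite sets


def _ring_category_probs(mean_rings: float, acyclic_frac: float) -> np.ndarray:
    """Probabilities over ring categories {0, 1, 2, 3} with the given
    acyclic fraction and the given mean ring count among cyclic molecules."""
    if not 1.0 <= mean_rings <= 3.0:
        raise ValueError(
            f"mean ring count among cyclic molecules must lie in [1, 3]; "
            f"got {mean_rings:.2f} — the requested rigidity shift exceeds the scaffold pool"
        )
    if mean_rings <= 2.0:
        cyc = np.array([2.0 - mean_rings, mean_rings - 1.0, 0.0])
    else:
        cyc = np.array([0.0, 3.0 - mean_rings, mean_rings - 2.0])
    probs = np.concatenate([[acyclic_frac], (1.0 - acyclic_frac) * cyc])
    return probs / probs.sum()


@dataclass
class SyntheticSets:
    metabolites_a: list[Metabolite]
    metabolites_b: list[Metabolite]
    ledger: pd.DataFrame
    scaffold_partition: dict[str, list[str]]   # shared / a_only / b_only

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "setA": outdir / "setA.smi",
            "setB": outdir / "setB.smi",
            "ledger": outdir / "metabolite_truth.tsv",
        }
        for key, mets in (("setA", self.metabolites_a), ("setB", self.metabolites_b)):
            with paths[key].open("w") as fh:
                for m in mets:
                    fh.write(f"{m.smiles} {m.id}\n")
        self.ledger.to_csv(paths["ledger"], sep="\t", index=False)
        return paths


def generate_metabolite_sets(cfg: SynthConfig) -> SyntheticSets:
    """Generate the two labeled metabolite sets plus a truth ledger.

    Set B's decoration draws push its hydrophobicity up by the configured
    polarity shift and its scaffold draws push its ring count up by the
    rigidity shift.  Every designated shared and set-unique scaffold is
    guaranteed to appear, so a downstream census comparison recovers the
    configured shared/novel counts exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = scaffold_pool()
    flat = [s for cat in (1, 2, 3) for s in pool[cat]]
    n_needed = cfg.n_shared_scaffolds + cfg.n_unique_scaffolds_A + cfg.n_unique_scaffolds_B
    if n_needed > len(flat):
        raise ValueError(f"scaffold pool has {len(flat)} members; {n_needed} requested")

    # interleave ring-count categories across the three partitions so each
    # partition spans the categories
    by_cat = [list(pool[c]) for c in (1, 2, 3)]
    for lst in by_cat:
        rng.shuffle(lst)
    interleaved = [s for tup in itertools.zip_longest(*by_cat) for s in tup if s is not None]
    shared = interleaved[: cfg.n_shared_scaffolds]
    a_only = interleaved[cfg.n_shared_scaffolds: cfg.n_shared_scaffolds + cfg.n_unique_scaffolds_A]
    b_only = interleaved[
        cfg.n_shared_scaffolds + cfg.n_unique_scaffolds_A: n_needed
    ]
    ring_count = {s: num_rings(Chem.MolFromSmiles(s)) for s in interleaved[:n_needed]}

    # decoration probabilities from the requested polarity shift
    gap = _MEAN_NONPOLAR_EFFECT - _MEAN_POLAR_EFFECT
    d = cfg.polarity_shift / (_MEAN_DECORATIONS * gap) / 2.0
    if not -0.5 <= d <= 0.5:
        raise ValueError(f"polarity shift {cfg.polarity_shift} exceeds the decoration grammar")
    p_np = {"setA": 0.5 - d, "setB": 0.5 + d}

    # overall mean rings = (1 - acyclic_frac) * mean among cyclic molecules;
    # solve for set B's cyclic mean so the overall gap matches the shift
    overall_a = (1.0 - cfg.acyclic_frac_A) * cfg.mean_rings_A
    mean_rings_b = (overall_a + cfg.rigidity_shift) / max(1.0 - cfg.acyclic_frac_B, 1e-9)
    cat_probs = {
        "setA": _ring_category_probs(cfg.mean_rings_A, cfg.acyclic_frac_A),
        "setB": _ring_category_probs(mean_rings_b, cfg.acyclic_frac_B),
    }
    allowed = {"setA": shared + a_only, "setB": shared + b_only}
    required = {"setA": shared + a_only, "setB": shared + b_only}
    n_per_set = {"setA": cfg.n_setA, "setB": cfg.n_setB}
    for label in ("setA", "setB"):
        if n_per_set[label] < len(required[label]):
            raise ValueError(
                f"{label} has {n_per_set[label]} molecules but must cover "
                f"{len(required[label])} scaffolds"
            )

    records = []
    sets: dict[str, list[Metabolite]] = {"setA": [], "setB": []}
    for label in ("setA", "setB"):
        allowed_by_cat = {c: [s for s in allowed[label] if ring_count[s] == c] for c in (1, 2, 3)}
        for i in range(n_per_set[label]):
            if i < len(required[label]):
                scaf = required[label][i]
                cat = ring_count[scaf]
            else:
                cat = int(rng.choice(4, p=cat_probs[label]))
                while cat > 0 and not allowed_by_cat[cat]:
                    cat -= 1
                scaf = None if cat == 0 else str(rng.choice(allowed_by_cat[cat]))
            n_dec = int(rng.integers(1, 5))
            subs = []
            for _ in range(n_dec):
                if rng.random() < p_np[label]:
                    subs.append(str(rng.choice(NONPOLAR_SUBSTITUENTS)))
                else:
                    subs.append(str(rng.choice(POLAR_SUBSTITUENTS)))
            mol = _acyclic_molecule(subs, rng) if scaf is None else _decorate(scaf, subs, rng)
            mid = f"{label}_{i:04d}"
            met = Metabolite(mid, mol, label)
            sets[label].append(met)
            records.append(
                {
                    "id": mid,
                    "set_label": label,
                    "scaffold": scaf or "",
                    "ring_category": cat if scaf else 0,
                    "n_polar": sum(1 for s in subs if s in POLAR_SUBSTITUENTS),
                    "n_nonpolar": sum(1 for s in subs if s in NONPOLAR_SUBSTITUENTS),
                    "smiles": met.smiles,
                }
            )
    ledger = pd.DataFrame(records)
    return SyntheticSets(
        sets["setA"], sets["setB"], ledger,
        {"shared": shared, "a_only": a_only, "b_only": b_only},
    )


# ---------------------------------------------------------------------------
# reaction chains


@dataclass
class SyntheticNetwork:
    reactions: list[Reaction]
    reaction_lines: list[str]
    metabolites: list[Metabolite]
    chain_a_ids: list[str]       # anaerobic-style (polarity decreasing)
    chain_b_ids: list[str]       # aerobic-style (polarity increasing)
    truth: pd.DataFrame          # per-step true descriptor deltas

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reactions": outdir / "reactions.txt",
            "structures": outdir / "structures.smi",
            "truth": outdir / "reaction_truth.tsv",
        }
        paths["reactions"].write_text("\n".join(self.reaction_lines) + "\n")
        with paths["structures"].open("w") as fh:
            for m in self.metabolites:
                fh.write(f"{m.smiles} {m.id}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _anaerobic_chain_molecule(step: int, length: int) -> Chem.Mol:
    """Naphthalene bearing (length - step) hydroxyls and step methyls."""
    mol = Chem.MolFromSmiles("c1ccc2ccccc2c1")
    rng_positions = _decoration_sites(mol)[:length]
    for k, _pos in enumerate(rng_positions):
        sub = "C" if k < step else "O"
        sites = _decoration_sites(mol)
        mol = _attach(mol, sites[0], sub)
    return mol


def _aerobic_chain_molecule(step: int, length: int) -> Chem.Mol:
    """Alkylbenzene whose first ``step`` chain carbons carry hydroxyls."""
    chain = length + 2
    mol = Chem.MolFromSmiles("C" * chain + "c1ccccc1")
    for k in range(step):
        mol = _attach(mol, k, "O")
    return mol


def generate_reaction_network(cfg: SynthConfig) -> SyntheticNetwork:
    """Two reaction chains with known per-step polarity deltas.

    The anaerobic-style chain starts polar (polyhydroxylated ring system)
    and replaces a hydroxyl by a methyl at every step, so per step PSA
    falls and AlogP98 rises.  The aerobic-style chain starts hydrophobic
    (long alkylbenzene) and hydroxylates one chain carbon per oxygen-
    dependent step, so PSA rises and AlogP98 falls.  Cofactor species are
    injected into the equations and filtered out downstream.
    """
    L = cfg.reaction_chain_length
    if not 1 <= L <= 8:
        raise ValueError("reaction_chain_length must be in [1, 8]")

    mets: list[Metabolite] = []
    lines: list[str] = []
    truth_rows = []
    chains: dict[str, list[str]] = {"ana": [], "aer": []}

    builders = {"ana": _anaerobic_chain_molecule, "aer": _aerobic_chain_molecule}
    cof = {"ana": ("NADH", "NAD+"), "aer": ("O2", "H2O")}
    for style in ("ana", "aer"):
        mols = [builders[style](i, L) for i in range(L + 1)]
        ids = [f"{style}_{i}" for i in range(L + 1)]
        chains[style] = ids
        for mid, mol in zip(ids, mols):
            mets.append(Metabolite(mid, mol, "setA" if style == "ana" else "setB"))
        for i in range(1, L + 1):
            left, right = cof[style]
            flag = " | o2" if style == "aer" else ""
            lines.append(f"{style.upper()}{i}: {ids[i-1]} + {left} => {ids[i]} + {right}{flag}")
            prev = compute_descriptors(mols[i - 1], allow_fallback=True)
            curr = compute_descriptors(mols[i], allow_fallback=True)
            truth_rows.append(
                {
                    "reaction": f"{style.upper()}{i}",
                    "chain_style": "anaerobic" if style == "ana" else "aerobic",
                    "substrate": ids[i - 1],
                    "product": ids[i],
                    "dAlogP98": float(curr["AlogP98"] - prev["AlogP98"]),
                    "dPSA": float(curr["PSA"] - prev["PSA"]),
                    "dAcceptor": float(curr["Acceptor"] - prev["Acceptor"]),
                    "dDonor": float(curr["Donor"] - prev["Donor"]),
                }
            )

    from metachem.reactions import parse_reactions  # avoid cycle at import time
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False) as fh:
        fh.write("\n".join(lines) + "\n")
        tmp = fh.name
    reactions, rejected = parse_reactions(tmp)
    Path(tmp).unlink()
    assert not rejected
    truth = pd.DataFrame(truth_rows)
    return SyntheticNetwork(reactions, lines, mets, chains["ana"], chains["aer"], truth)


# ---------------------------------------------------------------------------
# enzyme annotations


@dataclass
class SyntheticAnnotations:
    cofactor_table: pd.DataFrame   # enzyme, set, cofactors (semicolon list)
    residue_table: pd.DataFrame    # enzyme, set, residues (semicolon list)
    ec_labels_a: list[int]
    ec_labels_b: list[int]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cofactors": outdir / "enzyme_cofactors.tsv",
            "residues": outdir / "enzyme_residues.tsv",
        }
        self.cofactor_table.to_csv(paths["cofactors"], sep="\t", index=False)
        self.residue_table.to_csv(paths["residues"], sep="\t", index=False)
        return paths


def generate_enzyme_annotations(cfg: SynthConfig) -> SyntheticAnnotations:
    """Draw cofactor and catalytic-residue annotations for both enzyme sets.

    Cofactors are independent Bernoulli draws per enzyme and cofactor
    (categories are non-exclusive); residues are multinomial draws from the
    configured 20-vectors; EC classes are multinomial over classes 1-6.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    cof_rows = []
    specs = (
        ("setA", cfg.n_enzymes_A, cfg.cofactor_probs_A),
        ("setB", cfg.n_enzymes_B, cfg.cofactor_probs_B),
    )
    for label, n, probs in specs:
        names = sorted(probs)
        for i in range(n):
            used = [c for c in names if rng.random() < probs[c]]
            cof_rows.append({"enzyme": f"{label}_enz{i:03d}", "set": label,
                             "cofactors": ";".join(used)})

    res_rows = []
    for label, n_sites, probs in (
        ("setA", cfg.n_sites_A, cfg.residue_probs_A),
        ("setB", cfg.n_sites_B, cfg.residue_probs_B),
    ):
        aas = list(probs)
        p = np.array([probs[a] for a in aas])
        for i in range(n_sites):
            residues = rng.choice(aas, size=cfg.residues_per_site, p=p)
            res_rows.append({"enzyme": f"{label}_site{i:04d}", "set": label,
                             "residues": ";".join(residues)})

    ec_a = [int(c) + 1 for c in rng.choice(6, size=cfg.n_enzymes_A, p=np.asarray(cfg.ec_probs_A))]
    ec_b = [int(c) + 1 for c in rng.choice(6, size=cfg.n_enzymes_B, p=np.asarray(cfg.ec_probs_B))]

    truth = {
        "cofactor_probs_A": dict(cfg.cofactor_probs_A),
        "cofactor_probs_B": dict(cfg.cofactor_probs_B),
        "residue_probs_A": dict(cfg.residue_probs_A),
        "residue_probs_B": dict(cfg.residue_probs_B),
        "ec_probs_A": tuple(cfg.ec_probs_A),
        "ec_probs_B": tuple(cfg.ec_probs_B),
    }
    return SyntheticAnnotations(
        pd.DataFrame(cof_rows), pd.DataFrame(res_rows), ec_a, ec_b, truth
    )
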
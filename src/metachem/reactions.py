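"""Reaction parsing, substrate/product pair extraction, net property
changes, pathway trajectories, and network module profiles.

Reactions are plain-text equations, one per line::

    R1: 2 A + B => C        (irreversible)
    R2: A <=> B             (reversible)
    R3: S + O2 => P | o2    (flags after '|'; 'o2' marks oxygen dependence)

Reaction pairs are built from irreversible reactions only, after discarding
enzyme cofactors (editable list) and metabolites below a molecular-weight
floor (default 70 Da, strict).  The default pairing is the Cartesian
product of surviving reactants and products; a "main pair" mode (heaviest
reactant x heaviest product) is available.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from metachem.descriptors import POLARITY_DESCRIPTORS

logger = logging.getLogger(__name__)


@dataclass
class Reaction:
    id: str
    reactants: list[tuple[str, float]]   # (metabolite id, stoichiometry)
    products: list[tuple[str, float]]
    reversible: bool
    oxygen_dependent: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def reactant_ids(self) -> list[str]:
        return [m for m, _ in self.reactants]

    @property
    def product_ids(self) -> list[str]:
        return [m for m, _ in self.products]


@dataclass(frozen=True)
class ReactionPair:
    substrate_id: str
    product_id: str
    reaction_id: str


def _parse_side(side: str) -> list[tuple[str, float]]:
    out = []
    # split only on whitespace-delimited '+' so species like NAD+ survive
    for term in re.split(r"(?:^|\s)\+(?:\s|$)", " " + side + " "):
        term = term.strip()
        if not term:
            raise ValueError("empty term")
        parts = term.split()
        if len(parts) == 2:
            coef, name = float(parts[0]), parts[1]
        elif len(parts) == 1:
            coef, name = 1.0, parts[0]
        else:
            raise ValueError(f"malformed term: {term!r}")
        out.append((name, coef))
    return out


def parse_reactions(path: str | Path) -> tuple[list[Reaction], list[str]]:
    """Parse a reaction equation file; malformed lines are logged and
    returned as rejections, never silently dropped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reaction file not found: {path}")
    reactions: list[Reaction] = []
    rejected: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            head, _, flagpart = line.partition("|")
            rid, _, eqn = head.partition(":")
            rid, eqn = rid.strip(), eqn.strip()
            if not rid or not eqn:
                raise ValueError("missing id or equation")
            if "<=>" in eqn:
                lhs, rhs = eqn.split("<=>")
                reversible = True
            elif "=>" in eqn:
                lhs, rhs = eqn.split("=>")
                reversible = False
            else:
                raise ValueError("no reaction arrow")
            reactants, products = _parse_side(lhs), _parse_side(rhs)
            flags = flagpart.split() if flagpart else []
            rxn = Reaction(
                rid, reactants, products, reversible,
                oxygen_dependent="o2" in flags, flags=flags,
            )
            overlap = set(rxn.reactant_ids) & set(rxn.product_ids)
            if overlap:
                rxn.flags.append(f"identity_overlap:{','.join(sorted(overlap))}")
                logger.warning("reaction %s has ids on both sides: %s", rid, sorted(overlap))
            reactions.append(rxn)
        except ValueError as exc:
            logger.warning("rejected reaction line %r: %s", line, exc)
            rejected.append(line)
    return reactions, rejected


def default_cofactor_list() -> set[str]:
    """Editable default list of cofactor/currency species names."""
    text = resources.files("metachem.data").joinpath("cofactors.txt").read_text()
    return {ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")}


def extract_pairs(
    rxns: Sequence[Reaction],
    mw: Mapping[str, float],
    cofactors: Optional[Iterable[str]] = None,
    mw_min: float = 70.0,
    mode: str = "cartesian",
) -> list[ReactionPair]:
    """Substrate/product pairs from irreversible reactions.

    Members on the cofactor list or with MW < ``mw_min`` (strict) are
    discarded; the survivors are paired.  ``mode='cartesian'`` emits all
    reactant x product combinations; ``mode='main'`` emits only the
    heaviest-reactant/heaviest-product pair.  Every metabolite id must
    resolve through ``mw`` or appear on the cofactor list.
    """
    if mode not in ("cartesian", "main"):
        raise ValueError(f"unknown pairing mode: {mode!r}")
    cof = set(cofactors) if cofactors is not None else default_cofactor_list()

    def survivors(ids: Sequence[str]) -> list[str]:
        out = []
        for mid in ids:
            if mid in cof:
                continue
            if mid not in mw:
                raise KeyError(f"metabolite {mid!r} has no structure and is not a listed cofactor")
            if mw[mid] < mw_min:
                continue
            out.append(mid)
        return out

    pairs: list[ReactionPair] = []
    for rxn in rxns:
        if rxn.reversible:
            continue
        subs = survivors(rxn.reactant_ids)
        prods = survivors(rxn.product_ids)
        if not subs or not prods:
            logger.info("reaction %s contributes no pairs after filtering", rxn.id)
            continue
        if mode == "main":
            subs = [max(subs, key=lambda m: (mw[m], m))]
            prods = [max(prods, key=lambda m: (mw[m], m))]
        for s in subs:
            for p in prods:
                pairs.append(ReactionPair(s, p, rxn.id))
    return pairs


@dataclass
class NetChangeSummary:
    """Mean product-minus-substrate change per polarity descriptor."""

    deltas: pd.Series      # mean delta per descriptor
    n_pairs: int


def net_changes(
    pairs: Sequence[ReactionPair],
    descriptors: pd.DataFrame,
    columns: Sequence[str] = POLARITY_DESCRIPTORS,
) -> NetChangeSummary:
    """Average net change (product minus substrate) over reaction pairs."""
    if not pairs:
        raise ValueError("no reaction pairs to summarize")
    cols = [c for c in columns if c in descriptors.columns]
    deltas = []
    for pr in pairs:
        for mid in (pr.substrate_id, pr.product_id):
            if mid not in descriptors.index:
                raise KeyError(f"no descriptor vector for {mid!r}")
        deltas.append(descriptors.loc[pr.product_id, cols].astype(float)
                      - descriptors.loc[pr.substrate_id, cols].astype(float))
    mean = pd.concat(deltas, axis=1).T.mean()
    return NetChangeSummary(mean, len(pairs))


def pathway_trajectory(
    ordered_path: Sequence[str],
    descriptors: pd.DataFrame,
    column: str = "AlogP98",
) -> pd.DataFrame:
    """Per-step descriptor series along an ordered pathway, plus the fraction
    of increasing steps (stored in ``df.attrs['fraction_increasing']``)."""
    if len(ordered_path) < 2:
        raise ValueError("pathway needs at least 2 metabolites")
    missing = [m for m in ordered_path if m not in descriptors.index]
    if missing:
        raise KeyError(f"unresolvable metabolite id(s): {missing}")
    series = [float(descriptors.loc[m, column]) for m in ordered_path]
    steps = [b - a for a, b in zip(series, series[1:])]
    frac_inc = sum(1 for s in steps if s > 0) / len(steps)
    df = pd.DataFrame({"id": list(ordered_path), column: series})
    df.attrs["fraction_increasing"] = frac_inc
    return df


@dataclass
class ModuleProfile:
    initial_reactants: list[str]
    mean_participation: float
    mean_distance_to_core: float
    n_unreachable: int
    participation: dict
    distances: dict


def module_profile(
    rxns: Sequence[Reaction],
    module_members: Iterable[str],
    core: Iterable[str] = (),
    directed: bool = False,
) -> ModuleProfile:
    """Profile one network module.

    Over the bipartite metabolite/reaction graph restricted to the module:
    initial reactants are member metabolites never produced within the
    module; participation counts reactions consuming the metabolite;
    distance to the core is the number of reaction nodes on the shortest
    path (undirected by default).  Core members unreachable from a
    metabolite are excluded from the mean with a count.
    """
    members = set(module_members)
    if not members:
        raise ValueError("module has no members")
    rxns = [r for r in rxns
            if (set(r.reactant_ids) | set(r.product_ids)) & members]
    if not rxns:
        raise ValueError("no reactions touch the module members")

    G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    produced: set[str] = set()
    consumed_in: dict[str, int] = {m: 0 for m in members}
    for r in rxns:
        rnode = ("rxn", r.id)
        G.add_node(rnode, kind="reaction")
        for m in r.reactant_ids:
            G.add_node(("met", m), kind="metabolite")
            G.add_edge(("met", m), rnode)
            if m in members:
                consumed_in[m] += 1
        for m in r.product_ids:
            G.add_node(("met", m), kind="metabolite")
            G.add_edge(rnode, ("met", m))
            if m in members:
                produced.add(m)
        if r.reversible:
            produced.update(set(r.reactant_ids) & members)
            for m in r.product_ids:
                if m in members:
                    consumed_in[m] += 1

    initial = sorted(m for m in members if m not in produced and G.has_node(("met", m)))
    participation = {m: consumed_in.get(m, 0) for m in initial}
    mean_part = (sum(participation.values()) / len(initial)) if initial else math.nan

    core = [c for c in core if G.has_node(("met", c))]
    distances: dict[str, float] = {}
    unreachable = 0
    # directed mode measures metabolite -> core along edge direction
    search_graph = G.reverse() if directed else G
    if core:
        # multi-source BFS from the core over the bipartite graph; distances
        # count reaction nodes on the path (half the bipartite edge count)
        lengths = nx.multi_source_dijkstra_path_length(
            search_graph, {("met", c) for c in core}
        )
        for m in sorted(members):
            node = ("met", m)
            if not G.has_node(node):
                continue
            if node in lengths:
                distances[m] = lengths[node] / 2.0
            elif m in initial:
                unreachable += 1
    reachable_initial = [m for m in initial if m in distances]
    mean_dist = (
        sum(distances[m] for m in reachable_initial) / len(reachable_initial)
        if reachable_initial else math.nan
    )
    return ModuleProfile(initial, mean_part, mean_dist, unreachable, participation, distances)
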
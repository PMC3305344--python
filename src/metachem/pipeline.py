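"""End-to-end orchestration of the two-set comparison.

``run_pipeline`` wires the stages together — standardize, descriptors,
scaffold census, structural cluster map, chemical-space statistics,
reaction net changes, enzyme profiles — and writes the report tables plus
a run log that accounts for every record dropped by any filter.
Sections whose inputs are not configured are skipped and noted in the log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from metachem import chemspace, descriptors, enzymes, io, reactions, scaffolds, simmap

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and the fixed analysis constants.

    Thresholds default to the canonical values used throughout the
    analysis: TC cluster threshold 0.85, reaction-pair MW floor 70 Da,
    factor-loading cutoff 0.85, significance tiers 0.05/0.01.
    """

    set_a: Optional[str] = None            # SMILES/SDF path, set A
    set_b: Optional[str] = None
    format: str = "smiles-lines"
    reactions_path: Optional[str] = None
    cofactor_list: Optional[str] = None
    enzyme_cofactors: Optional[str] = None  # TSV: enzyme, set, cofactors
    enzyme_residues: Optional[str] = None   # TSV: enzyme, set, residues
    outdir: str = "metachem_out"
    tc_threshold: float = 0.85
    mw_min: float = 70.0
    loading_cutoff: float = 0.85
    alpha_tiers: tuple[float, float] = (0.05, 0.01)
    embed_3d: bool = False                 # 3D surface/volume descriptors
    max_map_compounds: int = 400           # NLM cost is O(n^2) per iteration
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tc_threshold <= 1:
            raise ValueError("tc_threshold must be in [0, 1]")
        if self.mw_min < 0:
            raise ValueError("mw_min must be >= 0")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage; returns a summary dict (also written as
    ``run_log.json`` in the output directory)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "stages": {}, "files": []}

    def emit(name: str, df: pd.DataFrame, **to_csv_kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **to_csv_kwargs)
        log["files"].append(name)

    if cfg.set_a is None or cfg.set_b is None:
        raise ValueError("run_pipeline requires both metabolite sets")

    # --- standardize ------------------------------------------------------
    parsed = {}
    for label, path in (("setA", cfg.set_a), ("setB", cfg.set_b)):
        res = io.parse_structures(path, format=cfg.format, set_label=label)
        std = io.standardize_all(res.metabolites)
        parsed[label] = std
        log["stages"][f"standardize_{label}"] = {
            "input": len(res.metabolites) + len(res.rejected),
            "kept": len(std),
            "rejected": len(res.rejected),
        }
    mets_a, mets_b = parsed["setA"], parsed["setB"]
    io.write_smiles_table(mets_a + mets_b, out / "standardized.tsv")
    log["files"].append("standardized.tsv")

    # --- descriptors ------------------------------------------------------
    desc_a = descriptors.descriptor_table(mets_a, seed=cfg.seed, embed=cfg.embed_3d)
    desc_b = descriptors.descriptor_table(mets_b, seed=cfg.seed, embed=cfg.embed_3d)
    emit("descriptors_setA.tsv", desc_a)
    emit("descriptors_setB.tsv", desc_b)

    # --- scaffolds --------------------------------------------------------
    cen_a, cen_b = scaffolds.census(mets_a), scaffolds.census(mets_b)
    comp = scaffolds.compare_censuses(cen_a, cen_b)
    scaffolds.write_census_table(cen_a, cen_b, out / "scaffold_census.tsv")
    log["files"].append("scaffold_census.tsv")
    log["stages"]["scaffolds"] = {
        "distinct_a": cen_a.n_distinct, "density_a": cen_a.density,
        "distinct_b": cen_b.n_distinct, "density_b": cen_b.density,
        "shared": len(comp.shared), "novel_in_b": len(comp.novel_in_b),
    }

    # --- structural cluster map ------------------------------------------
    both = mets_a + mets_b
    if len(both) > cfg.max_map_compounds:
        import numpy as np

        rng = np.random.default_rng(cfg.seed)
        idx = sorted(rng.choice(len(both), size=cfg.max_map_compounds, replace=False))
        sample = [both[i] for i in idx]
        log["stages"]["map_subsample"] = {"from": len(both), "to": len(sample)}
    else:
        sample = both
    fps = [simmap.fingerprint(m) for m in sample]
    points, sres = simmap.nlm_embed(fps, seed=cfg.seed, ids=[m.id for m in sample],
                                    t=cfg.tc_threshold)
    emit("embedding.tsv", simmap.embedding_table(points, [m.set_label for m in sample]),
         index=False)
    log["stages"]["map"] = {"stress": sres.stress, "n": len(sample)}

    # --- chemical space ---------------------------------------------------
    table2 = chemspace.summarize_and_test(desc_a, desc_b)
    emit("property_comparison.tsv", table2)
    combined = pd.concat([desc_a, desc_b])
    if len(combined) >= 3 * combined.shape[1]:
        model = chemspace.factor_analysis_varimax(combined, loading_cutoff=cfg.loading_cutoff)
        emit("factor_loadings.tsv", model.loadings)
        emit("factor_scores.tsv", model.scores)
        log["stages"]["chemspace"] = {
            "variance_explained": list(model.variance_explained),
            "high_loading_factor1": model.high_loading_descriptors[0],
            "high_loading_factor2": model.high_loading_descriptors[1],
        }
    else:
        log["stages"]["chemspace"] = (
            f"factor analysis skipped ({len(combined)} rows < 3x {combined.shape[1]} descriptors)"
        )

    # --- reactions --------------------------------------------------------
    if cfg.reactions_path:
        rxns, rejected = reactions.parse_reactions(cfg.reactions_path)
        cof = None
        if cfg.cofactor_list:
            cof = {ln.strip() for ln in Path(cfg.cofactor_list).read_text().splitlines()
                   if ln.strip() and not ln.startswith("#")}
        all_desc = pd.concat([desc_a, desc_b])
        mw = all_desc["MW"].to_dict()
        pairs = reactions.extract_pairs(rxns, mw, cofactors=cof, mw_min=cfg.mw_min)
        log["stages"]["reactions"] = {
            "parsed": len(rxns), "rejected": len(rejected), "pairs": len(pairs),
        }
        if pairs:
            nc = reactions.net_changes(pairs, all_desc)
            emit("net_changes.tsv", nc.deltas.to_frame("mean_delta"))
            log["stages"]["reactions"]["n_pairs"] = nc.n_pairs
    else:
        log["stages"]["reactions"] = "skipped (no reaction file configured)"

    # --- enzymes ----------------------------------------------------------
    if cfg.enzyme_cofactors:
        annot = pd.read_csv(cfg.enzyme_cofactors, sep="\t").fillna("")
        table = enzymes.CofactorTable.from_annotations(annot)
        emit("cofactor_enrichment.tsv", enzymes.cofactor_enrichment(table))
        log["stages"]["enzymes_cofactors"] = {"n_a": table.n_a, "n_b": table.n_b}
    else:
        log["stages"]["enzymes_cofactors"] = "skipped (no cofactor table configured)"
    if cfg.enzyme_residues:
        annot = pd.read_csv(cfg.enzyme_residues, sep="\t")
        sites = {"setA": [], "setB": []}
        for _, row in annot.iterrows():
            sites[row["set"]].extend(str(row["residues"]).split(";"))
        emit("residue_composition.tsv",
             enzymes.residue_composition_test(sites["setA"], sites["setB"]))
        log["stages"]["enzymes_residues"] = {
            "sites_a": len(sites["setA"]), "sites_b": len(sites["setB"]),
        }
    else:
        log["stages"]["enzymes_residues"] = "skipped (no residue table configured)"

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log
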
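"""Replicated null-calibration and power checks for the statistical tests.

These routines quantify how the package's between-set tests behave under a
true null (no planted effect: do they flag at roughly the nominal alpha?)
and under the cofactor-usage contrast at the study's enzyme sample sizes
(do they detect it reliably?).
"""

from __future__ import annotations

import numpy as np

from metachem.chemspace import summarize_and_test
from metachem.descriptors import descriptor_table
from metachem.enzymes import CofactorTable, cofactor_enrichment
from metachem.synth import SynthConfig, generate_enzyme_annotations, generate_metabolite_sets


def null_calibration_flag_rate(
    base_seed: int,
    n_replicates: int = 100,
    alpha: float = 0.05,
) -> float:
    """Fraction of null tests flagged at ``alpha``.

    Per replicate: two 60-molecule metabolite sets drawn from one
    distribution (zero polarity/rigidity shifts, a single shared scaffold
    list) are compared on AlogP98 and RingCount with Welch t-tests, and two
    80-enzyme sets with equal cofactor usage probabilities (0.3 for each of
    10 cofactors) are compared with per-cofactor chi-squares.  All P values
    are pooled.
    """
    pvals: list[float] = []
    for r in range(n_replicates):
        cfg = SynthConfig(
            n_setA=60, n_setB=60, polarity_shift=0.0, rigidity_shift=0.0,
            acyclic_frac_A=0.25, acyclic_frac_B=0.25,
            n_shared_scaffolds=8, n_unique_scaffolds_A=0, n_unique_scaffolds_B=0,
            cofactor_probs_A={f"c{i}": 0.3 for i in range(10)},
            cofactor_probs_B={f"c{i}": 0.3 for i in range(10)},
            n_enzymes_A=80, n_enzymes_B=80, seed=base_seed + r,
        )
        sets = generate_metabolite_sets(cfg)
        da = descriptor_table(sets.metabolites_a, embed=False)
        db = descriptor_table(sets.metabolites_b, embed=False)
        t = summarize_and_test(da[["AlogP98", "RingCount"]], db[["AlogP98", "RingCount"]])
        pvals.extend(t["p_value"])
        ann = generate_enzyme_annotations(cfg)
        enr = cofactor_enrichment(CofactorTable.from_annotations(ann.cofactor_table))
        pvals.extend(enr["p_value"])
    return float((np.asarray(pvals) < alpha).mean())


def nadh_power(base_seed: int, n_replicates: int = 100, alpha: float = 0.05) -> int:
    """Replicates in which the NAD(H) usage contrast at the study's sample
    sizes (success probabilities 70/154 vs 12/121) is flagged at ``alpha``."""
    rng = np.random.default_rng(base_seed)
    hits = 0
    for _ in range(n_replicates):
        ka = int(rng.binomial(154, 70 / 154))
        kb = int(rng.binomial(121, 12 / 121))
        enr = cofactor_enrichment(CofactorTable({"NAD(H)": (ka, kb)}, 154, 121))
        hits += bool(enr.loc["NAD(H)", "p_value"] < alpha)
    return hits
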
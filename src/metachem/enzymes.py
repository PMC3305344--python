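"""Enzyme-level contingency analyses.

Cofactor usage between two enzyme sets is tested per cofactor with a 2x2
chi-square (uses / does-not-use x set) without continuity correction; when
an expected cell drops below 1 the test falls back to Fisher's exact test
and the row is flagged.  Catalytic-residue compositions are compared with
two-sided two-proportion z-tests.  Cofactor categories are non-exclusive:
an enzyme with several cofactors counts once per cofactor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)


@dataclass
class CofactorTable:
    """Per-cofactor usage counts for two enzyme sets."""

    counts: dict[str, tuple[int, int]]   # cofactor -> (count_setA, count_setB)
    n_a: int                             # enzymes in set A
    n_b: int

    @classmethod
    def from_annotations(cls, annot: pd.DataFrame) -> "CofactorTable":
        """Build from a table with columns (enzyme, set, cofactors) where
        cofactors is a semicolon-separated list."""
        counts: dict[str, list[int]] = {}
        n = {"setA": 0, "setB": 0}
        for _, row in annot.iterrows():
            s = row["set"]
            n[s] += 1
            for cof in str(row["cofactors"]).split(";"):
                cof = cof.strip()
                if not cof:
                    continue
                counts.setdefault(cof, [0, 0])[0 if s == "setA" else 1] += 1
        return cls({k: (v[0], v[1]) for k, v in counts.items()}, n["setA"], n["setB"])


def _chi2_2x2(used_a: int, n_a: int, used_b: int, n_b: int) -> tuple[float, str]:
    """(P value, test name) for a uses/does-not-use x set table."""
    table = np.array([[used_a, n_a - used_a], [used_b, n_b - used_b]])
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        p = float(stats.fisher_exact(table)[1])
        return p, "fisher"
    p = float(stats.chi2_contingency(table, correction=False)[1])
    return p, "chi2"


def cofactor_enrichment(table: CofactorTable, correction: bool = False) -> pd.DataFrame:
    """Per-cofactor percentages, chi-square P values, and significance tiers.

    Percentages are 100 * count/total (1-decimal reporting); tiers are
    '**' for P < 0.01 and '*' for P < 0.05.
    """
    if table.n_a <= 0 or table.n_b <= 0:
        raise ValueError("both enzyme totals must be positive")
    rows = []
    for cof, (ca, cb) in sorted(table.counts.items()):
        tab = np.array([[ca, table.n_a - ca], [cb, table.n_b - cb]])
        expected = stats.contingency.expected_freq(tab)
        if (expected < 1).any():
            p, test = float(stats.fisher_exact(tab)[1]), "fisher"
        else:
            p = float(stats.chi2_contingency(tab, correction=correction)[1])
            test = "chi2"
        tier = "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append(
            {
                "cofactor": cof,
                "count_a": ca,
                "count_b": cb,
                "pct_a": round(100.0 * ca / table.n_a, 1),
                "pct_b": round(100.0 * cb / table.n_b, 1),
                "p_value": p,
                "test": test,
                "tier": tier,
            }
        )
    return pd.DataFrame(rows).set_index("cofactor")


def residue_composition_test(
    sites_a: Sequence[str],
    sites_b: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Catalytic-site residue composition comparison.

    ``sites_a``/``sites_b`` are multisets of residue three-letter codes.
    Per-residue frequencies (summing to 1 per set) are compared with a
    two-sided two-proportion z-test; residues are flagged ``enriched_in``
    'setA' or 'setB' at P < alpha.  A residue absent from both sets is
    reported with frequency 0 and no test.
    """
    if not len(sites_a) or not len(sites_b):
        raise ValueError("both residue multisets must be non-empty")
    na, nb = len(sites_a), len(sites_b)
    ca = pd.Series(sites_a).value_counts()
    cb = pd.Series(sites_b).value_counts()
    residues = sorted(set(ca.index) | set(cb.index) | set(AMINO_ACIDS))
    rows = []
    for r in residues:
        ka, kb = int(ca.get(r, 0)), int(cb.get(r, 0))
        if ka == 0 and kb == 0:
            p, enriched = np.nan, ""
        else:
            stat, p = proportions_ztest([ka, kb], [na, nb])
            p = float(p)
            enriched = ""
            if p < alpha:
                enriched = "setA" if ka / na > kb / nb else "setB"
        rows.append(
            {
                "residue": r,
                "freq_a": ka / na,
                "freq_b": kb / nb,
                "count_a": ka,
                "count_b": kb,
                "p_value": p,
                "enriched_in": enriched,
            }
        )
    return pd.DataFrame(rows).set_index("residue")


def ec_class_frequency(
    ec_labels_a: Sequence[int],
    ec_labels_b: Sequence[int],
) -> pd.DataFrame:
    """Normalized frequency of top-level EC classes 1-6 per set; labels
    outside 1-6 are logged and rejected."""
    out = {}
    for name, labels in (("setA", ec_labels_a), ("setB", ec_labels_b)):
        valid = [l for l in labels if isinstance(l, (int, np.integer)) and 1 <= l <= 6]
        bad = len(labels) - len(valid)
        if bad:
            logger.warning("%s: rejected %d EC labels outside 1-6", name, bad)
        if not valid:
            raise ValueError(f"no valid EC labels in {name}")
        counts = pd.Series(valid).value_counts().reindex(range(1, 7), fill_value=0)
        out[name] = counts / counts.sum()
    df = pd.DataFrame(out)
    df.index.name = "ec_class"
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
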
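"""Regulatory-coherence test on a regulator-perturbation response matrix.

Given per-gene response profiles across a panel of regulator knockdowns,
the test asks whether a candidate gene group (e.g. a network neighborhood)
responds more coherently than it does with outside genes: Pearson
correlations are computed across perturbations for every gene pair, the
within-group pair correlations are compared with the group x non-group
pair correlations (pairs of two outside genes are not part of the
comparison), and a Welch two-sample t test on the two collections of
correlation values yields the significance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("clrnet")


@dataclass(frozen=True)
class CoherenceResult:
    group_genes: tuple[str, ...]
    r_in: float
    r_out: float
    t_statistic: float
    p_value: float
    n_in_pairs: int
    n_out_pairs: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "group_genes": list(self.group_genes),
                "r_in": self.r_in,
                "r_out": self.r_out,
                "t": self.t_statistic,
                "p": self.p_value,
                "n_in_pairs": self.n_in_pairs,
                "n_out_pairs": self.n_out_pairs,
            },
            indent=2,
        )


def read_response_matrix(path) -> pd.DataFrame:
    """Gene x perturbation TSV: rows genes, columns perturbation labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene rows in response matrix")
    return df.astype(float)


def coherence_test(responses: pd.DataFrame, group) -> CoherenceResult:
    """In-group vs out-of-group pairwise-correlation comparison.

    ``responses``: genes x perturbations. Genes with zero variance across
    perturbations are excluded (logged); the test requires >= 2 surviving
    group genes and >= 1 non-group gene.
    """
    group = sorted(set(group))
    missing = set(group) - set(responses.index)
    if missing:
        raise KeyError(f"group genes absent from matrix: {sorted(missing)}")
    if responses.shape[1] < 3:
        raise ValueError("need >= 3 perturbation columns")
    variances = responses.var(axis=1, ddof=0)
    dead = variances[variances == 0].index
    if len(dead):
        logger.warning("excluding %d zero-variance genes from coherence test", len(dead))
        responses = responses.drop(index=dead)
        group = [g for g in group if g not in set(dead)]
    if len(group) < 2:
        raise ValueError("fewer than 2 group genes with nonzero variance")
    others = [g for g in responses.index if g not in set(group)]
    if not others:
        raise ValueError("no non-group genes to compare against")
    corr = np.corrcoef(responses.to_numpy())
    idx = {g: i for i, g in enumerate(responses.index)}
    gi = [idx[g] for g in group]
    oi = [idx[g] for g in others]
    in_vals = [corr[a, b] for i, a in enumerate(gi) for b in gi[i + 1:]]
    out_vals = [corr[a, b] for a in gi for b in oi]
    t, p = stats.ttest_ind(in_vals, out_vals, equal_var=False)
    return CoherenceResult(
        tuple(group),
        float(np.mean(in_vals)),
        float(np.mean(out_vals)),
        float(t),
        float(p),
        len(in_vals),
        len(out_vals),
    )
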
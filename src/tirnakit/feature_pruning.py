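"""Pearson-correlation feature pruning.

Features whose pairwise |PCC| exceeds a threshold (default 0.75) are grouped
into connected components of the correlation graph; one representative per
component is retained, chosen by a preference order that defaults to
FAA, FAB, EIS, PAU, RBS11, PT (then remaining features alphabetically).
Grouping by connected components makes the outcome order-independent; the
chain convention (A-B and B-C correlated but not A-C still collapse to one
group) is deliberate and tested.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("tirnakit")

DEFAULT_THRESHOLD = 0.75
DEFAULT_PREFERENCE = ("FAA", "FAB", "EIS", "PAU", "RBS11", "PT")


@dataclass
class CorrelationReport:
    pcc: pd.DataFrame
    threshold: float
    groups: list[list[str]]
    retained: list[str]
    dropped: dict[str, str]  # feature -> representative that supplanted it

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "groups": self.groups,
            "retained": self.retained,
            "dropped": self.dropped,
            "pcc": {
                "features": list(self.pcc.columns),
                "matrix": self.pcc.to_numpy().round(12).tolist(),
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations on complete rows.

    Constant columns have undefined correlation; those entries are recorded
    as 0 with a warning (the diagonal stays 1).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    data = table.dropna()
    constant = [c for c in data.columns if data[c].nunique() <= 1]
    if constant:
        logger.warning(
            "constant feature column(s) %s: correlations undefined, set to 0",
            constant,
        )
    pcc = data.corr(method="pearson")
    pcc = pcc.fillna(0.0)
    np.fill_diagonal(pcc.values, 1.0)
    return pcc


def prune(
    pcc: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    preference: tuple[str, ...] = DEFAULT_PREFERENCE,
) -> CorrelationReport:
    """Connected-component pruning of the |PCC| > threshold graph."""
    features = list(pcc.columns)
    mat = pcc.to_numpy()
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("pcc must be a symmetric square matrix")
    adj = (np.abs(mat) > threshold).astype(int)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    rank = {name: i for i, name in enumerate(preference)}

    def pref_key(name: str):
        return (rank.get(name, len(preference)), name)  # then alphabetical

    groups: list[list[str]] = []
    retained: list[str] = []
    dropped: dict[str, str] = {}
    for comp in range(n_comp):
        members = [features[i] for i in range(len(features)) if labels[i] == comp]
        members.sort(key=pref_key)
        rep = members[0]
        groups.append(sorted(members))
        retained.append(rep)
        for m in members[1:]:
            dropped[m] = rep
    # keep the original column order for the retained list
    retained = [f for f in features if f in set(retained)]
    groups.sort(key=lambda g: features.index(g[0]))
    return CorrelationReport(
        pcc=pcc, threshold=threshold, groups=groups,
        retained=retained, dropped=dropped,
    )
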
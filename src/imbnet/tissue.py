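"""Tissue-preferential expression calls and per-tissue tallies.

A gene is preferentially expressed in a tissue when its atlas value there
is at least ``z_threshold`` standard deviations above its own across-tissue
mean (sample sd, ddof=1). Calls are non-exclusive: a gene may be
preferential in several tissues. The tally counts, per tissue, how many
genes from a list of interest (typically common downstream genes of key
drivers) are preferentially expressed there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .synthetic import TissueMatrix

__all__ = ["TissueCall", "preferential_tissues", "tally_by_tissue"]


@dataclass
class TissueCall:
    gene: str
    tissue: str
    zscore: float
    is_preferential: bool


def preferential_tissues(
    atlas: TissueMatrix | pd.DataFrame, z_threshold: float = 2.0
) -> list[TissueCall]:
    """Z-score each gene's tissue profile; call tissues with z >= threshold.

    Genes with zero across-tissue spread yield no calls.
    """
    expr = atlas.expression if isinstance(atlas, TissueMatrix) else atlas
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 tissues")
    calls: list[TissueCall] = []
    values = expr.to_numpy(dtype=float)
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=1)
    for i, gene in enumerate(expr.index):
        if sds[i] == 0:
            continue
        z = (values[i] - means[i]) / sds[i]
        for j, tissue in enumerate(expr.columns):
            if z[j] >= z_threshold:
                calls.append(
                    TissueCall(
                        gene=gene,
                        tissue=tissue,
                        zscore=float(z[j]),
                        is_preferential=True,
                    )
                )
    return calls


def tally_by_tissue(
    calls: list[TissueCall], genes_of_interest: Iterable[str]
) -> list[tuple[str, int]]:
    """Count genes of interest preferentially expressed per tissue,
    descending (ties: tissue name)."""
    interest = set(genes_of_interest)
    counts: dict[str, int] = {}
    for c in calls:
        if c.is_preferential and c.gene in interest:
            counts[c.tissue] = counts.get(c.tissue, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
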
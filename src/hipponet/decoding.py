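"""Mask-based meta-analytic decoding.

Correlates a binarized spatial network mask with a stack of term-wise
activation maps over a common grid and ranks the terms by correlation —
the decoding computation itself, independent of any particular
meta-analytic database.  Term curation (anatomical/redundant terms) is a
user-supplied exclude list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hipponet")

__all__ = ["TermMapStack", "decode_terms"]


@dataclass
class TermMapStack:
    """Term activation maps over a common voxel/vertex grid."""

    terms: list[str]
    maps: np.ndarray  # n_terms x grid_size
    grid_id: str = "grid"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2 or self.maps.shape[0] != len(self.terms):
            raise ValueError("maps must be n_terms x grid_size")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("non-finite values in term maps")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in stack")


def decode_terms(
    mask: np.ndarray,
    stack: TermMapStack,
    top_k: int | None = None,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Rank terms by Pearson correlation between map and binary mask.

    Returns a DataFrame ``term, r, rank`` in descending r (ties broken by
    term token for a stable order), truncated to ``top_k`` when given.
    Terms in ``exclude`` are dropped; constant maps are skipped with a
    warning and reported in the ``skipped`` attribute of the frame.
    """
    mask = np.asarray(mask, dtype=float)
    if mask.ndim != 1 or mask.shape[0] != stack.maps.shape[1]:
        raise ValueError("mask length must equal term-map grid size")
    uniq = np.unique(mask)
    if not np.array_equal(uniq, [0.0, 1.0]):
        raise ValueError("mask must be binary with both 0s and 1s present")
    excluded = set(exclude)
    mask_c = mask - mask.mean()
    mask_norm = np.linalg.norm(mask_c)
    rows = []
    skipped = []
    for term, tmap in zip(stack.terms, stack.maps):
        if term in excluded:
            continue
        map_c = tmap - tmap.mean()
        denom = np.linalg.norm(map_c) * mask_norm
        if denom == 0.0:
            skipped.append(term)
            continue
        rows.append((term, float(mask_c @ map_c / denom)))
    if skipped:
        logger.warning("terms skipped (constant map): %s", skipped)
    rows.sort(key=lambda tr: (-tr[1], tr[0]))
    if top_k is not None:
        rows = rows[:top_k]
    frame = pd.DataFrame(rows, columns=["term", "r"])
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame.attrs["skipped"] = skipped
    return frame
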
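"""Sign-aligned composite modulation score and its quadrant decomposition.

The score links an in-vitro perturbation DEG list to an in-vivo modulation
axis. For each gene called differentially expressed both in vitro (variant
vs. empty vector) and in vivo (modulated vs. differentiated SMCs), the
in-vitro log2FC is multiplied by the in-vivo direction sign: +1 for genes up
in modulated cells, -1 for genes up in differentiated cells (so, e.g.,
up-regulating a contractile marker like CNN1 counts against modulation).
The signed contributions are summed per variant; positive totals mean the
perturbation shifts the transcriptome toward the modulated phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, Mapping

import numpy as np
import pandas as pd

QUADRANTS = (
    "up_mod_up_vitro",
    "up_mod_down_vitro",
    "up_diff_up_vitro",
    "up_diff_down_vitro",
)


@dataclass
class CompositeScore:
    """Total score, per-gene signed contributions, and quadrant sums."""

    total: float
    contributions: pd.Series
    quadrants: Dict[str, float]
    n_intersect: int

    @property
    def normalized(self) -> float:
        """Size-normalized variant (total / n_intersect); 0 on empty
        intersection. Not part of the published procedure; reported only for
        cross-variant comparability."""
        return self.total / self.n_intersect if self.n_intersect else 0.0


def composite_score(invitro_degs: pd.DataFrame, ref: pd.DataFrame) -> CompositeScore:
    """Score a variant's DEG list against the in-vivo modulation reference.

    ``invitro_degs`` is a DE/DEG table indexed by gene with a ``log2fc``
    column (as produced by :func:`modscore.bulk.call_degs`); ``ref`` is the
    oriented reference with a ``sign`` column (+1 up in modulated, -1 up in
    differentiated; see :func:`modscore.sc.build_modulation_reference`).
    Contributions are sign * in-vitro log2fc over the gene intersection; the
    total is their sum. An empty intersection warns and scores 0.
    """
    common = invitro_degs.index.intersection(ref.index)
    if len(common) == 0:
        warnings.warn("no genes shared between DEG list and reference; score = 0")
        return CompositeScore(0.0, pd.Series(dtype=float), dict.fromkeys(QUADRANTS, 0.0), 0)
    lfc = invitro_degs.loc[common, "log2fc"].astype(float)
    sign = ref.loc[common, "sign"].astype(int)
    contrib = sign * lfc
    contrib.name = "contribution"

    quads = dict.fromkeys(QUADRANTS, 0.0)
    zero_lfc = lfc == 0
    if zero_lfc.any():
        warnings.warn(
            f"{int(zero_lfc.sum())} gene(s) with in-vitro log2fc == 0 excluded "
            "from quadrant assignment"
        )
    key = np.where(
        sign > 0,
        np.where(lfc > 0, "up_mod_up_vitro", "up_mod_down_vitro"),
        np.where(lfc > 0, "up_diff_up_vitro", "up_diff_down_vitro"),
    )
    for q, c, z in zip(key, contrib, zero_lfc):
        if not z:
            quads[q] += float(c)
    return CompositeScore(
        total=float(contrib.sum()),
        contributions=contrib,
        quadrants=quads,
        n_intersect=int(len(common)),
    )


def score_decomposition(cs: CompositeScore) -> pd.DataFrame:
    """Quadrant table of a composite score with the dominant quadrant flagged.

    Rows are the four (in-vivo direction, in-vitro direction) quadrants; the
    dominant quadrant is the one with the largest absolute contribution sum.
    The four sums always total ``cs.total`` (zero-log2fc genes cannot occur in
    a strict-cutoff DEG list).
    """
    sums = pd.Series(cs.quadrants, name="contribution_sum").reindex(QUADRANTS)
    dominant = sums.abs().idxmax() if cs.n_intersect else None
    return pd.DataFrame(
        {"contribution_sum": sums, "dominant": sums.index == dominant}
    )


def score_all_variants(
    deg_lists: Mapping[str, pd.DataFrame],
    refs: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, Dict[tuple[str, str], CompositeScore]]:
    """Composite scores for every (variant, axis) pair.

    ``deg_lists`` maps variant name to its DEG table; ``refs`` maps axis name
    (e.g. ``"all_modulated"`` and ``"cmc"``) to a modulation reference.
    Returns (totals DataFrame variants x axes, detail dict of CompositeScore
    for audit). Variants with an empty DEG list score 0 with a warning.
    """
    if not deg_lists or not refs:
        raise ValueError("need at least one variant and one axis")
    details: Dict[tuple[str, str], CompositeScore] = {}
    totals = pd.DataFrame(index=list(deg_lists), columns=list(refs), dtype=float)
    for vname, degs in deg_lists.items():
        for aname, ref in refs.items():
            if degs.empty:
                warnings.warn(f"variant {vname!r} has an empty DEG list; score 0")
                cs = CompositeScore(
                    0.0, pd.Series(dtype=float), dict.fromkeys(QUADRANTS, 0.0), 0
                )
            else:
                cs = composite_score(degs, ref)
            details[(vname, aname)] = cs
            totals.loc[vname, aname] = cs.total
    return totals, details
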
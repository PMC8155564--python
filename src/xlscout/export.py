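"""Export validated cross-links as a CSV suitable for xiView-style viewers."""

from __future__ import annotations

import pandas as pd

from .validate import Crosslink

_CONF_RANK = {"high": 0, "medium": 1, "rejected": 2}

COLUMNS = ["Protein1", "Protein2", "PepSeq1", "PepSeq2", "PepPos1", "PepPos2",
           "LinkPos1", "LinkPos2", "AbsPos1", "AbsPos2", "Charge", "Score",
           "Decoy1", "Decoy2"]


def _side(hit, accession: str, residue: int):
    """Find the peptide location consistent with the residue-pair side."""
    for acc, start in hit.peptide.protein_locations:
        if acc == accession and start + hit.link_position - 1 == residue:
            return start
    return hit.peptide.protein_locations[0][1]


def export_xiview(crosslinks: list[Crosslink], minimum_confidence: str = "medium",
                  include_decoys: bool = False) -> pd.DataFrame:
    """One row per cross-link at or above the requested confidence.

    Positions are 1-based; AbsPos is the linked residue position within the
    protein.  Decoy cross-links are excluded unless explicitly requested.
    """
    if minimum_confidence not in _CONF_RANK:
        raise ValueError(f"unknown confidence {minimum_confidence!r}")
    max_rank = _CONF_RANK[minimum_confidence]
    rows = []
    for xl in crosslinks:
        if _CONF_RANK.get(xl.confidence, 99) > max_rank:
            continue
        if xl.decoy and not include_decoys:
            continue
        best = xl.csms[0]
        (a1, r1), (a2, r2) = xl.residue_pair
        # orient alpha/beta to the sorted residue pair
        hit1, hit2 = best.alpha, best.beta
        if not any(acc == a1 and start + hit1.link_position - 1 == r1
                   for acc, start in hit1.peptide.protein_locations):
            hit1, hit2 = hit2, hit1
        rows.append({
            "Protein1": a1, "Protein2": a2,
            "PepSeq1": hit1.peptide.sequence, "PepSeq2": hit2.peptide.sequence,
            "PepPos1": _side(hit1, a1, r1), "PepPos2": _side(hit2, a2, r2),
            "LinkPos1": hit1.link_position, "LinkPos2": hit2.link_position,
            "AbsPos1": r1, "AbsPos2": r2,
            "Charge": best.precursor_charge, "Score": xl.score,
            "Decoy1": hit1.peptide.is_decoy, "Decoy2": hit2.peptide.is_decoy,
        })
    return pd.DataFrame(rows, columns=COLUMNS)
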
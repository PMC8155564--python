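"""Target-decoy validation: CSM grouping into cross-links and two-level FDR.

A cross-link is the unique unordered pair of linked protein residues; it
aggregates every CSM that resolves to that residue pair (so a peptide that is
a substring of a longer peptide still lands in the same cross-link).  The FDR
is estimated by the target-decoy assumption — the number of false positives
among targets is taken to be no larger than the number of decoy hits at the
same score — independently at the CSM and the cross-link level, with two
confidence tiers (default 1% high, 5% medium) and optional separate
validation of intra- and inter-protein links.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .chem import Peptide
from .search import CSM


@dataclass(frozen=True)
class Crosslink:
    """A unique linked residue pair with its supporting CSMs."""

    residue_pair: tuple[tuple[str, int], tuple[str, int]]  # sorted, 1-based
    csms: tuple[CSM, ...]
    score: float
    link_class: str  # intra | inter
    decoy: bool
    confidence: str = "rejected"  # high | medium | rejected

    @property
    def is_decoy(self) -> bool:
        return self.decoy


@dataclass(frozen=True)
class FdrConfig:
    """FDR thresholds and estimator options."""

    csm_thresholds: tuple[float, float] = (0.01, 0.05)  # (high, medium)
    crosslink_thresholds: tuple[float, float] = (0.01, 0.05)
    separate_intra_inter: bool = False
    pseudocount: bool = False  # True: (D+1)/T instead of D/T

    def __post_init__(self) -> None:
        for hi, med in (self.csm_thresholds, self.crosslink_thresholds):
            if hi > med:
                raise ValueError("high-confidence threshold must not exceed medium")


def classify_csm(csm: CSM) -> str:
    """TT / TD / DD class; TD and DD both count as decoy for FDR purposes."""
    return csm.decoy_class


def _residue_pairs(csm: CSM) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """All unordered absolute residue pairs a CSM supports (shared peptides
    contribute every protein location)."""

    def absolute(hit) -> list[tuple[str, int]]:
        pep: Peptide = hit.peptide
        if not pep.protein_locations:
            raise ValueError(f"peptide {pep.sequence!r} has no protein location")
        return [(acc, start + hit.link_position - 1)
                for acc, start in pep.protein_locations]

    pairs = set()
    for pa in absolute(csm.alpha):
        for pb in absolute(csm.beta):
            pairs.add(tuple(sorted((pa, pb))))
    return pairs


def group_crosslinks(csms: list[CSM]) -> list[Crosslink]:
    """Merge CSMs into cross-links keyed by the unordered residue pair.

    A CSM with shared peptides joins every residue-pair group it supports.
    The cross-link score is the maximum member CSM score; its class is intra
    iff both residues lie on the same protein accession.  A cross-link is a
    decoy if any member CSM involves a decoy peptide.
    """
    groups: dict[tuple, list[CSM]] = {}
    for csm in csms:
        for key in _residue_pairs(csm):
            groups.setdefault(key, []).append(csm)
    out = []
    for key in sorted(groups):
        members = tuple(sorted(groups[key], key=lambda c: (-c.score, c.scan_id)))
        out.append(Crosslink(
            residue_pair=key, csms=members,
            score=max(c.score for c in members),
            link_class="intra" if key[0][0] == key[1][0] else "inter",
            decoy=any(c.is_decoy for c in members)))
    return out


def estimate_fdr(items: list, thresholds: tuple[float, float],
                 pseudocount: bool = False) -> tuple[list, list[float]]:
    """Assign high/medium/rejected confidence by a descending-score FDR scan.

    At each rank the FDR estimate is (#decoys)/(#targets) among the items at
    or above that score (undefined while no target has been seen).  The
    high-confidence set is the largest score-prefix whose FDR is at or below
    the high threshold; the medium set likewise for the medium threshold.
    Tie groups (equal scores) pass or fail as a whole, judged at the bottom of
    the group.  Returns (labeled items, per-item FDR estimates).
    """
    if not items:
        return [], []
    order = sorted(range(len(items)), key=lambda i: -items[i].score)
    fdr_at: list[float] = []
    d = t = 0
    for rank, i in enumerate(order):
        if items[i].is_decoy:
            d += 1
        else:
            t += 1
        num = d + 1 if pseudocount else d
        fdr_at.append(num / t if t > 0 else float("inf"))
    # a tie group shares the FDR computed at its deepest rank
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and \
                items[order[j + 1]].score == items[order[k]].score:
            j += 1
        for r in range(k, j + 1):
            fdr_at[r] = fdr_at[j]
        k = j + 1
    hi_thr, med_thr = thresholds
    cut_hi = max((r for r, f in enumerate(fdr_at) if f <= hi_thr), default=-1)
    cut_med = max((r for r, f in enumerate(fdr_at) if f <= med_thr), default=-1)
    labels = ["rejected"] * len(items)
    for r, i in enumerate(order):
        if r <= cut_hi:
            labels[i] = "high"
        elif r <= cut_med:
            labels[i] = "medium"
    labeled = [replace(it, confidence=lab) for it, lab in zip(items, labels)]
    fdrs = [0.0] * len(items)
    for r, i in enumerate(order):
        fdrs[i] = fdr_at[r]
    return labeled, fdrs


def separated_fdr(items: list, thresholds: tuple[float, float],
                  pseudocount: bool = False) -> list:
    """Validate intra- and inter-protein items independently, then reconcatenate.

    Labels within one class are invariant to any change in the other class.
    """
    intra_idx = [i for i, it in enumerate(items) if it.link_class == "intra"]
    inter_idx = [i for i, it in enumerate(items) if it.link_class != "intra"]
    out: list = [None] * len(items)
    for idx in (intra_idx, inter_idx):
        labeled, _ = estimate_fdr([items[i] for i in idx], thresholds, pseudocount)
        for i, it in zip(idx, labeled):
            out[i] = it
    return out


@dataclass(frozen=True)
class _LabeledCSM:
    """CSM wrapper carrying a confidence label through FDR estimation."""

    csm: CSM
    confidence: str = "rejected"

    @property
    def score(self) -> float:
        return self.csm.score

    @property
    def is_decoy(self) -> bool:
        return self.csm.is_decoy

    @property
    def link_class(self) -> str:
        return self.csm.link_class


def validate_all(csms: list[CSM], config: FdrConfig = FdrConfig(),
                 ) -> tuple[list[_LabeledCSM], list[Crosslink]]:
    """Estimate FDR independently at the CSM and the cross-link level.

    Decoy items are labeled like targets but are never reported as
    identifications by the exporters.
    """
    wrapped = [_LabeledCSM(c) for c in csms]
    if config.separate_intra_inter:
        labeled_csms = separated_fdr(wrapped, config.csm_thresholds,
                                     config.pseudocount)
    else:
        labeled_csms, _ = estimate_fdr(wrapped, config.csm_thresholds,
                                       config.pseudocount)
    links = group_crosslinks(csms)
    if config.separate_intra_inter:
        labeled_links = separated_fdr(links, config.crosslink_thresholds,
                                      config.pseudocount)
    else:
        labeled_links, _ = estimate_fdr(links, config.crosslink_thresholds,
                                        config.pseudocount)
    return labeled_csms, labeled_links
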
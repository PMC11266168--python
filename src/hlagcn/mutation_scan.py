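"""Substitution scanning: 9-mer windows, wild-type vs mutant affinity
across an HLA panel, and the paired t-test on the affinity change.

For a single amino-acid substitution in a protein, every 9-mer window
covering the mutated position (up to nine; fewer near the ends) is scored
against each HLA of a panel.  Per HLA the window scores are combined (max
by default, the usual epitope-scan convention, mean optionally) into one
wild-type and one mutant score, and the per-HLA paired differences are
tested with a two-sided paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ContractError
from .gcn_model import AffinityModel, predict
from .peptide_graph import build_peptide_graph

WINDOW = 9


@dataclass(frozen=True)
class SubstitutionEvent:
    protein_seq: str
    position: int  # 1-based
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if not (1 <= self.position <= len(self.protein_seq)):
            raise ContractError("position outside protein sequence")
        if self.protein_seq[self.position - 1] != self.ref_aa:
            raise ContractError(
                f"reference mismatch: sequence has "
                f"{self.protein_seq[self.position - 1]!r} at {self.position}, "
                f"event says {self.ref_aa!r}"
            )
        if self.alt_aa == self.ref_aa:
            raise ContractError("synonymous event: alt_aa equals ref_aa")

    def mutant_seq(self) -> str:
        i = self.position - 1
        return self.protein_seq[:i] + self.alt_aa + self.protein_seq[i + 1:]


@dataclass
class DeltaAffinityResult:
    per_hla: list[tuple[str, float, float, float]]  # (id, wt, mut, delta)
    t_statistic: float
    p_value: float
    combine: str


def extract_9mers(ev: SubstitutionEvent) -> list[tuple[str, str]]:
    """All (wild-type, mutant) 9-mer window pairs covering the position."""
    L = len(ev.protein_seq)
    if L < WINDOW:
        raise ContractError(f"protein length {L} shorter than the {WINDOW}-mer window")
    mut = ev.mutant_seq()
    pos0 = ev.position - 1
    first = max(0, pos0 - (WINDOW - 1))
    last = min(L - WINDOW, pos0)
    pairs = []
    for start in range(first, last + 1):
        pairs.append((ev.protein_seq[start: start + WINDOW], mut[start: start + WINDOW]))
    return pairs


def delta_affinity(
    model: AffinityModel,
    panel: dict[str, "object"],
    ev: SubstitutionEvent,
    combine: str = "max",
) -> DeltaAffinityResult:
    """Score wild-type vs mutant across the HLA panel and test the change.

    ``panel`` maps HLA id to its ResidueGraph.  Window scores per HLA are
    combined by ``combine`` ("max" or "mean"); the per-HLA (wt, mut) pairs
    feed a two-sided paired t-test.
    """
    if not panel:
        raise ContractError("empty HLA panel")
    if len(panel) < 2:
        raise ContractError("paired t-test needs a panel of at least 2 HLAs")
    if combine not in ("max", "mean"):
        raise ContractError(f"unknown combine mode {combine!r}")
    reduce = np.max if combine == "max" else np.mean

    pairs = extract_9mers(ev)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt_graphs = [build_peptide_graph(w) for w, _ in pairs]
        mut_graphs = [build_peptide_graph(m) for _, m in pairs]

    per_hla = []
    for hla_id in sorted(panel):
        graph = panel[hla_id]
        wt = float(reduce([predict(model, graph, g) for g in wt_graphs]))
        mu = float(reduce([predict(model, graph, g) for g in mut_graphs]))
        per_hla.append((hla_id, wt, mu, mu - wt))

    wt_scores = np.array([row[1] for row in per_hla])
    mut_scores = np.array([row[2] for row in per_hla])
    if np.allclose(wt_scores, mut_scores):
        t_stat, p_val = float("nan"), float("nan")
    else:
        t_stat, p_val = stats.ttest_rel(mut_scores, wt_scores)
        t_stat, p_val = float(t_stat), float(p_val)
    return DeltaAffinityResult(
        per_hla=per_hla, t_statistic=t_stat, p_value=p_val, combine=combine
    )
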
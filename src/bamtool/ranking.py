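"""Candidate scoring, average-rank tie handling, and benchmark metrics.

Candidates are ranked by the likelihood that their reaction-center atom
is a site of metabolism.  The scorer is a pluggable contract: any object
mapping a molecule to one likelihood per heavy atom can drive the
ranking, so a learned graph model can replace the built-in frequency
heuristic without touching the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .chem import Molecule, inchikey14_match, tanimoto
from .errors import InputError
from .generate import Candidate, generate_candidates
from .network import AnchorSuspectPair
from .rules import RuleTable, atom_code

log = logging.getLogger(__name__)

TANIMOTO_BINS = ((0.0, 0.5), (0.5, 0.7), (0.7, 0.9), (0.9, 1.0))


@dataclass(frozen=True)
class SiteScorer:
    """Per-heavy-atom site-of-metabolism likelihoods for a molecule."""

    name: str
    fn: Callable[[Molecule], Sequence[float]] = field(compare=False)

    def score_atoms(self, molecule: Molecule) -> Tuple[float, ...]:
        values = tuple(float(v) for v in self.fn(molecule))
        n_heavy = molecule.to_mol().GetNumAtoms()
        if len(values) != n_heavy:
            raise ValueError(
                f"scorer {self.name!r} returned {len(values)} values for "
                f"{n_heavy} heavy atoms"
            )
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ValueError(f"scorer {self.name!r} returned values outside [0, 1]")
        return values


def score_candidates(
    anchor: Molecule, candidates: Sequence[Candidate], scorer: SiteScorer
) -> List[Candidate]:
    """Assign each candidate the likelihood of its reaction-center atom.

    A candidate holding several provenances (same derivative reachable at
    several sites) takes the maximum likelihood over those sites.
    """
    if not candidates:
        return []
    likelihoods = scorer.score_atoms(anchor)
    scored = []
    for cand in candidates:
        sites = [p.site_atom for p in cand.all_provenances]
        for s in sites:
            if not 0 <= s < len(likelihoods):
                raise InputError(
                    f"candidate {cand.derivative.inchikey14}: site index {s} "
                    f"out of range for anchor with {len(likelihoods)} heavy atoms"
                )
        scored.append(replace(cand, score=max(likelihoods[s] for s in sites)))
    return scored


def rank_candidates(candidates: Sequence[Candidate]) -> List[Candidate]:
    """Order candidates by descending score and assign average ranks.

    A block of t candidates tied over positions p..p+t-1 all receive rank
    (sum of those positions)/t, so ranks may be fractional; the assigned
    ranks always sum to n(n+1)/2.  Within a tie block display order is
    lexicographic by InChIKey.
    """
    if not candidates:
        return []
    for cand in candidates:
        if math.isnan(cand.score):
            raise InputError("all candidate scores must be populated before ranking")
    ordered = sorted(candidates, key=lambda c: (-c.score, c.derivative.inchikey))
    scores = np.array([c.score for c in ordered])
    ranks = rankdata(-scores, method="average")
    return [replace(c, rank=float(r)) for c, r in zip(ordered, ranks)]


@dataclass(frozen=True)
class EvaluationReport:
    """Recall and ranking metrics over a benchmark of anchor–suspect pairs."""

    n_queries: int
    n_with_derivatives: int
    n_correct: int
    recall: float
    rank_at_k: Dict[int, float]
    average_rank: Optional[float]
    recall_by_tanimoto: Dict[str, Optional[float]]
    mean_candidates_per_query: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "n_with_derivatives": self.n_with_derivatives,
            "n_correct": self.n_correct,
            "recall": self.recall,
            "rank_at_k": {str(k): v for k, v in sorted(self.rank_at_k.items())},
            "average_rank": self.average_rank,
            "recall_by_tanimoto": dict(self.recall_by_tanimoto),
            "mean_candidates_per_query": self.mean_candidates_per_query,
        }

    def to_tsv(self) -> str:
        rows = [("metric", "value")]
        d = self.to_dict()
        for key in ("n_queries", "n_with_derivatives", "n_correct", "recall",
                    "average_rank", "mean_candidates_per_query"):
            rows.append((key, str(d[key])))
        for k, v in d["rank_at_k"].items():
            rows.append((f"rank_at_{k}", str(v)))
        for label, v in d["recall_by_tanimoto"].items():
            rows.append((f"recall_tanimoto_{label}", str(v)))
        return "\n".join("\t".join(r) for r in rows) + "\n"


def evaluate(
    benchmark: Sequence[AnchorSuspectPair],
    table: RuleTable,
    scorer: SiteScorer,
) -> EvaluationReport:
    """Run generate → score → rank per pair and aggregate the metrics.

    Correctness is a first-InChIKey-block match between a candidate and
    the pair's ground-truth suspect; recall is computed over queries that
    produced at least one derivative; rank metrics over correct queries.
    """
    if not benchmark:
        raise InputError("benchmark is empty")
    n_queries = n_with = n_correct = 0
    true_ranks: List[float] = []
    n_candidates: List[int] = []
    bin_totals = {b: 0 for b in TANIMOTO_BINS}
    bin_correct = {b: 0 for b in TANIMOTO_BINS}
    for pair in benchmark:
        truth = pair.suspect.annotation
        if truth is None:
            raise InputError(f"pair {pair.id}: ground-truth suspect annotation missing")
        anchor = pair.anchor.annotation
        n_queries += 1
        candidates = generate_candidates(pair, table)
        if not candidates:
            continue
        n_with += 1
        n_candidates.append(len(candidates))
        ranked = rank_candidates(score_candidates(anchor, candidates, scorer))
        sim = tanimoto(anchor, truth)
        tbin = _tanimoto_bin(sim)
        bin_totals[tbin] += 1
        hits = [c for c in ranked if inchikey14_match(c.derivative, truth)]
        if hits:
            n_correct += 1
            bin_correct[tbin] += 1
            true_ranks.append(min(c.rank for c in hits))
    recall = n_correct / n_with if n_with else 0.0
    rank_at_k = {
        k: (sum(1 for r in true_ranks if r <= k) / len(true_ranks)) if true_ranks else 0.0
        for k in range(1, 6)
    }
    return EvaluationReport(
        n_queries=n_queries,
        n_with_derivatives=n_with,
        n_correct=n_correct,
        recall=recall,
        rank_at_k=rank_at_k,
        average_rank=(sum(true_ranks) / len(true_ranks)) if true_ranks else None,
        recall_by_tanimoto={
            f"{lo:g}-{hi:g}": (bin_correct[(lo, hi)] / bin_totals[(lo, hi)]
                               if bin_totals[(lo, hi)] else None)
            for lo, hi in TANIMOTO_BINS
        },
        mean_candidates_per_query=(
            sum(n_candidates) / len(n_candidates) if n_candidates else None
        ),
    )


def _tanimoto_bin(sim: float) -> Tuple[float, float]:
    for lo, hi in TANIMOTO_BINS:
        if lo <= sim < hi:
            return (lo, hi)
    return TANIMOTO_BINS[-1]


def default_site_scorer(table: RuleTable) -> SiteScorer:
    """Frequency heuristic: atoms whose type occurs often as a reaction
    center in the rule table score higher (Laplace-smoothed); with an
    empty table every atom scores 0.5.
    """
    counts: Dict[str, int] = {}
    for rule in table.rules.values():
        counts[rule.center] = counts.get(rule.center, 0) + 1
    max_count = max(counts.values(), default=0)

    def fn(molecule: Molecule) -> List[float]:
        mol = molecule.to_mol()
        return [
            (1 + counts.get(atom_code(mol, i), 0)) / (2 + max_count)
            for i in range(mol.GetNumAtoms())
        ]

    return SiteScorer(name="default", fn=fn)


def uniform_site_scorer(value: float = 0.5) -> SiteScorer:
    """Every atom equally likely; useful as a degenerate baseline."""
    if not 0.0 <= value <= 1.0:
        raise InputError("uniform scorer value must be in [0, 1]")

    def fn(molecule: Molecule) -> List[float]:
        return [value] * molecule.to_mol().GetNumAtoms()

    return SiteScorer(name="uniform", fn=fn)
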
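import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bamtool import chem
from bamtool.errors import InputError
from bamtool.generate import Candidate
from bamtool.ranking import (
    SiteScorer,
    default_site_scorer,
    evaluate,
    rank_candidates,
    score_candidates,
    uniform_site_scorer,
)
from bamtool.rules import RuleTable


def _candidates(scores, smiles=None):
    smiles = smiles or ["C" * (i + 1) for i in range(len(scores))]
    return [
        Candidate(
            derivative=chem.canonicalize(s), rule_id=f"r{i}", site_atom=0, score=v
        )
        for i, (s, v) in enumerate(zip(smiles, scores))
    ]


class TestRankCandidates:
    def test_three_way_tie_at_top_gets_rank_two(self):
        ranked = rank_candidates(_candidates([0.7, 0.7, 0.7]))
        assert [c.rank for c in ranked] == [2.0, 2.0, 2.0]

    def test_distinct_scores_rank_one_to_n(self):
        ranked = rank_candidates(_candidates([0.9, 0.1, 0.5, 0.3]))
        assert [c.rank for c in ranked] == [1.0, 2.0, 3.0, 4.0]
        assert [c.score for c in ranked] == [0.9, 0.5, 0.3, 0.1]

    def test_leader_then_tied_pair(self):
        ranked = rank_candidates(_candidates([0.9, 0.4, 0.4]))
        assert ranked[0].rank == 1.0
        assert ranked[1].rank == ranked[2].rank == 2.5

    def test_rank_sum_invariant(self):
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(1, 12)
            scores = [rng.choice([0.1, 0.3, 0.5, 0.9]) for _ in range(n)]
            ranked = rank_candidates(_candidates(scores))
            assert sum(c.rank for c in ranked) == pytest.approx(n * (n + 1) / 2)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=1, max_size=10))
    def test_rank_sum_invariant_property(self, scores):
        ranked = rank_candidates(_candidates(scores))
        assert sum(c.rank for c in ranked) == pytest.approx(len(scores) * (len(scores) + 1) / 2)

    def test_permutation_invariance_of_assigned_ranks(self):
        cands = _candidates([0.9, 0.4, 0.4, 0.1])
        by_key = {c.derivative.inchikey14: c.rank for c in rank_candidates(cands)}
        shuffled = list(reversed(cands))
        by_key2 = {c.derivative.inchikey14: c.rank for c in rank_candidates(shuffled)}
        assert by_key == by_key2

    def test_unscored_candidates_rejected(self):
        cands = [
            Candidate(derivative=chem.canonicalize("CC"), rule_id="r", site_atom=0)
        ]
        with pytest.raises(InputError):
            rank_candidates(cands)

    def test_empty_ok(self):
        assert rank_candidates([]) == []


class TestScoreCandidates:
    def _scorer(self, values):
        return SiteScorer(name="fixed", fn=lambda mol: values[: mol.to_mol().GetNumAtoms()])

    def test_equal_likelihoods_equal_scores(self):
        anchor = chem.canonicalize("CCO")
        cands = [
            Candidate(derivative=chem.canonicalize("CCCO"), rule_id="r", site_atom=i)
            for i in range(3)
        ]
        scored = score_candidates(anchor, cands, uniform_site_scorer(0.5))
        assert all(c.score == 0.5 for c in scored)

    def test_multiple_provenances_take_maximum(self):
        from bamtool.generate import Provenance

        anchor = chem.canonicalize("CCO")
        cand = Candidate(
            derivative=chem.canonicalize("CCCO"), rule_id="r", site_atom=0,
            provenances=(Provenance("r", 2),),
        )
        scored = score_candidates(anchor, [cand], self._scorer([0.3, 0.1, 0.7]))
        assert scored[0].score == 0.7

    def test_site_out_of_range_raises(self):
        anchor = chem.canonicalize("CCO")
        cand = Candidate(derivative=chem.canonicalize("CCCO"), rule_id="r", site_atom=11)
        with pytest.raises(InputError):
            score_candidates(anchor, [cand], uniform_site_scorer())

    def test_scorer_output_validated(self):
        anchor = chem.canonicalize("CCO")
        bad = SiteScorer(name="bad", fn=lambda mol: [2.0, 2.0, 2.0])
        cand = Candidate(derivative=chem.canonicalize("CCCO"), rule_id="r", site_atom=0)
        with pytest.raises(ValueError):
            score_candidates(anchor, [cand], bad)


class TestDefaultScorer:
    def test_empty_table_uniform(self):
        scorer = default_site_scorer(RuleTable())
        values = scorer.score_atoms(chem.canonicalize("CCO"))
        assert len(set(values)) == 1

    def test_center_matching_atom_holds_maximum(self, cyclohexanol, cyclohexanone):
        from bamtool.rules import build_rule_table

        table = build_rule_table([(cyclohexanol, cyclohexanone)])
        scorer = default_site_scorer(table)
        values = scorer.score_atoms(cyclohexanol)
        mol = cyclohexanol.to_mol()
        carbinol = next(
            a.GetIdx() for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and any(n.GetSymbol() == "O" for n in a.GetNeighbors())
        )
        assert values[carbinol] == max(values)
        assert values[carbinol] > min(values)

    def test_deterministic(self, benchmark10_table, catalogue):
        scorer = default_site_scorer(benchmark10_table)
        for mol in catalogue[:5]:
            assert scorer.score_atoms(mol) == scorer.score_atoms(mol)


class TestEvaluate:
    def test_empty_benchmark_raises(self, benchmark10_table):
        with pytest.raises(InputError):
            evaluate([], benchmark10_table, uniform_site_scorer())

    def test_oracle_scorer_full_marks(self, benchmark10, benchmark10_table):
        report = evaluate(benchmark10.pairs, benchmark10_table, benchmark10.oracle_scorer())
        assert report.recall == 1.0
        assert report.rank_at_k[1] == 1.0
        assert report.average_rank == 1.0
        assert report.n_queries == report.n_with_derivatives == report.n_correct == 10

    def test_rank_at_k_nondecreasing(self, benchmark10, benchmark10_table):
        report = evaluate(
            benchmark10.pairs, benchmark10_table, default_site_scorer(benchmark10_table)
        )
        ks = sorted(report.rank_at_k)
        values = [report.rank_at_k[k] for k in ks]
        assert values == sorted(values)
        assert report.average_rank is None or report.average_rank >= 1.0

    def test_recall_one_of_four(self):
        from bamtool.rules import build_rule_table
        from bamtool.spectra import Spectrum
        from bamtool.network import AnchorSuspectPair

        phenol = chem.canonicalize("Oc1ccccc1")
        anisole = chem.canonicalize("COc1ccccc1")
        table = build_rule_table([(phenol, anisole)])  # O-methylation only

        def pair(anchor_smiles, suspect_smiles):
            anchor_mol = chem.canonicalize(anchor_smiles)
            suspect_mol = chem.canonicalize(suspect_smiles)
            anchor = Spectrum(
                id=f"a_{anchor_smiles}", peaks=((50.0, 1.0),),
                precursor_mz=anchor_mol.monoisotopic_mass + chem.PROTON_MASS,
                annotation=anchor_mol,
            )
            suspect = Spectrum(
                id=f"s_{suspect_smiles}", peaks=((50.0, 1.0),),
                precursor_mz=suspect_mol.monoisotopic_mass + chem.PROTON_MASS,
                annotation=suspect_mol,
            )
            return AnchorSuspectPair(
                anchor=anchor, suspect=suspect,
                mass_difference=suspect.neutral_mass - anchor.neutral_mass,
                edge_score=0.9,
            )

        # one query whose truth is the O-methyl ether (reachable), three whose
        # truth is a ring-methylated isomer (same mass delta, unreachable)
        pairs = [
            pair("Oc1ccccc1", "COc1ccccc1"),
            pair("Cc1ccc(O)cc1", "Cc1ccc(O)c(C)c1"),
            pair("Oc1cccc(O)c1", "Cc1cc(O)ccc1O"),
            pair("CCc1ccc(O)cc1", "CCc1ccc(O)c(C)c1"),
        ]
        report = evaluate(pairs, table, uniform_site_scorer())
        assert report.n_with_derivatives == 4
        assert report.n_correct == 1
        assert report.recall == 0.25

    def test_recall_quarter_arithmetic(self, benchmark10):
        # withhold nothing, then cripple the table down to one family so
        # only some queries stay solvable; recall is the solvable share
        table = benchmark10.rule_table()
        report = evaluate(benchmark10.pairs, table, uniform_site_scorer())
        assert report.recall == pytest.approx(report.n_correct / report.n_with_derivatives)
        assert 0.0 <= report.recall <= 1.0
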
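import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bamtool import chem
from bamtool.errors import InputError
from bamtool.network import (
    AnchorSuspectPair,
    NetworkEdge,
    build_network,
    derive_pairs,
    modified_cosine,
)
from bamtool.spectra import Spectrum

from .oracles import brute_force_modified_cosine

TOL = 0.02


def spectrum(id, precursor, peaks):
    return Spectrum(id=id, precursor_mz=precursor, peaks=tuple(peaks))


def random_spectrum(rng, id, max_peaks=8):
    n = rng.randint(1, max_peaks)
    mzs = sorted(rng.uniform(50, 500) for _ in range(n))
    peaks = [(mz, rng.uniform(0.05, 1.0)) for mz in mzs]
    return spectrum(id, rng.uniform(100, 600), peaks)


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        s = spectrum("s", 300.0, [(100.0, 1.0), (150.0, 0.5), (200.0, 2.0)])
        score, n = modified_cosine(s, s, TOL)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert n == 3

    def test_global_shift_matches_via_shifted_peaks(self):
        a = spectrum("a", 300.0, [(100.0, 1.0), (200.0, 1.0)])
        b = spectrum("b", 350.0, [(150.0, 1.0), (250.0, 1.0)])
        score, n = modified_cosine(a, b, TOL)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert n == 2

    def test_no_match_gives_zero(self):
        a = spectrum("a", 300.0, [(100.0, 1.0)])
        b = spectrum("b", 300.0, [(170.0, 1.0)])
        score, n = modified_cosine(a, b, TOL)
        assert score == 0.0 and n == 0

    def test_nonpositive_tolerance_raises(self):
        s = spectrum("s", 300.0, [(100.0, 1.0)])
        with pytest.raises(InputError):
            modified_cosine(s, s, 0.0)

    def test_matches_brute_force_oracle_on_random_spectra(self):
        rng = random.Random(11)
        for k in range(60):
            a = random_spectrum(rng, f"a{k}")
            b = random_spectrum(rng, f"b{k}")
            expected = brute_force_modified_cosine(a, b, TOL)
            got, _ = modified_cosine(a, b, TOL)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_overlapping_direct_and_shifted_options_resolved_optimally(self):
        # peak can match directly or shifted; assignment must pick the best
        a = spectrum("a", 300.0, [(100.0, 1.0), (110.0, 0.2)])
        b = spectrum("b", 310.0, [(100.0, 0.2), (110.0, 1.0)])
        expected = brute_force_modified_cosine(a, b, TOL)
        got, _ = modified_cosine(a, b, TOL)
        assert got == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = random.Random(seed)
        a = random_spectrum(rng, "a")
        b = random_spectrum(rng, "b")
        ab, _ = modified_cosine(a, b, TOL)
        ba, _ = modified_cosine(b, a, TOL)
        assert ab == pytest.approx(ba, abs=1e-9)


class TestBuildNetwork:
    def _triple(self):
        base = [(100.0, 1.0), (150.0, 0.8), (200.0, 0.6)]
        s1 = spectrum("s1", 300.0, base)
        s2 = spectrum("s2", 300.0, base)  # identical to s1 -> score 1
        s3 = spectrum("s3", 300.0, [(100.0, 1.0), (410.0, 1.0)])
        return [s1, s2, s3]

    def test_threshold_strictly_above(self):
        spectra = self._triple()
        edges = build_network(spectra, threshold=0.8, fragment_tol=TOL)
        keys = {(e.spectrum_id_a, e.spectrum_id_b) for e in edges}
        assert ("s1", "s2") in keys
        for e in edges:
            assert e.score > 0.8

    def test_all_below_threshold_empty(self):
        a = spectrum("a", 300.0, [(100.0, 1.0)])
        b = spectrum("b", 300.0, [(170.0, 1.0)])
        assert build_network([a, b], 0.8, TOL) == []

    def test_fewer_than_two_spectra(self):
        a = spectrum("a", 300.0, [(100.0, 1.0)])
        assert build_network([a], 0.8, TOL) == []

    def test_duplicate_ids_emitted_once(self):
        spectra = self._triple()
        edges = build_network(spectra + spectra, 0.8, TOL)
        pairs = [(e.spectrum_id_a, e.spectrum_id_b) for e in edges]
        assert len(pairs) == len(set(pairs))

    def test_order_invariance(self):
        spectra = self._triple()
        e1 = build_network(spectra, 0.8, TOL)
        e2 = build_network(list(reversed(spectra)), 0.8, TOL)
        assert e1 == e2

    def test_bad_threshold_raises(self):
        with pytest.raises(InputError):
            build_network(self._triple(), threshold=0.0)


class TestDerivePairs:
    def _spectra(self, annotate_a=True, annotate_b=True, same_structure=False):
        mol_a = chem.canonicalize("Oc1ccccc1")
        mol_b = mol_a if same_structure else chem.canonicalize("COc1ccccc1")
        a = Spectrum(id="a", precursor_mz=95.049, peaks=((50.0, 1.0),),
                     annotation=mol_a if annotate_a else None)
        b = Spectrum(id="b", precursor_mz=109.065, peaks=((50.0, 1.0),),
                     annotation=mol_b if annotate_b else None)
        return {"a": a, "b": b}

    def _edge(self):
        return [NetworkEdge("a", "b", 0.9, 3)]

    def test_both_annotated_distinct_yields_two_directed_pairs(self):
        pairs = derive_pairs(self._edge(), self._spectra())
        assert len(pairs) == 2
        assert {p.anchor.id for p in pairs} == {"a", "b"}

    def test_mass_difference_antisymmetric(self):
        p1, p2 = derive_pairs(self._edge(), self._spectra())
        assert p1.mass_difference == pytest.approx(-p2.mass_difference, abs=1e-9)

    def test_one_annotated_yields_one_pair(self):
        pairs = derive_pairs(self._edge(), self._spectra(annotate_b=False))
        assert len(pairs) == 1
        assert pairs[0].anchor.id == "a"
        assert pairs[0].suspect.id == "b"

    def test_same_first_block_yields_no_pairs(self):
        spectra = self._spectra(same_structure=True)
        assert derive_pairs(self._edge(), spectra) == []

    def test_unannotated_edge_yields_no_pairs(self):
        spectra = self._spectra(annotate_a=False, annotate_b=False)
        assert derive_pairs(self._edge(), spectra) == []

    def test_dangling_id_raises(self):
        with pytest.raises(InputError):
            derive_pairs([NetworkEdge("a", "zzz", 0.9, 3)], self._spectra())

    def test_pair_mass_consistency_enforced(self):
        spectra = self._spectra()
        with pytest.raises(ValueError):
            AnchorSuspectPair(
                anchor=spectra["a"], suspect=spectra["b"],
                mass_difference=99.0, edge_score=0.9,
            )
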
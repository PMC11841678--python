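"""Modified cosine similarity, molecular-network construction, and
anchor–suspect pair derivation.

The modified cosine aligns two peak lists allowing each peak of one
spectrum to pair with a peak of the other either directly (m/z within
tolerance) or shifted by the precursor neutral-mass difference.  The
one-to-one pairing is solved exactly as a maximum-weight assignment
(intensity-product weights), not greedily, so tied and overlapping
candidate pairs cannot change the score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import Molecule, inchikey14_match
from .errors import InputError
from .spectra import Spectrum

log = logging.getLogger(__name__)

DEFAULT_FRAGMENT_TOL = 0.02
DEFAULT_THRESHOLD = 0.8


@dataclass(frozen=True)
class NetworkEdge:
    """Undirected network edge between two spectra above threshold."""

    spectrum_id_a: str
    spectrum_id_b: str
    score: float
    n_matched_peaks: int


@dataclass(frozen=True)
class AnchorSuspectPair:
    """Directed pair: annotated anchor spectrum and suspect spectrum.

    ``mass_difference`` is the suspect-minus-anchor neutral precursor
    mass difference in Da; the suspect's annotation, when present, is
    ground truth hidden from candidate generation.
    """

    anchor: Spectrum
    suspect: Spectrum
    mass_difference: float
    edge_score: float

    def __post_init__(self) -> None:
        if self.anchor.annotation is None:
            raise ValueError("anchor spectrum must be annotated")
        expected = self.suspect.neutral_mass - self.anchor.neutral_mass
        if abs(expected - self.mass_difference) > 1e-4:
            raise ValueError(
                "mass_difference inconsistent with precursor masses: "
                f"{self.mass_difference} vs {expected}"
            )

    @property
    def id(self) -> str:
        return f"{self.anchor.id}->{self.suspect.id}"


def _normalized_intensities(spectrum: Spectrum, sqrt_transform: bool) -> np.ndarray:
    x = np.array([i for _, i in spectrum.peaks], dtype=float)
    if sqrt_transform:
        x = np.sqrt(x)
    norm = np.linalg.norm(x)
    return x / norm if norm > 0 else x


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tol: float = DEFAULT_FRAGMENT_TOL,
    sqrt_transform: bool = True,
) -> Tuple[float, int]:
    """Modified cosine score and matched-peak count between two spectra.

    Peaks pair directly (|mz_a - mz_b| <= tol) or shifted by the neutral
    precursor mass difference; each peak is used at most once and the
    total matched intensity product is maximized exactly.
    """
    if fragment_tol <= 0:
        raise InputError(f"fragment tolerance must be positive, got {fragment_tol}")
    delta = b.neutral_mass - a.neutral_mass
    mz_a = np.array([mz for mz, _ in a.peaks])
    mz_b = np.array([mz for mz, _ in b.peaks])
    x = _normalized_intensities(a, sqrt_transform)
    y = _normalized_intensities(b, sqrt_transform)

    diff = mz_b[None, :] - mz_a[:, None]
    eligible = (np.abs(diff) <= fragment_tol) | (np.abs(diff - delta) <= fragment_tol)
    if not eligible.any():
        return 0.0, 0
    weights = np.where(eligible, x[:, None] * y[None, :], 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    used = eligible[rows, cols]
    score = float(weights[rows, cols][used].sum())
    return score, int(used.sum())


def build_network(
    spectra: Sequence[Spectrum],
    threshold: float = DEFAULT_THRESHOLD,
    fragment_tol: float = DEFAULT_FRAGMENT_TOL,
) -> List[NetworkEdge]:
    """All-vs-all network: edges where modified cosine is strictly above threshold."""
    if not 0 < threshold <= 1:
        raise InputError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(spectra, key=lambda s: s.id)
    edges: List[NetworkEdge] = []
    seen_pairs = set()
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if a.id == b.id:
                continue
            key = (a.id, b.id)
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            score, n_matched = modified_cosine(a, b, fragment_tol)
            if score > threshold:
                edges.append(NetworkEdge(a.id, b.id, score, n_matched))
    return edges


def derive_pairs(
    edges: Iterable[NetworkEdge], spectra: Dict[str, Spectrum]
) -> List[AnchorSuspectPair]:
    """Turn network edges into directed anchor–suspect pairs.

    Both endpoints annotated with distinct 2D structures -> two directed
    pairs (biotransformations are reversible); exactly one annotated ->
    one pair; same first InChIKey block or no annotations -> none.
    """
    pairs: List[AnchorSuspectPair] = []
    for edge in edges:
        try:
            a = spectra[edge.spectrum_id_a]
            b = spectra[edge.spectrum_id_b]
        except KeyError as exc:
            raise InputError(f"edge references unknown spectrum id {exc}") from exc
        annotated = [s for s in (a, b) if s.annotation is not None]
        if len(annotated) == 0:
            continue
        if len(annotated) == 2 and inchikey14_match(a.annotation, b.annotation):
            continue  # not structurally unique: no suspect to explain
        for anchor, suspect in ((a, b), (b, a)):
            if anchor.annotation is None:
                continue
            pairs.append(
                AnchorSuspectPair(
                    anchor=anchor,
                    suspect=suspect,
                    mass_difference=suspect.neutral_mass - anchor.neutral_mass,
                    edge_score=edge.score,
                )
            )
    return pairs


def write_edges_tsv(edges: Iterable[NetworkEdge], path) -> None:
    lines = ["spectrum_id_a\tspectrum_id_b\tscore\tn_matched_peaks"]
    for e in edges:
        lines.append(
            f"{e.spectrum_id_a}\t{e.spectrum_id_b}\t{e.score:.6f}\t{e.n_matched_peaks}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(edges: Iterable[NetworkEdge], spectra: Sequence[Spectrum], path) -> None:
    """Export the network as GraphML (node attribute: annotated flag)."""
    import networkx as nx

    g = nx.Graph()
    for s in spectra:
        g.add_node(s.id, annotated=s.annotation is not None)
    for e in edges:
        g.add_edge(
            e.spectrum_id_a, e.spectrum_id_b,
            score=e.score, n_matched_peaks=e.n_matched_peaks,
        )
    nx.write_graphml(g, path)
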
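"""Independent reference implementations used only by the test suite.

These deliberately avoid the code paths they check: the mass oracle sums
a frozen element-mass table; the modified-cosine oracle enumerates every
one-to-one peak pairing by brute force.
"""

import math

# frozen monoisotopic masses (most abundant isotope), Da
ELEMENT_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

PROTON = 1.00728


def mass_by_atom_summation(rdmol) -> float:
    """Monoisotopic mass as a plain per-atom sum over a frozen mass table."""
    total = 0.0
    for atom in rdmol.GetAtoms():
        total += ELEMENT_MASS[atom.GetSymbol()]
        total += atom.GetTotalNumHs() * ELEMENT_MASS["H"]
    return total


def _unit(intensities, sqrt_transform=True):
    vals = [math.sqrt(v) if sqrt_transform else v for v in intensities]
    norm = math.sqrt(sum(v * v for v in vals))
    return [v / norm for v in vals] if norm else vals


def brute_force_modified_cosine(a, b, tol):
    """Maximum cosine over all one-to-one (direct or shifted) peak pairings."""
    delta = b.neutral_mass - a.neutral_mass
    x = _unit([i for _, i in a.peaks])
    y = _unit([i for _, i in b.peaks])
    eligible = []
    for i, (mza, _) in enumerate(a.peaks):
        for j, (mzb, _) in enumerate(b.peaks):
            if abs(mzb - mza) <= tol or abs(mzb - mza - delta) <= tol:
                eligible.append((i, j, x[i] * y[j]))

    best = 0.0

    def recurse(k, used_a, used_b, acc):
        nonlocal best
        remaining = sum(w for (i, j, w) in eligible[k:])
        if acc + remaining <= best:
            return
        if k == len(eligible):
            best = max(best, acc)
            return
        i, j, w = eligible[k]
        if i not in used_a and j not in used_b:
            recurse(k + 1, used_a | {i}, used_b | {j}, acc + w)
        recurse(k + 1, used_a, used_b, acc)

    recurse(0, frozenset(), frozenset(), 0.0)
    return best
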
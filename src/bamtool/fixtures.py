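"""Synthetic, fully ground-truthed data for exercising the pipeline.

Everything here is generated in-process from a built-in scaffold
catalogue, so tests and demos never download anything:

* reaction pairs related by a single named transformation (the stand-in
  for a curated reaction database),
* deterministic pseudo-fragmentation spectra whose shared and shifted
  peaks mirror shared and modified substructures, and
* benchmarks of anchor–suspect pairs with known true structures and
  known reaction-center atoms.
"""

from __future__ import annotations

import hashlib
import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from rdkit import Chem

from . import chem
from .chem import Molecule
from .network import AnchorSuspectPair, modified_cosine
from .ranking import SiteScorer
from .rules import FragmentOp, RuleTable, StructuralEdit, apply_edit, build_rule_table
from .spectra import Spectrum, write_mgf

log = logging.getLogger(__name__)

_PT = Chem.GetPeriodicTable()

#: Built-in drug-like / natural-product-like scaffolds (validated in tests).
SCAFFOLD_SMILES: Tuple[str, ...] = (
    "CC(=O)Nc1ccc(O)cc1",                 # acetaminophen
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",         # ibuprofen
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",       # naproxen
    "OC(=O)c1ccccc1O",                    # salicylic acid
    "CC(=O)Oc1ccccc1C(=O)O",              # aspirin
    "COc1ccc(C=O)cc1O",                   # vanillin
    "NC(Cc1ccc(O)cc1)C(=O)O",             # tyrosine
    "NC(Cc1ccccc1)C(=O)O",                # phenylalanine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",        # tryptophan
    "NCCc1c[nH]c2ccc(O)cc12",             # serotonin
    "NCCc1ccc(O)c(O)c1",                  # dopamine
    "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O",  # testosterone skeleton
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",     # estradiol skeleton
    "CC(C)C1CCC(C)CC1O",                  # menthol
    "CC1(C)C2CCC1(C)C(=O)C2",             # camphor skeleton
    "COc1cc(C(=O)O)ccc1O",                # vanillic acid
    "COc1cc(C=CC(=O)O)ccc1O",             # ferulic acid (2D)
    "CCOC(=O)c1ccc(N)cc1",                # benzocaine
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",         # lidocaine
    "OC(=O)C=Cc1ccccc1",                  # cinnamic acid
    "Nc1ccc(C(=O)O)cc1",                  # 4-aminobenzoic acid
    "Oc1cccc(O)c1",                       # resorcinol
    "COc1ccccc1O",                        # guaiacol
    "CCCCCCCC(=O)O",                      # octanoic acid
    "CC(C)=CCCC(C)=CCO",                  # geraniol (2D)
    "OCC1OC(O)C(O)C(O)C1O",               # hexose
)


# ---------------------------------------------------------------------------
# transformation families


@dataclass(frozen=True)
class TransformationFamily:
    """A named single-step biotransformation with its monoisotopic delta."""

    name: str
    mass_delta: float
    edit: StructuralEdit
    site_finder: Callable[[Chem.Mol], List[int]] = field(compare=False)

    def legal_sites(self, mol: Chem.Mol) -> List[int]:
        return self.site_finder(mol)


def _carbons_with_h(mol: Chem.Mol) -> List[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _heteroatoms_with_h(mol: Chem.Mol) -> List[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() in ("O", "N") and a.GetTotalNumHs() >= 1
    ]


def _carbinol_carbons(mol: Chem.Mol) -> List[int]:
    """sp3 C-H carbons bearing a terminal hydroxyl (oxidizable to C=O)."""
    sites = []
    for a in mol.GetAtoms():
        if a.GetSymbol() != "C" or a.GetIsAromatic() or a.GetTotalNumHs() < 1:
            continue
        for nbr in a.GetNeighbors():
            if (
                nbr.GetSymbol() == "O"
                and nbr.GetDegree() == 1
                and nbr.GetTotalNumHs() >= 1
                and mol.GetBondBetweenAtoms(a.GetIdx(), nbr.GetIdx()).GetBondTypeAsDouble() == 1.0
            ):
                sites.append(a.GetIdx())
                break
    return sites


def _methyl_bearers(mol: Chem.Mol) -> List[int]:
    """Atoms carrying a terminal CH3 (demethylatable)."""
    sites = []
    for a in mol.GetAtoms():
        for nbr in a.GetNeighbors():
            if (
                nbr.GetSymbol() == "C"
                and nbr.GetDegree() == 1
                and nbr.GetTotalNumHs() == 3
                and not nbr.GetIsAromatic()
            ):
                sites.append(a.GetIdx())
                break
    return sites


FAMILIES: Tuple[TransformationFamily, ...] = (
    TransformationFamily(
        "hydroxylation", +15.9949,
        StructuralEdit(additions=(FragmentOp("O", 1.0),)), _carbons_with_h,
    ),
    TransformationFamily(
        "methylation", +14.0157,
        StructuralEdit(additions=(FragmentOp("C", 1.0),)), _heteroatoms_with_h,
    ),
    TransformationFamily(
        "dehydrogenation", -2.0157,
        StructuralEdit(removals=(FragmentOp("O", 1.0),), additions=(FragmentOp("O", 2.0),)),
        _carbinol_carbons,
    ),
    TransformationFamily(
        "demethylation", -14.0157,
        StructuralEdit(removals=(FragmentOp("C", 1.0),)), _methyl_bearers,
    ),
    TransformationFamily(
        "acetylation", +42.0106,
        StructuralEdit(additions=(FragmentOp("C(C)=O", 1.0),)), _heteroatoms_with_h,
    ),
)

FAMILY_BY_NAME: Dict[str, TransformationFamily] = {f.name: f for f in FAMILIES}


def apply_family(
    anchor: Molecule, family: TransformationFamily, site: int
) -> Optional[Molecule]:
    """Apply a family's edit at a specific anchor atom; None if illegal."""
    product_mol = apply_edit(anchor.to_mol(), site, family.edit)
    if product_mol is None:
        return None
    try:
        product = chem.from_mol(product_mol)
    except Exception:
        return None
    realized = product.monoisotopic_mass - anchor.monoisotopic_mass
    if abs(realized - family.mass_delta) > 1e-3:
        return None
    if product.inchikey14 == anchor.inchikey14:
        return None
    return product


def make_reaction_pairs(
    families: Sequence[TransformationFamily],
    scaffolds: Sequence[Molecule],
    seed: int,
) -> List[Tuple[Molecule, Molecule]]:
    """One (reactant, product) pair per (scaffold, family) with a legal site.

    The site is chosen at random under ``seed``; scaffolds offering no
    legal site for a family are skipped with a log message.
    """
    rng = random.Random(seed)
    pairs: List[Tuple[Molecule, Molecule]] = []
    for scaffold in scaffolds:
        mol = scaffold.to_mol()
        for family in families:
            sites = family.legal_sites(mol)
            rng.shuffle(sites)
            product = None
            for site in sites:
                product = apply_family(scaffold, family, site)
                if product is not None:
                    break
            if product is None:
                log.info("no legal %s site on %s; skipped", family.name, scaffold.inchikey14)
                continue
            pairs.append((scaffold, product))
    return pairs


# ---------------------------------------------------------------------------
# pseudo-fragmentation spectra


def _hash01(text: str) -> float:
    digest = hashlib.sha256(text.encode()).hexdigest()[:12]
    return int(digest, 16) / float(16 ** 12)


def _fragment_mass(mol: Chem.Mol, atoms: Sequence[int]) -> float:
    """Monoisotopic mass of a bond-cleavage fragment, capped with one H."""
    mass = chem.HYDROGEN_MASS  # cap for the broken bond
    for idx in atoms:
        atom = mol.GetAtomWithIdx(idx)
        mass += _PT.GetMostCommonIsotopeMass(atom.GetAtomicNum())
        mass += atom.GetTotalNumHs() * chem.HYDROGEN_MASS
    return mass


def simulate_spectrum(mol: Molecule, seed: int, spectrum_id: Optional[str] = None) -> Spectrum:
    """Deterministic pseudo-fragmentation spectrum of ``mol``.

    Each acyclic single bond is broken once; both fragments give a peak at
    their proton adduct m/z with an intensity hashed from the fragment's
    canonical form (so identical substructures give identical peaks across
    molecules, and modified substructures shift by the modification mass).
    """
    rdmol = mol.to_mol()
    precursor_mz = mol.monoisotopic_mass + chem.PROTON_MASS
    peaks: Dict[float, float] = {precursor_mz: 1.0}
    for bond in rdmol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        begin, end = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        side_a = _component_without_bond(rdmol, begin, end)
        side_b = sorted(set(range(rdmol.GetNumAtoms())) - set(side_a))
        for comp in (side_a, side_b):
            if not comp:
                continue
            smiles = Chem.MolFragmentToSmiles(rdmol, atomsToUse=comp, canonical=True)
            mz = _fragment_mass(rdmol, comp) + chem.PROTON_MASS
            intensity = 0.25 + 0.75 * _hash01(f"{seed}:{smiles}")
            peaks[mz] = max(peaks.get(mz, 0.0), intensity)
    return Spectrum(
        id=spectrum_id or mol.inchikey14,
        precursor_mz=precursor_mz,
        peaks=tuple(sorted(peaks.items())),
        precursor_charge=1,
        adduct="[M+H]+",
        annotation=mol,
    )


def _component_without_bond(mol: Chem.Mol, start: int, blocked: int) -> List[int]:
    seen = {start}
    stack = [start]
    while stack:
        a = stack.pop()
        for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
            j = nbr.GetIdx()
            if j in seen or {a, j} == {start, blocked}:
                continue
            seen.add(j)
            stack.append(j)
    return sorted(seen)


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class FixtureBenchmark:
    """Ground-truthed anchor–suspect benchmark plus its generating pairs."""

    spectra: List[Spectrum]
    pairs: List[AnchorSuspectPair]
    rule_pairs: List[Tuple[str, Molecule, Molecule]]
    withheld_rule_ids: List[str]
    seed: int
    truth_sites: Dict[str, int]  # anchor InChIKey-14 -> true reaction-center atom
    pair_families: Dict[str, str]  # rule-pair id -> family name

    def rule_table(self, include_withheld: bool = False) -> RuleTable:
        withheld = set() if include_withheld else set(self.withheld_rule_ids)
        kept = [(pid, r, p) for pid, r, p in self.rule_pairs if pid not in withheld]
        return build_rule_table(
            [(r, p) for _, r, p in kept], pair_ids=[pid for pid, _, _ in kept]
        )

    def oracle_scorer(self) -> SiteScorer:
        """Scores 1.0 exactly at each anchor's true reaction-center atom."""
        truth = dict(self.truth_sites)

        def fn(molecule: Molecule) -> List[float]:
            n = molecule.to_mol().GetNumAtoms()
            values = [0.0] * n
            site = truth.get(molecule.inchikey14)
            if site is not None and site < n:
                values[site] = 1.0
            return values

        return SiteScorer(name="oracle", fn=fn)


def scaffold_catalogue() -> List[Molecule]:
    return [chem.canonicalize(s) for s in SCAFFOLD_SMILES]


_DECORATIONS = (
    StructuralEdit(additions=(FragmentOp("C", 1.0),)),
    StructuralEdit(additions=(FragmentOp("F", 1.0),)),
    StructuralEdit(additions=(FragmentOp("CC", 1.0),)),
)


def _distinct_anchors(n: int, rng: random.Random) -> List[Molecule]:
    """Up to ``n`` structurally distinct anchors: the catalogue, extended by
    decorating scaffolds with small substituents when more are needed."""
    base = scaffold_catalogue()
    anchors = list(base) if n >= len(base) else rng.sample(base, n)
    used = {m.inchikey14 for m in anchors}
    attempts = 0
    while len(anchors) < n and attempts < 40 * n:
        attempts += 1
        scaffold = rng.choice(base)
        edit = rng.choice(_DECORATIONS)
        mol = scaffold.to_mol()
        sites = _carbons_with_h(mol)
        if not sites:
            continue
        site = rng.choice(sites)
        product_mol = apply_edit(mol, site, edit)
        if product_mol is None:
            continue
        try:
            variant = chem.from_mol(product_mol)
        except Exception:
            continue
        if variant.inchikey14 in used:
            continue
        used.add(variant.inchikey14)
        anchors.append(variant)
    if len(anchors) < n:
        log.warning("could only build %d distinct anchors of %d requested", len(anchors), n)
    return anchors


def make_benchmark(
    n_pairs: int,
    seed: int,
    withhold_fraction: float = 0.0,
    threshold: float = 0.8,
    fragment_tol: float = 0.02,
) -> FixtureBenchmark:
    """Build a ground-truthed benchmark of ``n_pairs`` anchor–suspect pairs.

    Each pair is a distinct anchor plus a single-family derivative whose
    simulated spectra clear the network threshold (other sites/families
    are tried otherwise).  ``withhold_fraction`` of the transformation
    families present is withheld from the rule table to create queries no
    rule can explain.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = random.Random(seed)
    anchors = _distinct_anchors(2 * n_pairs, rng)
    spectra: List[Spectrum] = []
    pairs: List[AnchorSuspectPair] = []
    rule_pairs: List[Tuple[str, Molecule, Molecule]] = []
    truth_sites: Dict[str, int] = {}
    pair_families: Dict[str, str] = {}
    i = 0
    for anchor in anchors:
        if i >= n_pairs:
            break
        found = None
        for family in rng.sample(FAMILIES, len(FAMILIES)):
            sites = family.legal_sites(anchor.to_mol())
            rng.shuffle(sites)
            for site in sites[:6]:
                product = apply_family(anchor, family, site)
                if product is None:
                    continue
                anchor_spec = simulate_spectrum(anchor, seed, f"q{i:03d}_anchor")
                suspect_spec = simulate_spectrum(product, seed, f"q{i:03d}_suspect")
                score, _ = modified_cosine(anchor_spec, suspect_spec, fragment_tol)
                if score > threshold:
                    found = (family, site, product, anchor_spec, suspect_spec, score)
                    break
            if found:
                break
        if found is None:
            log.info("no spectral-threshold-clearing pair for %s; skipped", anchor.inchikey14)
            continue
        family, site, product, anchor_spec, suspect_spec, score = found
        pid = f"pair_{i:03d}"
        spectra.extend([anchor_spec, suspect_spec])
        pairs.append(
            AnchorSuspectPair(
                anchor=anchor_spec,
                suspect=suspect_spec,
                mass_difference=suspect_spec.neutral_mass - anchor_spec.neutral_mass,
                edge_score=score,
            )
        )
        rule_pairs.append((pid, anchor, product))
        truth_sites[anchor.inchikey14] = site
        pair_families[pid] = family.name
        i += 1

    families_used = sorted(set(pair_families.values()))
    n_withhold = round(withhold_fraction * len(families_used))
    withheld_families = set(rng.sample(families_used, n_withhold)) if n_withhold else set()
    withheld_rule_ids = [
        pid for pid in pair_families if pair_families[pid] in withheld_families
    ]
    return FixtureBenchmark(
        spectra=spectra,
        pairs=pairs,
        rule_pairs=rule_pairs,
        withheld_rule_ids=withheld_rule_ids,
        seed=seed,
        truth_sites=truth_sites,
        pair_families=pair_families,
    )


def write_fixtures(benchmark: FixtureBenchmark, outdir) -> None:
    """Write a benchmark as plain-text files: MGF spectra + TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mgf(benchmark.spectra, outdir / "spectra.mgf")
    pair_rows = ["query_id\tanchor_spectrum_id\tsuspect_spectrum_id\tmass_difference\tedge_score"]
    for k, p in enumerate(benchmark.pairs):
        pair_rows.append(
            f"q{k:03d}\t{p.anchor.id}\t{p.suspect.id}\t{p.mass_difference:.5f}\t{p.edge_score:.6f}"
        )
    (outdir / "pairs.tsv").write_text("\n".join(pair_rows) + "\n")
    rp_rows = ["pair_id\treactant_smiles\tproduct_smiles"]
    for pid, r, p in benchmark.rule_pairs:
        rp_rows.append(f"{pid}\t{r.structure}\t{p.structure}")
    (outdir / "rule_pairs.tsv").write_text("\n".join(rp_rows) + "\n")
    truth_rows = ["query_id\tfamily\tsuspect_smiles\tsuspect_inchikey\tanchor_site"]
    for k, (pid, r, p) in enumerate(benchmark.rule_pairs):
        truth_rows.append(
            f"q{k:03d}\t{benchmark.pair_families[pid]}\t{p.structure}\t{p.inchikey}\t"
            f"{benchmark.truth_sites[r.inchikey14]}"
        )
    (outdir / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
    (outdir / "withheld_rules.txt").write_text(
        "\n".join(benchmark.withheld_rule_ids) + ("\n" if benchmark.withheld_rule_ids else "")
    )
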
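"""Biotransformation rule extraction and lookup.

A rule records where a transformation happens (reaction-center atom type
plus the types of its bonded neighbors) and what happens there (branches
removed from / attached to the center), together with the monoisotopic
mass change it causes.  Rules are extracted by aligning a reactant with
a product via a bond-order-sensitive maximum common substructure: atoms
falling outside the MCS delimit the reaction center, and each connected
group of such atoms hanging off a single center atom becomes one rule.

The rule table indexes rules by their unit-rounded mass delta so that an
observed precursor mass difference retrieves every chemically plausible
edit in O(1).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import Descriptors, rdFMCS

from . import chem
from .chem import Molecule
from .errors import InputError

log = logging.getLogger(__name__)

MCS_TIMEOUT_S = 10
MIN_MCS_FRACTION = 0.5
MASS_DELTA_TOL = 1e-3

_BOND_TYPE_FROM_ORDER = {
    1.0: Chem.BondType.SINGLE,
    1.5: Chem.BondType.AROMATIC,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
}


# ---------------------------------------------------------------------------
# atom typing


def atom_code(mol: Chem.Mol, idx: int) -> str:
    """Compact atom-environment code: element, aromaticity, ring membership,
    and the sorted (neighbor element, bond order) profile.

    Two atoms with identical element, aromaticity, ring flag and neighbor
    profile receive identical codes, which is the property rule matching
    relies on.
    """
    atom = mol.GetAtomWithIdx(idx)
    profile = sorted(
        (nbr.GetSymbol(), mol.GetBondBetweenAtoms(idx, nbr.GetIdx()).GetBondTypeAsDouble())
        for nbr in atom.GetNeighbors()
    )
    profile_text = ",".join(f"{sym}{order:g}" for sym, order in profile)
    arom = "ar" if atom.GetIsAromatic() else "al"
    ring = "ring" if atom.IsInRing() else "chain"
    return f"{atom.GetSymbol()};{arom};{ring};[{profile_text}]"


def neighborhood_codes(mol: Chem.Mol, idx: int) -> Tuple[str, ...]:
    """Sorted codes of the atoms bonded to ``idx`` (the center's shell)."""
    return tuple(
        sorted(atom_code(mol, nbr.GetIdx()) for nbr in mol.GetAtomWithIdx(idx).GetNeighbors())
    )


# ---------------------------------------------------------------------------
# structural edits


@dataclass(frozen=True)
class FragmentOp:
    """A branch attached to (or detached from) the reaction center.

    ``smiles`` is rooted so the attachment atom parses at index 0;
    ``bond_order`` is the order of the bond joining it to the center.
    """

    smiles: str
    bond_order: float


@dataclass(frozen=True)
class StructuralEdit:
    """Branches removed from and added to a single reaction-center atom."""

    removals: Tuple[FragmentOp, ...] = ()
    additions: Tuple[FragmentOp, ...] = ()

    def is_empty(self) -> bool:
        return not self.removals and not self.additions

    def serialize(self) -> str:
        rem = ";".join(f"-{op.smiles}@{op.bond_order:g}" for op in sorted(
            self.removals, key=lambda o: (o.smiles, o.bond_order)))
        add = ";".join(f"+{op.smiles}@{op.bond_order:g}" for op in sorted(
            self.additions, key=lambda o: (o.smiles, o.bond_order)))
        return f"{rem}|{add}"

    def to_dict(self) -> dict:
        return {
            "removals": [[op.smiles, op.bond_order] for op in self.removals],
            "additions": [[op.smiles, op.bond_order] for op in self.additions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructuralEdit":
        return cls(
            removals=tuple(FragmentOp(s, o) for s, o in d["removals"]),
            additions=tuple(FragmentOp(s, o) for s, o in d["additions"]),
        )


def _find_dangling_branch(
    mol: Chem.Mol, center: int, frag: Chem.Mol, bond_order: float, exclude: set
) -> Optional[List[int]]:
    """Locate a branch attached to ``center`` matching ``frag`` exactly.

    The branch's only bond to the rest of the molecule must be the
    attachment bond (frag atom 0 -> center) with the stated order.
    """
    for match in mol.GetSubstructMatches(frag, uniquify=True):
        if center in match or exclude.intersection(match):
            continue
        attach = match[0]
        bond = mol.GetBondBetweenAtoms(center, attach)
        if bond is None or bond.GetBondTypeAsDouble() != bond_order:
            continue
        match_set = set(match)
        dangling = True
        for idx in match:
            for nbr in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nbr.GetIdx()
                if j in match_set or (idx == attach and j == center):
                    continue
                dangling = False
                break
            if not dangling:
                break
        if dangling:
            return list(match)
    return None


def apply_edit(mol: Chem.Mol, center: int, edit: StructuralEdit) -> Optional[Chem.Mol]:
    """Apply a structural edit at ``center``; None if it cannot be realized.

    Hydrogens are implicit: sanitization re-derives hydrogen counts after
    the heavy-atom surgery, and explicit hydrogens on the center (e.g.
    pyrrole-type N-H) are consumed as needed to keep valence legal.
    """
    rw = Chem.RWMol(mol)
    to_delete: List[int] = []
    used: set = set()
    for op in edit.removals:
        frag = Chem.MolFromSmiles(op.smiles)
        if frag is None:
            return None
        match = _find_dangling_branch(mol, center, frag, op.bond_order, used)
        if match is None:
            return None
        used.update(match)
        to_delete.extend(match)
    for op in edit.additions:
        frag = Chem.MolFromSmiles(op.smiles)
        if frag is None:
            return None
        amap: Dict[int, int] = {}
        for atom in frag.GetAtoms():
            new_atom = Chem.Atom(atom.GetAtomicNum())
            new_atom.SetFormalCharge(atom.GetFormalCharge())
            new_atom.SetIsAromatic(atom.GetIsAromatic())
            amap[atom.GetIdx()] = rw.AddAtom(new_atom)
        for bond in frag.GetBonds():
            rw.AddBond(
                amap[bond.GetBeginAtomIdx()], amap[bond.GetEndAtomIdx()], bond.GetBondType()
            )
        bond_type = _BOND_TYPE_FROM_ORDER.get(op.bond_order)
        if bond_type is None:
            return None
        rw.AddBond(center, amap[0], bond_type)
    for idx in sorted(to_delete, reverse=True):
        rw.RemoveAtom(idx)
    product = rw.GetMol()
    center_atom = product.GetAtomWithIdx(center) if center < product.GetNumAtoms() else None
    while True:
        try:
            Chem.SanitizeMol(product)
            return product
        except Chem.AtomValenceException:
            if center_atom is not None and center_atom.GetNumExplicitHs() > 0:
                center_atom.SetNumExplicitHs(center_atom.GetNumExplicitHs() - 1)
                continue
            return None
        except Exception:
            return None


# ---------------------------------------------------------------------------
# rules and tables


@dataclass(frozen=True)
class BiotransformationRule:
    """Reaction-center pattern + structural edit + monoisotopic mass delta."""

    id: str
    source_pair: Tuple[str, str]
    center: str
    neighborhood: Tuple[str, ...]
    edit: StructuralEdit
    mass_delta: float

    @property
    def identity(self) -> Tuple[str, Tuple[str, ...], str]:
        return (self.center, self.neighborhood, self.edit.serialize())

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "source_pair": list(self.source_pair),
            "center": self.center,
            "neighborhood": list(self.neighborhood),
            "edit": self.edit.to_dict(),
            "mass_delta": self.mass_delta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiotransformationRule":
        return cls(
            id=d["id"],
            source_pair=tuple(d["source_pair"]),
            center=d["center"],
            neighborhood=tuple(d["neighborhood"]),
            edit=StructuralEdit.from_dict(d["edit"]),
            mass_delta=float(d["mass_delta"]),
        )


def _rule_id(center: str, neighborhood: Tuple[str, ...], edit: StructuralEdit) -> str:
    payload = "\x1f".join((center, "\x1e".join(neighborhood), edit.serialize()))
    return "rule_" + hashlib.sha1(payload.encode()).hexdigest()[:12]


def round_unit(x: float) -> int:
    """Round to integer Da, half away from zero (deterministic at ±0.5)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def extract_rules(
    reactant: Molecule,
    product: Molecule,
    source_pair: Optional[Tuple[str, str]] = None,
) -> List[BiotransformationRule]:
    """Extract one rule per connected reaction center of a reactant→product pair.

    Alignment is a bond-order-sensitive MCS with ring-to-ring matching.
    Identity pairs yield no rules; so do pairs whose MCS covers less than
    half the smaller molecule's heavy atoms (unreliable alignment).
    """
    if reactant.inchikey14 == product.inchikey14:
        return []
    rmol = reactant.to_mol()
    pmol = product.to_mol()
    params = rdFMCS.MCSParameters()
    params.BondTyper = rdFMCS.BondCompare.CompareOrder
    params.BondCompareParameters.RingMatchesRingOnly = True
    params.AtomCompareParameters.RingMatchesRingOnly = True
    params.Timeout = MCS_TIMEOUT_S
    mcs = rdFMCS.FindMCS([rmol, pmol], params)
    min_heavy = min(rmol.GetNumAtoms(), pmol.GetNumAtoms())
    if mcs.numAtoms < MIN_MCS_FRACTION * min_heavy:
        log.info(
            "MCS covers %d/%d heavy atoms for pair (%s, %s); no rule extracted",
            mcs.numAtoms, min_heavy, reactant.inchikey14, product.inchikey14,
        )
        return []
    query = Chem.MolFromSmarts(mcs.smartsString)
    r_match = rmol.GetSubstructMatch(query)
    p_match = pmol.GetSubstructMatch(query)
    if not r_match or not p_match:
        return []
    r_to_p = dict(zip(r_match, p_match))
    p_to_r = dict(zip(p_match, r_match))

    # bonds between matched atoms must agree on both sides; anything else
    # (ring closure/opening between mapped atoms) is outside this scheme
    matched_r = list(r_match)
    for i, ri in enumerate(matched_r):
        for rj in matched_r[i + 1:]:
            rb = rmol.GetBondBetweenAtoms(ri, rj)
            pb = pmol.GetBondBetweenAtoms(r_to_p[ri], r_to_p[rj])
            r_order = rb.GetBondTypeAsDouble() if rb else None
            p_order = pb.GetBondTypeAsDouble() if pb else None
            if r_order != p_order:
                log.info("bond change between mapped atoms; pair skipped")
                return []

    # reaction centers: group unmatched branches by their (reactant-frame)
    # attachment atom
    centers: Dict[int, Dict[str, List[FragmentOp]]] = {}

    def collect(mol: Chem.Mol, matched: set, kind: str, to_reactant: Dict[int, int]) -> bool:
        unmatched = [a for a in range(mol.GetNumAtoms()) if a not in matched]
        seen: set = set()
        for start in unmatched:
            if start in seen:
                continue
            comp = _connected_component(mol, start, matched)
            seen.update(comp)
            attachments = []
            for a in comp:
                for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
                    if nbr.GetIdx() in matched:
                        bond = mol.GetBondBetweenAtoms(a, nbr.GetIdx())
                        attachments.append((nbr.GetIdx(), a, bond.GetBondTypeAsDouble()))
            if len(attachments) != 1:
                log.info("branch with %d attachment points; pair skipped", len(attachments))
                return False
            anchor_atom, attach_atom, order = attachments[0]
            frag_smiles = Chem.MolFragmentToSmiles(
                mol, atomsToUse=comp, rootedAtAtom=attach_atom, canonical=True
            )
            if Chem.MolFromSmiles(frag_smiles) is None:
                log.info("branch %r not reparseable; pair skipped", frag_smiles)
                return False
            center_r = to_reactant[anchor_atom]
            centers.setdefault(center_r, {"removals": [], "additions": []})[kind].append(
                FragmentOp(frag_smiles, order)
            )
        return True

    identity = {i: i for i in range(rmol.GetNumAtoms())}
    if not collect(rmol, set(r_match), "removals", identity):
        return []
    if not collect(pmol, set(p_match), "additions", p_to_r):
        return []
    if not centers:
        return []

    src = source_pair or (reactant.inchikey14, product.inchikey14)
    rules: List[BiotransformationRule] = []
    for center_idx in sorted(centers):
        ops = centers[center_idx]
        edit = StructuralEdit(
            removals=tuple(sorted(ops["removals"], key=lambda o: (o.smiles, o.bond_order))),
            additions=tuple(sorted(ops["additions"], key=lambda o: (o.smiles, o.bond_order))),
        )
        if edit.is_empty():
            continue
        applied = apply_edit(rmol, center_idx, edit)
        if applied is None:
            log.info("edit at atom %d could not be re-applied; rule dropped", center_idx)
            continue
        delta = Descriptors.ExactMolWt(applied) - reactant.monoisotopic_mass
        center_code = atom_code(rmol, center_idx)
        nbh = neighborhood_codes(rmol, center_idx)
        rules.append(
            BiotransformationRule(
                id=_rule_id(center_code, nbh, edit),
                source_pair=src,
                center=center_code,
                neighborhood=nbh,
                edit=edit,
                mass_delta=delta,
            )
        )
    return rules


def _connected_component(mol: Chem.Mol, start: int, excluded: set) -> List[int]:
    comp, stack, seen = [], [start], {start}
    while stack:
        a = stack.pop()
        comp.append(a)
        for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
            j = nbr.GetIdx()
            if j not in seen and j not in excluded:
                seen.add(j)
                stack.append(j)
    return sorted(comp)


class RuleTable:
    """Rules indexed by unit-rounded mass delta."""

    SCHEMA_VERSION = 1

    def __init__(self, rules: Iterable[BiotransformationRule] = ()) -> None:
        self.rules: Dict[str, BiotransformationRule] = {}
        self.index: Dict[int, List[str]] = {}
        self._identities: set = set()
        for rule in rules:
            self.add(rule)

    def __len__(self) -> int:
        return len(self.rules)

    def add(self, rule: BiotransformationRule) -> bool:
        """Add a rule unless an identical one is already stored."""
        if rule.identity in self._identities:
            return False
        self._identities.add(rule.identity)
        self.rules[rule.id] = rule
        self.index.setdefault(round_unit(rule.mass_delta), []).append(rule.id)
        return True

    def match(self, observed_mass_difference: float) -> List[BiotransformationRule]:
        key = round_unit(observed_mass_difference)
        return [self.rules[rid] for rid in self.index.get(key, [])]

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": self.SCHEMA_VERSION,
                "rules": [self.rules[rid].to_dict() for rid in sorted(self.rules)],
                "index": {str(k): sorted(v) for k, v in sorted(self.index.items())},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleTable":
        data = json.loads(text)
        if data.get("schema_version") != cls.SCHEMA_VERSION:
            raise InputError(f"unsupported rule table schema: {data.get('schema_version')}")
        return cls(BiotransformationRule.from_dict(d) for d in data["rules"])

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "RuleTable":
        path = Path(path)
        if not path.exists():
            raise InputError(f"rule table not found: {path}")
        return cls.from_json(path.read_text())


def build_rule_table(
    pairs: Iterable[Tuple[Molecule, Molecule]],
    pair_ids: Optional[Sequence[str]] = None,
) -> RuleTable:
    """Extract rules from every pair in both directions and index them.

    Each reactant→product pair also contributes the reverse rules with the
    negated mass delta (biotransformations are reversible).  Structurally
    identical rules are stored once; unusable pairs are logged and skipped.
    """
    table = RuleTable()
    for k, (reactant, product) in enumerate(pairs):
        pid = pair_ids[k] if pair_ids is not None else f"pair_{k}"
        for direction, (r, p) in (("fwd", (reactant, product)), ("rev", (product, reactant))):
            try:
                extracted = extract_rules(r, p, source_pair=(f"{pid}:{direction}", p.inchikey14))
            except Exception as exc:
                log.warning("pair %s (%s) failed rule extraction: %s", pid, direction, exc)
                continue
            for rule in extracted:
                table.add(rule)
    return table


def match_rules(
    table: RuleTable, observed_mass_difference: float
) -> List[BiotransformationRule]:
    """Rules whose unit-rounded mass delta equals the rounded observation."""
    return table.match(observed_mass_difference)


def read_pairs_tsv(path) -> List[Tuple[str, Molecule, Molecule]]:
    """Read (pair_id, reactant_smiles, product_smiles) rows, skipping bad ones."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"pairs file not found: {path}")
    out: List[Tuple[str, Molecule, Molecule]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#") or (lineno == 1 and "smiles" in line.lower()):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            log.warning("pairs line %d malformed; skipped", lineno)
            continue
        pid, rs, ps = fields[0], fields[1], fields[2]
        try:
            out.append((pid, chem.canonicalize(rs), chem.canonicalize(ps)))
        except Exception as exc:
            log.warning("pairs line %d unparseable (%s); skipped", lineno, exc)
    return out
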
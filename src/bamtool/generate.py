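"""Candidate suspect-structure enumeration.

Mass-matched rules are applied to an anchor structure at every site whose
atom-type code and full bonded-neighborhood profile match the rule's
reaction center.  Products failing valence/InChI sanity or the mass-delta
check are discarded; survivors are de-duplicated on the first InChIKey
block while every (rule, site) provenance is retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

from . import chem
from .chem import Molecule
from .network import AnchorSuspectPair
from .rules import (
    BiotransformationRule,
    RuleTable,
    apply_edit,
    atom_code,
    match_rules,
    neighborhood_codes,
)

log = logging.getLogger(__name__)

MAX_SITES_PER_RULE = 64
MASS_TOL = 1e-3


@dataclass(frozen=True)
class Provenance:
    rule_id: str
    site_atom: int


@dataclass(frozen=True)
class Candidate:
    """A generated derivative with its provenance and (later) score/rank.

    ``site_atom`` indexes the anchor's canonical heavy-atom order; when a
    derivative arises from several (rule, site) combinations the extra
    ones are kept in ``provenances``.
    """

    derivative: Molecule
    rule_id: str
    site_atom: int
    provenances: Tuple[Provenance, ...] = ()
    score: float = math.nan
    rank: float = math.nan

    @property
    def all_provenances(self) -> Tuple[Provenance, ...]:
        primary = Provenance(self.rule_id, self.site_atom)
        return (primary,) + tuple(p for p in self.provenances if p != primary)


def matching_sites(anchor: Molecule, rule: BiotransformationRule) -> List[int]:
    """Anchor atoms whose center code and neighborhood match the rule."""
    mol = anchor.to_mol()
    sites = [
        idx
        for idx in range(mol.GetNumAtoms())
        if atom_code(mol, idx) == rule.center
        and neighborhood_codes(mol, idx) == rule.neighborhood
    ]
    if len(sites) > MAX_SITES_PER_RULE:
        log.warning(
            "rule %s matches %d sites on %s; capped at %d",
            rule.id, len(sites), anchor.inchikey14, MAX_SITES_PER_RULE,
        )
        sites = sites[:MAX_SITES_PER_RULE]
    return sites


def apply_rule(anchor: Molecule, rule: BiotransformationRule) -> List[Candidate]:
    """Apply one rule at every matching site of the anchor.

    Returns candidates de-duplicated on the first InChIKey block, ordered
    by site index of first occurrence.
    """
    mol = anchor.to_mol()
    by_key: Dict[str, Candidate] = {}
    for site in matching_sites(anchor, rule):
        product = apply_edit(mol, site, rule.edit)
        if product is None:
            log.debug("rule %s at site %d: edit not realizable", rule.id, site)
            continue
        try:
            derivative = chem.from_mol(product)
        except Exception as exc:
            log.warning("rule %s at site %d: invalid product (%s)", rule.id, site, exc)
            continue
        realized = derivative.monoisotopic_mass - anchor.monoisotopic_mass
        if abs(realized - rule.mass_delta) > MASS_TOL:
            log.debug(
                "rule %s at site %d: realized delta %.4f != %.4f",
                rule.id, site, realized, rule.mass_delta,
            )
            continue
        key = derivative.inchikey14
        if key in by_key:
            existing = by_key[key]
            by_key[key] = replace(
                existing,
                provenances=existing.provenances + (Provenance(rule.id, site),),
            )
        else:
            by_key[key] = Candidate(derivative=derivative, rule_id=rule.id, site_atom=site)
    return list(by_key.values())


def generate_candidates(pair: AnchorSuspectPair, table: RuleTable) -> List[Candidate]:
    """All candidates for an anchor–suspect pair from mass-matched rules.

    De-duplicates across rules on the first InChIKey block, merging
    provenance records; output order is deterministic (InChIKey-sorted).
    An empty list means "no derivative generated" and is a legal outcome.
    """
    anchor = pair.anchor.annotation
    if anchor is None:
        raise ValueError("pair anchor must be annotated")
    by_key: Dict[str, Candidate] = {}
    for rule in match_rules(table, pair.mass_difference):
        for cand in apply_rule(anchor, rule):
            key = cand.derivative.inchikey14
            if key in by_key:
                existing = by_key[key]
                merged = existing.provenances + cand.all_provenances
                seen: set = set()
                uniq = tuple(
                    p for p in merged if not (p in seen or seen.add(p))
                )
                by_key[key] = replace(existing, provenances=uniq)
            else:
                by_key[key] = replace(cand, provenances=cand.provenances)
    return sorted(by_key.values(), key=lambda c: c.derivative.inchikey)
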
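"""Ortholog-derived gene classes and cross-species conservation tiers.

From consumed orthogroup families this module derives single/multi-copy
labels, 1:1 ortholog tuples (families with exactly one member per declared
species), and conservation tiers for focal-species tissue-specific genes:
HCTSG (call shared by all declared species), MCTSG (shared by the focal
species and its designated partner species, e.g. pig+cattle+sheep, but not
by all), LCTSG (unique to the focal species), OTHER (any remaining sharing
pattern) and UNMAPPED (gene not in the 1:1 map).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from tsgkit.formats import OrthoGroups

logger = logging.getLogger(__name__)

TIER_LABELS = ("HCTSG", "MCTSG", "LCTSG", "OTHER", "UNMAPPED")


def copy_class(groups: OrthoGroups, species: str, genes=None) -> dict[str, str]:
    """Label genes of one species as single-copy (SC) or multi-copy (MC).

    A gene is MC iff its family holds >= 2 genes of that species.  Genes
    absent from every family are singleton families of their own and are
    labelled SC; pass ``genes`` to include such unclustered genes.
    """
    labels: dict[str, str] = {}
    for members in groups.families.values():
        mine = members.get(species, [])
        lab = "MC" if len(mine) >= 2 else "SC"
        for g in mine:
            labels[g] = lab
    if genes is not None:
        for g in genes:
            labels.setdefault(g, "SC")
    return labels


@dataclass
class OneToOneMap:
    """1:1 ortholog tuples: family_id -> species -> single gene id."""

    species: tuple[str, ...]
    tuples: dict[str, dict[str, str]]
    _index: dict[str, dict[str, str]] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.tuples)

    def gene_index(self, species: str) -> dict[str, str]:
        """Map gene id -> family id for one species (cached)."""
        if species not in self._index:
            self._index[species] = {
                members[species]: fam for fam, members in self.tuples.items()
            }
        return self._index[species]

    def ortholog(self, gene: str, from_species: str, to_species: str) -> str | None:
        fam = self.gene_index(from_species).get(gene)
        return None if fam is None else self.tuples[fam][to_species]


def one_to_one(groups: OrthoGroups, species_list) -> OneToOneMap:
    """Extract families with exactly one member in every listed species."""
    species = tuple(species_list)
    if not species:
        raise ValueError("species_list must be non-empty")
    tuples: dict[str, dict[str, str]] = {}
    for fam, members in groups.families.items():
        if all(len(members.get(sp, ())) == 1 for sp in species):
            tuples[fam] = {sp: members[sp][0] for sp in species}
    return OneToOneMap(species, tuples)


@dataclass
class ConservationTier:
    """Tier label and sharing pattern per focal tissue-specific gene."""

    focal: str
    species: tuple[str, ...]
    labels: dict[str, str]
    patterns: dict[str, str]  # gene -> bitmask string over ``species`` order

    def counts(self) -> dict[str, int]:
        c = Counter(self.labels.values())
        return {lab: c.get(lab, 0) for lab in TIER_LABELS}


def conservation_tiers(
    tsg_sets: dict,
    omap: OneToOneMap,
    focal: str = "pig",
    mc_partners: tuple[str, ...] = ("cattle", "sheep"),
) -> ConservationTier:
    """Assign a conservation tier to each focal-species tissue-specific gene.

    "Shared" means the 1:1 ortholog is itself called tissue-specific in
    that species under the same calling parameters — conservation of the
    call, not of abundance.  The tiers are disjoint by construction: MCTSG
    additionally requires that not all species share the call.
    """
    if focal not in omap.species:
        raise ValueError(f"focal species {focal!r} not in the ortholog map")
    unknown = sorted(set(tsg_sets) - set(omap.species))
    if unknown:
        raise ValueError(f"unknown species in tsg_sets: {unknown}")
    bad_partner = [p for p in mc_partners if p not in omap.species]
    if bad_partner:
        raise ValueError(f"mc_partners not in the ortholog map: {bad_partner}")

    sets = {sp: set(tsg_sets.get(sp, ())) for sp in omap.species}
    idx = omap.gene_index(focal)
    mc_required = (focal,) + tuple(mc_partners)

    labels: dict[str, str] = {}
    patterns: dict[str, str] = {}
    for gene in sorted(sets[focal]):
        fam = idx.get(gene)
        if fam is None:
            labels[gene] = "UNMAPPED"
            patterns[gene] = "-" * len(omap.species)
            continue
        tup = omap.tuples[fam]
        shared = {sp: tup[sp] in sets[sp] for sp in omap.species}
        patterns[gene] = "".join("1" if shared[sp] else "0" for sp in omap.species)
        if all(shared.values()):
            labels[gene] = "HCTSG"
        elif all(shared[sp] for sp in mc_required):
            labels[gene] = "MCTSG"
        elif sum(shared.values()) == 1:  # focal only
            labels[gene] = "LCTSG"
        else:
            labels[gene] = "OTHER"
    return ConservationTier(focal, omap.species, labels, patterns)
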
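"""Exhaustive Venn partitioning of labeled sets and the cross-species
pathway comparison.

With k labeled sets there are 2^k - 1 possible non-empty membership
categories (15 for the four-way shoot/root x two-species comparison);
every element lands in exactly one category, the subset of labels whose
sets contain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class VennPartition:
    """Disjoint membership categories of up to four labeled sets."""

    set_labels: tuple
    categories: dict  # frozenset of labels -> sorted member list
    category_count: int  # possible non-empty categories: 2^k - 1

    def occupied(self) -> int:
        return len(self.categories)

    def counts(self) -> dict:
        return {"+".join(sorted(k)): len(v) for k, v in self.categories.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("labels\tcount\tmembers\n")
            for key in sorted(self.categories, key=lambda s: sorted(s)):
                members = self.categories[key]
                fh.write("+".join(sorted(key)) + f"\t{len(members)}\t"
                         + ",".join(members) + "\n")


def venn_partition(labeled_sets: dict) -> VennPartition:
    """Partition elements by exactly which input sets contain them.

    ``labeled_sets`` maps 2-4 distinct labels to sets. Empty categories are
    omitted from the mapping but counted as possible in
    ``category_count``.
    """
    labels = list(labeled_sets)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate set labels")
    if not (2 <= len(labels) <= 4):
        raise ValueError("venn_partition takes 2-4 labeled sets")
    categories: dict = {}
    universe = set().union(*labeled_sets.values())
    for el in universe:
        key = frozenset(l for l in labels if el in labeled_sets[l])
        categories.setdefault(key, []).append(el)
    for key in categories:
        categories[key] = sorted(categories[key])
    return VennPartition(set_labels=tuple(labels), categories=categories,
                         category_count=2 ** len(labels) - 1)


@dataclass
class SpeciesComparison:
    """Pathway ids partitioned by species/organ specificity, one direction."""

    direction: str
    turf_specific_both_organs: list = field(default_factory=list)
    turf_specific_single_organ: list = field(default_factory=list)
    shared_both_species: list = field(default_factory=list)
    rice_specific: list = field(default_factory=list)
    shared_organ_detail: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\tpathway_ids\n")
            for k in ("turf_specific_both_organs", "turf_specific_single_organ",
                      "shared_both_species", "rice_specific"):
                ids = getattr(self, k)
                fh.write(f"{k}\t{len(ids)}\t" + ",".join(ids) + "\n")


def species_compare(turf_shoot: set, turf_root: set, rice_leaf: set,
                    rice_root: set, direction: str = "up"
                    ) -> SpeciesComparison:
    """Categorize enriched pathway ids across the two species.

    Turf-specific-both-organs: enriched in both turf organs and in neither
    rice organ; turf-specific-single-organ: in exactly one turf organ and
    no rice organ; shared-both-species: in at least one organ of each
    species (organ detail retained); rice-specific: rice only.
    """
    turf = set(turf_shoot) | set(turf_root)
    rice = set(rice_leaf) | set(rice_root)
    shared = turf & rice
    comp = SpeciesComparison(
        direction=direction,
        turf_specific_both_organs=sorted((set(turf_shoot) & set(turf_root))
                                         - rice),
        turf_specific_single_organ=sorted(
            (turf - (set(turf_shoot) & set(turf_root))) - rice),
        shared_both_species=sorted(shared),
        rice_specific=sorted(rice - turf),
    )
    for pid in sorted(shared):
        comp.shared_organ_detail[pid] = {
            "turf": sorted(o for o, s in
                           (("shoot", turf_shoot), ("root", turf_root))
                           if pid in s),
            "rice": sorted(o for o, s in
                           (("leaf", rice_leaf), ("root", rice_root))
                           if pid in s),
        }
    return comp
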
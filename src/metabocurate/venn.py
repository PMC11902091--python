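"""Three-set membership algebra over {extract (CSE), plasma baseline, plasma day 7}.

A compound is "detected" in a group when it has at least one measured
(non-imputed) value in a sample of that group — imputed cells encode
non-detection by construction.  The bioavailability call is the region
present in the extract and at day 7 but absent at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CuratedMatrix

#: Deterministic region order, keyed by (in_cse, in_basal, in_day7).
REGION_ORDER = [
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, True, True),
]

REGION_NAMES = {
    (True, False, False): "cse_only",
    (False, True, False): "basal_only",
    (False, False, True): "day7_only",
    (True, True, False): "cse_and_basal",
    (True, False, True): "cse_and_day7",
    (False, True, True): "basal_and_day7",
    (True, True, True): "all_three",
}


@dataclass
class VennPartition:
    regions: dict[tuple[bool, bool, bool], frozenset[str]]
    set_sizes: dict[str, int]  # input set sizes: cse / basal / day7

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def region(self, name_or_key) -> frozenset[str]:
        if isinstance(name_or_key, tuple):
            return self.regions[name_or_key]
        for key, name in REGION_NAMES.items():
            if name == name_or_key:
                return self.regions[key]
        raise KeyError(name_or_key)

    @property
    def percentages(self) -> dict[str, float]:
        u = self.union_size
        if u == 0:
            return {REGION_NAMES[k]: 0.0 for k in REGION_ORDER}
        return {REGION_NAMES[k]: 100.0 * len(self.regions[k]) / u for k in REGION_ORDER}


def detected_set(cm: CuratedMatrix, group: str) -> frozenset[str]:
    """Compound ids with >= 1 measured (non-imputed) value in the given group."""
    cols = cm.columns_for_group(group)
    measured = ~cm.imputed[cols]
    return frozenset(cm.values.index[measured.any(axis=1)])


def venn_partition(cse, basal, day7) -> VennPartition:
    """Exact seven-region partition of the three compound-id sets."""
    cse, basal, day7 = set(cse), set(basal), set(day7)
    regions: dict[tuple[bool, bool, bool], set[str]] = {k: set() for k in REGION_ORDER}
    for cid in cse | basal | day7:
        regions[(cid in cse, cid in basal, cid in day7)].add(cid)
    return VennPartition(
        regions={k: frozenset(v) for k, v in regions.items()},
        set_sizes={"cse": len(cse), "basal": len(basal), "day7": len(day7)},
    )


def classify_bioavailable(partition: VennPartition) -> frozenset[str]:
    """Compounds supplied by the extract, absent at baseline, detected at day 7."""
    return partition.regions[(True, False, True)]


def audit_percentages(partition: VennPartition, round_to: int = 1) -> dict:
    """Report region counts with percentages of the union and of each input set."""
    u = partition.union_size
    report: dict = {"union_size": u, "set_sizes": dict(partition.set_sizes), "regions": {}}
    for key in REGION_ORDER:
        ids = partition.regions[key]
        name = REGION_NAMES[key]
        entry = {
            "count": len(ids),
            "pct_of_union": round(100.0 * len(ids) / u, round_to) if u else 0.0,
        }
        for flag, set_name in zip(key, ("cse", "basal", "day7")):
            if flag and partition.set_sizes[set_name]:
                entry[f"pct_of_{set_name}"] = round(
                    100.0 * len(ids) / partition.set_sizes[set_name], round_to
                )
        report["regions"][name] = entry
    return report


def audit_reported_counts(
    region_counts: dict[str, int], set_sizes: dict[str, int], tol: int = 0
) -> dict:
    """Consistency audit of externally reported Venn figures.

    Checks that each input set size equals the sum of its four regions and
    that the union equals the sum of all seven; reports every violation
    without attempting to reconcile the figures.
    """
    problems = []
    get = lambda name: region_counts.get(name, 0)
    union = sum(get(REGION_NAMES[k]) for k in REGION_ORDER)
    for set_name, idx in (("cse", 0), ("basal", 1), ("day7", 2)):
        total = sum(get(REGION_NAMES[k]) for k in REGION_ORDER if k[idx])
        if set_name in set_sizes and abs(total - set_sizes[set_name]) > tol:
            problems.append(
                f"{set_name}: regions sum to {total}, reported set size {set_sizes[set_name]}"
            )
    if "union" in set_sizes and abs(union - set_sizes["union"]) > tol:
        problems.append(f"union: regions sum to {union}, reported union {set_sizes['union']}")
    return {"union_from_regions": union, "consistent": not problems, "problems": problems}
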
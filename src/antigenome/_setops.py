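"""Venn-style set partitions shared by library QC and differential analysis."""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping


def venn_partition(sets: Mapping[str, Iterable[Hashable]]) -> dict[frozenset, set]:
    """Partition the union of named sets into exclusive Venn regions.

    Each element of the union is assigned to exactly one region, keyed by
    the frozenset of set names that contain it.  Region member sets are
    disjoint and their sizes sum to the union size.
    """
    named = {name: set(members) for name, members in sets.items()}
    if not named:
        raise ValueError("venn_partition requires at least one set")
    regions: dict[frozenset, set] = {}
    union = set().union(*named.values())
    for element in union:
        key = frozenset(name for name, members in named.items() if element in members)
        regions.setdefault(key, set()).add(element)
    return regions
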
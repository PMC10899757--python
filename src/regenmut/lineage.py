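"""Pedigree reconstruction from shared, lineage-specific variants.

Offspring are assigned to the parent (and, within the regenerated group, the
regenerant) with which they exclusively share the most pre-existing variants;
the three-generation star topology (parent -> regenerant -> offspring) is the
only model considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .calling import VariantCall


@dataclass
class Pedigree:
    samples: List[Tuple[str, str, str]]          # (name, role, group)
    edges: Dict[str, Tuple[Optional[str], Optional[str]]]  # offspring -> (parent, regenerant)
    sibling_groups: List[Set[str]] = field(default_factory=list)
    ambiguous: List[str] = field(default_factory=list)

    def parent_of(self, offspring: str) -> Optional[str]:
        return self.edges.get(offspring, (None, None))[0]

    def regenerant_of(self, offspring: str) -> Optional[str]:
        return self.edges.get(offspring, (None, None))[1]


def sharing_matrix(calls: Iterable[VariantCall], samples: Sequence[str],
                   mode: str = "family") -> np.ndarray:
    """Pairwise exclusive-sharing counts of lineage-specific variants.

    mode='family' (default): entry (i, j) counts variants carried by both i
    and j (and, since carrier sets are actual carrier lists, by nobody
    outside the sharing family); variants carried by every sample contribute
    to no pair. mode='exact': only variants whose carrier set is exactly
    {i, j} count.
    """
    if mode not in ("family", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    idx = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    mat = np.zeros((n, n), dtype=int)
    calls = list(calls)
    if not calls:
        warnings.warn("empty call set: zero sharing matrix")
        return mat
    for call in calls:
        carriers = [s for s in call.carriers if s in idx]
        if len(carriers) < 2 or len(carriers) == n:
            continue
        if mode == "exact" and len(carriers) != 2:
            continue
        for a in range(len(carriers)):
            for b in range(a + 1, len(carriers)):
                i, j = idx[carriers[a]], idx[carriers[b]]
                mat[i, j] += 1
                mat[j, i] += 1
    return mat


def _argmax_with_margin(scores: Dict[str, int], margin: int
                        ) -> Tuple[Optional[str], bool]:
    """(winner, ambiguous): winner None when all scores are zero; ambiguous
    when the top score does not exceed the runner-up by the margin."""
    if not scores or max(scores.values()) == 0:
        return None, False
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < margin:
        return ranked[0][0], True
    return ranked[0][0], False


def assign_pedigree(matrix: np.ndarray, samples: Sequence[str],
                    roles: Dict[str, str], groups: Dict[str, str],
                    margin: int = 3) -> Pedigree:
    """Assign each offspring (and regenerant) to its argmax parent.

    Assignment requires the top sharing count to exceed the runner-up by
    ``margin`` variants, else the sample is flagged ambiguous (reported, not
    silently chosen). Offspring with an all-zero row stay unassigned.
    Within the regenerated group, each offspring is also linked to the
    regenerant of its parent's line with maximal sharing.
    """
    idx = {s: i for i, s in enumerate(samples)}
    parents = [s for s in samples if roles.get(s) == "parent"]
    regenerants = [s for s in samples if roles.get(s) == "regenerant"]
    offspring = [s for s in samples if roles.get(s) == "offspring"]

    regen_parent: Dict[str, Optional[str]] = {}
    ambiguous: List[str] = []
    for r in regenerants:
        scores = {p: int(matrix[idx[r], idx[p]]) for p in parents}
        winner, amb = _argmax_with_margin(scores, margin)
        regen_parent[r] = winner
        if amb:
            ambiguous.append(r)

    edges: Dict[str, Tuple[Optional[str], Optional[str]]] = {}
    for o in offspring:
        scores = {p: int(matrix[idx[o], idx[p]]) for p in parents}
        winner, amb = _argmax_with_margin(scores, margin)
        if amb:
            ambiguous.append(o)
        regen: Optional[str] = None
        if winner is not None and groups.get(o) == "regenerated":
            line = [r for r in regenerants if regen_parent.get(r) == winner]
            if line:
                rscores = {r: int(matrix[idx[o], idx[r]]) for r in line}
                regen, amb_r = _argmax_with_margin(rscores, margin)
                if amb_r:
                    ambiguous.append(o)
        edges[o] = (winner, regen)

    siblings: Dict[str, Set[str]] = {}
    for o, (p, _) in edges.items():
        if p is not None:
            siblings.setdefault(p, set()).add(o)
    sibling_groups = [g for g in siblings.values() if len(g) > 1]
    return Pedigree(
        samples=[(s, roles.get(s, "?"), groups.get(s, "?")) for s in samples],
        edges=edges,
        sibling_groups=sibling_groups,
        ambiguous=sorted(set(ambiguous)),
    )


def sibling_shared_denovo(calls: Iterable[VariantCall], pedigree: Pedigree,
                          min_shared: int = 2
                          ) -> List[Tuple[Set[str], int, float]]:
    """Group same-parent offspring sharing >= min_shared de novo variants.

    Returns (sibling set, shared count, shared fraction of the group's de
    novo union) per group: siblings sharing most of their de novo mutations
    descend from one germline lineage of the parent (or regenerant).
    """
    calls = list(calls)
    per_offspring: Dict[str, Set] = {}
    for call in calls:
        for s in call.carriers:
            per_offspring.setdefault(s, set()).add(call.key)
    out: List[Tuple[Set[str], int, float]] = []
    for group in pedigree.sibling_groups:
        members = sorted(group)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                va = per_offspring.get(members[a], set())
                vb = per_offspring.get(members[b], set())
                shared = len(va & vb)
                if shared >= min_shared:
                    union = len(va | vb)
                    out.append(({members[a], members[b]}, shared,
                                shared / union if union else 0.0))
    return out
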
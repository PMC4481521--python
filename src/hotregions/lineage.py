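"""SNP-in-HOT dynamics along a developmental lineage tree.

Dynamics are computed at SNP resolution: for each variant and each stage
we ask whether the variant sits inside a HOT region active at that stage,
then classify parent-to-child transitions as lost / gained / shared /
absent, locate each variant's stage of origin along a root-to-leaf path,
and test stage specificity against every stage of the tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from .intervals import RegionSet
from .variant_mapping import SNP

__all__ = [
    "LineageTree",
    "StagePresence",
    "TransitionAccounting",
    "compute_presence",
    "classify_transition",
    "transition_accounting",
    "origin_and_specificity",
    "retained_fraction",
]

TransitionClass = Literal["lost", "gained", "shared", "absent"]


class LineageTree:
    """Rooted tree of developmental stages (e.g. ESC -> Hemat -> {B, T})."""

    def __init__(self, parent: dict[str, Optional[str]]) -> None:
        roots = [s for s, p in parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"lineage tree must have exactly one root, found {len(roots)}")
        for s, p in parent.items():
            if p is not None and p not in parent:
                raise ValueError(f"stage {s!r} has unknown parent {p!r}")
        self.parent = dict(parent)
        self.root = roots[0]
        self.stages = list(parent)
        # cycle check: every stage must reach the root
        for s in self.stages:
            seen = set()
            cur: Optional[str] = s
            while cur is not None:
                if cur in seen:
                    raise ValueError("lineage tree contains a cycle")
                seen.add(cur)
                cur = self.parent[cur]

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, Optional[str]]]) -> "LineageTree":
        return cls({child: parent for child, parent in pairs})

    def path_to(self, stage: str) -> list[str]:
        """Root-to-stage path, inclusive."""
        path = []
        cur: Optional[str] = stage
        while cur is not None:
            path.append(cur)
            cur = self.parent[cur]
        return path[::-1]

    def children(self, stage: str) -> list[str]:
        return [s for s, p in self.parent.items() if p == stage]

    def transitions(self) -> list[tuple[str, str]]:
        """All (parent, child) edges in stage order."""
        return [(p, s) for s, p in self.parent.items() if p is not None]

    def leaves(self) -> list[str]:
        has_child = set(p for p in self.parent.values() if p is not None)
        return [s for s in self.stages if s not in has_child]


@dataclass
class StagePresence:
    """Per-stage HOT membership of one SNP."""

    snp_id: str
    presence: dict[str, bool]


@dataclass
class TransitionAccounting:
    parent: str
    child: str
    lost: int
    gained: int
    shared: int
    absent: int

    @property
    def net(self) -> int:
        return self.gained - self.lost


def compute_presence(
    snps: Sequence[SNP],
    stage_regions: dict[str, RegionSet],
    tree: LineageTree,
) -> list[StagePresence]:
    """HOT membership of every SNP at every stage of the tree."""
    missing = [s for s in tree.stages if s not in stage_regions]
    if missing:
        raise ValueError(f"no region set for stage(s): {', '.join(missing)}")
    out = []
    for s in snps:
        out.append(
            StagePresence(
                snp_id=s.snp_id,
                presence={
                    stage: stage_regions[stage].contains(s.chrom, s.pos)
                    for stage in tree.stages
                },
            )
        )
    return out


def classify_transition(
    presence: StagePresence, parent: str, child: str
) -> TransitionClass:
    """lost = in parent only; gained = in child only; shared = both; absent = neither."""
    p, c = presence.presence[parent], presence.presence[child]
    if p and not c:
        return "lost"
    if c and not p:
        return "gained"
    if p and c:
        return "shared"
    return "absent"


def transition_accounting(
    presences: Sequence[StagePresence], parent: str, child: str
) -> TransitionAccounting:
    counts = {"lost": 0, "gained": 0, "shared": 0, "absent": 0}
    for pr in presences:
        counts[classify_transition(pr, parent, child)] += 1
    return TransitionAccounting(parent=parent, child=child, **counts)


def origin_and_specificity(
    presence: StagePresence, path: Sequence[str], all_stages: Sequence[str]
) -> tuple[Optional[str], Optional[str]]:
    """(origin stage, specific stage) for one SNP.

    Origin is the earliest stage on the root-to-leaf path where the SNP is
    present (presence on a sibling branch does not affect it); the SNP is
    stage-specific iff it is present at exactly one stage of the whole tree.
    """
    origin = next((st for st in path if presence.presence[st]), None)
    present_stages = [st for st in all_stages if presence.presence[st]]
    specific = present_stages[0] if len(present_stages) == 1 else None
    return origin, specific


def retained_fraction(
    presences: Sequence[StagePresence], root: str, leaf: str
) -> float:
    """Of SNPs present at the leaf stage, the fraction also present at the root."""
    at_leaf = [p for p in presences if p.presence[leaf]]
    if not at_leaf:
        raise ValueError(f"no SNPs present at leaf stage {leaf!r}")
    both = sum(1 for p in at_leaf if p.presence[root])
    return both / len(at_leaf)
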
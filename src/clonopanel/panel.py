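"""Panel resources: target intervals, reference, hotspots, artifact pool."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from intervaltree import IntervalTree

Site = Tuple[str, int]  # (contig, 1-based position)
PoolEntry = Tuple[str, int, str, str]  # (contig, 1-based pos, ref, alt)


@dataclass
class PanelResources:
    """Static per-panel resources shared by every sample of a cohort.

    Coordinates are half-open 0-based for intervals and 1-based for
    sites, matching the BED and VCF dialects they serialize to.
    """

    #: contig -> sorted list of (start, end), half-open 0-based
    targets: Dict[str, List[Tuple[int, int]]]
    #: contig -> uppercase base string covering all targets
    reference: Dict[str, str]
    #: whitelisted hotspot sites: (contig, pos) -> (gene, codon label)
    hotspots: Dict[Site, Tuple[str, str]] = field(default_factory=dict)
    #: recurrent-artifact sites pooled across normal libraries
    artifact_pool: Set[PoolEntry] = field(default_factory=set)
    #: gene intervals: (contig, start, end, gene), half-open 0-based
    genes: List[Tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self):
        self._target_trees = {
            contig: IntervalTree.from_tuples((s, e) for s, e in ivs if e > s)
            for contig, ivs in self.targets.items()
        }
        self._gene_trees: Dict[str, IntervalTree] = {}
        for contig, start, end, gene in self.genes:
            self._gene_trees.setdefault(contig, IntervalTree()).addi(start, end, gene)
        self.validate()

    def validate(self) -> None:
        for contig, ivs in self.targets.items():
            if contig not in self.reference:
                raise ValueError(f"reference is missing contig {contig}")
            ref_len = len(self.reference[contig])
            for s, e in ivs:
                if not (0 <= s < e <= ref_len):
                    raise ValueError(
                        f"target {contig}:{s}-{e} outside reference (length {ref_len})"
                    )
        for (contig, pos) in self.hotspots:
            if not self.in_targets(contig, pos):
                raise ValueError(f"hotspot site {contig}:{pos} outside panel targets")
        for (contig, pos, _ref, _alt) in self.artifact_pool:
            if not self.in_targets(contig, pos):
                raise ValueError(f"artifact site {contig}:{pos} outside panel targets")

    # -- lookups ---------------------------------------------------------
    def in_targets(self, contig: str, pos: int) -> bool:
        """True if the 1-based position falls inside a target interval."""
        tree = self._target_trees.get(contig)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def gene_at(self, contig: str, pos: int) -> Optional[str]:
        tree = self._gene_trees.get(contig)
        if tree is None:
            return None
        hits = tree[pos - 1]
        return next(iter(hits)).data if hits else None

    def is_hotspot(self, contig: str, pos: int) -> bool:
        return (contig, pos) in self.hotspots

    def hotspot_label(self, contig: str, pos: int) -> Optional[Tuple[str, str]]:
        return self.hotspots.get((contig, pos))

    def in_artifact_pool(self, contig: str, pos: int, ref: str, alt: str) -> bool:
        return (contig, pos, ref, alt) in self.artifact_pool

    def base_at(self, contig: str, pos: int) -> str:
        return self.reference[contig][pos - 1]

    def trinucleotide(self, contig: str, pos: int) -> Optional[str]:
        """Reference trinucleotide centered on the 1-based position."""
        seq = self.reference[contig]
        if pos < 2 or pos > len(seq) - 1:
            return None
        return seq[pos - 2 : pos + 1]

    # -- sizes -----------------------------------------------------------
    @property
    def footprint_bases(self) -> int:
        return sum(e - s for ivs in self.targets.values() for s, e in ivs)

    @property
    def footprint_mb(self) -> float:
        return self.footprint_bases / 1e6

    @property
    def contig_order(self) -> List[str]:
        return list(self.targets.keys())
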
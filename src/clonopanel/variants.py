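"""Variant call records and filter parameter containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported for callers)
from typing import Optional, Tuple

VariantKey = Tuple[str, int, str, str]  # (contig, 1-based pos, ref, alt)

#: closed vocabulary of functional consequence terms
CONSEQUENCE_TERMS = frozenset(
    {
        "synonymous",
        "missense",
        "stop_gain",
        "start_loss",
        "splice_site",
        "frameshift",
        "inframe_indel",
    }
)

#: consequences that count as non-synonymous for gene-burden comparisons
NONSYNONYMOUS_TERMS = CONSEQUENCE_TERMS - {"synonymous"}


@dataclass
class VariantCall:
    """One small-variant observation in a tumor or normal library.

    Read support is carried as per-strand alt depths plus read-pair
    orientation counts of the alt allele (F1R2/F2R1), which is what the
    low-VAF oxidative-damage check needs.  ``vaf_expected`` is only set
    by the simulator's noise-free mode, where the call represents
    expected rather than sampled counts.
    """

    sample: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_fwd: int
    alt_rev: int
    depth: int
    alt_f1r2: int = 0
    alt_f2r1: int = 0
    pop_maf: float = 0.0
    gene: str = ""
    context: Optional[str] = None  # reference trinucleotide, SNVs only
    hotspot: bool = False
    pooled_artifact: bool = False
    consequence: str = "missense"
    vaf_expected: Optional[float] = None

    def __post_init__(self):
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(
                f"alt depth {self.alt_fwd}+{self.alt_rev} exceeds total depth "
                f"{self.depth} at {self.contig}:{self.pos}"
            )
        if self.context is not None and len(self.context) != 3:
            raise ValueError(f"trinucleotide context must have length 3, got {self.context!r}")

    @property
    def key(self) -> VariantKey:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def alt_depth(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def vaf(self) -> float:
        if self.vaf_expected is not None:
            return self.vaf_expected
        return self.alt_depth / self.depth if self.depth > 0 else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the two-step somatic filter.

    Defaults follow the published strategy: >=5 supporting reads, a
    population MAF below 0.05%, the extra oxidative-damage and
    both-strand checks only below 5% VAF, and a 2% matched-normal VAF
    tolerance when no contamination is measurable.
    """

    min_alt_reads: int = 5
    max_population_maf: float = 0.0005
    low_vaf_cutoff: float = 0.05
    default_normal_vaf: float = 0.02
    oxog_enabled: bool = True
    max_indel_len_strand_check: int = 5  # counting-tool limit for indels

    def __post_init__(self):
        for name in ("max_population_maf", "low_vaf_cutoff", "default_normal_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_alt_reads < 1:
            raise ValueError(f"min_alt_reads must be >= 1, got {self.min_alt_reads}")


REASON_CODES = (
    "low_support",
    "germline_common",
    "pooled_artifact",
    "oxog_artifact",
    "strand_bias",
    "normal_contaminated",
)


@dataclass(frozen=True)
class FilterVerdict:
    reasons: Tuple[str, ...] = ()

    def __post_init__(self):
        unknown = set(self.reasons) - set(REASON_CODES)
        if unknown:
            raise ValueError(f"unknown reason codes: {sorted(unknown)}")

    @property
    def decision(self) -> str:
        return "pass" if not self.reasons else "reject"

    @property
    def passed(self) -> bool:
        return not self.reasons


@dataclass
class ContaminationProfile:
    """Contaminated calls found in one normal library.

    ``threshold`` is the maximum VAF over the contaminated calls — the
    per-sample tolerance for matched-normal evidence when filtering the
    tumor — or None when the normal shows no contamination.
    """

    sample: str
    contaminated_calls: list = field(default_factory=list)

    @property
    def threshold(self) -> Optional[float]:
        if not self.contaminated_calls:
            return None
        return max(c.vaf for c in self.contaminated_calls)

    @property
    def keys(self) -> set:
        return {c.key for c in self.contaminated_calls}
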
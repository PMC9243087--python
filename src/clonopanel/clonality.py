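"""Cancer cell fraction (CCF) estimation and clonal-exclusivity analysis.

For a variant with allele fraction VAF in a tumor of known purity and
local total copy number cn, the expected number of mutated copies per
tumor cell is

    u = ((1 - purity) * 2 + purity * cn) / purity * VAF = CCF * m

with m the multiplicity (mutated copies per carrying cell).  Since a
clonal mutation has CCF 1, multiplicity is resolved as m = u when
u >= 1 and m = 1 otherwise, giving CCF = u / m.  A mutation is called
clonal at CCF >= 0.8 to absorb purity and copy-number uncertainty.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLONAL_CCF = 0.8
U_CAP = 1e3  # reporting-side cap for pathological purity/VAF combinations


@dataclass(frozen=True)
class PurityEstimate:
    sample: str
    purity: float

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")


@dataclass(frozen=True)
class CopySegment:
    """Total-copy-number segment, half-open coordinates."""

    sample: str
    contig: str
    start: int
    end: int
    total_cn: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"segment end must exceed start: {self}")
        if self.total_cn < 0:
            raise ValueError(f"total copy number must be non-negative: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CCFAssignment:
    u: float
    m: float
    ccf: float
    capped: bool = False

    @property
    def clonal(self) -> bool:
        return self.ccf >= CLONAL_CCF


@dataclass(frozen=True)
class HotspotGroup:
    """A named group of recurrent oncogenic codons, e.g. KRAS G12/G13/Q61."""

    label: str
    members: frozenset  # of (gene, codon) pairs

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"hotspot group {self.label!r} has no members")


def compute_ccf(
    vaf: float,
    purity: float,
    local_cn: float,
    multiplicity_mode: str = "literal",
) -> Optional[CCFAssignment]:
    """Mutated-copy load u, multiplicity m and CCF for one variant.

    ``multiplicity_mode='literal'`` resolves m = u for u >= 1 (so every
    u >= 1 maps to CCF 1); ``'rounded'`` uses the integer-multiplicity
    variant m = max(1, round(u)) common in other CCF tools.  Returns
    None for the inconsistent case of observed alt reads on a
    zero-copy segment.
    """
    if purity <= 0:
        raise ValueError(f"purity must be positive, got {purity}")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF must lie in [0, 1], got {vaf}")
    if local_cn < 0:
        raise ValueError(f"local copy number must be non-negative, got {local_cn}")
    if local_cn == 0 and vaf > 0:
        logger.warning(
            "variant with VAF %.3f on a zero-copy segment: inconsistent, skipped", vaf
        )
        return None
    u = ((1.0 - purity) * 2.0 + purity * local_cn) / purity * vaf
    capped = u > U_CAP
    if capped:
        u = U_CAP
    if multiplicity_mode == "literal":
        m = u if u >= 1.0 else 1.0
    elif multiplicity_mode == "rounded":
        m = max(1.0, float(round(u)))
    else:
        raise ValueError(f"unknown multiplicity_mode {multiplicity_mode!r}")
    ccf = min(u / m, 1.0)
    return CCFAssignment(u=u, m=m, ccf=ccf, capped=capped)


def classify_clonality(ccf: float) -> str:
    if not 0.0 <= ccf <= 1.0:
        raise ValueError(f"CCF must lie in [0, 1], got {ccf}")
    return "clonal" if ccf >= CLONAL_CCF else "subclonal"


def assign_local_cn(
    contig: str,
    pos: int,
    segments: Sequence[CopySegment],
    default_cn: float = 2.0,
) -> float:
    """Total copy number of the covering segment at a 1-based position.

    Segments must be sorted and non-overlapping per contig; a half-open
    boundary end belongs to the next segment.  Uncovered positions fall
    back to the diploid default with a warning.
    """
    segs = [s for s in segments if s.contig == contig]
    starts = [s.start for s in segs]
    for a, b in zip(segs, segs[1:]):
        if b.start < a.end:
            raise ValueError(f"segments overlap or are unsorted: {a} / {b}")
    p0 = pos - 1
    i = bisect.bisect_right(starts, p0) - 1
    if i >= 0 and segs[i].start <= p0 < segs[i].end:
        return segs[i].total_cn
    logger.warning("position %s:%d not covered by any segment; default CN %.1f", contig, pos, default_cn)
    return default_cn


def assign_ccf_table(
    somatic_by_sample: Mapping[str, Sequence],
    purity: Mapping[str, float],
    segments_by_sample: Mapping[str, Sequence[CopySegment]],
    hotspot_labels: Optional[Mapping[Tuple[str, int], Tuple[str, str]]] = None,
    multiplicity_mode: str = "literal",
) -> pd.DataFrame:
    """Cohort CCF table: one row per somatic variant.

    ``hotspot_labels`` maps (contig, pos) to (gene, codon) so hotspot
    variants can be grouped downstream.
    """
    hotspot_labels = hotspot_labels or {}
    rows = []
    for sample, calls in somatic_by_sample.items():
        pur = purity[sample]
        segs = sorted(segments_by_sample.get(sample, ()), key=lambda s: (s.contig, s.start))
        for call in calls:
            cn = assign_local_cn(call.contig, call.pos, segs)
            asg = compute_ccf(call.vaf, pur, cn, multiplicity_mode=multiplicity_mode)
            if asg is None:
                continue
            hs = hotspot_labels.get((call.contig, call.pos))
            rows.append(
                {
                    "sample": sample,
                    "contig": call.contig,
                    "pos": call.pos,
                    "ref": call.ref,
                    "alt": call.alt,
                    "gene": call.gene,
                    "codon": hs[1] if hs else "",
                    "vaf": call.vaf,
                    "purity": pur,
                    "local_cn": cn,
                    "u": asg.u,
                    "m": asg.m,
                    "ccf": asg.ccf,
                    "clonal": asg.clonal,
                }
            )
    columns = [
        "sample", "contig", "pos", "ref", "alt", "gene", "codon",
        "vaf", "purity", "local_cn", "u", "m", "ccf", "clonal",
    ]
    return pd.DataFrame(rows, columns=columns)


# -- clonality-stratified mutual exclusivity ----------------------------


def build_exclusivity_matrix(
    ccf_table: pd.DataFrame,
    groups: Sequence[HotspotGroup],
    min_ccf: float = 0.05,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Patient x hotspot-group status matrix plus pairwise counts.

    Variants below ``min_ccf`` are excluded; patients with no remaining
    group-member variant are dropped.  Entries are 'clonal' if any
    member variant is clonal (CCF >= 0.8), else 'subclonal' if any
    member variant remains, else 'absent'.  The pairwise table counts
    patients with both groups clonal (exclusivity violations under the
    one-active-clone model), both subclonal, and mixed.
    """
    if not groups:
        raise ValueError("at least one hotspot group is required")
    df = ccf_table[ccf_table["ccf"] >= min_ccf]
    status: Dict[str, Dict[str, str]] = {}
    for g in groups:
        members = g.members
        mask = np.fromiter(
            ((gene, codon) in members for gene, codon in zip(df["gene"], df["codon"])),
            dtype=bool, count=len(df),
        )
        sub = df.loc[mask]
        for sample, grp in sub.groupby("sample"):
            entry = "clonal" if (grp["ccf"] >= CLONAL_CCF).any() else "subclonal"
            status.setdefault(sample, {})[g.label] = entry
    labels = [g.label for g in groups]
    matrix = pd.DataFrame(
        [
            {"sample": sample, **{lbl: status[sample].get(lbl, "absent") for lbl in labels}}
            for sample in sorted(status)
        ],
        columns=["sample"] + labels,
    ).set_index("sample")
    pair_rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            if matrix.empty:
                both_c = both_s = mixed = 0
            else:
                a, b = matrix[g1], matrix[g2]
                both_c = int(((a == "clonal") & (b == "clonal")).sum())
                both_s = int(((a == "subclonal") & (b == "subclonal")).sum())
                mixed = int(
                    (((a == "clonal") & (b == "subclonal")) | ((a == "subclonal") & (b == "clonal"))).sum()
                )
            pair_rows.append(
                {"group_a": g1, "group_b": g2, "both_clonal": both_c,
                 "both_subclonal": both_s, "mixed": mixed}
            )
    pairs = pd.DataFrame(pair_rows, columns=["group_a", "group_b", "both_clonal", "both_subclonal", "mixed"])
    return matrix, pairs


def _clonal_cooccurrence_stat(clonal: np.ndarray) -> int:
    """Total both-clonal pair count across groups; clonal is (n_patients, n_groups) bool."""
    k = clonal.sum(axis=1)
    return int((k * (k - 1) // 2).sum())


def exclusivity_permutation_test(
    matrix: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    tie_break: str = "conservative",
) -> Optional[float]:
    """Permutation p-value for clonal mutual exclusivity.

    The statistic is the number of patient-level both-clonal group
    pairs; the null permutes each group's patient labels independently,
    preserving per-group clonal frequencies.  ``tie_break='conservative'``
    is p = (1 + #{null <= observed}) / (1 + N); ``'randomized'`` breaks
    ties uniformly, which is exactly U(0,1) under the null and is used
    for calibration checks.  Returns None when no clonal calls exist.
    """
    if n_permutations < 100:
        raise ValueError(f"n_permutations must be >= 100, got {n_permutations}")
    clonal = (matrix.to_numpy() == "clonal")
    if clonal.size == 0 or not clonal.any():
        logger.info("no clonal calls in exclusivity matrix; p-value undefined")
        return None
    rng = np.random.default_rng(seed)
    observed = _clonal_cooccurrence_stat(clonal)
    n_pat, n_grp = clonal.shape
    null = np.empty(n_permutations, dtype=np.int64)
    perm = clonal.copy()
    for i in range(n_permutations):
        for j in range(n_grp):
            perm[:, j] = clonal[rng.permutation(n_pat), j]
        null[i] = _clonal_cooccurrence_stat(perm)
    if tie_break == "conservative":
        return float((1 + int((null <= observed).sum())) / (1 + n_permutations))
    if tie_break == "randomized":
        less = int((null < observed).sum())
        ties = int((null == observed).sum()) + 1  # observed value joins its tie class
        return float((less + rng.uniform() * ties) / (n_permutations + 1))
    raise ValueError(f"unknown tie_break {tie_break!r}")


DEFAULT_HOTSPOT_GROUPS: Tuple[HotspotGroup, ...] = (
    HotspotGroup("KRAS G12/G13/Q61", frozenset({("KRAS", "G12"), ("KRAS", "G13"), ("KRAS", "Q61")})),
    HotspotGroup("NRAS Q61", frozenset({("NRAS", "Q61"), ("NRAS", "G12"), ("NRAS", "G13")})),
    HotspotGroup("BRAF V600", frozenset({("BRAF", "V600")})),
)
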
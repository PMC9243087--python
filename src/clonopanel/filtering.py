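"""Two-step contamination-aware somatic variant filtering.

Tumor biopsies from advanced patients shed circulating tumor cells into
the blood used as the matched "normal", so true somatic variants appear
in the normal library at VAFs that can exceed any fixed cutoff.  The
strategy is therefore two-step: (1) call contaminated mutations in the
normal alone with strict artifact/germline criteria and record their
maximum VAF; (2) filter tumor calls with the same base criteria while
tolerating matched-normal VAF up to that per-sample maximum (2% when no
contamination is measurable).
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .panel import PanelResources, Site
from .variants import ContaminationProfile, FilterCriteria, FilterVerdict, VariantCall

logger = logging.getLogger(__name__)

OXOG_CHANGES = {("C", "A"), ("G", "T")}  # 8-oxo-guanine damage signature


def _is_pooled(call: VariantCall, resources: Optional[PanelResources]) -> bool:
    if resources is not None:
        return resources.in_artifact_pool(call.contig, call.pos, call.ref, call.alt)
    return call.pooled_artifact


def _is_hotspot(call: VariantCall, resources: Optional[PanelResources]) -> bool:
    if resources is not None:
        return resources.is_hotspot(call.contig, call.pos)
    return call.hotspot


def apply_base_criteria(
    call: VariantCall,
    resources: Optional[PanelResources] = None,
    criteria: FilterCriteria = FilterCriteria(),
) -> FilterVerdict:
    """Evaluate criteria (1)-(5) on a single call.

    (1) >= min_alt_reads supporting reads; (2) population MAF below the
    cutoff; (3) not in the pooled-artifact database unless the site is a
    white-listed hotspot.  Below the low-VAF cutoff two extra checks
    fire: (4) oxidative-damage orientation balance for C>A / G>T SNVs,
    and (5) alt support on both strands.  (4)-(5) also apply to indels
    only up to the read-counting tool's length limit.
    """
    reasons: List[str] = []
    if call.alt_depth < criteria.min_alt_reads:
        reasons.append("low_support")
    if call.pop_maf >= criteria.max_population_maf:
        reasons.append("germline_common")
    if _is_pooled(call, resources) and not _is_hotspot(call, resources):
        reasons.append("pooled_artifact")
    low_vaf = call.vaf < criteria.low_vaf_cutoff
    checkable = call.is_snv or call.indel_length <= criteria.max_indel_len_strand_check
    if low_vaf and checkable:
        if (
            criteria.oxog_enabled
            and call.is_snv
            and (call.ref, call.alt) in OXOG_CHANGES
            and call.alt_depth > 0
            and (call.alt_f1r2 == 0 or call.alt_f2r1 == 0)
        ):
            reasons.append("oxog_artifact")
        if call.alt_depth > 0 and (call.alt_fwd == 0 or call.alt_rev == 0):
            reasons.append("strand_bias")
    return FilterVerdict(tuple(reasons))


def call_normal_contamination(
    normal_calls: Sequence[VariantCall],
    resources: Optional[PanelResources] = None,
    criteria: FilterCriteria = FilterCriteria(),
) -> ContaminationProfile:
    """Identify contaminated mutations in one normal library.

    Returns the per-sample profile whose ``threshold`` (max VAF over
    contaminated calls, or None) tolerances the tumor-normal step.
    """
    samples = {c.sample for c in normal_calls}
    if len(samples) > 1:
        raise ValueError(f"normal calls span multiple samples: {sorted(samples)}")
    sample = next(iter(samples)) if samples else ""
    contaminated = [
        c for c in normal_calls if apply_base_criteria(c, resources, criteria).passed
    ]
    return ContaminationProfile(sample=sample, contaminated_calls=contaminated)


def filter_somatic(
    tumor_calls: Sequence[VariantCall],
    normal_calls: Sequence[VariantCall],
    profile: ContaminationProfile,
    resources: Optional[PanelResources] = None,
    criteria: FilterCriteria = FilterCriteria(),
) -> Tuple[List[VariantCall], List[Tuple[VariantCall, FilterVerdict]]]:
    """Tumor-normal filtering step.

    A tumor call is somatic iff it passes the base criteria and its VAF
    in the matched normal is <= the contamination threshold (inclusive;
    a real somatic call sitting exactly at the observed contamination
    maximum must not be rejected), or <= the 2% default when the normal
    shows no contamination.  Sites absent from the normal call set count
    as normal VAF 0.
    """
    normal_vaf: Dict[tuple, float] = {c.key: c.vaf for c in normal_calls}
    tolerance = profile.threshold if profile.threshold is not None else criteria.default_normal_vaf
    somatic: List[VariantCall] = []
    rejected: List[Tuple[VariantCall, FilterVerdict]] = []
    missing = 0
    for call in tumor_calls:
        verdict = apply_base_criteria(call, resources, criteria)
        nvaf = normal_vaf.get(call.key)
        if nvaf is None:
            nvaf = 0.0
            missing += 1
        reasons = list(verdict.reasons)
        if nvaf > tolerance:
            reasons.append("normal_contaminated")
        if reasons:
            rejected.append((call, FilterVerdict(tuple(reasons))))
        else:
            somatic.append(call)
    if missing:
        logger.debug("%d tumor sites had no matched-normal call; treated as normal VAF 0", missing)
    return somatic, rejected


def classify_variant_site_origin(
    tumor_somatic: Sequence[VariantCall],
    profile: ContaminationProfile,
) -> Dict[tuple, str]:
    """Per-variant origin: biopsy, blood_only, or shared.

    Contaminated normal-library mutations absent from the biopsy's
    somatic set are blood-only (carried by circulating tumor cells
    only); variants seen in both compartments are shared.
    """
    tumor_keys = {c.key for c in tumor_somatic}
    origin = {key: "biopsy" for key in tumor_keys}
    for key in profile.keys:
        origin[key] = "shared" if key in tumor_keys else "blood_only"
    return origin


def build_artifact_pool(
    normal_call_sets: Mapping[str, Sequence[VariantCall]],
    min_recurrence: int = 3,
    hotspot_whitelist: Optional[Iterable[Site]] = None,
) -> Set[tuple]:
    """Pool sites recurrently called across normal libraries.

    A (contig, pos, ref, alt) entry is pooled iff called in at least
    ``min_recurrence`` distinct normals; white-listed hotspot sites are
    removed because recurrent oncogenic positions are more likely real
    mutations than artifacts.
    """
    if min_recurrence < 2:
        raise ValueError(f"min_recurrence must be >= 2, got {min_recurrence}")
    if len(normal_call_sets) < 2:
        raise ValueError("artifact pooling needs at least two normal libraries")
    whitelist = set(hotspot_whitelist or ())
    counts: Counter = Counter()
    for calls in normal_call_sets.values():
        for key in {c.key for c in calls}:
            counts[key] += 1
    return {
        key
        for key, n in counts.items()
        if n >= min_recurrence and (key[0], key[1]) not in whitelist
    }
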
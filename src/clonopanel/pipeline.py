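"""End-to-end orchestration: simulate -> filter -> ccf -> signature ->
compare -> resist, driven by a single run configuration.

Every stage reads its inputs from and writes its outputs to the run's
output directory, so any stage can be re-run from cached upstream
outputs.  Outputs contain no timestamps; identical configuration and
seed give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from . import cohort_io as cio
from .clonality import (
    DEFAULT_HOTSPOT_GROUPS,
    assign_ccf_table,
    build_exclusivity_matrix,
    exclusivity_permutation_test,
)
from .compare import (
    DEFAULT_RESISTANCE_CATALOG,
    Alteration,
    annotate_resistance,
    compare_cohorts,
    focal_deletion_test,
    load_resistance_catalog,
)
from .filtering import build_artifact_pool, call_normal_contamination, filter_somatic, classify_variant_site_origin
from .panel import PanelResources
from .signature import signature_report
from .simulate import SimulationConfig, simulate_cohort
from .variants import FilterCriteria

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "ccf", "signature", "compare", "resist")
_STAGE_DEPS = {
    "filter": "simulate",
    "ccf": "filter",
    "signature": "filter",
    "compare": "filter",
    "resist": "filter",
}
_STAGE_SENTINELS = {
    "simulate": "cohort/config.json",
    "filter": "filter/contamination.tsv",
    "ccf": "ccf/ccf_table.tsv",
    "signature": "signature/signature_report.tsv",
    "compare": "compare/comparison.tsv",
    "resist": "resist/resistance_report.tsv",
}


class DependencyError(RuntimeError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-backed)."""

    outdir: str = "clonopanel_out"
    seed: int = 0
    stages: Sequence[str] = STAGES
    simulate: Dict = dataclasses.field(default_factory=dict)
    fixture_dir: Optional[str] = None  # pre-existing cohort instead of simulation
    filter: Dict = dataclasses.field(default_factory=dict)
    clonality: Dict = dataclasses.field(default_factory=dict)
    signature: Dict = dataclasses.field(default_factory=dict)
    compare: Dict = dataclasses.field(default_factory=dict)
    resist: Dict = dataclasses.field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @property
    def parameter_hash(self) -> str:
        """Digest of everything that can change results (not outdir/logging)."""
        d = self.to_canonical_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def sim_config(self, seed_shift: int = 0, **overrides) -> SimulationConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        params.update(overrides)
        params["seed"] = int(params["seed"]) + seed_shift
        return cio.config_from_dict(params)

    def filter_criteria(self) -> FilterCriteria:
        params = {
            k: v for k, v in self.filter.items()
            if k in {f.name for f in dataclasses.fields(FilterCriteria)}
        }
        return FilterCriteria(**params)


class _EventLog:
    """Timestamp-free JSON-lines event file (stderr logging carries time)."""

    def __init__(self, path: Path):
        self.path = path
        self._n = 0
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("")

    def emit(self, stage: str, event: str, **detail) -> None:
        self._n += 1
        rec = {"n": self._n, "stage": stage, "event": event, **detail}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
        logger.info("[%s] %s %s", stage, event, detail if detail else "")


# ----------------------------------------------------------------------
# validation


def validate_inputs(config: RunConfig) -> List[dict]:
    """Validate a run configuration and (if present) its input fixture.

    Returns a list of {level, message} entries; never raises.
    """
    report: List[dict] = []

    def err(msg):
        report.append({"level": "error", "message": msg})

    def warn(msg):
        report.append({"level": "warning", "message": msg})

    for stage in config.stages:
        if stage not in STAGES:
            err(f"unknown stage {stage!r}")
    if "simulate" in config.stages and config.fixture_dir:
        warn("both simulation and fixture_dir configured; simulation wins")
    try:
        config.filter_criteria()
    except Exception as e:
        err(f"filter criteria invalid: {e}")
    if "simulate" in config.stages:
        try:
            config.sim_config()
        except Exception as e:
            err(f"simulation config invalid: {e}")
        return report
    fixture = config.fixture_dir or str(Path(config.outdir) / "cohort")
    fdir = Path(fixture)
    if not fdir.is_dir():
        err(f"fixture directory {fixture} does not exist")
        return report
    try:
        bundle = cio.read_fixture(fdir)
    except Exception as e:
        err(f"fixture unreadable: {e}")
        return report
    for pid, p in bundle.patients.items():
        if not 0.0 < p.purity <= 1.0:
            err(f"purity {p.purity} out of (0, 1] for {pid}")
        for seg in p.segments:
            if seg.end <= seg.start or seg.total_cn < 0:
                err(f"malformed segment {seg}")
        covered = {
            (s.contig, s.start, s.end) for s in p.segments
        }
        for call in p.tumor:
            if not any(
                c == call.contig and s <= call.pos - 1 < e for c, s, e in covered
            ):
                warn(f"{pid} variant {call.contig}:{call.pos} not covered by any segment")
                break
    return report


# ----------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, outdir: Path, events: _EventLog) -> None:
    bundle = simulate_cohort(config.sim_config())
    cio.write_fixture(bundle, outdir / "cohort")
    events.emit("simulate", "cohort_written", patients=len(bundle.patients),
                variants=int(len(bundle.truth.variants)))


def _load_cohort(config: RunConfig, outdir: Path):
    fixture = Path(config.fixture_dir) if config.fixture_dir else outdir / "cohort"
    if not fixture.is_dir():
        raise DependencyError(
            "cohort inputs not found: enable the 'simulate' stage or set fixture_dir"
        )
    return cio.read_fixture(fixture)


def _stage_filter(config: RunConfig, outdir: Path, events: _EventLog) -> None:
    bundle = _load_cohort(config, outdir)
    criteria = config.filter_criteria()
    res = bundle.resources
    if config.filter.get("rebuild_artifact_pool", True) and len(bundle.patients) >= 2:
        pool = build_artifact_pool(
            {pid: p.normal for pid, p in bundle.patients.items()},
            min_recurrence=int(config.filter.get("min_recurrence", 3)),
            hotspot_whitelist=set(res.hotspots),
        )
        res = PanelResources(
            targets=res.targets, reference=res.reference, hotspots=res.hotspots,
            artifact_pool=set(pool), genes=res.genes,
        )
    fdir = outdir / "filter"
    fdir.mkdir(parents=True, exist_ok=True)
    contamination_rows, origin_rows = [], []
    for pid, p in bundle.patients.items():
        profile = call_normal_contamination(p.normal, res, criteria)
        somatic, rejected = filter_somatic(p.tumor, p.normal, profile, res, criteria)
        cio.write_calls_vcf(somatic, fdir / f"{pid}.somatic.vcf", res, sample=pid)
        cio.write_calls_vcf(
            [c for c, _ in rejected], fdir / f"{pid}.rejected.vcf", res, sample=pid,
            filters={c.key: v.reasons for c, v in rejected},
        )
        thr = profile.threshold
        contamination_rows.append(
            {"sample": pid, "n_contaminated": len(profile.contaminated_calls),
             "threshold": "" if thr is None else thr,
             "applied_tolerance": thr if thr is not None else criteria.default_normal_vaf}
        )
        for key, origin in sorted(classify_variant_site_origin(somatic, profile).items()):
            origin_rows.append({"sample": pid, "contig": key[0], "pos": key[1],
                                "ref": key[2], "alt": key[3], "origin": origin})
    pd.DataFrame(contamination_rows).to_csv(fdir / "contamination.tsv", sep="\t", index=False)
    pd.DataFrame(origin_rows, columns=["sample", "contig", "pos", "ref", "alt", "origin"]).to_csv(
        fdir / "origins.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(res.artifact_pool), columns=["contig", "pos", "ref", "alt"]).to_csv(
        fdir / "artifact_pool.tsv", sep="\t", index=False
    )
    events.emit("filter", "done", samples=len(bundle.patients))


def _read_somatic(config: RunConfig, outdir: Path, bundle):
    fdir = outdir / "filter"
    if not (fdir / "contamination.tsv").exists():
        raise DependencyError("filter outputs not found: run the 'filter' stage first")
    return {
        pid: cio.read_calls_vcf(fdir / f"{pid}.somatic.vcf", bundle.resources, sample=pid)
        for pid in bundle.patients
    }


def _stage_ccf(config: RunConfig, outdir: Path, events: _EventLog) -> None:
    bundle = _load_cohort(config, outdir)
    somatic = _read_somatic(config, outdir, bundle)
    table = assign_ccf_table(
        somatic,
        purity={pid: p.purity for pid, p in bundle.patients.items()},
        segments_by_sample={pid: p.segments for pid, p in bundle.patients.items()},
        hotspot_labels=bundle.resources.hotspots,
        multiplicity_mode=config.clonality.get("multiplicity_mode", "literal"),
    )
    cdir = outdir / "ccf"
    cdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(cdir / "ccf_table.tsv", sep="\t", index=False)
    matrix, pairs = build_exclusivity_matrix(
        table, DEFAULT_HOTSPOT_GROUPS, min_ccf=float(config.clonality.get("min_ccf", 0.05))
    )
    matrix.to_csv(cdir / "exclusivity_matrix.tsv", sep="\t")
    pairs.to_csv(cdir / "pair_counts.tsv", sep="\t", index=False)
    p = exclusivity_permutation_test(
        matrix,
        n_permutations=int(config.clonality.get("n_permutations", 1000)),
        seed=config.seed,
    )
    with open(cdir / "exclusivity_test.json", "w") as fh:
        json.dump({"p_value": p, "clonal_cooccurrence": int(pairs["both_clonal"].sum())},
                  fh, indent=2, sort_keys=True)
    events.emit("ccf", "done", variants=int(len(table)),
                clonal=int(table["clonal"].sum()) if len(table) else 0)


def _stage_signature(config: RunConfig, outdir: Path, events: _EventLog) -> None:
    bundle = _load_cohort(config, outdir)
    somatic = _read_somatic(config, outdir, bundle)
    report = signature_report(
        somatic, bundle.resources,
        hypermutation_threshold=float(config.signature.get("hypermutation_threshold", 10.0)),
    )
    sdir = outdir / "signature"
    sdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(sdir / "signature_report.tsv", sep="\t", index=False)
    events.emit("signature", "done", enriched=int(report["enriched"].sum()))


def _filtered_somatic_for(config: RunConfig, bundle):
    """Filter a cohort in memory (used for the comparison cohort)."""
    criteria = config.filter_criteria()
    res = bundle.resources
    out = {}
    for pid, p in bundle.patients.items():
        profile = call_normal_contamination(p.normal, res, criteria)
        somatic, _ = filter_somatic(p.tumor, p.normal, profile, res, criteria)
        out[pid] = somatic
    return out


def _stage_compare(config: RunConfig, outdir: Path, events: _EventLog) -> None:
    bundle = _load_cohort(config, outdir)
    somatic_a = _read_somatic(config, outdir, bundle)
    n_b = int(config.compare.get("n_patients_b", max(10, len(bundle.patients))))
    seed_shift = int(config.compare.get("seed_shift", 7919))
    bundle_b = simulate_cohort(config.sim_config(seed_shift=seed_shift, n_patients=n_b))
    somatic_b = _filtered_somatic_for(config, bundle_b)
    genes = sorted({g for _, _, _, g in bundle.resources.genes})
    table = compare_cohorts(
        somatic_a, somatic_b, genes,
        min_vaf=float(config.compare.get("min_vaf", 0.05)),
    )
    cdir = outdir / "compare"
    cdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(cdir / "comparison.tsv", sep="\t", index=False)
    gene_ivs = {g: (c, s, e) for c, s, e, g in bundle.resources.genes}
    del_rows = []
    for gene in sorted(DEFAULT_RESISTANCE_CATALOG_GENES() & set(gene_ivs)):
        r = focal_deletion_test(
            {pid: p.segments for pid, p in bundle.patients.items()},
            {pid: p.segments for pid, p in bundle_b.patients.items()},
            gene_ivs[gene], gene=gene,
        )
        del_rows.append({"gene": gene, "a": r.a, "A": r.total_a, "b": r.b, "B": r.total_b,
                         "OR": r.odds_ratio, "p": r.p})
    pd.DataFrame(del_rows, columns=["gene", "a", "A", "b", "B", "OR", "p"]).to_csv(
        cdir / "focal_deletions.tsv", sep="\t", index=False
    )
    events.emit("compare", "done", genes=len(genes), cohort_b=n_b)


def DEFAULT_RESISTANCE_CATALOG_GENES() -> set:
    return {g for genes in DEFAULT_RESISTANCE_CATALOG.values() for g in genes}


TRUNCATING_CONSEQUENCES = {"stop_gain", "frameshift", "splice_site", "start_loss"}


def alterations_from_cohort(somatic_by_sample, segments_by_sample, gene_intervals,
                            catalog=None) -> List[Alteration]:
    """Derive resistance-screening alteration records from calls and segments.

    Truncating consequences map directly; deletions are segments below
    diploid copy shorter than 20 Mb overlapping a catalog gene
    (homozygous at copy 0, hemizygous otherwise).
    """
    catalog = catalog if catalog is not None else DEFAULT_RESISTANCE_CATALOG
    genes = {g for cls in catalog.values() for g in cls}
    records = []
    for pid, calls in somatic_by_sample.items():
        for c in calls:
            if c.gene in genes and c.consequence in TRUNCATING_CONSEQUENCES:
                records.append(Alteration(patient=pid, gene=c.gene, alteration_type="truncating"))
    for pid, segs in segments_by_sample.items():
        for gene in genes:
            iv = gene_intervals.get(gene)
            if iv is None:
                continue
            contig, start, end = iv
            for s in segs:
                if (s.contig == contig and s.total_cn < 2 and s.length < 20_000_000
                        and s.start < end and s.end > start):
                    alt_type = "homozygous_deletion" if s.total_cn == 0 else "hemizygous_deletion"
                    records.append(Alteration(patient=pid, gene=gene, alteration_type=alt_type))
                    break
    return records


def _stage_resist(config: RunConfig, outdir: Path, events: _EventLog) -> None:
    bundle = _load_cohort(config, outdir)
    somatic = _read_somatic(config, outdir, bundle)
    catalog = (
        load_resistance_catalog(config.resist["catalog"])
        if config.resist.get("catalog")
        else DEFAULT_RESISTANCE_CATALOG
    )
    gene_ivs = {g: (c, s, e) for c, s, e, g in bundle.resources.genes}
    records = alterations_from_cohort(
        somatic, {pid: p.segments for pid, p in bundle.patients.items()}, gene_ivs, catalog
    )
    flags, fraction = annotate_resistance(
        records, sorted(bundle.patients), catalog,
        panel_genes={g for _, _, _, g in bundle.resources.genes},
    )
    rdir = outdir / "resist"
    rdir.mkdir(parents=True, exist_ok=True)
    flags.to_csv(rdir / "resistance_report.tsv", sep="\t", index=False)
    with open(rdir / "summary.json", "w") as fh:
        json.dump({"fraction_with_resistance_alteration": fraction,
                   "n_patients": len(bundle.patients)}, fh, indent=2, sort_keys=True)
    events.emit("resist", "done", fraction=round(fraction, 4))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "ccf": _stage_ccf,
    "signature": _stage_signature,
    "compare": _stage_compare,
    "resist": _stage_resist,
}


def run_pipeline(config: RunConfig, stages: Optional[Sequence[str]] = None) -> Dict[str, str]:
    """Execute the enabled stages in dependency order.

    A stage whose upstream outputs are missing (neither enabled in this
    run nor cached from a previous one) raises DependencyError before
    anything runs; a failure mid-run leaves prior stage outputs intact
    and raises StageError naming the stage.
    """
    enabled = [s for s in STAGES if s in (stages if stages is not None else config.stages)]
    unknown = set(stages or config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in enabled:
        dep = _STAGE_DEPS.get(stage)
        if dep and dep not in enabled:
            cached = (outdir / _STAGE_SENTINELS[dep]).exists()
            external = dep == "simulate" and config.fixture_dir
            if not cached and not external:
                raise DependencyError(
                    f"stage '{stage}' requires '{dep}', which is neither enabled nor cached"
                )
    events = _EventLog(outdir / "events.jsonl")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash,
        "stages": enabled,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for stage in enabled:
        events.emit(stage, "start")
        try:
            _STAGE_FUNCS[stage](config, outdir, events)
        except DependencyError:
            raise
        except Exception as e:  # pragma: no cover - exercised via StageError tests
            events.emit(stage, "failed", error=str(e))
            raise StageError(stage, e) from e
    return {s: str(outdir / _STAGE_SENTINELS[s]) for s in enabled}
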
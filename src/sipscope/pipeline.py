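"""End-to-end pipeline: bin gradients, estimate enrichment, validate the genome.

Stage order follows the experimental workflow: load fraction tables ->
delimit light/middle/heavy bins (explicit cutoffs or treatment-vs-control
auto-binning) -> normalize per-fraction coverage and locate the focal
genome's density centroid -> estimate 13C atom-fraction excess -> GC-skew
origin/terminus call (and optional rotation) on the focal genome -> the
comparative genome-statistics table.  Every stage writes its machine-readable
output under the configured directory, and a single JSON report collects the
headline numbers.  Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.SeqUtils import gc_fraction

from . import compare as cmp
from . import gradient as grad
from . import isotope, repliskew
from .errors import PipelineError, SipScopeError

logger = logging.getLogger("sipscope")


@dataclass
class RunConfig:
    """Validated run configuration; fully serialized next to the outputs."""

    treatment: str
    control: str | None = None
    coverage: str | None = None
    focal_genome_id: str = "focal"
    focal_fasta: str | None = None
    focal_gene_table: str | None = None
    gc: float | None = None
    cutoffs: dict | None = None  # {"light": [lo, hi], ...}; None -> auto_bin
    epsilon: float = 0.05
    delta: float = 0.02
    skew_window: int = 1000
    skew_step: int = 10
    rotate: bool = False
    isotope_model: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "sipscope_out"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a JSON superset
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SipScopeError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def model(self) -> isotope.IsotopeDensityModel:
        return isotope.IsotopeDensityModel(**self.isotope_model)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: starting", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except (SipScopeError, OSError) as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("load")
def _load_profiles(config: RunConfig, model):
    treatment = grad.load_profile(config.treatment, role="treatment", model=model)
    control = (
        grad.load_profile(config.control, role="control", model=model)
        if config.control
        else None
    )
    return treatment, control


@_stage("bin")
def _bin(config: RunConfig, treatment, control):
    if config.cutoffs is not None:
        scheme = grad.BinScheme(
            light=tuple(config.cutoffs["light"]) if config.cutoffs.get("light") else None,
            middle=tuple(config.cutoffs["middle"]) if config.cutoffs.get("middle") else None,
            heavy=tuple(config.cutoffs["heavy"]) if config.cutoffs.get("heavy") else None,
        )
        logger.info("bin: using explicit cutoffs %s", config.cutoffs)
    else:
        if control is None:
            raise SipScopeError("auto-binning requires a control profile")
        scheme = grad.auto_bin(
            treatment, control, epsilon=config.epsilon, delta=config.delta
        )
        logger.info(
            "bin: auto-derived scheme (epsilon=%s, delta=%s): light=%s middle=%s heavy=%s",
            config.epsilon, config.delta, scheme.light, scheme.middle, scheme.heavy,
        )
    return scheme, grad.assign_bins(treatment, scheme)


@_stage("enrich")
def _enrich(config: RunConfig, treatment, binned, model, gc: float):
    if not config.coverage:
        raise SipScopeError("no coverage table configured")
    coverages = grad.load_coverage(config.coverage)
    if config.focal_genome_id not in coverages:
        raise SipScopeError(
            f"focal genome {config.focal_genome_id!r} absent from coverage table"
        )
    cov = coverages[config.focal_genome_id]
    if "seq_depth" in cov.fractions.columns:
        cov = grad.normalize_coverage(cov)
    centroid = grad.genome_density_centroid(cov, treatment)
    estimate = isotope.enrichment_from_density(centroid, gc, model)

    weights_col = "normalized" if "normalized" in cov.fractions.columns else "coverage"
    per_bin: dict[str, float] = {}
    for rec in cov.fractions.itertuples(index=False):
        label = binned.assignments.get(int(rec.fraction_id), "unbinned")
        per_bin[label] = per_bin.get(label, 0.0) + float(getattr(rec, weights_col))
    dominant = max(per_bin, key=per_bin.get)
    interval = None
    if dominant != "unbinned" and getattr(binned.scheme, dominant) is not None:
        lo, hi = getattr(binned.scheme, dominant)
        interval = isotope.enrichment_from_density_interval(lo, hi, gc, model)
    return cov, centroid, estimate, per_bin, dominant, interval


@_stage("skew")
def _skew(config: RunConfig, seq: str):
    profile = repliskew.gc_skew(
        seq, window=config.skew_window, step=config.skew_step, circular=True
    )
    call = repliskew.predict_ori_ter(profile)
    rotated = repliskew.rotate_to_origin(seq, call.ori_pos) if config.rotate else None
    return profile, call, rotated


@_stage("compare")
def _compare(config: RunConfig):
    stats = cmp.stats_from_inputs(
        config.focal_fasta,
        config.focal_gene_table,
        genome_id=config.focal_genome_id,
        environment="synthetic",
    )
    rows = [stats] + [
        r for r in cmp.load_reference_table() if r.genome_id != config.focal_genome_id
    ]
    return cmp.build_comparison(rows, config.focal_genome_id)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write outputs plus a JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)

    model = config.model()
    report: dict = {"sample": {}, "stages": []}
    try:
        treatment, control = _load_profiles(config, model)
        report["sample"] = {
            "treatment": treatment.sample_id,
            "control": control.sample_id if control else None,
        }
        report["stages"].append("load")

        scheme, binned = _bin(config, treatment, control)
        report["bin_scheme"] = {
            label: list(getattr(scheme, label)) if getattr(scheme, label) else None
            for label in grad.BIN_LABELS
        }
        report["bin_flags"] = list(scheme.flags)
        report["pooled_mass"] = binned.pooled_mass
        report["stages"].append("bin")

        gc = config.gc
        seq = None
        if config.focal_fasta:
            records = list(SeqIO.parse(config.focal_fasta, "fasta"))
            seq = str(records[0].seq)
            if gc is None:
                gc = gc_fraction(records[0].seq)
        if config.coverage:
            if gc is None:
                raise PipelineError(
                    "enrich", "focal GC unknown: provide gc or focal_fasta"
                )
            cov, centroid, estimate, per_bin, dominant, interval = _enrich(
                config, treatment, binned, model, gc
            )
            cov.fractions.to_csv(out / "focal_coverage.tsv", sep="\t", index=False)
            report["focal_gc"] = gc
            report["density_centroid"] = centroid
            report["coverage_per_bin"] = per_bin
            report["dominant_bin"] = dominant
            report["afe"] = {
                "point": estimate.afe,
                "from_dominant_bin": None
                if interval is None
                else {
                    "bin": dominant,
                    "afe": interval.afe,
                    "lower": interval.afe_lower,
                    "upper": interval.afe_upper,
                },
            }
            report["stages"].append("enrich")

        if seq is not None:
            profile, call, rotated = _skew(config, seq)
            profile.to_frame().to_csv(out / "skew.tsv", sep="\t", index=False)
            report["ori_ter"] = {
                "ori_pos": call.ori_pos,
                "ter_pos": call.ter_pos,
                "amplitude": call.amplitude,
            }
            if rotated is not None:
                with open(out / "rotated.fasta", "w") as fh:
                    fh.write(f">{config.focal_genome_id} rotated_to_origin\n")
                    for i in range(0, len(rotated), 80):
                        fh.write(rotated[i : i + 80] + "\n")
            report["stages"].append("skew")

        if config.focal_fasta and config.focal_gene_table:
            table = _compare(config)
            table.to_tsv(out / "comparison.tsv")
            report["comparison"] = {
                "diff_from_average": table.diff_from_average,
                "pct_larger_than_largest": table.pct_larger_than_largest,
            }
            report["stages"].append("compare")
    except PipelineError as exc:
        report["failed_stage"] = exc.stage
        report["error"] = str(exc)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete: %s", out / "report.json")
    return report
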
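"""End-to-end orchestration: simulate -> call -> filter -> analyze -> report.

A single :class:`RunConfig` drives either a synthetic run (cohort generated by
:mod:`rdnadiv.simulate`) or a real-input run (VCFs + metadata TSV). Stages
execute in a fixed order; every output file carries the configuration hash and
the global seed in its header, and a synthetic rerun with the same config is
bit-identical. Per-stage seeds derive from the global seed by fixed offsets so
stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity, selection
from .calling import call_variants
from .cooccurrence import CooccurrenceConfig, find_coupled_pairs, pairs_to_table
from .copynumber import (IsolateRecord, group_median_copies, isolates_to_table,
                         read_isolate_metadata)
from .errors import ConfigError
from .filtering import FilterConfig, apply_filter_cascade
from .prototype import RDNAPrototype, load_prototype
from .simulate import CohortConfig, generate_cohort, simulate_pileup, synthetic_prototype
from .structure import (StructureAnnotation, read_structure_annotation,
                        synthetic_structure_annotation)
from .variants import calls_to_table, read_variant_calls, write_variant_calls

log = logging.getLogger(__name__)

# fixed per-stage seed offsets (stage seeds = global seed + offset, < 2**31)
STAGE_OFFSETS = {"cohort": 0, "pileup": 10_000, "call": 20_000}


@dataclass
class RunConfig:
    """One pipeline run: exactly one of synthetic or real inputs is active."""

    output_dir: str
    seed: int = 0
    synthetic: CohortConfig | None = None
    prototype_fasta: str | None = None
    prototype_bed: str | None = None
    vcf_paths: dict[str, str] | None = None  # isolate_id -> vcf path
    metadata_tsv: str | None = None
    structure_shells_tsv: str | None = None
    structure_regions_tsv: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    cooccurrence: CooccurrenceConfig = field(default_factory=CooccurrenceConfig)
    run_entropy: bool = True
    run_cooccurrence: bool = True
    run_enrichment: bool = True
    alpha: float = 0.01

    def __post_init__(self) -> None:
        real = self.vcf_paths is not None or self.metadata_tsv is not None
        if self.synthetic is not None and real:
            raise ConfigError("choose either synthetic or real inputs, not both")
        if self.synthetic is None and not real:
            raise ConfigError("no inputs: provide a synthetic CohortConfig or real paths")
        if real:
            for name in ("vcf_paths", "metadata_tsv", "prototype_fasta", "prototype_bed"):
                if getattr(self, name) is None:
                    raise ConfigError(f"real-mode config missing required field {name!r}")

    # -- serialization --------------------------------------------------------------

    def to_dict(self) -> dict:
        def unwrap(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: unwrap(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, dict):
                return {str(k): unwrap(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return [unwrap(x) for x in v]
            return v

        return {k: unwrap(v) for k, v in dataclasses.asdict(self).items()}

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "ploidy_weights" in syn:
                syn["ploidy_weights"] = {int(k): float(v) for k, v in syn["ploidy_weights"].items()}
            for key in ("copy_number_range", "clades", "niches", "habitats"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = CohortConfig(**syn)
        if "filter" in raw and raw["filter"] is not None:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "cooccurrence" in raw and raw["cooccurrence"] is not None:
            raw["cooccurrence"] = CooccurrenceConfig(**raw["cooccurrence"])
        return cls(**raw)


def _provenance_header(cfg: RunConfig) -> str:
    return f"# rdnadiv seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory.

    Any stage failure aborts with the stage name; outputs of completed stages
    are left in place.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # -- inputs -----------------------------------------------------------
        if cfg.prototype_fasta:
            prototype = load_prototype(cfg.prototype_fasta, cfg.prototype_bed)
        else:
            prototype = synthetic_prototype()
        annotation: StructureAnnotation | None = None
        if cfg.structure_shells_tsv:
            annotation = read_structure_annotation(
                cfg.structure_shells_tsv, cfg.structure_regions_tsv
            )
        elif cfg.run_enrichment:
            annotation = synthetic_structure_annotation()

        if cfg.synthetic is not None:
            stage = "simulate"
            syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed + STAGE_OFFSETS["cohort"])
            isolates, truth = generate_cohort(syn, prototype)
            _write_tsv(truth, out / "truth.tsv", cfg)
            _write_tsv(isolates_to_table(isolates), out / "isolates.tsv", cfg)
            stage = "call"
            all_calls = []
            for i, iso in enumerate(isolates):
                pile = simulate_pileup(
                    prototype, truth[truth["isolate_id"] == iso.isolate_id],
                    syn.rdna_coverage, syn.error_rate,
                    seed=cfg.seed + STAGE_OFFSETS["pileup"] + i,
                    isolate_id=iso.isolate_id,
                )
                all_calls.append(call_variants(pile, syn.error_rate, cfg.alpha))
        else:
            stage = "load"
            isolates = read_isolate_metadata(cfg.metadata_tsv)
            by_id = {iso.isolate_id: iso for iso in isolates}
            missing = set(cfg.vcf_paths) - set(by_id)
            if missing:
                raise ConfigError(f"VCFs for isolates absent from metadata: {sorted(missing)}")
            isolates = [by_id[i] for i in sorted(cfg.vcf_paths)]
            all_calls = [
                read_variant_calls(cfg.vcf_paths[iso.isolate_id], iso.isolate_id, prototype)
                for iso in isolates
            ]

        # -- filter -----------------------------------------------------------
        stage = "filter"
        kept_calls = []
        report_rows = []
        for iso, calls in zip(isolates, all_calls):
            kept, report = apply_filter_cascade(
                calls, prototype, iso.copy_estimate, cfg.filter
            )
            kept_calls.extend(kept)
            for rule, count in report.removed.items():
                log.info("filter %s %s removed=%d", iso.isolate_id, rule, count)
            report_rows.append({"isolate_id": iso.isolate_id,
                                "input": report.input_total,
                                "output": report.output_total,
                                **report.removed})
        write_variant_calls(
            kept_calls, out / "filtered.vcf", prototype=prototype,
            meta={"rdnadiv_seed": cfg.seed, "rdnadiv_config": cfg.config_hash()},
        )
        _write_tsv(pd.DataFrame(report_rows), out / "filter_report.tsv", cfg)
        table = calls_to_table(kept_calls)
        niche_of = {iso.isolate_id: iso.niche for iso in isolates}
        copies_of = {iso.isolate_id: iso.total_copies for iso in isolates}

        # -- analyses ---------------------------------------------------------
        if cfg.run_entropy:
            stage = "entropy"
            _write_tsv(
                diversity.entropy_profile(table, copies_of, prototype),
                out / "entropy.tsv", cfg,
            )
            _write_tsv(diversity.summarize_elements(table, prototype),
                       out / "element_summary.tsv", cfg)
            sharing, sharing_tests = diversity.sharing_distribution(table, prototype)
            _write_tsv(sharing, out / "sharing.tsv", cfg)
            _write_tsv(sharing_tests, out / "sharing_tests.tsv", cfg)
        if cfg.run_cooccurrence:
            stage = "cooccurrence"
            profiles = find_coupled_pairs(table, niche_of, cfg.cooccurrence)
            _write_tsv(pairs_to_table(profiles), out / "coupled_pairs.tsv", cfg)
        if cfg.run_enrichment and annotation is not None:
            stage = "enrichment"
            tallies = selection.all_shell_tallies(table, annotation, prototype)
            shells = pd.concat([t.to_table(sentinel=True) for t in tallies],
                               ignore_index=True)
            _write_tsv(shells, out / "shell_tallies.tsv", cfg)
            _write_tsv(selection.shell_skew_test(tallies), out / "shell_tests.tsv", cfg)
            for region in ("ES", "CNE"):
                if region in annotation.region_sets:
                    tally = selection.region_enrichment(table, annotation, prototype, region)
                    _write_tsv(tally.per_cutoff, out / f"enrichment_{region}.tsv", cfg)
        stage = "copy_number"
        if len({iso.habitat for iso in isolates}) >= 2:
            summary, pairwise = group_median_copies(isolates, "habitat")
            _write_tsv(summary, out / "copies_by_habitat.tsv", cfg)
            _write_tsv(pairwise, out / "copies_by_habitat_tests.tsv", cfg)

        manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                    "n_isolates": len(isolates), "n_filtered_calls": len(kept_calls)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
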
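"""End-to-end pipeline driver: simulate -> filter -> quantify -> test -> enrich.

Mirrors the stage order of a two-library expression study.  All stage
parameters live in one :class:`PipelineConfig` (built from a YAML file or a
plain dict); all randomness is derived from its single seed, so a run is
fully reproducible and two runs with the same config are byte-identical.
A manifest recording package/library versions, every parameter, and the
SHA-256 checksum of each written artifact is placed next to the outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import dgepipe
from dgepipe import io as dio
from dgepipe.dge import call_degs
from dgepipe.enrichment import enrich_terms
from dgepipe.fastq_filter import FilterPolicy, filter_reads
from dgepipe.quantification import rpkm_table
from dgepipe.synthetic import (
    FastqSpec,
    QualityModel,
    SimulationSpec,
    generate_annotation,
    generate_count_tables,
    generate_fastq,
)

__all__ = ["PipelineConfig", "run_pipeline"]

_ALLOWED_TOP = {"seed", "out_dir", "simulate", "fastq", "dge", "enrichment"}
_ALLOWED_SIMULATE = {
    "n_genes",
    "library_totals",
    "de_fraction",
    "fold_change",
    "gene_length_range",
    "expression_range",
    "overdispersion",
}
_ALLOWED_FASTQ = {
    "n_reads",
    "read_length",
    "n_fraction_per_read",
    "contamination_rate",
    "quality",
    "policy",
}
_ALLOWED_QUALITY = {"mean", "sd", "low_read_rate", "low_mean"}
_ALLOWED_DGE = {"fdr_threshold", "log2_threshold", "ratio_basis"}
_ALLOWED_ENRICH = {
    "annotation",
    "n_terms",
    "n_enriched",
    "background_rate",
    "enriched_rate",
    "mode",
}


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated stage parameters for one pipeline run."""

    seed: int
    simulate: dict
    dge: dict = field(default_factory=dict)
    fastq: dict | None = None
    enrichment: dict | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        _check_keys(self.simulate, _ALLOWED_SIMULATE, "simulate")
        for key in ("n_genes", "library_totals", "de_fraction", "fold_change"):
            if key not in self.simulate:
                raise ValueError(f"simulate section missing {key!r}")
        _check_keys(self.dge, _ALLOWED_DGE, "dge")
        if self.fastq is not None:
            _check_keys(self.fastq, _ALLOWED_FASTQ, "fastq")
            if "n_reads" not in self.fastq:
                raise ValueError("fastq section missing 'n_reads'")
            _check_keys(self.fastq.get("quality", {}), _ALLOWED_QUALITY, "fastq.quality")
        if self.enrichment is not None:
            _check_keys(self.enrichment, _ALLOWED_ENRICH, "enrichment")
            if "annotation" not in self.enrichment and "n_terms" not in self.enrichment:
                raise ValueError(
                    "enrichment enabled but no annotation source: supply "
                    "'annotation' (a TSV path) or 'n_terms' (simulate one)"
                )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, _ALLOWED_TOP, "config")
        return cls(
            seed=raw.get("seed"),
            simulate=raw.get("simulate", {}),
            dge=raw.get("dge", {}),
            fastq=raw.get("fastq"),
            enrichment=raw.get("enrichment"),
            out_dir=raw.get("out_dir"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def _child_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir=None) -> Path:
    """Run every configured stage and write artifacts plus a manifest.

    Returns the artifact directory.  Written files (as configured):
    ``counts.tsv`` (+ truth), ``reads.fastq``/``reads.clean.fastq`` and
    ``filter_report.tsv``, ``rpkm.tsv``, ``dge.tsv``, ``annotation.tsv``
    (+ truth) and ``enrichment.tsv``, ``manifest.json``.
    """
    out = Path(out_dir or config.out_dir or "dgepipe_run")
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 3)
    artifacts: list[Path] = []

    sim = dict(config.simulate)
    spec = SimulationSpec(
        n_genes=int(sim["n_genes"]),
        library_totals=tuple(int(v) for v in sim["library_totals"]),
        de_fraction=float(sim["de_fraction"]),
        fold_changes=sim["fold_change"],
        seed=seeds[0],
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in sim.items()
            if k in ("gene_length_range", "expression_range", "overdispersion")
        },
    )
    table, truth = generate_count_tables(spec)
    counts_path = out / "counts.tsv"
    dio.write_count_table(table, counts_path)
    truth_path = out / ("counts" + dio.TRUTH_SUFFIX)
    dio.write_tsv(truth, truth_path)
    artifacts += [counts_path, truth_path]

    if config.fastq is not None:
        fq = dict(config.fastq)
        policy_name = fq.pop("policy", "transcriptome")
        quality = QualityModel(**fq.pop("quality", {}))
        fastq_spec = FastqSpec(seed=seeds[1], quality=quality, **{
            "n_reads": int(fq["n_reads"]),
            **{k: fq[k] for k in fq if k != "n_reads"},
        })
        policy = getattr(FilterPolicy, policy_name)(
            adaptor=fastq_spec.adaptor_sequence
        )
        reads, labels = generate_fastq(fastq_spec, policy)
        raw_path = out / "reads.fastq"
        dio.write_fastq(reads, raw_path)
        retained, report = filter_reads(reads, policy)
        clean_path = out / "reads.clean.fastq"
        dio.write_fastq(retained, clean_path)
        report_path = out / "filter_report.tsv"
        dio.write_tsv(pd.DataFrame([report.as_dict()]), report_path)
        labels_path = out / ("reads" + dio.TRUTH_SUFFIX)
        dio.write_tsv(
            pd.DataFrame(
                {"read_id": [r.identifier for r in reads], "label": labels}
            ),
            labels_path,
        )
        artifacts += [raw_path, clean_path, report_path, labels_path]

    quant_path = out / "rpkm.tsv"
    dio.write_tsv(rpkm_table(table), quant_path)
    artifacts.append(quant_path)

    dge_params = dict(config.dge)
    results = call_degs(
        table,
        fdr_threshold=float(dge_params.get("fdr_threshold", 0.001)),
        log2_threshold=float(dge_params.get("log2_threshold", 1.0)),
        ratio_basis=dge_params.get("ratio_basis", "rpkm"),
    )
    dge_path = out / "dge.tsv"
    dio.write_tsv(results, dge_path)
    artifacts.append(dge_path)

    if config.enrichment is not None:
        enr = dict(config.enrichment)
        mode = enr.get("mode", "bonferroni")
        called = results.loc[results["call"] != "not_significant", "gene_id"]
        if "annotation" in enr:
            annotation = dio.read_annotation(enr["annotation"])
        else:
            n_terms = int(enr["n_terms"])
            n_enriched = int(enr.get("n_enriched", 0))
            true_degs = truth.loc[truth["is_de"], "gene_id"].tolist()
            annotation, enriched = generate_annotation(
                n_genes=len(table),
                n_terms=n_terms,
                enriched_terms=[f"T{i:03d}" for i in range(n_enriched)],
                deg_list=true_degs,
                seed=seeds[2],
                background_rate=float(enr.get("background_rate", 0.05)),
                enriched_rate=float(enr.get("enriched_rate", 0.5)),
                gene_ids=table.gene_ids.tolist(),
            )
            ann_path = out / "annotation.tsv"
            dio.write_annotation(annotation, ann_path)
            ann_truth_path = out / ("annotation" + dio.TRUTH_SUFFIX)
            dio.write_tsv(
                pd.DataFrame({"term_id": enriched}), ann_truth_path
            )
            artifacts += [ann_path, ann_truth_path]
        enrichment = enrich_terms(
            annotation,
            deg_list=called.tolist(),
            background=table.gene_ids.tolist(),
            mode=mode,
        )
        enr_path = out / "enrichment.tsv"
        dio.write_tsv(enrichment, enr_path)
        artifacts.append(enr_path)

    manifest = {
        "package": {"name": "dgepipe", "version": dgepipe.__version__},
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "stage_seeds": {"counts": seeds[0], "fastq": seeds[1], "annotation": seeds[2]},
        "parameters": {
            "simulate": config.simulate,
            "fastq": config.fastq,
            "dge": {
                "fdr_threshold": float(dge_params.get("fdr_threshold", 0.001)),
                "log2_threshold": float(dge_params.get("log2_threshold", 1.0)),
                "ratio_basis": dge_params.get("ratio_basis", "rpkm"),
            },
            "enrichment": config.enrichment,
        },
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
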
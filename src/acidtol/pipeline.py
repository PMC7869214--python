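"""Funnel orchestration: scan → union → intersect → filter → regulon → reports.

One :class:`RunConfig` (loadable from a flat YAML file) drives the whole
candidate-gene funnel and the quantitative reports, writing tidy TSVs (one
observation per row) plus a machine-readable stage report.  Default
thresholds reproduce the standard analysis without overrides: runs of >= 3
prolines, high dependence at >= 2 runs or a run of >= 4, URS1 core
consensus TCGGCGGCT scanned on both strands over a 1000-bp promoter
window, qPCR against ACT1 at efficiency 2.0, growth windows of 4 points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import genesets, growth, motifscan, quant, regulon

__all__ = [
    "RunConfig",
    "StageResult",
    "FunnelReport",
    "StageError",
    "run_funnel",
    "run_quant_report",
    "UME6_TE_EXAMPLE",
]

logger = logging.getLogger(__name__)

# Reference worked example for the UME6 translation-efficiency comparison:
# the unstressed TE advantage of the eIF5A-overexpressing strain and each
# strain's mRNA/protein induction by 87 mM acetic acid, as inputs to
# quant.stress_te_gain.
UME6_TE_EXAMPLE = {
    "baseline_te_ratio": 1.67,
    "mrna_fold_control": 1.6,
    "mrna_fold_treated": 2.7,
    "protein_fold_control": 2.4,
    "protein_fold_treated": 4.1,
}


@dataclass
class RunConfig:
    """Flat configuration for a full run; paths may be None to skip stages."""

    out_dir: str = "acidtol_out"
    # motif scan
    fasta: str | None = None
    min_run_len: int = 3
    min_multi_runs: int = 2
    min_long_run: int = 4
    # gene sets
    screens: list[str] = field(default_factory=list)
    aliases: str | None = None
    annotations: str | None = None
    # regulon
    regulon: str | None = None
    promoters: str | None = None
    pattern: str = "TCGGCGGCT"
    both_strands: bool = True
    promoter_window: int = 1000
    # quantification
    cq_table: str | None = None
    target_gene: str | None = None
    reference_gene: str = "ACT1"
    calibrator: str | None = None
    efficiency: float = 2.0
    te_example: bool = True
    # growth / survival
    growth_csv: str | None = None
    growth_window: int = 4
    survival_csv: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class StageResult:
    stage: str
    n_in: int
    n_out: int
    path: str = ""


@dataclass
class FunnelReport:
    stages: list[StageResult] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.n_in, s.n_out, s.path) for s in self.stages],
            columns=["stage", "n_in", "n_out", "path"],
        )

    def size(self, stage: str) -> int:
        for s in self.stages:
            if s.stage == stage:
                return s.n_out
        raise KeyError(stage)


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def run_funnel(config: RunConfig) -> FunnelReport:
    """Execute the candidate-gene funnel; returns stage-by-stage sizes.

    Stages (each skipped when its inputs are absent): proteome motif scan;
    deduplicating union of the screens; intersection of union and
    polyproline genes; high-dependence filter; functional categorization;
    direct-target calling; regulon/tolerance overlap.  On a stage failure a
    ``FAILED`` marker is written next to any partial outputs and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = FunnelReport()
    stage = "setup"
    try:
        alias_map = (
            genesets.AliasMap.from_tsv(config.aliases)
            if config.aliases
            else genesets.AliasMap()
        )

        profiles: list[motifscan.MotifProfile] = []
        if config.fasta:
            stage = "scan"
            records = motifscan.read_protein_fasta(config.fasta)
            profiles = [
                motifscan.profile_protein(
                    r,
                    min_len=config.min_run_len,
                    min_multi_runs=config.min_multi_runs,
                    min_long_run=config.min_long_run,
                )
                for r in records
            ]
            cens = motifscan.census(profiles)
            p1 = _write(motifscan.profiles_to_table(profiles), out / "profiles.tsv")
            _write(motifscan.census_to_table(cens), out / "census.tsv")
            report.stages.append(
                StageResult("scan", len(records), cens.n_with_any_run, p1)
            )

        union_set: genesets.GeneSet | None = None
        if config.screens:
            stage = "union"
            screen_sets = [
                genesets.load_gene_list(p, alias_map) for p in config.screens
            ]
            ures = genesets.consistency_union(screen_sets, name="tolerance")
            union_set = ures.union
            pairs = pd.DataFrame(
                [
                    (a, b, n) for (a, b), n in ures.pairwise_overlaps.items()
                ],
                columns=["set_a", "set_b", "overlap"],
            )
            p2 = _write(pairs, out / "union_overlaps.tsv")
            report.stages.append(
                StageResult(
                    "union", sum(ures.per_source.values()), ures.union_size, p2
                )
            )

        common: genesets.GeneSet | None = None
        if union_set is not None and profiles:
            stage = "common"
            polypro = genesets.GeneSet(
                name="polyproline",
                ids=frozenset(p.protein_id for p in profiles if p.n_runs > 0),
                provenance="motif scan",
            )
            common = genesets.intersect(union_set, polypro, name="common")
            report.stages.append(
                StageResult("common", len(union_set), len(common), "")
            )

            stage = "high_dependence"
            high = genesets.filter_high_dependence(common, profiles)
            members = pd.DataFrame(
                sorted(high.ids), columns=["gene"]
            )
            p3 = _write(members, out / "high_dependence.tsv")
            report.stages.append(
                StageResult("high_dependence", len(common), len(high), p3)
            )

            if config.annotations:
                stage = "categorize"
                ann = genesets.AnnotationMap.from_tsv(config.annotations)
                cat = genesets.categorize(common, ann)
                p4 = _write(cat, out / "categories.tsv")
                report.stages.append(
                    StageResult("categorize", len(common), len(cat), p4)
                )

        if config.regulon and config.promoters:
            stage = "direct_targets"
            table = regulon.read_regulon_tsv(config.regulon)
            promoters = regulon.read_promoter_fasta(
                config.promoters, window=config.promoter_window
            )
            pat = regulon.ConsensusPattern(
                config.pattern, scan_both_strands=config.both_strands
            )
            classified = regulon.classify_direct_targets(table, promoters, pat)
            p5 = _write(classified.to_table(), out / "regulon_classified.tsv")
            report.stages.append(
                StageResult(
                    "direct_targets",
                    len(classified.targets),
                    len(classified.direct_ids),
                    p5,
                )
            )
            if union_set is not None:
                stage = "regulon_overlap"
                ov = regulon.overlap_with_tolerance(classified, union_set)
                p6 = _write(ov.to_table(), out / "regulon_overlap.tsv")
                report.stages.append(
                    StageResult(
                        "regulon_overlap",
                        ov.n_targets,
                        ov.n_targets_in_tolerance,
                        p6,
                    )
                )
                report.stages.append(
                    StageResult(
                        "regulon_overlap_direct",
                        ov.n_direct,
                        ov.n_direct_in_tolerance,
                        p6,
                    )
                )
    except Exception as exc:  # noqa: BLE001 - annotate stage, retain partials
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise StageError(stage, exc) from exc

    _write(report.to_table(), out / "funnel_report.tsv")
    return report


def run_quant_report(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Quantification reports: relative expression, TE gains, growth, survival.

    Returns the tables it writes, keyed by report name.  The TE table
    always carries the bundled UME6 reference row (disable with
    ``te_example=False``); raises :class:`StageError` when a requested
    stage is missing its calibrator or reference.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    stage = "setup"
    try:
        if config.cq_table:
            stage = "relative_expression"
            if not config.calibrator or not config.target_gene:
                raise ValueError("cq_table requires target_gene and calibrator")
            df = pd.read_csv(config.cq_table)
            levels = quant.relative_expression(
                df,
                target_gene=config.target_gene,
                reference_gene=config.reference_gene,
                calibrator_sample=config.calibrator,
                efficiency=config.efficiency,
            )
            tables["relative_expression"] = pd.DataFrame(
                [
                    {
                        "sample": lv.sample,
                        "gene": lv.gene,
                        "level": lv.level,
                        "kind": lv.kind,
                        "calibrator": lv.calibrator,
                    }
                    for lv in levels
                ]
            )
            _write(tables["relative_expression"], out / "relative_expression.tsv")

        if config.te_example:
            stage = "translation_efficiency"
            gain = quant.stress_te_gain(**UME6_TE_EXAMPLE)
            baseline = quant.percent_difference(
                UME6_TE_EXAMPLE["baseline_te_ratio"], 1.0
            )
            tables["te_gain"] = pd.DataFrame(
                [
                    {
                        "comparison": "UME6-reference-unstressed",
                        "te_gain_pct": round(baseline),
                    },
                    {
                        "comparison": "UME6-reference-acetic-acid",
                        "te_gain_pct": round(gain),
                    },
                ]
            )
            _write(tables["te_gain"], out / "te_gain.tsv")

        if config.growth_csv:
            stage = "growth"
            df = pd.read_csv(config.growth_csv)
            rows = []
            for label, grp in df.groupby("label"):
                curve = growth.GrowthCurve(
                    times=grp["time_h"].to_numpy(),
                    od=grp["od600"].to_numpy(),
                    label=str(label),
                )
                gv = growth.growth_variables(curve, window_size=config.growth_window)
                rows.append(
                    {
                        "label": label,
                        "lag_h": gv.lag,
                        "rate_per_h": gv.rate,
                        "efficiency_dOD": gv.efficiency,
                    }
                )
            tables["growth_variables"] = pd.DataFrame(rows)
            _write(tables["growth_variables"], out / "growth_variables.tsv")

        if config.survival_csv:
            stage = "survival"
            df = pd.read_csv(config.survival_csv)
            rows = []
            for label, grp in df.groupby("label"):
                series = growth.SurvivalSeries(
                    times=grp["time_h"].to_numpy(),
                    cfu=grp["cfu"].to_numpy(),
                    label=str(label),
                )
                for t, pct in growth.survival_rate(series):
                    rows.append({"label": label, "time_h": t, "survival_pct": pct})
            tables["survival"] = pd.DataFrame(rows)
            _write(tables["survival"], out / "survival.tsv")
    except Exception as exc:  # noqa: BLE001
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise StageError(stage, exc) from exc
    return tables
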
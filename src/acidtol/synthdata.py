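"""Synthetic inputs with recorded ground truth for every pipeline stage.

Real inputs to this kind of study are a proteome download, supplementary
gene lists from published deletion-collection screens, a regulation
database's target table with promoter sequences, and plate-reader / qPCR /
CFU measurements.  None of those ship with the package; instead every
generator here emulates one of them with *planted*, exactly-known truth so
each analysis stage has a round-trip test: generate → run → compare to the
:class:`TruthBundle`.

Generators take an explicit integer seed (never global random state) and
are byte-deterministic: the same seed reproduces identical outputs.  The
proteome background alphabet excludes proline by default so the planted
motif census is exact; a "realistic" mode admits background prolines and
then the truth census is recomputed from the finished sequences.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSet
from .growth import GrowthCurve, SurvivalSeries
from .motifscan import SequenceRecord, find_proline_runs, pattern_label
from .regulon import (
    EVIDENCE_DOCUMENTED,
    ConsensusPattern,
    PromoterRecord,
    RegulonTable,
    TargetEvidence,
    reverse_complement,
    scan_consensus,
)

__all__ = [
    "TruthBundle",
    "FunnelBundle",
    "simulate_proteome",
    "simulate_screens",
    "simulate_regulon",
    "simulate_growth",
    "simulate_survival",
    "simulate_expression",
    "simulate_fluorescence",
    "simulate_funnel_bundle",
    "write_fasta",
    "DEFAULT_OVERLAP_SPEC",
    "FUNNEL_SCALE",
]

# Amino-acid alphabet without proline: background sequence drawn from these
# letters can never create a spontaneous proline run.
AA_NO_P = "ACDEFGHIKLMNQRSTVWY"

# One consistent solution for three screens of sizes 216 / 650 / 409 whose
# deduplicated union is 1031 genes.  Keys name the membership regions.
DEFAULT_OVERLAP_SPEC: dict[str, int] = {
    "s1_only": 72,
    "s2_only": 490,
    "s3_only": 275,
    "s1_s2": 60,
    "s1_s3": 34,
    "s2_s3": 50,
    "all": 50,
}

# Study-scale funnel defaults: proteome-wide polyproline gene count, the
# screens funnel, and the regulon/tolerance overlap sizes.
FUNNEL_SCALE: dict[str, int] = {
    "universe_size": 6000,
    "n_polyproline": 558,
    "n_common": 85,
    "n_high_dependence_common": 17,
    "n_targets": 1481,
    "n_direct": 170,
    "n_targets_in_tolerance": 176,
    "n_direct_in_tolerance": 24,
}


@dataclass
class TruthBundle:
    """Ground truth serialized next to every generated dataset."""

    seed: int
    motif_census: dict[str, int] | None = None
    motif_labels: dict[str, str] | None = None
    n_polyproline: int | None = None
    n_high_dependence: int | None = None
    screen_region_sizes: dict[str, int] | None = None
    screen_set_sizes: dict[str, int] | None = None
    union_size: int | None = None
    n_common: int | None = None
    n_high_dependence_common: int | None = None
    regulon: dict[str, Any] | None = None
    site_positions: dict[str, list[int]] | None = None
    expression_folds: dict[str, dict[str, float]] | None = None
    abundance: dict[str, float] | None = None
    growth: dict[str, float] | None = None
    death_rate: float | None = None
    category_counts: dict[str, int] | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        with open(path) as fh:
            return cls(**json.load(fh))


def _parse_pattern_label(label: str) -> list[int]:
    """'2×3P+1×4P' -> [3, 3, 4] ('x' accepted for '×')."""
    lengths: list[int] = []
    if not label:
        return lengths
    for part in label.split("+"):
        m = re.fullmatch(r"(\d+)[×x](\d+)P", part)
        if not m:
            raise ValueError(f"cannot parse pattern label part {part!r}")
        lengths.extend([int(m.group(2))] * int(m.group(1)))
    return sorted(lengths)


def _plant_runs(
    length: int, run_lengths: Sequence[int], rng: np.random.Generator,
    background: str = AA_NO_P, background_p_freq: float = 0.0,
) -> str:
    """A random protein of ``length`` with the given proline runs planted.

    Runs are separated from each other by >= 1 non-P residue; placement of
    the separating gaps is random.  Raises if the runs cannot fit.
    """
    total_p = sum(run_lengths)
    n_runs = len(run_lengths)
    min_len = total_p + max(n_runs - 1, 0)
    if length < min_len:
        raise ValueError(
            f"protein of length {length} cannot hold runs {list(run_lengths)}"
        )
    letters = list(background)
    probs = None
    if background_p_freq > 0:
        letters = list(background) + ["P"]
        p_rest = (1.0 - background_p_freq) / len(background)
        probs = [p_rest] * len(background) + [background_p_freq]

    def _bg(n: int) -> str:
        if n == 0:
            return ""
        return "".join(rng.choice(letters, size=n, p=probs))

    if n_runs == 0:
        return _bg(length)

    total_gap = length - total_p
    n_gaps = n_runs + 1
    spare = total_gap - (n_runs - 1)
    extra = rng.multinomial(spare, np.full(n_gaps, 1.0 / n_gaps))
    gaps = [int(extra[0])]
    for i in range(1, n_runs):
        gaps.append(1 + int(extra[i]))
    gaps.append(int(extra[-1]))

    parts = []
    for i, run_len in enumerate(run_lengths):
        parts.append(_bg(gaps[i]))
        parts.append("P" * run_len)
    parts.append(_bg(gaps[-1]))
    seq = "".join(parts)
    assert len(seq) == length
    return seq


def simulate_proteome(
    n_proteins: int = 500,
    length_range: tuple[int, int] = (200, 600),
    pattern_spec: Mapping[str, int] | None = None,
    background_p_freq: float = 0.0,
    seed: int = 0,
    id_prefix: str = "SYN",
) -> tuple[list[SequenceRecord], TruthBundle]:
    """A random proteome with a planted proline-run census.

    ``pattern_spec`` maps a canonical pattern label (e.g. ``"2×3P"``) to the
    number of proteins that should carry exactly that pattern; remaining
    proteins carry no runs.  With ``background_p_freq`` > 0 the background
    may create extra runs, so the recorded truth is recomputed from the
    finished sequences rather than taken from the plan.
    """
    pattern_spec = dict(pattern_spec or {})
    n_planted = sum(pattern_spec.values())
    if n_planted > n_proteins:
        raise ValueError(
            f"pattern_spec plants {n_planted} proteins but only "
            f"{n_proteins} requested"
        )
    rng = np.random.default_rng(seed)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_proteins)
    order = rng.permutation(n_proteins)

    assignments: dict[int, str] = {}
    cursor = 0
    for label, count in sorted(pattern_spec.items()):
        for _ in range(count):
            assignments[int(order[cursor])] = label
            cursor += 1

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for i in range(n_proteins):
        pid = f"{id_prefix}{i:05d}"
        label = assignments.get(i, "")
        runs = _parse_pattern_label(label)
        seq = _plant_runs(
            int(lengths[i]), runs, rng,
            background_p_freq=background_p_freq,
        )
        records.append(SequenceRecord(id=pid, description="synthetic", residues=seq))
        labels[pid] = label

    if background_p_freq > 0:
        # spontaneous runs possible: truth comes from rescanning the output
        labels = {
            r.id: pattern_label(
                run.length for run in find_proline_runs(r.residues)
            )
            for r in records
        }
    census = Counter(lb for lb in labels.values() if lb)
    n_high = sum(
        1 for lb in labels.values()
        if lb and (len(_parse_pattern_label(lb)) >= 2 or max(_parse_pattern_label(lb)) >= 4)
    )
    truth = TruthBundle(
        seed=seed,
        motif_census=dict(sorted(census.items())),
        motif_labels=labels,
        n_polyproline=sum(census.values()),
        n_high_dependence=n_high,
    )
    return records, truth


def write_fasta(records: Sequence[SequenceRecord] | Sequence[PromoterRecord],
                path: str | Path, width: int = 60) -> None:
    """Write records (protein or promoter) as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, PromoterRecord):
                ident, seq = rec.gene, rec.sequence
            else:
                ident, seq = rec.id, rec.residues
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _region_memberships() -> dict[str, tuple[bool, bool, bool]]:
    return {
        "s1_only": (True, False, False),
        "s2_only": (False, True, False),
        "s3_only": (False, False, True),
        "s1_s2": (True, True, False),
        "s1_s3": (True, False, True),
        "s2_s3": (False, True, True),
        "all": (True, True, True),
    }


def simulate_screens(
    universe_size: int = 6000,
    set_sizes: tuple[int, int, int] = (216, 650, 409),
    overlap_spec: Mapping[str, int] | None = None,
    seed: int = 0,
    universe: Sequence[str] | None = None,
) -> tuple[list[GeneSet], TruthBundle]:
    """Three screen gene lists with a planted overlap structure.

    ``overlap_spec`` gives the sizes of the 7 membership regions of a
    three-set Venn diagram (keys as in :data:`DEFAULT_OVERLAP_SPEC`); it
    must be consistent with ``set_sizes`` and fit in the universe.
    """
    spec = dict(overlap_spec or DEFAULT_OVERLAP_SPEC)
    missing = set(_region_memberships()) - set(spec)
    if missing:
        raise ValueError(f"overlap_spec missing regions: {sorted(missing)}")
    implied = (
        spec["s1_only"] + spec["s1_s2"] + spec["s1_s3"] + spec["all"],
        spec["s2_only"] + spec["s1_s2"] + spec["s2_s3"] + spec["all"],
        spec["s3_only"] + spec["s1_s3"] + spec["s2_s3"] + spec["all"],
    )
    if implied != tuple(set_sizes):
        raise ValueError(
            f"overlap_spec implies set sizes {implied}, requested {tuple(set_sizes)}"
        )
    union_size = sum(spec.values())
    if universe is None:
        universe = [f"Y{i:05d}W" for i in range(universe_size)]
    if union_size > len(universe):
        raise ValueError(
            f"union of {union_size} genes exceeds universe of {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(universe), size=union_size, replace=False)
    pool = [universe[int(i)] for i in chosen]

    sets: list[set[str]] = [set(), set(), set()]
    cursor = 0
    for region, membership in _region_memberships().items():
        genes = pool[cursor:cursor + spec[region]]
        cursor += spec[region]
        for k, member in enumerate(membership):
            if member:
                sets[k].update(genes)

    gene_sets = [
        GeneSet(
            name=f"screen{k + 1}",
            ids=frozenset(sets[k]),
            provenance=f"synthetic acid-sensitivity screen {k + 1}",
        )
        for k in range(3)
    ]
    truth = TruthBundle(
        seed=seed,
        screen_region_sizes=spec,
        screen_set_sizes={f"screen{k + 1}": len(sets[k]) for k in range(3)},
        union_size=union_size,
    )
    return gene_sets, truth


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _realize_pattern(pattern: ConsensusPattern, rng: np.random.Generator) -> str:
    from .regulon import IUPAC_CODES

    return "".join(rng.choice(list(IUPAC_CODES[c])) for c in pattern.iupac.upper())


def simulate_regulon(
    n_targets: int = 100,
    n_direct: int = 17,
    promoter_len: int = 1000,
    pattern: ConsensusPattern | str = "TCGGCGGCT",
    seed: int = 0,
    target_ids: Sequence[str] | None = None,
    tf: str = "UME6",
    max_attempts: int = 1000,
) -> tuple[RegulonTable, list[PromoterRecord], TruthBundle]:
    """A TF target table plus promoters with planted consensus sites.

    Exactly ``n_direct`` targets carry >= 1 planted site (strand chosen at
    random when the pattern scans both strands); the remaining promoters
    are rejection-sampled until they contain zero matches on either strand.
    """
    if isinstance(pattern, str):
        pattern = ConsensusPattern(pattern)
    if n_direct > n_targets:
        raise ValueError(f"n_direct {n_direct} > n_targets {n_targets}")
    m = len(pattern.iupac)
    if m > promoter_len:
        raise ValueError(f"pattern ({m} bp) longer than promoter ({promoter_len} bp)")
    rng = np.random.default_rng(seed)
    if target_ids is None:
        target_ids = [f"T{i:05d}" for i in range(n_targets)]
    elif len(target_ids) != n_targets:
        raise ValueError("target_ids length must equal n_targets")
    direct_idx = set(rng.choice(n_targets, size=n_direct, replace=False).tolist())

    promoters: list[PromoterRecord] = []
    site_positions: dict[str, list[int]] = {}
    for i, gene in enumerate(target_ids):
        if i in direct_idx:
            seq = _random_dna(rng, promoter_len)
            pos = int(rng.integers(0, promoter_len - m + 1))
            site = _realize_pattern(pattern, rng)
            if pattern.scan_both_strands and rng.random() < 0.5:
                site = reverse_complement(site)
            seq = seq[:pos] + site + seq[pos + m:]
            prom = PromoterRecord(gene=gene, sequence=seq, window=promoter_len)
            site_positions[gene] = [pos + 1]
        else:
            for _ in range(max_attempts):
                seq = _random_dna(rng, promoter_len)
                prom = PromoterRecord(gene=gene, sequence=seq, window=promoter_len)
                if not scan_consensus(prom, pattern):
                    break
            else:
                raise RuntimeError(
                    f"could not sample a match-free promoter for {gene} in "
                    f"{max_attempts} attempts; use longer promoters or a less "
                    "degenerate pattern"
                )
        promoters.append(prom)

    table = RegulonTable(
        tf=tf,
        targets=[TargetEvidence(g, EVIDENCE_DOCUMENTED) for g in target_ids],
    )
    truth = TruthBundle(
        seed=seed,
        regulon={
            "tf": tf,
            "n_targets": n_targets,
            "n_direct": n_direct,
            "direct_targets": sorted(target_ids[i] for i in direct_idx),
            "pattern": pattern.iupac,
        },
        site_positions=site_positions,
    )
    return table, promoters, truth


def simulate_growth(
    lag: float = 2.0,
    rate: float = 0.35,
    od0: float = 0.05,
    capacity: float = 4.0,
    noise_sd: float = 0.0,
    sampling_dt: float = 1.0,
    horizon: float = 48.0,
    seed: int = 0,
    label: str = "sim",
) -> tuple[GrowthCurve, TruthBundle]:
    """Three-phase growth curve: flat lag, then logistic rise to capacity.

    od(t) = od0 for t < lag, afterwards the logistic solution with
    intrinsic rate ``rate`` starting from od0; multiplicative Gaussian
    noise with sd ``noise_sd`` mimics an OD reader.  The default capacity
    (4.0) and inoculum (0.05) are shake-flask-like; rate 0.35/h is a
    healthy yeast culture in synthetic complete medium; hourly sampling
    matches periodic OD monitoring of flask cultures (and the 4-point
    regression window of the extractor then spans 3 h of exponential
    phase).
    """
    for name, v in [("rate", rate), ("od0", od0), ("capacity", capacity),
                    ("sampling_dt", sampling_dt), ("horizon", horizon)]:
        if v < 0 or (v <= 0 and name != "rate"):
            raise ValueError(f"{name} must be positive, got {v}")
    if lag < 0:
        raise ValueError(f"lag must be >= 0, got {lag}")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, horizon + sampling_dt / 2, sampling_dt)
    tau = np.maximum(times - lag, 0.0)
    if rate > 0:
        od = capacity / (1.0 + ((capacity - od0) / od0) * np.exp(-rate * tau))
    else:
        od = np.full_like(times, od0)
    if noise_sd > 0:
        od = od * (1.0 + rng.normal(0.0, noise_sd, size=od.shape))
        od = np.maximum(od, 1e-3)
    curve = GrowthCurve(times=times, od=od, label=label)
    truth = TruthBundle(
        seed=seed,
        growth={"lag": lag, "rate": rate, "od0": od0, "capacity": capacity,
                "noise_sd": noise_sd},
    )
    return curve, truth


def simulate_survival(
    times: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0),
    cfu0: float = 1e6,
    death_rate: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "sim",
) -> tuple[SurvivalSeries, TruthBundle]:
    """Exponential-death CFU series: cfu(t) = cfu0 · exp(−k·t) (+ noise)."""
    if cfu0 <= 0:
        raise ValueError(f"cfu0 must be > 0, got {cfu0}")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    cfu = cfu0 * np.exp(-death_rate * t)
    if noise_sd > 0:
        cfu = cfu * (1.0 + rng.normal(0.0, noise_sd, size=cfu.shape))
        cfu = np.maximum(cfu, 0.0)
    series = SurvivalSeries(times=t, cfu=cfu, label=label)
    truth = TruthBundle(seed=seed, death_rate=death_rate,
                        extras={"cfu0": cfu0, "noise_sd": noise_sd})
    return series, truth


def simulate_expression(
    true_folds: Mapping[str, Mapping[str, float]],
    reference_gene: str = "ACT1",
    calibrator_sample: str | None = None,
    cq_ref_base: float = 15.0,
    cq_target_base: float = 20.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    efficiency: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Cq table for planted expression folds.

    ``true_folds`` maps sample -> {gene: fold relative to the calibrator};
    the calibrator (first sample if not named) is forced to fold 1.  Target
    Cq is lowered by log_E(fold) relative to a per-gene base cycle, with
    Gaussian read noise of ``noise_sd`` cycles on every well.
    """
    samples = list(true_folds)
    if not samples:
        raise ValueError("true_folds is empty")
    calibrator = calibrator_sample or samples[0]
    if calibrator not in true_folds:
        raise ValueError(f"calibrator {calibrator!r} not among samples")
    rng = np.random.default_rng(seed)
    log_eff = np.log(efficiency)
    rows = []
    folds_out: dict[str, dict[str, float]] = {}
    for s in samples:
        genes = dict(true_folds[s])
        folds_out[s] = {}
        for rep in range(1, n_replicates + 1):
            rows.append({
                "sample": s, "gene": reference_gene, "replicate": rep,
                "cq": cq_ref_base + rng.normal(0.0, noise_sd),
            })
        for g, fold in genes.items():
            if fold <= 0:
                raise ValueError(f"fold must be > 0, got {fold} for {s}/{g}")
            eff_fold = 1.0 if s == calibrator else fold
            folds_out[s][g] = eff_fold
            for rep in range(1, n_replicates + 1):
                cq = cq_target_base - np.log(eff_fold) / log_eff
                rows.append({
                    "sample": s, "gene": g, "replicate": rep,
                    "cq": cq + rng.normal(0.0, noise_sd),
                })
    df = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "cq"])
    truth = TruthBundle(
        seed=seed,
        expression_folds=folds_out,
        extras={"reference_gene": reference_gene, "calibrator": calibrator,
                "noise_sd": noise_sd, "n_replicates": n_replicates,
                "efficiency": efficiency},
    )
    return df, truth


def simulate_fluorescence(
    true_abundance: Mapping[str, float],
    od600: Mapping[str, float],
    fi_per_unit: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Plate readings: FI = abundance × OD600 × fi_per_unit × (1 + noise)."""
    if set(true_abundance) != set(od600):
        raise ValueError("true_abundance and od600 must cover the same samples")
    rng = np.random.default_rng(seed)
    rows = []
    for s in true_abundance:
        fi = true_abundance[s] * od600[s] * fi_per_unit
        if noise_sd > 0:
            fi *= 1.0 + rng.normal(0.0, noise_sd)
        rows.append({"sample": s, "od600": od600[s], "FI": fi})
    df = pd.DataFrame(rows, columns=["sample", "od600", "FI"])
    truth = TruthBundle(
        seed=seed, abundance=dict(true_abundance),
        extras={"fi_per_unit": fi_per_unit, "noise_sd": noise_sd},
    )
    return df, truth


# --------------------------------------------------------------------------
# Coordinated full-funnel bundle


# Functional categories used for the common-gene annotation fixture;
# mirrors the biological-process groupings typical of this analysis.
FUNNEL_CATEGORIES = [
    "chromatin remodeling",
    "transcriptional regulation",
    "RNA processing",
    "protein modification",
    "intracellular trafficking and sorting",
    "signal transduction",
    "cytoskeleton organization and morphogenesis",
    "cell wall function",
    "metabolism",
    "mitochondrial function",
]

HIGH_DEP_LABELS = ["2×3P", "1×4P", "1×5P", "3×3P", "2×3P+1×4P", "1×6P"]
BACKGROUND_LABELS = ["1×3P", "1×3P", "1×3P", "2×3P", "1×4P", "1×5P"]


@dataclass
class FunnelBundle:
    """All file paths of one generated funnel dataset plus its truth."""

    proteome_fasta: Path
    screen_files: list[Path]
    alias_tsv: Path
    annotation_tsv: Path
    regulon_tsv: Path
    promoter_fasta: Path
    truth_json: Path
    truth: TruthBundle


def simulate_funnel_bundle(
    out_dir: str | Path,
    seed: int = 0,
    universe_size: int = FUNNEL_SCALE["universe_size"],
    n_polyproline: int = FUNNEL_SCALE["n_polyproline"],
    n_common: int = FUNNEL_SCALE["n_common"],
    n_high_dependence_common: int = FUNNEL_SCALE["n_high_dependence_common"],
    set_sizes: tuple[int, int, int] = (216, 650, 409),
    overlap_spec: Mapping[str, int] | None = None,
    n_targets: int = FUNNEL_SCALE["n_targets"],
    n_direct: int = FUNNEL_SCALE["n_direct"],
    n_targets_in_tolerance: int = FUNNEL_SCALE["n_targets_in_tolerance"],
    n_direct_in_tolerance: int = FUNNEL_SCALE["n_direct_in_tolerance"],
    promoter_len: int = 1000,
    pattern: ConsensusPattern | str = "TCGGCGGCT",
    protein_length_range: tuple[int, int] = (150, 450),
    alias_fraction: float = 0.1,
    seq_seed_offset: int = 1,
) -> FunnelBundle:
    """One coordinated dataset exercising the whole candidate-gene funnel.

    Plants, over a shared gene universe: a proteome in which exactly
    ``n_polyproline`` proteins carry proline runs; three screens whose
    deduplicated union has the planted size; exactly ``n_common`` of the
    polyproline genes inside that union, ``n_high_dependence_common`` of
    them with strong-dependence patterns; and a regulon with planted direct
    flags and tolerance overlaps.  Every stage size recorded in the
    :class:`TruthBundle` must be recovered exactly by the pipeline.
    """
    if isinstance(pattern, str):
        pattern = ConsensusPattern(pattern)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    universe = [f"Y{i:05d}W" for i in range(universe_size)]

    # --- screens with planted union ------------------------------------
    screens, screen_truth = simulate_screens(
        universe_size=universe_size,
        set_sizes=set_sizes,
        overlap_spec=overlap_spec,
        seed=int(rng.integers(0, 2**31 - 1)),
        universe=universe,
    )
    union_ids = frozenset().union(*(s.ids for s in screens))

    # --- choose polyproline genes: n_common inside the union ------------
    if n_common > min(n_polyproline, len(union_ids)):
        raise ValueError("n_common exceeds polyproline count or union size")
    union_sorted = sorted(union_ids)
    common = [
        union_sorted[int(i)]
        for i in rng.choice(len(union_sorted), size=n_common, replace=False)
    ]
    outside = sorted(set(universe) - union_ids)
    n_outside = n_polyproline - n_common
    if n_outside > len(outside):
        raise ValueError("not enough genes outside the union for the proteome plan")
    extra = [
        outside[int(i)]
        for i in rng.choice(len(outside), size=n_outside, replace=False)
    ]

    labels: dict[str, str] = {}
    high_common = common[:n_high_dependence_common]
    for k, g in enumerate(high_common):
        labels[g] = HIGH_DEP_LABELS[k % len(HIGH_DEP_LABELS)]
    for g in common[n_high_dependence_common:]:
        labels[g] = "1×3P"
    for g in extra:
        labels[g] = BACKGROUND_LABELS[int(rng.integers(0, len(BACKGROUND_LABELS)))]

    # --- proteome over the whole universe -------------------------------
    lengths = rng.integers(
        protein_length_range[0], protein_length_range[1] + 1, size=universe_size
    )
    prot_rng = np.random.default_rng(seed + seq_seed_offset)
    records: list[SequenceRecord] = []
    for i, gene in enumerate(universe):
        runs = _parse_pattern_label(labels.get(gene, ""))
        seq = _plant_runs(int(lengths[i]), runs, prot_rng)
        records.append(SequenceRecord(id=gene, description="synthetic", residues=seq))
    census = Counter(lb for lb in labels.values())

    # --- aliases: a fraction of universe genes get a standard-style name
    n_alias = int(alias_fraction * universe_size)
    alias_idx = rng.choice(universe_size, size=n_alias, replace=False)
    alias_of = {universe[int(i)]: f"GEN{int(i)}" for i in alias_idx}
    alias_rows = [(std, sysname) for sysname, std in alias_of.items()]

    # --- annotations for the common genes (5 left unannotated) ----------
    n_unannotated = min(5, n_common)
    annotated = common[:-n_unannotated] if n_unannotated else list(common)
    ann_rows: list[tuple[str, str]] = []
    cat_counts: Counter[str] = Counter()
    for g in annotated:
        k = 1 + int(rng.random() < 0.3)  # ~30% of genes carry two categories
        cats = rng.choice(len(FUNNEL_CATEGORIES), size=k, replace=False)
        for c in cats:
            ann_rows.append((g, FUNNEL_CATEGORIES[int(c)]))
            cat_counts[FUNNEL_CATEGORIES[int(c)]] += 1
    if n_unannotated:
        cat_counts["unknown function"] = n_unannotated

    # --- regulon: overlaps planted against the union ---------------------
    tol_sorted = sorted(union_ids)
    t_in = [
        tol_sorted[int(i)]
        for i in rng.choice(len(tol_sorted), size=n_targets_in_tolerance,
                            replace=False)
    ]
    non_tol = sorted(set(universe) - union_ids)
    t_out = [
        non_tol[int(i)]
        for i in rng.choice(len(non_tol), size=n_targets - n_targets_in_tolerance,
                            replace=False)
    ]
    # direct targets: n_direct_in_tolerance from the in-tolerance targets
    target_ids = t_in + t_out
    direct_ids = (
        t_in[:n_direct_in_tolerance]
        + t_out[: n_direct - n_direct_in_tolerance]
    )
    direct_set = set(direct_ids)
    order = rng.permutation(len(target_ids))
    target_ids = [target_ids[int(i)] for i in order]
    reg_rng = int(rng.integers(0, 2**31 - 1))
    table, promoters, reg_truth = _regulon_with_chosen_direct(
        target_ids, direct_set, promoter_len, pattern, reg_rng
    )

    # --- write files ------------------------------------------------------
    proteome_fasta = out_dir / "proteome.fasta"
    write_fasta(records, proteome_fasta)
    screen_files = []
    for s in screens:
        p = out_dir / f"{s.name}.txt"
        with open(p, "w") as fh:
            fh.write(f"# synthetic acid-sensitivity screen: {s.name}\n")
            for g in sorted(s.ids):
                fh.write(alias_of.get(g, g) + "\n")  # aliases exercise resolution
        screen_files.append(p)
    alias_tsv = out_dir / "aliases.tsv"
    with open(alias_tsv, "w") as fh:
        for std, sysname in sorted(alias_rows):
            fh.write(f"{std}\t{sysname}\n")
    annotation_tsv = out_dir / "annotations.tsv"
    with open(annotation_tsv, "w") as fh:
        for g, c in sorted(ann_rows):
            fh.write(f"{g}\t{c}\n")
    regulon_tsv = out_dir / "regulon.tsv"
    table.to_table()[["tf", "target", "evidence"]].to_csv(
        regulon_tsv, sep="\t", index=False, header=False
    )
    promoter_fasta = out_dir / "promoters.fasta"
    write_fasta(promoters, promoter_fasta)

    truth = TruthBundle(
        seed=seed,
        motif_census=dict(sorted(census.items())),
        n_polyproline=n_polyproline,
        n_high_dependence=sum(
            1 for lb in labels.values()
            if len(_parse_pattern_label(lb)) >= 2
            or max(_parse_pattern_label(lb), default=0) >= 4
        ),
        screen_region_sizes=screen_truth.screen_region_sizes,
        screen_set_sizes=screen_truth.screen_set_sizes,
        union_size=screen_truth.union_size,
        n_common=n_common,
        n_high_dependence_common=n_high_dependence_common,
        regulon={
            "tf": table.tf,
            "n_targets": n_targets,
            "n_direct": n_direct,
            "n_targets_in_tolerance": n_targets_in_tolerance,
            "n_direct_in_tolerance": n_direct_in_tolerance,
            "pattern": pattern.iupac,
        },
        site_positions=reg_truth.site_positions,
        category_counts=dict(sorted(cat_counts.items())),
    )
    truth_json = out_dir / "truth.json"
    truth.to_json(truth_json)
    return FunnelBundle(
        proteome_fasta=proteome_fasta,
        screen_files=screen_files,
        alias_tsv=alias_tsv,
        annotation_tsv=annotation_tsv,
        regulon_tsv=regulon_tsv,
        promoter_fasta=promoter_fasta,
        truth_json=truth_json,
        truth=truth,
    )


def _regulon_with_chosen_direct(
    target_ids: Sequence[str],
    direct_set: set[str],
    promoter_len: int,
    pattern: ConsensusPattern,
    seed: int,
    max_attempts: int = 1000,
) -> tuple[RegulonTable, list[PromoterRecord], TruthBundle]:
    """Like :func:`simulate_regulon` but with caller-chosen direct targets."""
    rng = np.random.default_rng(seed)
    m = len(pattern.iupac)
    promoters: list[PromoterRecord] = []
    site_positions: dict[str, list[int]] = {}
    for gene in target_ids:
        if gene in direct_set:
            seq = _random_dna(rng, promoter_len)
            pos = int(rng.integers(0, promoter_len - m + 1))
            site = _realize_pattern(pattern, rng)
            if pattern.scan_both_strands and rng.random() < 0.5:
                site = reverse_complement(site)
            seq = seq[:pos] + site + seq[pos + m:]
            promoters.append(PromoterRecord(gene, seq, window=promoter_len))
            site_positions[gene] = [pos + 1]
        else:
            for _ in range(max_attempts):
                seq = _random_dna(rng, promoter_len)
                prom = PromoterRecord(gene, seq, window=promoter_len)
                if not scan_consensus(prom, pattern):
                    break
            else:
                raise RuntimeError(f"no match-free promoter for {gene}")
            promoters.append(prom)
    table = RegulonTable(
        tf="UME6",
        targets=[TargetEvidence(g, EVIDENCE_DOCUMENTED) for g in target_ids],
    )
    truth = TruthBundle(
        seed=seed,
        regulon={"tf": "UME6", "n_targets": len(target_ids),
                 "n_direct": len(direct_set),
                 "direct_targets": sorted(direct_set),
                 "pattern": pattern.iupac},
        site_positions=site_positions,
    )
    return table, promoters, truth
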
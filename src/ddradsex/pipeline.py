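"""End-to-end orchestration: simulate -> process -> assemble -> scan -> decide.

Also provides the cohort summary (per-individual read/locus statistics with
per-sex aggregates, in the presentation style of the study's sequencing
table: means truncated to whole read pairs) and an in-memory discovery
driver used for replicate studies where disk artifacts are not needed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import assembly as asm
from . import decide as dec
from . import reads as rd
from . import sexlink as sx
from . import synth as sy

logger = logging.getLogger("ddradsex")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ScanParams:
    min_presence_frac: float = 1.0
    ratio_window: tuple[float, float] = (0.3, 0.7)
    min_autosomal_loci: int = 50
    subset_sizes: tuple[int, ...] = (1, 2, 4, 8)
    replicates: int = 20


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run byte-for-byte."""

    genome: sy.GenomeSpec = field(default_factory=sy.GenomeSpec)
    sim: sy.SimConfig = field(default_factory=sy.SimConfig)
    demux: rd.DemuxParams = field(default_factory=rd.DemuxParams)
    assembly: asm.AssemblyParams = field(default_factory=asm.AssemblyParams)
    scan: ScanParams = field(default_factory=ScanParams)
    n_females: int = 8
    n_males: int = 8
    error_rate: float = 0.001
    panel_females: int = 10
    panel_males: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("enzyme5", "enzyme3"):
            d["sim"][key] = dataclasses.asdict(getattr(self.sim, key))
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict = {}
        if "genome" in raw:
            g = dict(raw.pop("genome"))
            if "locus_length_window" in g:
                g["locus_length_window"] = tuple(g["locus_length_window"])
            kwargs["genome"] = sy.GenomeSpec(**g)
        if "sim" in raw:
            s = dict(raw.pop("sim"))
            for key in ("enzyme5", "enzyme3"):
                if key in s and isinstance(s[key], Mapping):
                    s[key] = sy.Enzyme(**s[key])
            kwargs["sim"] = sy.SimConfig(**s)
        if "demux" in raw:
            kwargs["demux"] = rd.DemuxParams(**raw.pop("demux"))
        if "assembly" in raw:
            kwargs["assembly"] = asm.AssemblyParams(**raw.pop("assembly"))
        if "scan" in raw:
            s = dict(raw.pop("scan"))
            for key in ("ratio_window", "subset_sizes"):
                if key in s:
                    s[key] = tuple(s[key])
            kwargs["scan"] = ScanParams(**s)
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)


def default_config() -> RunConfig:
    """The bundled default study design: 8F + 8M, 200 autosomal + 5 W loci."""
    return RunConfig()


# ---------------------------------------------------------------------------
# Cohort summary (sequencing-table style)
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """Per-individual statistics with per-sex aggregates of filtered reads.

    Means are truncated (floored) to whole read pairs, matching the
    presentation convention of the study's sequencing summary table.
    """

    rows: pd.DataFrame
    per_sex: dict[str, dict[str, int]]
    total_filtered_reads: int


def summarize_cohort(rows: pd.DataFrame) -> CohortSummary:
    """Aggregate a per-individual table with columns individual, sex,
    filtered_reads (and optionally loci/depth columns)."""
    required = {"individual", "sex", "filtered_reads"}
    if not required.issubset(rows.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    sexes = set(rows["sex"])
    if not sexes.issubset({"female", "male"}) or len(sexes) == 0:
        raise ValueError("sex column must contain 'female'/'male'")
    per_sex = {}
    for sex, group in rows.groupby("sex"):
        reads = group["filtered_reads"].astype(np.int64)
        per_sex[sex] = {
            "n": int(len(reads)),
            "mean": int(math.floor(reads.sum() / len(reads))),
            "min": int(reads.min()),
            "max": int(reads.max()),
        }
    return CohortSummary(
        rows=rows.reset_index(drop=True),
        per_sex=per_sex,
        total_filtered_reads=int(rows["filtered_reads"].astype(np.int64).sum()),
    )


def load_table1() -> pd.DataFrame:
    """The packaged 20-individual known-sex ddRAD sequencing summary fixture."""
    path = resources.files("ddradsex").joinpath("data/table1.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# In-memory discovery driver
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryResult:
    """Everything a planted-truth recovery analysis needs from one run."""

    reference: sy.ReferenceSet
    individuals: list[sy.IndividualSpec]
    process: rd.ProcessResult
    per_individual_loci: dict[str, list[asm.IndividualLocus]]
    catalog: list[asm.CatalogLocus]
    matrix: sx.PresenceMatrix
    stages: dict[str, sx.CandidateSet]
    verdict: dec.SystemCall
    truth_by_catalog_id: dict

    def recovered_sex_limited(self) -> tuple[set, set]:
        """(planted sex-limited locus ids recovered at the depth stage,
        final-stage candidate ids with no planted sex-limited source)."""
        limited = set(self.reference.sex_limited_ids())
        final = self.stages["depth"]
        het = self.reference.spec.heterogametic_sex
        ids = final.female_specific if het == "female" else final.male_specific
        hits = {self.truth_by_catalog_id.get(c) for c in ids}
        recovered = hits & limited
        spurious = {c for c in ids if self.truth_by_catalog_id.get(c) not in limited}
        return recovered, spurious

    def exact_recovery(self) -> bool:
        """True iff the final cascade equals the planted sex-limited set with
        nothing spurious in either direction."""
        limited = set(self.reference.sex_limited_ids())
        final = self.stages["depth"]
        het = self.reference.spec.heterogametic_sex
        carrier = final.female_specific if het == "female" else final.male_specific
        other = final.male_specific if het == "female" else final.female_specific
        recovered, spurious = self.recovered_sex_limited()
        return recovered == limited and not spurious and len(other) == 0 and len(carrier) == len(limited)


def _truth_by_catalog(catalog: Sequence[asm.CatalogLocus], ref: sy.ReferenceSet,
                      config: sy.SimConfig) -> dict:
    """Map catalog loci to planted locus ids via the read-visible sequences."""
    view_to_id: dict[str, str] = {}
    for locus in ref.loci:
        for allele in locus.alleles:
            view_to_id[sy.stitched_view(allele, config)] = locus.locus_id
    mapping = {}
    for c in catalog:
        hit = view_to_id.get(c.consensus)
        if hit is None:
            for m in c.members.values():
                for a in m.alleles:
                    if a in view_to_id:
                        hit = view_to_id[a]
                        break
                if hit:
                    break
        mapping[c.catalog_id] = hit
    return mapping


def discover(config: RunConfig, mean_depths: Sequence[float] | None = None) -> DiscoveryResult:
    """Run the whole discovery cascade in memory for one seeded study."""
    rng = np.random.default_rng(config.seed)
    ref = sy.simulate_reference(config.genome, rng, config.sim)
    cohort = sy.make_cohort(
        ref, config.n_females, config.n_males, config.sim, rng,
        error_rate=config.error_rate, mean_depths=mean_depths,
    )
    r1, r2 = sy.simulate_read_records(ref, cohort, config.sim)
    demux = dataclasses.replace(
        config.demux, barcode_map={i.barcode: i.individual_id for i in cohort}
    )
    processed = rd.process_read_pairs(zip(r1, r2), demux, config.sim.enzyme5, config.sim.enzyme3)
    per_individual = {
        ind: asm.depth_outlier_filter(
            asm.build_stacks(seqs, config.assembly), config.assembly.depth_sd_ceiling
        )
        for ind, seqs in processed.assigned.items()
    }
    catalog = asm.build_catalog(per_individual, config.assembly)
    sexes = {i.individual_id: i.sex for i in cohort}
    matrix = sx.presence_matrix_from_catalog(catalog, sexes)
    stages = sx.run_cascade(
        matrix,
        min_presence_frac=config.scan.min_presence_frac,
        ratio_window=config.scan.ratio_window,
        min_autosomal_loci=config.scan.min_autosomal_loci,
    )
    truth_map = _truth_by_catalog(catalog, ref, config.sim)

    final = stages["depth"]
    marker_ids = list(final.female_specific) + list(final.male_specific)
    if marker_ids:
        limited = set(ref.sex_limited_ids())
        marker_truth = {}
        for cid in marker_ids:
            src = truth_map.get(cid)
            if src in limited:
                marker_truth[cid] = (
                    dec.FEMALE_SPECIFIC if ref.spec.heterogametic_sex == "female" else dec.MALE_SPECIFIC
                )
            else:
                marker_truth[cid] = "autosomal"
        panel_individuals = (
            [(f"PF{i:02d}", "female") for i in range(config.panel_females)]
            + [(f"PM{i:02d}", "male") for i in range(config.panel_males)]
        )
        panel = dec.simulate_panel(marker_truth, panel_individuals, rng=rng)
        verdict = dec.infer_system(dec.classify_panel(panel))
    else:
        verdict = dec.SystemCall("inconclusive", (), {})
    return DiscoveryResult(
        reference=ref,
        individuals=cohort,
        process=processed,
        per_individual_loci=per_individual,
        catalog=catalog,
        matrix=matrix,
        stages=stages,
        verdict=verdict,
        truth_by_catalog_id=truth_map,
    )


def recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Replicate the discovery cascade across seeds and score planted-truth
    recovery.  One row per seed with per-stage candidate counts, whether the
    final set equals the planted sex-limited loci exactly, and the panel
    verdict."""
    rows = []
    for i in range(n_seeds):
        cfg = config or RunConfig()
        cfg = dataclasses.replace(cfg, seed=int(base_seed + i),
                                  sim=dataclasses.replace(cfg.sim, seed=int(base_seed + i)))
        result = discover(cfg)
        het = cfg.genome.heterogametic_sex
        stage_counts = {}
        for stage in ("presence", "zygosity", "depth"):
            nf, nm = result.stages[stage].counts()
            stage_counts[f"{stage}_female"] = nf
            stage_counts[f"{stage}_male"] = nm
        rows.append(
            {
                "seed": int(base_seed + i),
                **stage_counts,
                "planted": len(result.reference.sex_limited_ids()),
                "exact_recovery": result.exact_recovery(),
                "verdict": result.verdict.verdict,
                "expected_verdict": cfg.genome.system,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Disk pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage, writing all intermediate artifacts to ``out_dir``.

    Deterministic for a fixed config (identical reruns produce identical
    files).  Returns a summary dict which is also written as verdict.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        logger.info("parameters: %s", json.dumps(config.to_dict()))

        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim_dir = out / "sim"
        rng = np.random.default_rng(config.seed)
        ref = sy.simulate_reference(config.genome, rng, config.sim)
        cohort = sy.make_cohort(
            ref, config.n_females, config.n_males, config.sim, rng, error_rate=config.error_rate
        )
        paths = sy.simulate_reads(ref, cohort, config.sim, sim_dir)
        logger.info("simulated %d loci for %d individuals", len(ref.loci), len(cohort))

        # --- process ------------------------------------------------------
        stage = "process"
        proc_dir = out / "process"
        proc_dir.mkdir(exist_ok=True)
        demux = dataclasses.replace(
            config.demux, barcode_map={i.barcode: i.individual_id for i in cohort}
        )
        pairs = rd.read_fastq_pairs(paths["r1"], paths["r2"])
        processed = rd.process_read_pairs(
            pairs, demux, config.sim.enzyme5, config.sim.enzyme3, keep_records=True
        )
        processed.report.to_csv(proc_dir / "demux_report.tsv", sep="\t", index=False)
        assert processed.records is not None
        for ind, records in processed.records.items():
            rd.write_fastq(
                [rd.FastqRecord(r.read_id, r.sequence, r.qualities) for r in records],
                proc_dir / f"{ind}.stitched.fastq.gz",
            )

        # --- assemble -----------------------------------------------------
        stage = "assemble"
        asm_dir = out / "assembly"
        asm_dir.mkdir(exist_ok=True)
        per_individual = {}
        for ind in sorted(processed.assigned):
            loci = asm.depth_outlier_filter(
                asm.build_stacks(processed.assigned[ind], config.assembly),
                config.assembly.depth_sd_ceiling,
            )
            per_individual[ind] = loci
            asm.loci_to_frame(loci).to_csv(asm_dir / f"{ind}.loci.tsv", sep="\t", index=False)
        catalog = asm.build_catalog(per_individual, config.assembly)
        asm.catalog_to_frame(catalog).to_csv(asm_dir / "catalog.tsv", sep="\t", index=False)
        matches = asm.matches_to_frame(catalog)
        matches.to_csv(asm_dir / "matches.tsv", sep="\t", index=False)
        asm.write_catalog_fasta(catalog, asm_dir / "catalog.fasta")
        logger.info("catalog of %d loci from %d individuals", len(catalog), len(per_individual))

        # --- scan ---------------------------------------------------------
        stage = "scan"
        scan_dir = out / "scan"
        scan_dir.mkdir(exist_ok=True)
        sexes = {i.individual_id: i.sex for i in cohort}
        matrix = sx.presence_matrix_from_catalog(catalog, sexes)
        stages = sx.run_cascade(
            matrix,
            min_presence_frac=config.scan.min_presence_frac,
            ratio_window=config.scan.ratio_window,
            min_autosomal_loci=config.scan.min_autosomal_loci,
        )
        sx.candidates_to_frame(stages, matrix).to_csv(scan_dir / "candidates.tsv", sep="\t", index=False)
        sizes = [n for n in config.scan.subset_sizes
                 if n <= min(config.n_females, config.n_males)]
        sat_rng = np.random.default_rng(config.seed + 1)
        curve = sx.saturation_curve(matrix, sizes, config.scan.replicates, sat_rng)
        curve.to_csv(scan_dir / "saturation.tsv", sep="\t", index=False)
        sx.saturation_summary(curve).to_csv(scan_dir / "saturation_summary.tsv", sep="\t", index=False)
        sx.plot_saturation(curve, scan_dir / "saturation.png")
        for name, cand in stages.items():
            logger.info("stage %s: %d female-specific, %d male-specific", name, *cand.counts())

        # --- decide -------------------------------------------------------
        stage = "decide"
        dec_dir = out / "decide"
        dec_dir.mkdir(exist_ok=True)
        truth_map = _truth_by_catalog(catalog, ref, config.sim)
        final = stages["depth"]
        marker_ids = list(final.female_specific) + list(final.male_specific)
        if marker_ids:
            limited = set(ref.sex_limited_ids())
            het_class = dec.FEMALE_SPECIFIC if ref.spec.heterogametic_sex == "female" else dec.MALE_SPECIFIC
            marker_truth = {
                cid: (het_class if truth_map.get(cid) in limited else "autosomal")
                for cid in marker_ids
            }
            panel_individuals = (
                [(f"PF{i:02d}", "female") for i in range(config.panel_females)]
                + [(f"PM{i:02d}", "male") for i in range(config.panel_males)]
            )
            panel = dec.simulate_panel(marker_truth, panel_individuals, rng=np.random.default_rng(config.seed + 2))
            dec.panel_report(panel).to_csv(dec_dir / "panel_report.tsv", sep="\t", index=False)
            verdict = dec.infer_system(dec.classify_panel(panel))
        else:
            verdict = dec.SystemCall("inconclusive", (), {})
        logger.info("verdict: %s", verdict.verdict)

        # --- summarize ----------------------------------------------------
        stage = "summarize"
        rows = []
        for ind in cohort:
            loci = per_individual[ind.individual_id]
            retained = int(
                processed.report.set_index("individual").loc[ind.individual_id, "retained"]
            )
            rows.append(
                {
                    "individual": ind.individual_id,
                    "barcode": ind.barcode,
                    "sex": ind.sex,
                    "filtered_reads": retained,
                    "loci_assembled": len(loci),
                    "mean_depth": float(np.mean([l.depth for l in loci])) if loci else 0.0,
                }
            )
        cohort_df = pd.DataFrame(rows)
        summary = summarize_cohort(cohort_df)
        cohort_df.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

        result = {
            "verdict": verdict.verdict,
            "supporting_markers": [str(m) for m in verdict.supporting_marker_ids],
            "stage_counts": {name: dict(zip(("female", "male"), cand.counts()))
                             for name, cand in stages.items()},
            "catalog_size": len(catalog),
            "planted_sex_limited": len(ref.sex_limited_ids()),
            "per_sex_filtered_reads": summary.per_sex,
            "total_filtered_reads": summary.total_filtered_reads,
        }
        with open(out / "verdict.json", "w") as handle:
            json.dump(result, handle, indent=2)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
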
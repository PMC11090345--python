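"""End-to-end per-chromosome analysis.

For every chromosome: compute the MIC profile, build the feature-set
configurations (entire feature set, fixed MIC thresholds, optionally a
threshold learned jointly across all chromosomes), cluster the 2n unlabeled
samples under each configuration and algorithm, and score the result
against the held-out labels.  Chromosomes are processed in isolation (no
cross-chromosome pooling); the learned threshold is the only cross-
chromosome quantity, mirroring a single global cutoff chosen so that every
chromosome keeps at least ``min_loci`` loci.

A chromosome whose fixed-threshold selection is empty is reported as
unclustered (a 0/0/0 block) rather than aborting the run; any other
per-chromosome failure is logged and the run continues.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cohort import INTERLEAVED, PairedCohort, read_cohort, to_unlabeled
from .cluster import (
    fuzzy_cmeans,
    kernel_kmeans,
    linear_kernel,
    lloyd_kmeans,
    rbf_kernel,
    write_assignment,
)
from .evaluate import (
    EvaluationRecord,
    build_report,
    compare_feature_sets,
    comparison_table,
    nmi,
    true_rate,
    write_report,
)
from .mic import mic_profile, write_profile
from .selection import LocusSelection, learn_threshold, reduce_matrix, select_loci, write_selection
from .simulate import SimulationConfig, generate_cohort

log = logging.getLogger("micclust")

ALGORITHMS = ("kernel-kmeans", "kmeans", "fuzzy-cmeans")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; seed is mandatory."""

    seed: int
    input_dir: str | Path | None = None
    simulate: SimulationConfig | None = None
    thresholds: list[float] = field(default_factory=lambda: [0.65, 0.52])
    learn: bool = True
    min_loci: int = 2
    algorithms: list[str] = field(default_factory=lambda: ["kernel-kmeans"])
    kernel: str = "rbf"
    bandwidth: float | str = "median"
    restarts: int = 10
    epsilon: float = 1e-6
    max_iter: int = 300
    fuzzifier: float = 2.0
    out_dir: str | Path = "results"
    write_artifacts: bool = True

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir or simulate must be given")
        bad = set(self.algorithms) - set(ALGORITHMS)
        if bad:
            raise ValueError(f"unknown algorithms {sorted(bad)}; choose from {ALGORITHMS}")
        if not self.algorithms:
            raise ValueError("at least one clustering algorithm is required")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")


@dataclass
class RunResult:
    records: list[EvaluationRecord]
    selections: dict[tuple[str, str], LocusSelection]
    learned_gamma: float | None
    report_paths: list[Path]
    failures: dict[str, str]


def _load_cohorts(config: RunConfig) -> dict[str, PairedCohort]:
    if config.simulate is not None:
        cohorts, _ = generate_cohort(config.simulate)
        return cohorts
    input_dir = Path(config.input_dir)
    paths = sorted(input_dir.glob("chr*.tsv"), key=lambda p: (len(p.stem), p.stem))
    if not paths:
        raise FileNotFoundError(f"no chr*.tsv cohort files under {input_dir}")
    return {p.stem: read_cohort(p, INTERLEAVED) for p in paths}


def _derived_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _cluster(algo: str, samples, config: RunConfig, seed: int):
    if algo == "kernel-kmeans":
        if config.kernel == "rbf":
            kern = rbf_kernel(samples, config.bandwidth)
        else:
            kern = linear_kernel(samples)
        return kernel_kmeans(
            kern, K=2, seed=seed, epsilon=config.epsilon,
            max_iter=config.max_iter, restarts=config.restarts, check_psd=False,
        )
    if algo == "kmeans":
        return lloyd_kmeans(
            samples, K=2, seed=seed, epsilon=config.epsilon,
            max_iter=config.max_iter, restarts=config.restarts,
        )
    return fuzzy_cmeans(
        samples, K=2, seed=seed, fuzzifier=config.fuzzifier,
        epsilon=config.epsilon, max_iter=config.max_iter,
    )


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis; returns records and writes report TSVs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohorts = _load_cohorts(config)
    chrom_ids = list(cohorts)

    log.info("run start: %d chromosomes, algorithms=%s, seed=%d",
             len(chrom_ids), config.algorithms, config.seed)
    profiles = {}
    failures: dict[str, str] = {}
    for cid, cohort in cohorts.items():
        try:
            profiles[cid] = mic_profile(cohort)
            log.info("%s: MIC profile over m=%d loci (n=%d)", cid, cohort.m, cohort.n)
            if config.write_artifacts:
                write_profile(profiles[cid], out_dir / f"mic_{cid}.tsv", loci=list(cohort.loci))
        except Exception as exc:  # noqa: BLE001 - per-chromosome isolation
            failures[cid] = f"mic: {exc}"
            log.error("%s: MIC profile failed: %s", cid, exc)

    configurations: list[tuple[str, float | None]] = [("EFS", None)]
    configurations += [(f"MIC>{thr:g}", thr) for thr in config.thresholds]
    learned_gamma = None
    if config.learn and profiles:
        learned_gamma = learn_threshold(list(profiles.values()), min_loci=config.min_loci)
        log.info("learned threshold across %d chromosomes: gamma = %.2f",
                 len(profiles), learned_gamma)
        configurations.append(("learned", learned_gamma))

    records: list[EvaluationRecord] = []
    selections: dict[tuple[str, str], LocusSelection] = {}
    for ci, cid in enumerate(chrom_ids):
        if cid in failures:
            continue
        cohort = cohorts[cid]
        profile = profiles[cid]
        try:
            samples = to_unlabeled(cohort)
            for cfg_i, (cfg_name, gamma) in enumerate(configurations):
                if gamma is None:
                    reduced = samples
                    v = cohort.m
                else:
                    sel = select_loci(profile, gamma, loci=list(cohort.loci))
                    selections[(cid, cfg_name)] = sel
                    if config.write_artifacts:
                        write_selection(sel, out_dir / f"selection_{cid}.tsv",
                                        append=cfg_i > 1)
                    if sel.v == 0:
                        log.info("%s [%s]: no locus above gamma=%.2f -> unclustered",
                                 cid, cfg_name, gamma)
                        for algo in config.algorithms:
                            records.append(EvaluationRecord(cid, _cfg_algo(cfg_name, algo),
                                                            0, 0.0, 0.0, clustered=False))
                        continue
                    reduced = reduce_matrix(samples, sel)
                    v = sel.v
                for ai, algo in enumerate(config.algorithms):
                    seed = _derived_seed(config.seed, ci, cfg_i, ai)
                    assignment = _cluster(algo, reduced, config, seed)
                    tr = true_rate(assignment, reduced.true_labels)
                    score = nmi(assignment, reduced.true_labels)
                    records.append(EvaluationRecord(cid, _cfg_algo(cfg_name, algo), v, tr, score))
                    log.info("%s [%s/%s]: v=%d TR=%.4f NMI=%.4f (iters=%d)",
                             cid, cfg_name, algo, v, tr, score, assignment.iterations)
                    if config.write_artifacts:
                        write_assignment(assignment, reduced.sample_ids,
                                         out_dir / f"assignment_{cid}_{_slug(cfg_name)}_{algo}.tsv")
        except Exception as exc:  # noqa: BLE001 - per-chromosome isolation
            failures[cid] = str(exc)
            log.error("%s: aborted: %s", cid, exc)

    report_paths = _write_reports(records, config, learned_gamma, out_dir)
    return RunResult(records=records, selections=selections, learned_gamma=learned_gamma,
                     report_paths=report_paths, failures=failures)


def _cfg_algo(cfg_name: str, algo: str) -> str:
    # the primary algorithm keeps the bare configuration name so that the
    # main report mirrors the standard three-block table
    return cfg_name if algo == "kernel-kmeans" else f"{cfg_name}[{algo}]"


def _slug(name: str) -> str:
    return name.replace(">", "_gt_").replace("[", "_").replace("]", "")


def _write_reports(records, config: RunConfig, learned_gamma, out_dir: Path) -> list[Path]:
    paths = []
    provenance = {
        "micclust": __version__,
        "seed": config.seed,
        "algorithms": ",".join(config.algorithms),
        "kernel": config.kernel,
        "learned_gamma": learned_gamma if learned_gamma is not None else "n/a",
    }
    primary = [r for r in records if "[" not in r.configuration]
    if primary:
        path = out_dir / "report_main.tsv"
        write_report(build_report(primary), path, provenance)
        paths.append(path)
        rfs = next((c for c in ("MIC>0.52", "learned") if any(r.configuration == c for r in primary)), None)
        if rfs and any(r.configuration == "EFS" for r in primary):
            comp = compare_feature_sets(primary, efs_config="EFS", rfs_config=rfs)
            if comp:
                path = out_dir / "report_comparison.tsv"
                write_report(comparison_table(comp).set_index("chromosome"), path,
                             {**provenance, "rfs_configuration": rfs})
                paths.append(path)
    baseline = [r for r in records if "[" in r.configuration]
    if baseline:
        path = out_dir / "report_baselines.tsv"
        write_report(build_report(baseline), path, provenance)
        paths.append(path)
    return paths


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level.upper())
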
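"""Synthetic paired tumor/blood copy-number cohorts.

The real study cohort (63 NSCLC patients, one snap-frozen tumor and one
blood sample each, per-locus CN scores roughly in [1, 3] around the diploid
baseline 2) is not deposited, so every pipeline stage is exercised on a
generative stand-in with the statistical structure the analysis assumes:

* Background loci: tumor and blood CN drawn independently as
  ``baseline + N(0, noise_sd^2)`` — no tumor-blood association, no group
  separation.
* Shared loci (contiguous segments): a per-patient, per-segment latent
  germline aberration enters *both* tissues, scaled so that the marginal
  spread at aberrant loci is ``aberration_sd`` and the tumor-blood
  correlation is ``dependence_strength**2``; the tumor sample additionally
  carries a recurrent somatic CN shift of magnitude ``tumor_shift`` whose
  gain/deletion sign is drawn per segment and shared by all patients, the
  way recurrent aberrations (characteristic arm-level gains and deletions)
  appear in real tumor cohorts.  These loci therefore exhibit (i) a high
  tumor-blood MIC and (ii) a tumor-specific displacement that separates the
  two groups — exactly the loci the MIC-threshold selection is supposed to
  recover.

All values are clipped to ``clip_range`` and every draw is derived from the
config seed, so cohorts are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import PairedCohort, default_patient_ids

#: per-chromosome locus counts of the study data (chromosomes 1..22)
STUDY_CHROMOSOME_SIZES: tuple[int, ...] = (
    19873, 22215, 18381, 19067, 17165, 17147, 13951, 14840, 11941, 14279,
    13307, 13061, 11118, 8181, 7014, 7024, 4854, 8149, 2693, 5838, 3936, 2520,
)


def _default_chromosomes() -> list[tuple[str, int]]:
    return [(f"chr{i + 1}", m) for i, m in enumerate(STUDY_CHROMOSOME_SIZES)]


@dataclass
class SimulationConfig:
    """Parameters of the paired-cohort generator.

    ``dependence_strength`` (rho) controls the tumor-blood correlation at
    shared loci (corr = rho^2 before clipping); ``tumor_shift`` (delta) is
    the somatic CN offset in copy-number units; ``aberration_sd`` the
    marginal CN spread at aberrant loci; ``noise_sd`` the background spread.
    """

    n_patients: int = 63
    chromosomes: list[tuple[str, int]] = field(default_factory=_default_chromosomes)
    shared_fraction: float = 0.01
    dependence_strength: float = 0.9
    tumor_shift: float = 0.15
    noise_sd: float = 0.15
    aberration_sd: float = 0.3
    baseline: float = 2.0
    clip_range: tuple[float, float] = (1.0, 3.0)
    segment_length: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not 0.0 <= self.dependence_strength <= 1.0:
            raise ValueError("dependence_strength must lie in [0, 1]")
        if self.noise_sd <= 0 or self.aberration_sd <= 0:
            raise ValueError("noise_sd and aberration_sd must be positive")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for cid, m in self.chromosomes:
            if m < 2:
                raise ValueError(f"chromosome {cid} must have at least 2 loci")
        if self.segment_length < 1:
            raise ValueError("segment_length must be at least 1")


@dataclass
class ChromosomeTruth:
    """Ground truth for one chromosome: which loci carry the planted signal."""

    chromosome_id: str
    shared_loci: list[int]  # 1-based locus indices
    segments: list[tuple[int, int]]  # (start, end) 1-based inclusive
    signs: np.ndarray  # per-segment recurrent sign, +1 gain / -1 deletion
    delta: float
    rho: float


@dataclass
class SyntheticTruth:
    """Generator parameters plus per-chromosome planted-locus indices."""

    config: SimulationConfig
    chromosomes: dict[str, ChromosomeTruth]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.config.seed,
            "delta": self.config.tumor_shift,
            "rho": self.config.dependence_strength,
            "chromosomes": {
                cid: {
                    "shared_loci": t.shared_loci,
                    "segments": [list(s) for s in t.segments],
                    "signs": t.signs.astype(int).tolist(),
                }
                for cid, t in self.chromosomes.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _place_segments(m: int, n_shared: int, seg_len: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Non-overlapping contiguous segments covering ~n_shared loci (0-based spans)."""
    if n_shared <= 0:
        return []
    n_segments = max(1, int(round(n_shared / seg_len)))
    lengths = np.full(n_segments, min(seg_len, m), dtype=int)
    lengths[-1] = max(1, n_shared - seg_len * (n_segments - 1))
    lengths = np.minimum(lengths, m)
    segments: list[tuple[int, int]] = []
    occupied = np.zeros(m, dtype=bool)
    for L in lengths:
        starts = [s for s in range(0, m - L + 1) if not occupied[s : s + L].any()]
        if not starts:
            break
        s = int(rng.choice(np.asarray(starts)))
        occupied[s : s + L] = True
        segments.append((s, s + int(L) - 1))
    return sorted(segments)


def _generate_chromosome(
    cid: str, m: int, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[PairedCohort, ChromosomeTruth]:
    n = cfg.n_patients
    rho = cfg.dependence_strength
    blood = cfg.baseline + cfg.noise_sd * rng.standard_normal((n, m))
    tumor = cfg.baseline + cfg.noise_sd * rng.standard_normal((n, m))
    n_shared = int(round(cfg.shared_fraction * m))
    if n_shared < 2:
        warnings.warn(
            f"{cid}: fewer than 2 shared loci planted ({n_shared}); "
            "threshold learning may be infeasible on this chromosome",
            stacklevel=2,
        )
    segments = _place_segments(m, n_shared, cfg.segment_length, rng)
    signs = np.empty(len(segments), dtype=float)
    indep = np.sqrt(max(0.0, 1.0 - rho * rho))
    for si, (s0, s1) in enumerate(segments):
        width = s1 - s0 + 1
        z = rng.standard_normal(n)  # latent germline aberration, shared by both tissues
        g = float(rng.choice(np.array([-1.0, 1.0])))  # recurrent somatic gain/deletion
        signs[si] = g
        common = cfg.aberration_sd * rho * z
        blood[:, s0 : s1 + 1] = (
            cfg.baseline
            + common[:, None]
            + cfg.aberration_sd * indep * rng.standard_normal((n, width))
        )
        tumor[:, s0 : s1 + 1] = (
            cfg.baseline
            + common[:, None]
            + cfg.aberration_sd * indep * rng.standard_normal((n, width))
            + cfg.tumor_shift * g
        )
    lo, hi = cfg.clip_range
    np.clip(blood, lo, hi, out=blood)
    np.clip(tumor, lo, hi, out=tumor)
    shared = sorted(j + 1 for s0, s1 in segments for j in range(s0, s1 + 1))
    cohort = PairedCohort(
        chromosome_id=cid,
        patient_ids=default_patient_ids(n),
        loci=list(range(1, m + 1)),
        cancer_cn=tumor,
        blood_cn=blood,
    )
    truth = ChromosomeTruth(
        chromosome_id=cid,
        shared_loci=shared,
        segments=[(s0 + 1, s1 + 1) for s0, s1 in segments],
        signs=signs,
        delta=cfg.tumor_shift,
        rho=rho,
    )
    return cohort, truth


def generate_cohort(config: SimulationConfig) -> tuple[dict[str, PairedCohort], SyntheticTruth]:
    """Generate one paired cohort per configured chromosome, plus ground truth."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.chromosomes))
    cohorts: dict[str, PairedCohort] = {}
    truths: dict[str, ChromosomeTruth] = {}
    for (cid, m), child in zip(config.chromosomes, children):
        cohort, truth = _generate_chromosome(cid, m, config, np.random.default_rng(child))
        cohorts[cid] = cohort
        truths[cid] = truth
    return cohorts, SyntheticTruth(config=config, chromosomes=truths)


def study_shaped_suite(seed: int, **overrides) -> tuple[dict[str, PairedCohort], SyntheticTruth]:
    """22 cohorts whose locus counts match the study's per-chromosome sizes."""
    config = SimulationConfig(seed=seed, **overrides)
    config.chromosomes = _default_chromosomes()
    return generate_cohort(config)
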
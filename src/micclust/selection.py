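"""MIC-threshold feature reduction.

A locus is kept when its MIC score strictly exceeds the threshold gamma.
Besides fixed thresholds, a common gamma can be learned across chromosomes
as the largest grid value that still leaves a minimum number of loci on
every chromosome — the formalization of choosing a single global cutoff
under the "at least two loci per chromosome" constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import UnlabeledSampleMatrix
from .mic import MICProfile


class NoFeasibleThresholdError(ValueError):
    """No grid value leaves the required number of loci on every chromosome."""


@dataclass
class LocusSelection:
    """The loci of one chromosome whose MIC exceeds gamma (strictly)."""

    chromosome_id: str
    gamma: float
    selected: list[int]  # 1-based locus indices, order preserved
    v: int
    m: int

    def __post_init__(self) -> None:
        if self.v != len(self.selected):
            raise ValueError("v must equal the number of selected loci")
        if self.v > self.m:
            raise ValueError("cannot select more loci than exist")


def select_loci(profile: MICProfile, gamma: float, loci: list[int] | None = None) -> LocusSelection:
    """Loci with MIC strictly greater than gamma, in locus order."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    loci = loci if loci is not None else list(range(1, profile.m + 1))
    if len(loci) != profile.m:
        raise ValueError("loci list must match profile length")
    selected = [locus for locus, s in zip(loci, profile.scores) if s > gamma]
    return LocusSelection(
        chromosome_id=profile.chromosome_id,
        gamma=float(gamma),
        selected=selected,
        v=len(selected),
        m=profile.m,
    )


def learn_threshold(
    profiles: list[MICProfile],
    min_loci: int = 2,
    grid: tuple[float, float, float] = (0.0, 0.99, 0.01),
) -> float:
    """Largest grid gamma leaving >= min_loci loci with MIC > gamma everywhere."""
    if not profiles:
        raise ValueError("at least one MIC profile is required")
    if min_loci < 1:
        raise ValueError("min_loci must be at least 1")
    start, stop, step = grid
    if step <= 0:
        raise ValueError("grid step must be positive")
    values = np.round(np.arange(start, stop + step / 2.0, step), 12)
    for gamma in values[::-1]:
        if all(int(np.sum(p.scores > gamma)) >= min_loci for p in profiles):
            return float(gamma)
    counts = [(int(np.sum(p.scores > values[0])), p.chromosome_id) for p in profiles]
    worst = min(counts)
    raise NoFeasibleThresholdError(
        f"no grid threshold leaves {min_loci} loci on every chromosome; "
        f"limiting chromosome {worst[1]} has only {worst[0]} loci above gamma = {values[0]}"
    )


def reduce_matrix(samples: UnlabeledSampleMatrix, selection: LocusSelection) -> UnlabeledSampleMatrix:
    """Column-subset copy keeping only the selected loci."""
    if selection.v == 0:
        raise ValueError("clustering requires >= 1 feature: selection is empty")
    index_of = {locus: j for j, locus in enumerate(samples.feature_ids)}
    try:
        cols = [index_of[locus] for locus in selection.selected]
    except KeyError as exc:
        raise IndexError(f"selected locus {exc.args[0]} is not in the sample matrix") from exc
    return UnlabeledSampleMatrix(
        sample_ids=list(samples.sample_ids),
        true_labels=samples.true_labels.copy(),
        values=samples.values[:, cols].copy(),
        feature_ids=list(selection.selected),
    )


def write_selection(selection: LocusSelection, path: str | Path, append: bool = False) -> None:
    mode = "a" if append else "w"
    new = not (append and Path(path).exists())
    with open(path, mode) as fh:
        if new or not append:
            fh.write("chromosome\tgamma\tv\tm\tselected\n")
        joined = ",".join(str(i) for i in selection.selected)
        fh.write(f"{selection.chromosome_id}\t{selection.gamma!r}\t{selection.v}\t{selection.m}\t{joined}\n")
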
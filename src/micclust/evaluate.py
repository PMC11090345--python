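"""Clustering evaluation against held-out tissue labels.

True rate (TR) is two-cluster accuracy under the better of the two possible
cluster-to-label mappings, so it is floored at 0.5.  NMI is the mutual
information between the clustering and the true partition normalized to
[0, 1] (geometric-mean normalization by default; the variant is selectable
because different normalizations differ on unbalanced partitions).

Two feature-set comparisons are reported between the entire feature set
(EFS) and a reduced feature set (RFS): the performance difference
PD = (TR_RFS - TR_EFS) x 100 and the adjusted performance difference
APD = (TR_RFS - TR_EFS) / TR_EFS x 100, both signed percents where positive
means the reduced set clusters better.  (The sign convention follows the
stated interpretation — positive = improvement under RFS.)
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment

#: canonical configuration names in report order
CONFIG_ORDER = ("EFS", "MIC>0.65", "MIC>0.52", "learned")


@dataclass
class EvaluationRecord:
    """One chromosome x configuration outcome: feature count, NMI, TR."""

    chromosome_id: str
    configuration: str
    feature_count: int
    true_rate: float
    nmi: float
    clustered: bool = True


@dataclass
class ComparisonRecord:
    chromosome_id: str
    tr_efs: float
    tr_rfs: float
    pd: float
    apd: float
    proportional_size: float


def _labels_of(assignment) -> np.ndarray:
    if isinstance(assignment, ClusterAssignment):
        return assignment.labels
    return np.asarray(assignment)


def true_rate(assignment, labels) -> float:
    """Best-of-two-mappings accuracy for the two-group problem."""
    clusters = _labels_of(assignment)
    labels = np.asarray(labels)
    if clusters.shape[0] != labels.shape[0]:
        raise ValueError("assignment and labels must have equal length")
    cluster_ids = np.unique(clusters)
    class_ids = np.unique(labels)
    if isinstance(assignment, ClusterAssignment) and assignment.K != 2:
        raise ValueError("true rate is defined for the two-cluster problem only")
    if cluster_ids.size > 2 or class_ids.size != 2:
        raise ValueError("true rate requires two clusters and two label classes")
    in_first = clusters == cluster_ids[0]
    is_a = labels == class_ids[0]
    acc1 = np.mean(in_first == is_a)
    acc2 = np.mean(in_first == ~is_a)
    return float(max(acc1, acc2))


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def nmi(assignment, labels, average: str = "geometric") -> float:
    """Normalized mutual information between a clustering and the truth."""
    clusters = _labels_of(assignment)
    labels = np.asarray(labels)
    if clusters.shape[0] != labels.shape[0] or clusters.shape[0] == 0:
        raise ValueError("assignment and labels must be nonempty and equal length")
    _, ci = np.unique(clusters, return_inverse=True)
    _, li = np.unique(labels, return_inverse=True)
    counts = np.zeros((ci.max() + 1, li.max() + 1))
    np.add.at(counts, (ci, li), 1.0)
    hc = _entropy(counts.sum(axis=1))
    hl = _entropy(counts.sum(axis=0))
    if hc == 0.0 or hl == 0.0:
        return 0.0
    mi = hc + hl - _entropy(counts.ravel())
    norm = {
        "geometric": math.sqrt(hc * hl),
        "arithmetic": (hc + hl) / 2.0,
        "min": min(hc, hl),
        "max": max(hc, hl),
    }
    if average not in norm:
        raise ValueError(f"unknown NMI normalization {average!r}")
    return float(min(max(mi / norm[average], 0.0), 1.0))


def performance_difference(tr_efs: float, tr_rfs: float) -> float:
    """PD in signed percent; positive = reduced feature set clusters better."""
    for r in (tr_efs, tr_rfs):
        if not 0.0 <= r <= 1.0:
            raise ValueError("true rates must lie in [0, 1]")
    return (tr_rfs - tr_efs) * 100.0


def adjusted_performance_difference(tr_efs: float, tr_rfs: float) -> float:
    """APD = PD relative to the EFS true rate, in signed percent."""
    for r in (tr_efs, tr_rfs):
        if not 0.0 <= r <= 1.0:
            raise ValueError("true rates must lie in [0, 1]")
    if tr_efs == 0.0:
        raise ValueError("APD undefined for TR_EFS = 0")
    return (tr_rfs - tr_efs) / tr_efs * 100.0


def proportional_size(v: int, m: int) -> float:
    """Reduced-set size as a percentage of the entire feature set."""
    if m <= 0:
        raise ValueError("m must be positive")
    if v < 0 or v > m:
        raise ValueError("need 0 <= v <= m")
    return v / m * 100.0


def _chromosome_sort_key(chromosome_id: str):
    m = re.search(r"(\d+)", str(chromosome_id))
    return (0, int(m.group(1))) if m else (1, str(chromosome_id))


def build_report(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Wide per-chromosome table: (features, NMI, TR) per configuration.

    Configurations with no selected loci render as a 0/0/0 block
    (clustered = False) rather than aborting.
    """
    if not records:
        raise ValueError("at least one evaluation record is required")
    seen = set()
    for r in records:
        key = (r.chromosome_id, r.configuration)
        if key in seen:
            raise ValueError(f"duplicate record for chromosome/configuration {key}")
        seen.add(key)
    configs = [c for c in CONFIG_ORDER if any(r.configuration == c for r in records)]
    extras = sorted({r.configuration for r in records} - set(configs))
    configs += extras
    chroms = sorted({r.chromosome_id for r in records}, key=_chromosome_sort_key)
    by_key = {(r.chromosome_id, r.configuration): r for r in records}
    rows = []
    for chrom in chroms:
        row: dict[str, object] = {"chromosome": chrom}
        for cfg in configs:
            r = by_key.get((chrom, cfg))
            if r is None or not r.clustered:
                feats, nmi_v, tr = (0, 0.0, 0.0) if r is not None else (np.nan, np.nan, np.nan)
            else:
                feats, nmi_v, tr = r.feature_count, round(r.nmi, 4), round(r.true_rate, 4)
            row[f"{cfg}__features"] = feats
            row[f"{cfg}__nmi"] = nmi_v
            row[f"{cfg}__true_rate"] = tr
        rows.append(row)
    return pd.DataFrame(rows).set_index("chromosome")


def compare_feature_sets(
    records: list[EvaluationRecord],
    efs_config: str = "EFS",
    rfs_config: str = "MIC>0.52",
) -> list[ComparisonRecord]:
    """Per-chromosome PD/APD/proportional-size between two configurations.

    Chromosomes where the reduced configuration selected no loci are skipped
    (they are reported as unclustered in the main table instead).
    """
    by_key = {(r.chromosome_id, r.configuration): r for r in records}
    chroms = sorted({r.chromosome_id for r in records}, key=_chromosome_sort_key)
    out = []
    for chrom in chroms:
        e = by_key.get((chrom, efs_config))
        r = by_key.get((chrom, rfs_config))
        if e is None or r is None or not (e.clustered and r.clustered):
            continue
        out.append(
            ComparisonRecord(
                chromosome_id=chrom,
                tr_efs=e.true_rate,
                tr_rfs=r.true_rate,
                pd=performance_difference(e.true_rate, r.true_rate),
                apd=adjusted_performance_difference(e.true_rate, r.true_rate),
                proportional_size=proportional_size(r.feature_count, e.feature_count),
            )
        )
    return out


def comparison_table(comparisons: list[ComparisonRecord]) -> pd.DataFrame:
    """Improvement-ranked table (best APD first)."""
    rows = [
        {
            "chromosome": c.chromosome_id,
            "tr_efs": round(c.tr_efs, 4),
            "tr_rfs": round(c.tr_rfs, 4),
            "pd_pct": round(c.pd, 1),
            "apd_pct": round(c.apd),
            "proportional_size_pct": round(c.proportional_size, 2),
        }
        for c in sorted(comparisons, key=lambda c: -c.apd)
    ]
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """TSV with '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t")
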
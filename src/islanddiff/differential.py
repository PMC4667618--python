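"""Fold-change classification, multi-stage calls, clustering, expression.

A region is called *decreased* when the pair-normalized WT/mutant tag ratio
exceeds 1.8 (strictly), *increased* when the mutant/WT ratio does, and
*unchanged* otherwise. A pseudocount (default 1 on the raw-count scale) is
added to both sides before the ratio so zero-count regions stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import GenomicRegion, Island, Peak

__all__ = [
    "DifferentialCall",
    "call_differential",
    "call_decreased_any_stage",
    "call_induced_islands",
    "kmeans_cluster",
    "select_probe_set",
    "dynamic_expression_filter",
    "percent_input",
    "h3_normalized",
]

FOLD_CHANGE_THRESHOLD = 1.8
DYNAMIC_RANGE_FOLD = 4.0


@dataclass(frozen=True)
class DifferentialCall:
    """A WT-vs-mutant fold-change call for one region."""

    region: GenomicRegion
    wt_count: float
    mut_count: float
    fc: float  # mutant / WT, pseudocounted
    label: str  # decreased | increased | unchanged
    stage: str = ""

    @property
    def relative_density(self) -> tuple[float, float]:
        """(WT, mutant) normalized tag count per bp of region."""
        L = self.region.length
        return self.wt_count / L, self.mut_count / L


def call_differential(
    regions: Sequence[GenomicRegion],
    wt_counts: np.ndarray,
    mut_counts: np.ndarray,
    threshold: float = FOLD_CHANGE_THRESHOLD,
    pseudocount: float = 1.0,
    stage: str = "",
    use_density: bool = False,
) -> list[DifferentialCall]:
    """Classify each region as decreased/increased/unchanged.

    Counts must already be pair-normalized over identical regions. The
    ratio is computed on ``count + pseudocount``; with ``use_density`` the
    threshold is applied to length-scaled counts instead (the pseudocount
    is then also per-bp-scaled, so the two modes agree when all regions
    have equal length).
    """
    wt = np.asarray(wt_counts, dtype=float)
    mut = np.asarray(mut_counts, dtype=float)
    if wt.shape != mut.shape or len(wt) != len(regions):
        raise ValueError("regions, wt_counts and mut_counts must align")
    if (wt < 0).any() or (mut < 0).any():
        raise ValueError("negative tag counts")
    calls = []
    for reg, w, m in zip(regions, wt, mut):
        if use_density:
            w_eff = (w + pseudocount) / reg.length
            m_eff = (m + pseudocount) / reg.length
        else:
            w_eff, m_eff = w + pseudocount, m + pseudocount
        fc = m_eff / w_eff
        if 1.0 / fc > threshold:
            label = "decreased"
        elif fc > threshold:
            label = "increased"
        else:
            label = "unchanged"
        calls.append(DifferentialCall(reg, float(w), float(m), float(fc), label, stage))
    return calls


def call_decreased_any_stage(
    per_stage_calls: Mapping[str, Sequence[DifferentialCall]],
) -> set[GenomicRegion]:
    """Regions called decreased in at least one WT/mutant stage pair."""
    out: set[GenomicRegion] = set()
    for calls in per_stage_calls.values():
        out.update(c.region for c in calls if c.label == "decreased")
    return out


def call_induced_islands(
    pre_counts: Mapping[GenomicRegion, float],
    post_counts: Mapping[GenomicRegion, float],
    peaks: Sequence[Peak],
    threshold: float = FOLD_CHANGE_THRESHOLD,
    pseudocount: float = 1.0,
) -> set[GenomicRegion]:
    """Islands induced by a stimulus and bound by the factor.

    Keeps regions whose post/pre ratio exceeds the threshold *and* that
    overlap at least one peak. ``pre_counts``/``post_counts`` are keyed by
    the same regions (pre-missing regions count 0).
    """
    out: set[GenomicRegion] = set()
    for region, post in post_counts.items():
        pre = pre_counts.get(region, 0.0)
        if (post + pseudocount) / (pre + pseudocount) <= threshold:
            continue
        if any(region.overlaps(p.region) for p in peaks):
            out.add(region)
    return out


def kmeans_cluster(
    matrix: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    standardize_rows: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means row clustering of a tag-density (or expression) matrix.

    Rows are mean/SD standardized by default (constant rows map to zero),
    then clustered with Euclidean k-means over ``n_restarts`` restarts and
    a fixed seed, keeping the assignment with the lowest within-cluster sum
    of squares. Returns (labels, cluster centers).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("matrix must be finite")
    if k < 1 or k > X.shape[0]:
        raise ValueError(f"k must be in [1, n_rows={X.shape[0]}], got {k}")
    if standardize_rows:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def select_probe_set(probe_records: pd.DataFrame) -> str:
    """Pick one probe set for a gene: highest expression x fold-change score.

    ``probe_records`` is indexed by probe-set id with columns ``expression``
    and ``fc``; the score is their product and ties go to the first probe
    set in identifier order.
    """
    if probe_records.empty:
        raise ValueError("no probe sets for gene")
    df = probe_records.sort_index()
    score = df["expression"] * df["fc"]
    return str(score.idxmax())  # idxmax returns the first maximum


def dynamic_expression_filter(
    expression: pd.DataFrame,
    sample_columns: Sequence[str] | None = None,
    fold: float = DYNAMIC_RANGE_FOLD,
) -> set[str]:
    """Genes whose linear-scale max/min across samples strictly exceeds 4x.

    ``expression`` is the probe-set matrix from
    :func:`islanddiff.io.read_expression`; a gene passes if any of its
    probe sets does.
    """
    if sample_columns is None:
        sample_columns = [c for c in expression.columns if c != "gene_id"]
    vals = expression[list(sample_columns)].astype(float)
    if (vals <= 0).any().any():
        raise ValueError("dynamic-range filter needs positive linear-scale values")
    ratio = vals.max(axis=1) / vals.min(axis=1)
    passing = ratio > fold
    return set(expression.loc[passing, "gene_id"])


def percent_input(ab: float, igg: float, input_1pct: float) -> float:
    """ChIP-qPCR percent input: ((ab ChIP) - (IgG ChIP)) / 1% input.

    Negative background-subtracted signal is clamped to 0.
    """
    if input_1pct <= 0:
        raise ValueError("input_1pct must be positive")
    return max(ab - igg, 0.0) / input_1pct


def h3_normalized(k27_ab: float, igg: float, h3_ab: float) -> float:
    """H3-normalized ChIP-qPCR: ((K27 ChIP) - IgG) / ((H3 ChIP) - IgG)."""
    denom = h3_ab - igg
    if denom == 0:
        raise ValueError("H3 signal equals IgG background; ratio undefined")
    return max(k27_ab - igg, 0.0) / denom
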
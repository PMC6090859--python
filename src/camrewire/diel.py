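"""Cross-species diel expression phase-shift detection.

Two species sampled on different grids over one 12 h light : 12 h dark cycle
(CAM species every 3 h at 0,3,...,21 h; C3 reference every 4 h at
0,4,...,24 h after lights-on) are brought onto the union grid
{0,3,4,6,8,9,12,15,16,18,20,21} by shape-preserving piecewise-cubic
interpolation with periodic (24 h) extension, Z-scored, and compared by the
clock bin of their peak expression.  A gene whose C3 ortholog peaks in the
morning while the CAM gene peaks at night is a morning-to-night shift; a C3
afternoon peak opposite a CAM late-night peak is an afternoon-to-night shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.interpolate import PchipInterpolator

__all__ = [
    "AGAVE_GRID",
    "ARABIDOPSIS_GRID",
    "COMMON_GRID",
    "PHASE_BINS",
    "DielSeries",
    "DielPair",
    "ShiftCall",
    "filter_expressed",
    "interpolate_to_grid",
    "zscore",
    "peak_phase",
    "phase_bin",
    "classify_shift",
    "pair_orthologs",
    "cluster_pairs",
]

AGAVE_GRID = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0)
ARABIDOPSIS_GRID = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
#: union of the two sampling grids (24 h identified with 0 h)
COMMON_GRID = (0.0, 3.0, 4.0, 6.0, 8.0, 9.0, 12.0, 15.0, 16.0, 18.0, 20.0, 21.0)

#: half-open clock bins, hours after lights-on under a 12:12 photoperiod
PHASE_BINS = {
    "morning": (0.0, 6.0),
    "afternoon": (6.0, 12.0),
    "early_night": (12.0, 18.0),
    "late_night": (18.0, 24.0),
}

PERIOD_H = 24.0


@dataclass(frozen=True)
class DielSeries:
    """One gene's expression time course over a single diel cycle."""

    gene_id: str
    species: str
    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if len(t) != len(self.values):
            raise ValueError(f"{self.gene_id}: times/values length mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.gene_id}: times must be strictly increasing")
        if t.min() < 0 or t.max() > PERIOD_H:
            raise ValueError(f"{self.gene_id}: times must lie in [0, 24]")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times, float), np.asarray(self.values, float)


@dataclass(frozen=True)
class DielPair:
    """An ortholog pair's interpolated, Z-scored profiles on the common grid."""

    pair_id: str
    series_a: DielSeries  # CAM species
    series_b: DielSeries  # C3 reference species


@dataclass(frozen=True)
class ShiftCall:
    pair_id: str
    peak_a: float | None
    peak_b: float | None
    bin_a: str | None
    bin_b: str | None
    shift_class: str  # morning_to_night | afternoon_to_night | none
    reason: str = ""


def filter_expressed(
    matrix: pd.DataFrame, min_samples: int = 4, min_mean: float = 5.0
) -> pd.DataFrame:
    """Keep genes detected (> 0) in >= min_samples samples with mean >= min_mean.

    Mirrors the standard expressed-transcript pre-filter for RPKM matrices
    (detection in at least 4 of 15 samples at a 5 RPKM average).
    """
    if matrix.empty:
        return matrix
    detected = (matrix > 0).sum(axis=1) >= min_samples
    abundant = matrix.mean(axis=1) >= min_mean
    return matrix.loc[detected & abundant]


def _periodic_pchip(times: np.ndarray, values: np.ndarray) -> PchipInterpolator:
    # collapse a trailing 24 h sample onto 0 h, then tile one period each side
    mask = times < PERIOD_H
    t0 = times[mask] % PERIOD_H
    v0 = values[mask]
    order = np.argsort(t0)
    t0, v0 = t0[order], v0[order]
    t_ext = np.concatenate([t0 - PERIOD_H, t0, t0 + PERIOD_H])
    v_ext = np.tile(v0, 3)
    return PchipInterpolator(t_ext, v_ext)


def interpolate_to_grid(
    series: DielSeries, grid: Sequence[float] = COMMON_GRID
) -> DielSeries:
    """Resample a diel series onto a target grid.

    Uses monotone (shape-preserving) piecewise-cubic Hermite interpolation on
    the periodically extended course, so values never overshoot neighbouring
    samples and original sample times are reproduced exactly.
    """
    t, v = series.as_arrays()
    if len(t) < 4:
        raise ValueError(f"{series.gene_id}: need >= 4 timepoints, got {len(t)}")
    interp = _periodic_pchip(t, v)
    out = interp(np.asarray(grid, float))
    return replace(series, times=tuple(grid), values=tuple(float(x) for x in out))


class ConstantSeriesError(ValueError):
    """A flat series carries no phase information and cannot be Z-scored."""


def zscore(series: DielSeries) -> DielSeries:
    """Z-score transform (population denominator) over the series' grid."""
    _, v = series.as_arrays()
    sd = v.std()
    if sd == 0:
        raise ConstantSeriesError(f"{series.gene_id}: constant series")
    z = (v - v.mean()) / sd
    return replace(series, values=tuple(float(x) for x in z))


def phase_bin(hour: float) -> str:
    h = hour % PERIOD_H
    for name, (lo, hi) in PHASE_BINS.items():
        if lo <= h < hi:
            return name
    raise AssertionError("bins tile [0, 24)")


def peak_phase(series: DielSeries) -> tuple[float, str]:
    """Grid time of maximum value (earliest wins ties) and its clock bin."""
    t, v = series.as_arrays()
    idx = int(np.argmax(v))  # argmax returns the first maximum
    return float(t[idx]), phase_bin(float(t[idx]))


def classify_shift(pair: DielPair) -> ShiftCall:
    """Classify an ortholog pair's diel phase relationship.

    morning_to_night: C3 peak in the morning bin, CAM peak in either night
    bin.  afternoon_to_night: C3 peak in the afternoon bin, CAM peak in the
    late-night bin.  Anything else (including unclassifiable flat series) is
    none.
    """
    try:
        za = zscore(pair.series_a)
        zb = zscore(pair.series_b)
    except ConstantSeriesError as exc:
        return ShiftCall(pair.pair_id, None, None, None, None, "none", str(exc))
    peak_a, bin_a = peak_phase(za)
    peak_b, bin_b = peak_phase(zb)
    if bin_b == "morning" and bin_a in ("early_night", "late_night"):
        cls = "morning_to_night"
    elif bin_b == "afternoon" and bin_a == "late_night":
        cls = "afternoon_to_night"
    else:
        cls = "none"
    return ShiftCall(pair.pair_id, peak_a, peak_b, bin_a, bin_b, cls)


def pair_orthologs(
    rbh_pairs: Iterable[tuple[str, str]],
    groups: Iterable["OrthologGroup"],  # noqa: F821 - clades.OrthologGroup
) -> tuple[list[tuple[str, str]], list[str]]:
    """Intersect reciprocal-best-hit pairs with ortholog-group co-membership.

    A pair is retained iff its two genes co-occur in at least one ortholog
    group.  When one gene occurs in several retained pairs, all of its pairs
    are rejected and reported (RBH should be one-to-one; conflicts signal an
    upstream problem rather than data to be guessed at).

    Returns (kept_pairs, rejection_report).
    """
    gene_groups: dict[str, set[str]] = {}
    for g in groups:
        for members in g.members.values():
            for gene in members:
                gene_groups.setdefault(gene, set()).add(g.group_id)
    report: list[str] = []
    comember: list[tuple[str, str]] = []
    for a, b in rbh_pairs:
        if gene_groups.get(a, set()) & gene_groups.get(b, set()):
            comember.append((a, b))
        else:
            report.append(f"dropped {a}/{b}: no shared ortholog group")
    seen: dict[str, int] = {}
    for a, b in comember:
        seen[a] = seen.get(a, 0) + 1
        seen[b] = seen.get(b, 0) + 1
    kept = []
    for a, b in comember:
        if seen[a] > 1 or seen[b] > 1:
            report.append(f"rejected {a}/{b}: gene in conflicting pairs")
        else:
            kept.append((a, b))
    return kept, report


def cluster_pairs(
    pairs: Sequence[DielPair], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage hierarchical clustering of concatenated pair profiles.

    Each pair contributes the concatenation (series_a ++ series_b) of its
    Z-scored common-grid profiles; distances are Euclidean.  Returns
    (labels, linkage matrix); labels are 1-based cluster ids as assigned by a
    ``maxclust`` cut at ``k``.
    """
    if len(pairs) < 1:
        raise ValueError("no pairs to cluster")
    X = np.array(
        [np.concatenate([p.series_a.values, p.series_b.values]) for p in pairs]
    )
    if len(pairs) == 1:
        return np.array([1]), np.empty((0, 4))
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels, Z
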